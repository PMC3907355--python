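"""Reference study-cohort bookkeeping.

Descriptions of the whole-genome-sequenced family and control cohorts on
which the excess-IBD mask and the default model settings were
established: 30 families (258 sequenced members, 1490 documented pairwise
relationships) and 46 population controls in three groups (34 European,
8 East Asian, 4 Mexican-American; 595 control pairs in all).  These
numbers parameterize validation bookkeeping; no genotype or segment data
are included.
"""

from __future__ import annotations

from math import comb

#: number of sequenced members in each of the 30 reference families
FAMILY_SIZES = (16, 7, 25, 10, 4, 5, 5, 7, 10, 4, 17, 4, 4, 5, 4, 15, 10, 7,
                7, 8, 9, 15, 4, 4, 4, 4, 4, 6, 25, 9)

#: control-group sizes: European, East Asian, Mexican-American
CONTROL_GROUP_SIZES = {"CEU": 34, "ASI": 8, "MXL": 4}


def pairwise_relationships(sizes=FAMILY_SIZES) -> int:
    """Total within-family pairs, sum of n*(n-1)/2 over family sizes."""
    return sum(comb(n, 2) for n in sizes)


def control_pair_counts(sizes=None) -> dict[str, int]:
    """Within-group control pair counts (n choose 2 per group)."""
    sizes = sizes or CONTROL_GROUP_SIZES
    return {k: comb(n, 2) for k, n in sizes.items()}


def total_control_pairs() -> int:
    return sum(control_pair_counts().values())
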