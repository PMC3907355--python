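"""Detect and mask a genomic region with excess IBD in controls.

Plants an artifact-prone region (every control pair "shares" the same
6 cM of chromosome 5, as centromeric or assembly-gap artifacts do) on top
of uniform cryptic sharing, scans the genome in 0.5 cM windows, builds a
mask from windows whose observed/expected IBD ratio exceeds h = 4, and
applies it.  Masking removes the spurious sharing and reduces the
expected recombination count r by m/100 so that the relationship models
stay calibrated.  The packaged mask of 14 known problem regions of the
hg19 assembly is also shown.
"""

import numpy as np

from ibdrel import (apply_mask, build_mask, excess_ibd_scan,
                    known_excess_regions, make_synthetic_map)
from ibdrel.io import IBDSegment, SegmentSet, pair_key
from ibdrel.masking import adjust_r, mask_total_cM
from ibdrel.simulate import synthetic_unrelated_cohort

gmap = make_synthetic_map(seed=1)
rng = np.random.default_rng(3)

controls, manifest = synthetic_unrelated_cohort(600, gmap, rng)
lo, _ = gmap.chrom_span_cM("5")
artifact = [IBDSegment(pair_key(f"C{2*i}", f"C{2*i+1}"), "5",
                       int(gmap.interpolate_bp("5", lo + 30)),
                       int(gmap.interpolate_bp("5", lo + 36)),
                       lo + 30, lo + 36, 6.0) for i in range(600)]
cohort = SegmentSet(list(controls) + artifact)

scan = excess_ibd_scan(cohort, gmap, window_cM=0.5)
mask = build_mask(scan, h=4.0)
print(f"scan: {len(scan)} windows, max observed/expected ratio "
      f"{scan['ratio'].max():.1f}")
for region in mask:
    print(f"mask region: chr{region.chrom} {region.length_cM:.2f} cM, "
          f"ratio {region.observed_expected_ratio:.1f}")

masked, m = apply_mask(cohort, mask, gmap)
print(f"m = {m:.2f} cM masked; segments {len(cohort)} -> {len(masked)}; "
      f"r adjusted {35.0:.2f} -> {adjust_r(35.0, m):.4f}")

hg19 = known_excess_regions()
print(f"\npackaged hg19 mask: {len(hg19)} regions, "
      f"m = {mask_total_cM(hg19):.2f} cM "
      f"(r = 35 -> {adjust_r(35.0, mask_total_cM(hg19)):.4f})")
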