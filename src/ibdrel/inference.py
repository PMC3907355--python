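"""Maximum-likelihood relationship classification.

For each pair, every hypothesis (d, a) on a grid is scored by the
likelihood that some number np of the pair's IBD segments follow the
relationship's count/length model while the remaining segments follow
the control-population background; np is maximized, with the np longest
segments attributed to the relationship.  The best hypothesis is tested
against the background-only null with a likelihood-ratio test on 2
degrees of freedom (one for np, one for the (d, a) profile); a pair is
reported related when p < alpha (default 0.001), and the (d, a)
hypotheses within the chi-square confidence region (default 0.999) form
the confidence set.

Parent-offspring pairs are IBD1 across the whole genome with no
stochasticity, so they are recognized by a deterministic threshold on
the genome-wide IBD fraction rather than by likelihood (the threshold is
z full-sibling standard deviations above the sibling expectation 0.75).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .background import BackgroundModel, null_loglik
from .errors import InputError, ParameterError
from .io import IBD2, IBDSegment, SegmentSet, merge_pair_extents, pair_key
from .models import (ModelParams, RelationshipHypothesis, conditioned_models,
                     parent_offspring_test, sibling_ibd2_loglik)

logger = logging.getLogger(__name__)


def _poisson_logpmf(k, mu: float):
    """Poisson log-pmf that tolerates mu == 0 (point mass at 0)."""
    k = np.asarray(k, dtype=float)
    if mu == 0.0:
        return np.where(k == 0, 0.0, -math.inf)
    return k * math.log(mu) - mu - gammaln(k + 1.0)


@dataclass
class PairResult:
    """Classification outcome for one pair."""

    pair: tuple[str, str]
    best_hypothesis: RelationshipHypothesis | None  # None = unrelated
    max_loglik: float
    null_loglik: float
    p_value: float
    confidence_set: list[tuple[int, int]] = field(default_factory=list)
    n_attributed: int = 0
    n_segments: int = 0
    total_ibd_fraction: float = 0.0

    @property
    def related(self) -> bool:
        return self.best_hypothesis is not None

    @property
    def degree(self) -> int | None:
        return self.best_hypothesis.degree if self.best_hypothesis else None

    @property
    def family(self) -> str:
        return self.best_hypothesis.family if self.best_hypothesis else "unrelated"


def hypothesis_grid(params: ModelParams) -> list[RelationshipHypothesis]:
    """All hypotheses d = 1..d_max, a in {0, 1, 2}, ordered by d then a
    (closer relationships first, which also fixes tie-breaking)."""
    if params.d_max < 1:
        raise ParameterError("d_max must be >= 1")
    grid = []
    for d in range(1, params.d_max + 1):
        for a in (0, 1, 2):
            if a >= 1 and d < 2:
                continue
            grid.append(RelationshipHypothesis(d=d, a=a))
    return grid


def alternative_loglik(lengths, hyp: RelationshipHypothesis,
                       background: BackgroundModel, params: ModelParams
                       ) -> tuple[float, int]:
    """Maximized log-likelihood of one pair's segment lengths under a
    relationship hypothesis, and the maximizing number of attributed
    segments.

    The likelihood attributes np segments to the relationship's
    conditioned Poisson/length model and the remaining n - np to the
    background; the np longest segments are attributed, and np runs over
    0..n.  All lengths must already be >= t and mask-adjusted.
    """
    lengths = np.sort(np.asarray(list(lengths), dtype=float))[::-1]
    n = lengths.size
    if np.any(lengths < params.t):
        raise InputError(f"segment length below t={params.t}")
    lam, logpdf = conditioned_models(hyp, params)
    log_rel = logpdf(lengths) if n else np.empty(0)
    if background.degenerate:
        log_bg = np.full(n, -math.inf)
    else:
        log_bg = background.length_logpdf(lengths)
    rel_prefix = np.concatenate([[0.0], np.cumsum(log_rel)])
    bg_suffix = np.concatenate([np.cumsum(log_bg[::-1])[::-1], [0.0]])
    ks = np.arange(n + 1)
    ll = (_poisson_logpmf(ks, lam) + rel_prefix
          + _poisson_logpmf(n - ks, background.count_mean) + bg_suffix)
    best = int(np.argmax(ll))
    return float(ll[best]), best


def prepare_pair(segments: list[IBDSegment], params: ModelParams
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Reduce one pair's raw segments to classifier inputs.

    Returns (half-identity extent lengths >= t, IBD2 lengths >= t, total
    half-identity coverage in cM).  Overlapping segments are merged into
    half-identity extents first, so both detector conventions (merged
    IBD1-only, or IBD1 extents with overlapping IBD2 segments) reduce to
    the same representation.  Every IBD2 segment must lie within a
    half-identity extent.
    """
    merged = merge_pair_extents(segments)
    ibd2 = [s for s in segments if s.state == IBD2]
    ibd1_extents = merge_pair_extents([s for s in segments
                                       if s.state != IBD2])
    for s in ibd2:
        inside = any(m.chrom == s.chrom
                     and m.start_cM <= s.start_cM + 1e-6
                     and m.end_cM >= s.end_cM - 1e-6 for m in ibd1_extents)
        if not inside:
            raise InputError(
                f"IBD2 segment {s.pair} {s.chrom}:{s.start_cM:.3f}-"
                f"{s.end_cM:.3f} lies outside every IBD1 extent")
    total_cM = float(sum(m.length_cM for m in merged))
    ibd1_lengths = np.array([m.length_cM for m in merged
                             if m.length_cM >= params.t])
    ibd2_lengths = np.array([s.length_cM for s in ibd2
                             if s.length_cM >= params.t])
    return ibd1_lengths, ibd2_lengths, total_cM


def classify_pair(pair: tuple[str, str], segments: list[IBDSegment],
                  background: BackgroundModel, params: ModelParams,
                  grid: list[RelationshipHypothesis] | None = None
                  ) -> PairResult:
    """Classify one pair from its (mask-adjusted) segments.

    The global maximum-likelihood hypothesis is tested against the
    background-only null (2-df chi-square LRT); ties in log-likelihood
    resolve to the smaller d.  The parent-offspring threshold rule takes
    precedence over the likelihood ranking when it fires.  With
    ``params.use_ibd2_siblings`` and explicit IBD2 segments present, the
    full-sibling hypothesis scores the IBD2 data under the sibling IBD2
    model while every other hypothesis (and the null) scores it under the
    background-derived IBD2 null.
    """
    pair = pair_key(*pair)
    if grid is None:
        grid = hypothesis_grid(params)
    if not grid:
        raise ParameterError("empty hypothesis grid")
    ibd1, ibd2, total_cM = prepare_pair(segments, params)
    n = ibd1.size
    fraction = min(total_cM / params.total_cM, 1.0)

    null = null_loglik(ibd1, background)

    use_ibd2 = params.use_ibd2_siblings and ibd2.size > 0
    alt_i2 = null_i2 = 0.0
    if use_ibd2:
        alt_i2, null_i2 = sibling_ibd2_loglik(ibd2, total_cM, params,
                                              background)
        null += null_i2

    best_hyp = None
    best_ll = -math.inf
    best_np = 0
    lls = []
    for hyp in grid:
        ll, n_attr = alternative_loglik(ibd1, hyp, background, params)
        if use_ibd2:
            ll += alt_i2 if hyp.family == "full_sibling" else null_i2
        lls.append(ll)
        if ll > best_ll:  # strict: grid order favors smaller d on ties
            best_hyp, best_ll, best_np = hyp, ll, n_attr

    if math.isinf(null) and math.isinf(best_ll):
        lrt = 0.0  # nothing scoreable: no evidence either way
    elif math.isinf(null):
        lrt = math.inf  # data impossible under the null
    else:
        lrt = max(2.0 * (best_ll - null), 0.0)
    p_value = float(stats.chi2.sf(lrt, df=2))

    cut = stats.chi2.ppf(params.confidence_level, df=params.confidence_df) / 2.0
    confidence = [(h.d, h.a) for h, ll in zip(grid, lls)
                  if ll >= best_ll - cut and math.isfinite(ll)]

    if parent_offspring_test(fraction, params):
        po = RelationshipHypothesis(d=1, a=0)
        return PairResult(pair, po, best_ll, null, p_value,
                          confidence_set=[(1, 0)], n_attributed=n,
                          n_segments=n, total_ibd_fraction=fraction)

    related = p_value < params.alpha
    return PairResult(pair, best_hyp if related else None, best_ll, null,
                      p_value, confidence_set=confidence if related else [],
                      n_attributed=best_np if related else 0,
                      n_segments=n, total_ibd_fraction=fraction)


def run_cohort(segments: SegmentSet, pairs, background: BackgroundModel,
               params: ModelParams, mask=None,
               genetic_map=None) -> list[PairResult]:
    """Classify every requested pair; deterministic given inputs.

    When a mask is supplied (with its genetic map), it is applied to the
    segment set once and r is reduced by m/100 before classification.
    Pairs listed without any segment are classified from the empty set
    (always unrelated).
    """
    if mask:
        from .masking import apply_mask
        if genetic_map is None:
            raise ParameterError("masking requires the genetic map")
        segments, m = apply_mask(segments, mask, genetic_map,
                                 b_mb=params.b_mb)
        params = params.with_masking(m)
    by_pair = segments.by_pair()
    grid = hypothesis_grid(params)
    results = []
    for p in pairs:
        key = pair_key(*p)
        segs = by_pair.get(key, [])
        if not segs:
            logger.warning("pair %s has no segments; classifying as empty", key)
        results.append(classify_pair(key, segs, background, params, grid))
    return results


RESULT_COLUMNS = ["id1", "id2", "related", "d", "a", "family", "degree",
                  "n_segments", "n_attributed", "max_loglik", "null_loglik",
                  "p_value", "ibd_fraction", "confidence_set"]


def results_table(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        hyp = r.best_hypothesis
        conf = ";".join(f"{d},{a}" for d, a in r.confidence_set)
        rows.append((r.pair[0], r.pair[1], r.related,
                     hyp.d if hyp else 0, hyp.a if hyp else -1,
                     r.family, r.degree if hyp else 0,
                     r.n_segments, r.n_attributed,
                     r.max_loglik, r.null_loglik, r.p_value,
                     r.total_ibd_fraction, conf))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[PairResult], path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False,
                                  float_format="%.6g")
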