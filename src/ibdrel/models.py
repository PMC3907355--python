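"""Relationship-specific IBD segment distributions.

A hypothesized relationship is parameterized by ``d``, the total number
of meioses separating the pair along the connecting path(s), and ``a``,
the number of shared recent ancestors (2 full relatives, 1 half
relatives, 0 direct ancestor-descendant).  Under a hypothesis, the
number of IBD segments shared by the pair is Poisson and segment lengths
are exponential (full siblings use a gamma mixture; see below), with

* mean segment length ``100/d`` cM for full relatives (a = 2), and
  ``100/(d + c/r)`` for a in {0, 1}, which additionally accounts for
  segments broken at chromosome boundaries (c autosomes, r expected
  crossovers per generation, r ~ 35 in humans).  The two forms converge
  as d grows;
* mean segment count ``a (r d + c) / 2^(d-1)``.

Direct ancestor-descendant pairs differ in that recombinations in the
first meiosis are invisible to a pairwise comparison, so d is replaced
by d - 1 in both forms (for parent-offspring, d = 1, this degenerates to
c segments covering the whole genome, which is why that relationship is
handled by a deterministic total-sharing threshold instead of a
likelihood).

Full siblings are special because detectors that cannot see diploid
identity (IBD2) splice IBD1 segments together across IBD2 stretches and
report one long half-identity segment.  With k spliced joins the length
is modelled as a Gamma(k + 1, 50 cM) and k is given a geometric weight;
the expected number of half-identity segments is ``r + 3c/4``, which is
also the expected segment count of an avuncular pair (every sibling IBD2
stretch is avuncular IBD1, and splitting/inheritance effects cancel at
probability ~1/2 each).  When IBD2 segments are reported explicitly, a
sibling-specific IBD2 model applies: their count is Poisson with mean
``r + c/4`` and lengths are approximately exponential with mean 25 cM.

Whenever a minimum segment length t > 0 is in force (default 2.5 cM),
every count mean is multiplied by P(length >= t) under the hypothesis's
length law and every density is renormalized on [t, inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InputError, ParameterError

# ---------------------------------------------------------------------------
# calibrated constants (all from the package's own gene-dropping simulator;
# seeds and sample sizes in docs/methods.md)
# ---------------------------------------------------------------------------

#: standard deviation of the genome-wide IBD fraction (half-identity
#: coverage / map length) among full-sibling pairs; used by the
#: parent-offspring threshold 0.75 + z * SIGMA_SIB.  Estimated from
#: 10^4 gene-dropped sibling pairs on the default 3500 cM map (seed 7).
SIGMA_SIB = 0.0435

#: geometric decay of the full-sibling splice-count mixture: w(k) ∝ q^k.
#: Maximum-likelihood fit to the half-identity segment lengths of the
#: same 10^4 simulated sibling pairs, with the per-piece scale pinned at
#: the plain sibling exponential mean (50 cM).
SIB_MIX_Q = 0.0188

#: truncation of the sibling mixture sum over k.
SIB_MIX_KMAX = 30

#: mean length (cM) of a full-sibling IBD2 segment.
SIB_IBD2_MEAN_CM = 25.0

FAMILIES = ("parent_offspring", "ancestor_descendant", "full_sibling",
            "avuncular", "generic")


@dataclass(frozen=True)
class RelationshipHypothesis:
    """A (d, a) relationship hypothesis with its model family and degree.

    degree = d - 1 for full relatives (a = 2), else d; so full siblings
    are 1st degree, avuncular/grandparent/half-sibling 2nd degree.
    """

    d: int
    a: int

    def __post_init__(self):
        if self.d < 1 or self.a not in (0, 1, 2):
            raise ParameterError(f"invalid hypothesis d={self.d}, a={self.a}")
        if self.a in (1, 2) and self.d < 2:
            raise ParameterError(f"a={self.a} requires d >= 2")

    @property
    def family(self) -> str:
        if self.a == 0:
            return "parent_offspring" if self.d == 1 else "ancestor_descendant"
        if self.a == 2 and self.d == 2:
            return "full_sibling"
        if self.a == 2 and self.d == 3:
            return "avuncular"
        return "generic"

    @property
    def degree(self) -> int:
        return self.d - 1 if self.a == 2 else self.d

    def label(self) -> str:
        return f"d={self.d},a={self.a}({self.family},deg{self.degree})"


@dataclass
class ModelParams:
    """Shared model constants.

    r: expected recombination events per generation (map length / 100);
       reduce via :func:`ibdrel.masking.adjust_r` when masking is active.
    c: number of autosomes.
    t: minimum IBD segment length in cM; shorter segments are ignored and
       all models condition on length >= t.
    z: parent-offspring threshold in full-sibling standard deviations.
    h, b_mb: masking threshold and flank requirement (see masking module).
    alpha / confidence_level: significance level of the relatedness test
       and coverage of the reported (d, a) confidence set.
    d_max: deepest relationship hypothesis enumerated.
    confidence_df: chi-square df of the confidence-set cut (2 by default;
       1 treats (d, a) as a single profile parameter).
    """

    r: float = 35.0
    c: int = 22
    t: float = 2.5
    z: float = 2.33
    h: float = 4.0
    b_mb: float = 1.0
    alpha: float = 0.001
    confidence_level: float = 0.999
    d_max: int = 15
    use_ibd2_siblings: bool = False
    confidence_df: int = 2

    def __post_init__(self):
        if self.r <= 0 or self.c < 1 or self.t < 0:
            raise ParameterError("require r > 0, c >= 1, t >= 0")

    @property
    def total_cM(self) -> float:
        return 100.0 * self.r

    def with_masking(self, m_cM: float) -> "ModelParams":
        from .masking import adjust_r
        return replace(self, r=adjust_r(self.r, m_cM))


# ---------------------------------------------------------------------------
# segment count / length means
# ---------------------------------------------------------------------------

def mean_segment_length(hyp: RelationshipHypothesis, params: ModelParams,
                        boundary_adjusted: bool | None = None) -> float:
    """Mean IBD segment length (cM) under a hypothesis.

    ``boundary_adjusted=None`` follows the classification defaults: full
    relatives (a=2) use the plain exponential mean 100/d while a in
    {0, 1} uses 100/(d + c/r).  Forcing True applies the chromosome-
    boundary correction to every family (used by the conservation
    checks); forcing False disables it everywhere.
    """
    d, a, c, r = hyp.d, hyp.a, params.c, params.r
    if a == 0:
        dd = d - 1
        if boundary_adjusted is False:
            return math.inf if dd == 0 else 100.0 / dd
        return 100.0 / (dd + c / r)
    if boundary_adjusted is True or a == 1:
        return 100.0 / (d + c / r)
    return 100.0 / d


def mean_segment_count(hyp: RelationshipHypothesis,
                       params: ModelParams) -> float:
    """Mean number of IBD segments under a hypothesis (unconditioned)."""
    d, a, c, r = hyp.d, hyp.a, params.c, params.r
    if hyp.family in ("full_sibling", "avuncular"):
        return r + 0.75 * c
    if a == 0:
        return (r * (d - 1) + c) / 2.0 ** (d - 1)
    return a * (r * d + c) / 2.0 ** (d - 1)


def sibling_ibd2_count_mean(params: ModelParams) -> float:
    """Mean number of IBD2 segments between full siblings."""
    return params.r + params.c / 4.0


# ---------------------------------------------------------------------------
# full-sibling half-identity length mixture
# ---------------------------------------------------------------------------

def _sib_mixture(params: ModelParams):
    k = np.arange(SIB_MIX_KMAX + 1)
    w = (1.0 - SIB_MIX_Q) * SIB_MIX_Q ** k
    w /= w.sum()
    scale = 100.0 / 2.0  # plain exponential sibling mean, 100/d at d=2
    return k, w, scale

def sibling_length_logpdf(l, params: ModelParams) -> np.ndarray:
    """Log-density of a spliced full-sibling segment length (mixture of
    gammas over the number of spliced joins k); proper on [0, inf)."""
    l = np.asarray(l, dtype=float)
    k, w, scale = _sib_mixture(params)
    comp = stats.gamma.logpdf(l[..., None], a=k + 1, scale=scale)
    return _logsumexp_weighted(comp, w)


def sibling_length_cdf(l, params: ModelParams) -> np.ndarray:
    l = np.asarray(l, dtype=float)
    k, w, scale = _sib_mixture(params)
    comp = stats.gamma.cdf(l[..., None], a=k + 1, scale=scale)
    return comp @ w


def sibling_length_loglik(l, params: ModelParams) -> float:
    """Conditioned log-density of one spliced sibling segment, l >= t."""
    l = np.asarray(l, dtype=float)
    if np.any(l < params.t):
        raise InputError(f"segment length below t={params.t}")
    tail = 1.0 - float(sibling_length_cdf(np.array(params.t), params))
    out = sibling_length_logpdf(l, params) - math.log(tail)
    return float(out) if out.ndim == 0 else out


def _logsumexp_weighted(logcomp: np.ndarray, w: np.ndarray) -> np.ndarray:
    m = logcomp.max(axis=-1, keepdims=True)
    safe = np.where(np.isfinite(m), m, 0.0)
    s = np.log((w * np.exp(logcomp - safe)).sum(axis=-1)) + safe[..., 0]
    return s


# ---------------------------------------------------------------------------
# conditioning on the minimum segment length t
# ---------------------------------------------------------------------------

def conditioned_models(hyp: RelationshipHypothesis, params: ModelParams):
    """(count mean conditioned on length >= t, log-density on [t, inf)).

    The count mean is the unconditioned Poisson mean multiplied by
    P(length >= t) under the hypothesis's length law; the log-density is
    renormalized on [t, inf).  With t = 0 both are unchanged.
    """
    t = params.t
    lam = mean_segment_count(hyp, params)
    if hyp.family == "full_sibling":
        tail = 1.0 - float(sibling_length_cdf(np.array(t), params))

        def logpdf(l, _tail=tail):
            l = np.asarray(l, dtype=float)
            return sibling_length_logpdf(l, params) - math.log(_tail)

        return lam * tail, logpdf

    M = mean_segment_length(hyp, params)
    tail = math.exp(-t / M)

    def logpdf(l, _M=M, _t=t):
        # exponential is memoryless: conditional density is shifted
        l = np.asarray(l, dtype=float)
        out = -np.log(_M) - (l - _t) / _M
        return out

    return lam * tail, logpdf


# ---------------------------------------------------------------------------
# sibling IBD2 model
# ---------------------------------------------------------------------------

def sibling_ibd2_loglik(ibd2_lengths, total_ibd1_cM: float,
                        params: ModelParams, background) -> tuple[float, float]:
    """(alternative, null) log-likelihood of the observed IBD2 segments.

    Alternative (true full siblings): the count of IBD2 segments of
    length >= t is Poisson with mean (r + c/4) * P(l >= t) and lengths
    are exponential with mean 25 cM.  Null (not siblings): conditioned on
    the total half-identity length T, the expected number of IBD2
    segments is the background segment-count mean scaled by T/(100 r),
    with lengths following the background length law.
    """
    lengths = np.asarray(list(ibd2_lengths), dtype=float)
    if np.any(lengths < params.t):
        raise InputError("IBD2 segment below minimum length t")
    n2 = lengths.size
    t = params.t
    # alternative
    lam = sibling_ibd2_count_mean(params) * math.exp(-t / SIB_IBD2_MEAN_CM)
    alt = float(stats.poisson.logpmf(n2, lam))
    if n2:
        alt += float(np.sum(-math.log(SIB_IBD2_MEAN_CM)
                            - (lengths - t) / SIB_IBD2_MEAN_CM))
    # null
    mu = background.count_mean * total_ibd1_cM / (100.0 * params.r)
    null = float(stats.poisson.logpmf(n2, mu))
    if n2:
        null += float(np.sum(background.length_logpdf(lengths)))
    return alt, null


# ---------------------------------------------------------------------------
# parent-offspring rule
# ---------------------------------------------------------------------------

def parent_offspring_test(total_ibd_fraction: float,
                          params: ModelParams) -> bool:
    """True when the genome-wide half-identity fraction is at least z
    standard deviations above the full-sibling expectation of 0.75.

    Parents and offspring are IBD1 across the whole genome, so their
    fraction is ~1 with no stochasticity; the threshold separates them
    from full siblings, whose fraction is 0.75 +/- SIGMA_SIB.
    """
    if not 0.0 <= total_ibd_fraction <= 1.0 + 1e-9:
        raise InputError(f"IBD fraction {total_ibd_fraction} outside [0, 1]")
    return total_ibd_fraction >= 0.75 + params.z * SIGMA_SIB


def parent_offspring_threshold(params: ModelParams) -> float:
    return 0.75 + params.z * SIGMA_SIB
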