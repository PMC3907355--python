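"""Null model of IBD sharing among putatively unrelated pairs.

Nominally unrelated members of a population share short IBD-like
segments (distant cryptic ancestry plus detector artifacts).  The null
model treats, for each pair, the number of segments of length >= t as
Poisson with the control-cohort mean, and segment lengths as drawn from
a distribution fitted to the control segments above t.  The default fit
is a shifted exponential on (length - t), whose maximum-likelihood mean
excess is the sample mean of (length - t); the retained control lengths
also support a histogram-density variant.

Pairs with zero segments must be represented in the control manifest:
the count mean is (total segments >= t) / (number of control pairs), so
omitting empty pairs biases it upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, InputError, ParseError
from .io import SegmentSet, pair_key

_EPS_LOG = -745.0  # log of the smallest positive double; stands in for -inf


@dataclass
class BackgroundModel:
    """Fitted null distribution of per-pair segment counts and lengths.

    count_mean
        Poisson mean of the per-pair number of segments with length >= t.
    mean_excess_cM
        Mean of (length - t) among control segments; the shifted
        exponential's scale.  NaN when no control segment reached t, in
        which case the model is degenerate: any observed segment has null
        log-likelihood -inf.
    """

    count_mean: float
    mean_excess_cM: float
    t: float
    n_control_pairs: int = 0
    kind: str = "parametric"
    empirical_lengths: np.ndarray | None = field(default=None, repr=False)

    @property
    def degenerate(self) -> bool:
        return self.count_mean == 0.0 or not np.isfinite(self.mean_excess_cM)

    @property
    def length_mean_cM(self) -> float:
        return self.t + self.mean_excess_cM

    def length_logpdf(self, lengths) -> np.ndarray:
        """Log-density of segment lengths on [t, inf)."""
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths < self.t - 1e-9):
            raise InputError(f"segment length below t={self.t}")
        if self.degenerate:
            return np.full(lengths.shape, -math.inf)
        if self.kind == "empirical":
            return self._empirical_logpdf(lengths)
        th = self.mean_excess_cM
        return -math.log(th) - (lengths - self.t) / th

    def _empirical_logpdf(self, lengths: np.ndarray) -> np.ndarray:
        if self.empirical_lengths is None or self.empirical_lengths.size == 0:
            raise EstimationError("no retained control lengths for the "
                                  "empirical variant")
        sample = self.empirical_lengths
        hi = max(sample.max(), lengths.max()) + 1.0
        bins = np.linspace(self.t, hi, max(11, int(np.sqrt(sample.size)) + 1))
        dens, edges = np.histogram(sample, bins=bins, density=True)
        # small floor avoids -inf inside the observed support
        floor = 0.01 / (edges[-1] - edges[0])
        dens = np.maximum(dens, floor)
        idx = np.clip(np.searchsorted(edges, lengths, side="right") - 1,
                      0, dens.size - 1)
        return np.log(dens[idx])

    def sample_pair(self, rng: np.random.Generator) -> np.ndarray:
        """Segment lengths of one simulated unrelated pair."""
        n = rng.poisson(self.count_mean)
        if n == 0:
            return np.empty(0)
        if self.degenerate:
            raise EstimationError("cannot sample from a degenerate model")
        return self.t + rng.exponential(self.mean_excess_cM, n)

    # -- serialization ----------------------------------------------------
    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"count_mean\t{self.count_mean!r}\n")
            fh.write(f"mean_excess_cM\t{self.mean_excess_cM!r}\n")
            fh.write(f"t\t{self.t!r}\n")
            fh.write(f"n_control_pairs\t{self.n_control_pairs}\n")
            fh.write(f"kind\t{self.kind}\n")

    @classmethod
    def read(cls, path) -> "BackgroundModel":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    k, v = line.rstrip("\n").split("\t")
                    kv[k] = v
        try:
            return cls(count_mean=float(kv["count_mean"]),
                       mean_excess_cM=float(kv["mean_excess_cM"]),
                       t=float(kv["t"]),
                       n_control_pairs=int(kv.get("n_control_pairs", 0)),
                       kind=kv.get("kind", "parametric"))
        except KeyError as exc:
            raise ParseError(f"{path}: missing background field {exc}") from exc


def fit_background(controls: SegmentSet, control_pairs,
                   t: float = 2.5, kind: str = "parametric") -> BackgroundModel:
    """Fit the null model from a control cohort.

    ``control_pairs`` lists every putatively unrelated pair (as id
    2-tuples), including pairs that share no segment.  Segments belonging
    to pairs outside the manifest are ignored; segments shorter than t
    are discarded before fitting.
    """
    pairs = {pair_key(*p) for p in control_pairs}
    if not pairs:
        raise EstimationError("control manifest is empty")
    lengths = np.array([s.length_cM for s in controls
                        if s.pair in pairs and s.length_cM >= t])
    count_mean = lengths.size / len(pairs)
    mean_excess = float(np.mean(lengths - t)) if lengths.size else math.nan
    return BackgroundModel(count_mean=count_mean, mean_excess_cM=mean_excess,
                           t=t, n_control_pairs=len(pairs), kind=kind,
                           empirical_lengths=np.sort(lengths))


def null_loglik(pair_segment_lengths, model: BackgroundModel) -> float:
    """Log-likelihood of one pair's segments under the null model:
    log Poisson(n | count_mean) + sum of length log-densities."""
    lengths = np.asarray(list(pair_segment_lengths), dtype=float)
    n = lengths.size
    if model.degenerate:
        return 0.0 if n == 0 else -math.inf
    ll = float(stats.poisson.logpmf(n, model.count_mean))
    if n:
        ll += float(np.sum(model.length_logpdf(lengths)))
    return ll


def read_control_manifest(path) -> list[tuple[str, str]]:
    """Read a 2-column (id1, id2) TSV of putatively unrelated pairs."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                raise ParseError(f"{path}:{lineno}: expected two ids")
            if f[0] == "id1":
                continue
            pairs.append(pair_key(f[0], f[1]))
    return pairs
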