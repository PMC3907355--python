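"""Reading, writing and coordinate handling for IBD segment data.

The canonical in-memory objects are :class:`GeneticMap` (a monotone
physical<->genetic coordinate map per chromosome), :class:`IBDSegment`
(one reported shared segment for one pair of individuals) and
:class:`SegmentSet` (a collection of segments grouped by pair).

Physical coordinates are 0-based half-open ``[start_bp, end_bp)``
internally; dialects that use 1-based inclusive coordinates are converted
on read.  Genetic coordinates are in centimorgans (cM).

Only the 22 human autosomes participate in the relationship models; any
segment on another chromosome (X, Y, MT, ...) is dropped with a warning
when a map restricted to autosomes is in use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, InputError, ParameterError, ParseError

logger = logging.getLogger(__name__)

IBD1 = "IBD1"
IBD2 = "IBD2"

#: column layout of the canonical tab-delimited segment format
CANONICAL_COLUMNS = [
    "id1", "id2", "chrom", "start_bp", "end_bp",
    "start_cM", "end_cM", "length_cM", "state",
]


def pair_key(id1: str, id2: str) -> tuple[str, str]:
    """Canonical unordered pair identifier (lexicographically sorted)."""
    return (id1, id2) if id1 <= id2 else (id2, id1)


def unordered_pairs(ids) -> list[tuple[str, str]]:
    """All n*(n-1)/2 unordered pairs among ``ids``, canonically keyed."""
    ids = list(ids)
    return [pair_key(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]


class GeneticMap:
    """Piecewise-linear physical(bp) <-> genetic(cM) map per chromosome.

    Parameters
    ----------
    anchors
        Mapping ``chrom -> (bp_array, cM_array)`` with both arrays strictly
        increasing.  Interpolation is linear between anchors and clamped at
        the outermost anchors.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise CoordinateError(f"chromosome {chrom}: need >= 2 anchors")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise CoordinateError(
                    f"chromosome {chrom}: anchors must be strictly increasing"
                )
            self._anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    @property
    def n_chromosomes(self) -> int:
        """Number of chromosomes in the map (the model's autosome count c)."""
        return len(self._anchors)

    def _get(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._anchors[str(chrom)]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def chrom_span_bp(self, chrom: str) -> tuple[int, int]:
        bp, _ = self._get(chrom)
        return int(bp[0]), int(bp[-1])

    def chrom_span_cM(self, chrom: str) -> tuple[float, float]:
        _, cm = self._get(chrom)
        return float(cm[0]), float(cm[-1])

    def chrom_length_cM(self, chrom: str) -> float:
        lo, hi = self.chrom_span_cM(chrom)
        return hi - lo

    @property
    def total_cM(self) -> float:
        """Total genetic map length; 100*r where r is the expected number
        of recombination events per generation."""
        return float(sum(self.chrom_length_cM(c) for c in self._anchors))

    @property
    def r(self) -> float:
        """Expected recombination events per generation implied by the map."""
        return self.total_cM / 100.0

    def interpolate_cM(self, chrom: str, position_bp) -> float | np.ndarray:
        """Genetic position of ``position_bp``; clamps beyond the anchors."""
        bp, cm = self._get(chrom)
        out = np.interp(np.asarray(position_bp, dtype=float), bp, cm)
        return float(out) if np.isscalar(position_bp) else out

    def interpolate_bp(self, chrom: str, position_cM) -> float | np.ndarray:
        """Inverse interpolation, genetic -> physical."""
        bp, cm = self._get(chrom)
        out = np.interp(np.asarray(position_cM, dtype=float), cm, bp)
        return float(out) if np.isscalar(position_cM) else out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (bp, cm) in self._anchors.items():
            for b, c in zip(bp, cm):
                rows.append((chrom, int(b), float(c)))
        return pd.DataFrame(rows, columns=["chrom", "position_bp", "position_cM"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a 3-column (chrom, bp, cM) tab-delimited genome-wide map."""
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"cannot read genetic map {path}: {exc}") from exc
        required = {"chrom", "position_bp", "position_cM"}
        if not required.issubset(df.columns):
            raise ParseError(
                f"genetic map {path} must have columns {sorted(required)}"
            )
        anchors = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            anchors[str(chrom)] = (
                grp["position_bp"].to_numpy(float),
                grp["position_cM"].to_numpy(float),
            )
        return cls(anchors)


@dataclass(frozen=True)
class IBDSegment:
    """One reported IBD segment shared by one pair of individuals.

    ``length_cM`` normally equals ``end_cM - start_cM``; after mask
    subtraction (see :mod:`ibdrel.masking`) it may be smaller than the
    extent implies.
    """

    pair: tuple[str, str]
    chrom: str
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    length_cM: float
    state: str = IBD1

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise CoordinateError(
                f"segment {self.pair} {self.chrom}: start_bp >= end_bp"
            )
        if self.start_cM >= self.end_cM:
            raise CoordinateError(
                f"segment {self.pair} {self.chrom}: start_cM >= end_cM"
            )
        if self.length_cM <= 0:
            raise CoordinateError(f"segment {self.pair}: non-positive length")
        if self.state not in (IBD1, IBD2):
            raise ParseError(f"unknown IBD state {self.state!r}")


@dataclass
class SegmentSet:
    """A collection of IBD segments, grouped by unordered pair id."""

    segments: list[IBDSegment] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def pairs(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for s in self.segments:
            seen.setdefault(s.pair)
        return list(seen)

    def by_pair(self) -> dict[tuple[str, str], list[IBDSegment]]:
        out: dict[tuple[str, str], list[IBDSegment]] = {}
        for s in self.segments:
            out.setdefault(s.pair, []).append(s)
        return out

    def for_pair(self, id1: str, id2: str) -> list[IBDSegment]:
        key = pair_key(id1, id2)
        return [s for s in self.segments if s.pair == key]

    def total_cM(self) -> float:
        return float(sum(s.length_cM for s in self.segments))

    def filter_state(self, state: str) -> "SegmentSet":
        return SegmentSet([s for s in self.segments if s.state == state],
                          self.provenance)

    def filter_min_length(self, t: float) -> "SegmentSet":
        return SegmentSet([s for s in self.segments if s.length_cM >= t],
                          self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.pair[0], s.pair[1], s.chrom, s.start_bp, s.end_bp,
             s.start_cM, s.end_cM, s.length_cM, s.state)
            for s in self.segments
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)

    def write(self, path) -> None:
        """Write in the canonical tab-delimited segment format."""
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")


# ---------------------------------------------------------------------------
# dialect readers
# ---------------------------------------------------------------------------

_DIALECTS = ("generic_tsv", "germline_match", "isca_ibd12")


def _row_error(path, lineno, msg):
    return ParseError(f"{path}:{lineno}: {msg}")


def read_segments(path, dialect: str = "generic_tsv",
                  genetic_map: GeneticMap | None = None) -> SegmentSet:
    """Read a tab-delimited IBD segment file.

    Dialects
    --------
    ``generic_tsv``
        The canonical format written by :meth:`SegmentSet.write`
        (header, 0-based half-open bp, explicit cM coordinates and state).
    ``germline_match``
        GERMLINE-like match output: ``id1 id2 chrom start_bp end_bp
        length_cM`` with 1-based inclusive physical coordinates and no
        IBD1/IBD2 state column (all segments are half-identity, IBD1).
        Genetic coordinates are recomputed from ``genetic_map``.
    ``isca_ibd12``
        ``id1 id2 chrom start_bp end_bp state`` with an explicit
        IBD1/IBD2 state column and 0-based half-open coordinates; genetic
        coordinates are recomputed from ``genetic_map``.

    Segments on chromosomes absent from the supplied map are rejected;
    with no map, the generic dialect is accepted as-is.
    """
    if dialect not in _DIALECTS:
        raise ParameterError(
            f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    segments: list[IBDSegment] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (expected at least a header)")

    def check_chrom(chrom, lineno):
        if genetic_map is not None and chrom not in genetic_map.chromosomes:
            raise CoordinateError(f"{path}:{lineno}: unknown chromosome "
                                  f"{chrom!r} (not in genetic map)")

    if dialect == "generic_tsv":
        header = lines[0].split("\t")
        if header != CANONICAL_COLUMNS:
            raise ParseError(
                f"{path}:1: expected header {CANONICAL_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise _row_error(path, lineno, f"expected 9 fields, got {len(f)}")
            try:
                seg = IBDSegment(
                    pair=pair_key(f[0], f[1]), chrom=f[2],
                    start_bp=int(f[3]), end_bp=int(f[4]),
                    start_cM=float(f[5]), end_cM=float(f[6]),
                    length_cM=float(f[7]), state=f[8],
                )
            except (ValueError, CoordinateError, ParseError) as exc:
                raise _row_error(path, lineno, str(exc)) from exc
            check_chrom(seg.chrom, lineno)
            segments.append(seg)
    else:
        if genetic_map is None:
            raise ParameterError(f"dialect {dialect!r} requires a genetic map "
                                 f"to recover cM coordinates")
        start_offset = 1 if dialect == "germline_match" else 0
        ncol = 6
        first = lines[0].split("\t")
        body = lines[1:] if first and first[0] in ("id1", "#id1") else lines
        start_lineno = 2 if body is not lines else 1
        for lineno, line in enumerate(body, start=start_lineno):
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) != ncol:
                raise _row_error(path, lineno, f"expected {ncol} fields, got {len(f)}")
            chrom = f[2]
            if chrom not in genetic_map.chromosomes:
                if _non_autosome(chrom):
                    logger.warning("%s:%d: dropping segment on non-autosome %s",
                                   path, lineno, chrom)
                    continue
                raise CoordinateError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start_bp = int(f[3]) - start_offset
                end_bp = int(f[4]) - start_offset + (1 if start_offset else 0)
            except ValueError as exc:
                raise _row_error(path, lineno, str(exc)) from exc
            start_cM = genetic_map.interpolate_cM(chrom, start_bp)
            end_cM = genetic_map.interpolate_cM(chrom, end_bp)
            state = IBD1 if dialect == "germline_match" else f[5]
            if end_cM - start_cM <= 0:
                raise _row_error(path, lineno,
                                 "segment has non-positive genetic length")
            try:
                seg = IBDSegment(pair=pair_key(f[0], f[1]), chrom=chrom,
                                 start_bp=start_bp, end_bp=end_bp,
                                 start_cM=start_cM, end_cM=end_cM,
                                 length_cM=end_cM - start_cM, state=state)
            except (CoordinateError, ParseError) as exc:
                raise _row_error(path, lineno, str(exc)) from exc
            segments.append(seg)
    return SegmentSet(segments, provenance=f"read:{dialect}:{path}")


def _non_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr").upper()
    return c in ("X", "Y", "XY", "MT", "M")


def write_segments(segset: SegmentSet, path) -> None:
    segset.write(path)


# ---------------------------------------------------------------------------
# multi-run merging (detectors that are run several times, e.g. 10 runs of a
# haplotype-sampling IBD caller, report overlapping/nearby copies of the same
# segment; copies within gap_mb of each other are unioned)
# ---------------------------------------------------------------------------

def merge_multirun(runs: list[SegmentSet], genetic_map: GeneticMap,
                   gap_mb: float = 1.0) -> SegmentSet:
    """Union segments across detector runs.

    For each pair and chromosome, segments from any run that overlap or
    whose physical gap is at most ``gap_mb`` megabases are merged into a
    single segment spanning their union; genetic coordinates are
    recomputed from the merged physical extent.  The operation is
    order-independent in the run list and idempotent on its own output.
    """
    gap_bp = gap_mb * 1e6
    grouped: dict[tuple, list[tuple[int, int]]] = {}
    for run in runs:
        for s in run:
            if s.chrom not in genetic_map.chromosomes:
                raise CoordinateError(
                    f"segment chromosome {s.chrom!r} not in genetic map")
            grouped.setdefault((s.pair, s.chrom, s.state), []).append(
                (s.start_bp, s.end_bp))
    merged: list[IBDSegment] = []
    for (pair, chrom, state), ivs in sorted(grouped.items()):
        ivs.sort()
        cur_s, cur_e = ivs[0]
        out = []
        for s0, e0 in ivs[1:]:
            if s0 - cur_e <= gap_bp:
                cur_e = max(cur_e, e0)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s0, e0
        out.append((cur_s, cur_e))
        for s0, e0 in out:
            c0 = genetic_map.interpolate_cM(chrom, s0)
            c1 = genetic_map.interpolate_cM(chrom, e0)
            merged.append(IBDSegment(pair=pair, chrom=chrom,
                                     start_bp=s0, end_bp=e0,
                                     start_cM=c0, end_cM=c1,
                                     length_cM=c1 - c0, state=state))
    return SegmentSet(merged, provenance="merged_multirun")


def merge_pair_extents(segments: list[IBDSegment],
                       genetic_map: GeneticMap | None = None
                       ) -> list[IBDSegment]:
    """Merge overlapping segments of one pair (any state) into half-identity
    extents, in genetic coordinates.

    This reproduces the representation produced by detectors that do not
    distinguish IBD1 from IBD2: diploid-identical stretches are absorbed
    into their flanking half-identical segments and reported as one longer
    segment.  The input segments must belong to a single pair.
    """
    if not segments:
        return []
    pair = segments[0].pair
    out: list[IBDSegment] = []
    by_chrom: dict[str, list[IBDSegment]] = {}
    for s in segments:
        if s.pair != pair:
            raise InputError("merge_pair_extents expects segments of a single pair")
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in sorted(by_chrom.items()):
        segs.sort(key=lambda s: (s.start_cM, s.end_cM))
        cur = segs[0]
        cur_scM, cur_ecM = cur.start_cM, cur.end_cM
        cur_sbp, cur_ebp = cur.start_bp, cur.end_bp
        for s in segs[1:]:
            if s.start_cM <= cur_ecM + 1e-9:
                cur_ecM = max(cur_ecM, s.end_cM)
                cur_ebp = max(cur_ebp, s.end_bp)
                cur_sbp = min(cur_sbp, s.start_bp)
            else:
                out.append(IBDSegment(pair, chrom, cur_sbp, cur_ebp,
                                      cur_scM, cur_ecM, cur_ecM - cur_scM, IBD1))
                cur_scM, cur_ecM = s.start_cM, s.end_cM
                cur_sbp, cur_ebp = s.start_bp, s.end_bp
        out.append(IBDSegment(pair, chrom, cur_sbp, cur_ebp,
                              cur_scM, cur_ecM, cur_ecM - cur_scM, IBD1))
    return out
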