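"""Excess-IBD genomic region masking.

Some genomic regions (centromeres, assembly gaps, long-range LD and
inversion polymorphisms) accumulate spurious IBD calls in every detector
and inflate false-positive relationship calls among unrelated pairs.
This module scans a control cohort for windows whose observed total IBD
length exceeds the uniform-sharing expectation by a factor h (default 4),
coalesces them into mask regions, and applies the mask to segment input:

* a segment that wholly contains a region and extends at least b (default
  1 Mb) past both region ends keeps its extent but loses the region's cM
  length;
* any other segment crossing a region boundary is truncated at the
  boundary (applied iteratively, left to right);
* segments entirely inside a region are removed.

Let m be the summed cM length of all mask regions; m/100 is subtracted
from r in every relationship model to account for recombination events
that can no longer be observed.

A curated mask of 14 known excess-IBD regions of the hg19 human assembly
(119.92 cM total) ships with the package; see
:func:`known_excess_regions`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import CoordinateError, EstimationError, ParameterError
from .io import GeneticMap, IBDSegment, SegmentSet

SCAN_COLUMNS = ["chrom", "start_bp", "end_bp", "start_cM", "end_cM",
                "observed_cM", "expected_cM", "ratio"]


@dataclass(frozen=True)
class MaskRegion:
    """A genomic interval with excess control-cohort IBD."""

    chrom: str
    start_bp: int
    end_bp: int
    length_cM: float
    observed_expected_ratio: float = 0.0

    def __post_init__(self):
        if self.start_bp >= self.end_bp or self.length_cM <= 0:
            raise CoordinateError("mask region must have positive extent")


def excess_ibd_scan(controls: SegmentSet, genetic_map: GeneticMap,
                    window_cM: float = 0.5) -> pd.DataFrame:
    """Tile the genome into ``window_cM`` windows and compare observed
    control IBD per window against the uniform-sharing expectation.

    observed_cM(window) sums the control segments intersected with the
    window (truncated at window boundaries); expected_cM(window) is the
    total observed IBD genome-wide times window_length / total map
    length.  The last window of a chromosome may be shorter.  Ratio is 0
    where expected is 0.
    """
    if window_cM <= 0:
        raise ParameterError("window_cM must be positive")
    if len(controls) == 0 or not controls.pairs():
        raise EstimationError("control cohort has no segments")
    total_map = genetic_map.total_cM
    total_obs = controls.total_cM()

    rows = []
    by_chrom: dict[str, list[IBDSegment]] = {}
    for s in controls:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in genetic_map.chromosomes:
        lo, hi = genetic_map.chrom_span_cM(chrom)
        edges = np.arange(lo, hi, window_cM)
        edges = np.append(edges, hi)
        obs = np.zeros(edges.size - 1)
        for s in by_chrom.get(chrom, []):
            a = np.clip(edges[:-1], s.start_cM, s.end_cM)
            b = np.clip(edges[1:], s.start_cM, s.end_cM)
            obs += np.maximum(b - a, 0.0)
        wlen = np.diff(edges)
        exp = total_obs * wlen / total_map
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(exp > 0, obs / np.where(exp > 0, exp, 1.0), 0.0)
        for i in range(wlen.size):
            rows.append((chrom,
                         int(round(genetic_map.interpolate_bp(chrom, edges[i]))),
                         int(round(genetic_map.interpolate_bp(chrom, edges[i + 1]))),
                         float(edges[i]), float(edges[i + 1]),
                         float(obs[i]), float(exp[i]), float(ratio[i])))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def build_mask(scan: pd.DataFrame, h: float = 4.0) -> list[MaskRegion]:
    """Select windows with ratio > h and coalesce adjacent selected
    windows into regions; each region reports the length-weighted mean
    ratio of its windows."""
    if h <= 0:
        raise ParameterError("h must be positive")
    regions: list[MaskRegion] = []
    cur = None  # [chrom, sbp, ebp, scM, ecM, weighted_ratio_sum]
    prev_end_cM = None

    def flush():
        nonlocal cur
        if cur is not None:
            chrom, sbp, ebp, scm, ecm, wsum = cur
            regions.append(MaskRegion(chrom, sbp, ebp, ecm - scm,
                                      wsum / (ecm - scm)))
            cur = None

    for row in scan.itertuples(index=False):
        selected = row.ratio > h
        contiguous = (cur is not None and row.chrom == cur[0]
                      and prev_end_cM is not None
                      and abs(row.start_cM - cur[4]) < 1e-9)
        if selected:
            wlen = row.end_cM - row.start_cM
            if contiguous:
                cur[2] = row.end_bp
                cur[4] = row.end_cM
                cur[5] += row.ratio * wlen
            else:
                flush()
                cur = [row.chrom, row.start_bp, row.end_bp,
                       row.start_cM, row.end_cM, row.ratio * wlen]
        else:
            flush()
        prev_end_cM = row.end_cM
    flush()
    return regions


def mask_total_cM(mask: list[MaskRegion]) -> float:
    """m: summed genetic length of all mask regions."""
    return float(sum(rg.length_cM for rg in mask))


def adjust_r(r: float, m_cM: float) -> float:
    """Masking-corrected expected recombinations per generation,
    r - m/100 (recombinations inside masked regions are unobservable)."""
    if m_cM < 0:
        raise ParameterError("m must be >= 0")
    if m_cM / 100.0 >= r:
        raise ParameterError(f"mask length {m_cM} cM exhausts the map (r={r})")
    return r - m_cM / 100.0


def apply_mask(segments: SegmentSet, mask: list[MaskRegion],
               genetic_map: GeneticMap, b_mb: float = 1.0
               ) -> tuple[SegmentSet, float]:
    """Apply mask regions to a segment set; returns the masked set and m.

    Rules (per segment, regions scanned left to right):
    containment with >= b Mb flanks on both sides subtracts the region's
    cM length without changing the extent; any other boundary crossing
    truncates the segment at the boundary; segments entirely inside a
    region are removed.  Segment lengths and counts never increase.
    """
    b_bp = b_mb * 1e6
    by_chrom: dict[str, list[MaskRegion]] = {}
    for rg in mask:
        by_chrom.setdefault(rg.chrom, []).append(rg)
    for chrom, rgs in by_chrom.items():
        rgs.sort(key=lambda rg: rg.start_bp)
        for r1, r2 in zip(rgs, rgs[1:]):
            if r2.start_bp < r1.end_bp:
                raise ParameterError("mask regions must be non-overlapping")

    out: list[IBDSegment] = []
    for s in segments:
        regions = [rg for rg in by_chrom.get(s.chrom, [])
                   if rg.start_bp < s.end_bp and rg.end_bp > s.start_bp]
        if not regions:
            out.append(s)
            continue
        start_bp, end_bp = s.start_bp, s.end_bp
        subtract = 0.0
        dropped = False
        for rg in regions:
            if rg.start_bp <= start_bp and rg.end_bp >= end_bp:
                dropped = True  # entirely inside the region
                break
            if (start_bp <= rg.start_bp - b_bp and end_bp >= rg.end_bp + b_bp):
                subtract += rg.length_cM  # rule (i): contained with flanks
                continue
            if rg.start_bp > start_bp:
                end_bp = rg.start_bp  # entering the region: cut at its start
                break
            start_bp = rg.end_bp  # starting inside: resume past the region
        if dropped or end_bp <= start_bp:
            continue
        s_cm = genetic_map.interpolate_cM(s.chrom, start_bp)
        e_cm = genetic_map.interpolate_cM(s.chrom, end_bp)
        length = e_cm - s_cm - subtract
        # 1e-4 cM guards against sub-resolution slivers left by rounding
        # a truncation boundary to whole base pairs
        if length <= 1e-4 or e_cm - s_cm <= 1e-4:
            continue
        out.append(IBDSegment(s.pair, s.chrom, int(start_bp), int(end_bp),
                              float(s_cm), float(e_cm), float(length), s.state))
    return (SegmentSet(out, provenance=segments.provenance + "+masked"),
            mask_total_cM(mask))


# ---------------------------------------------------------------------------
# mask region I/O and the packaged hg19 mask
# ---------------------------------------------------------------------------

MASK_COLUMNS = ["chrom", "start_bp", "end_bp", "length_cM", "ratio"]


def write_mask(mask: list[MaskRegion], path) -> None:
    df = pd.DataFrame(
        [(rg.chrom, rg.start_bp, rg.end_bp, rg.length_cM,
          rg.observed_expected_ratio) for rg in mask],
        columns=MASK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_mask(path) -> list[MaskRegion]:
    """Read a BED-like TSV mask (chrom, start_bp, end_bp, length_cM, ratio)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MASK_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ParameterError(f"mask file {path} lacks columns {sorted(missing)}")
    return [MaskRegion(str(r.chrom), int(r.start_bp), int(r.end_bp),
                       float(r.length_cM), float(getattr(r, "ratio", 0.0)))
            for r in df.itertuples(index=False)]


def known_excess_regions() -> list[MaskRegion]:
    """The packaged mask of 14 excess-IBD regions of the hg19 assembly
    (total genetic length 119.92 cM), identified from whole-genome
    European control cohorts."""
    ref = resources.files("ibdrel").joinpath("data/hg19_excess_ibd_regions.tsv")
    with resources.as_file(ref) as path:
        return read_mask(path)
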