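"""Gene-dropping pedigree simulator.

Simulates inheritance down an arbitrary pedigree on a genetic map and
reports, for any pair of simulated individuals, the true IBD1/IBD2
segments implied by the founder-haplotype mosaics.  Crossovers are placed
as a Poisson process on the genetic (cM) scale with no interference, so a
chromosome of length L cM receives on average L/100 crossovers per
meiosis and a 3500 cM genome averages 35.

The simulator is the package's fixture generator and ground-truth oracle:
its output uses the same segment containers as real detector input, so an
end-to-end test can gene-drop a pedigree, extract true IBD and run the
classifier with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError, ParameterError, PedigreeError
from .io import IBD1, IBD2, GeneticMap, IBDSegment, SegmentSet, pair_key

# Sex-averaged genetic lengths (cM) of the 22 human autosomes; used as the
# relative length profile of synthetic maps.  Scaled so a default map
# totals exactly total_cM.
_HUMAN_AUTOSOME_CM = np.array([
    284.0, 269.0, 223.0, 214.0, 204.0, 192.0, 187.0, 168.0, 166.0, 181.0,
    158.0, 175.0, 126.0, 120.0, 142.0, 134.0, 129.0, 118.0, 108.0, 108.0,
    63.0, 74.0,
])


def make_synthetic_map(c: int = 22, total_cM: float = 3500.0,
                       anchors_per_chrom: int = 25,
                       seed: int | np.random.Generator = 0) -> GeneticMap:
    """Build a synthetic genome-wide genetic map.

    ``c`` chromosomes receive cM lengths proportional to the human
    autosome profile (cycled if c > 22), rescaled to sum to ``total_cM``.
    Physical anchors are laid out with mildly heterogeneous recombination
    rate around 1 cM/Mb (seeded), strictly increasing in both coordinates.
    """
    if c < 1 or total_cM <= 0:
        raise ParameterError("need c >= 1 and total_cM > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    profile = np.resize(_HUMAN_AUTOSOME_CM, c).astype(float)
    lengths = profile / profile.sum() * total_cM
    anchors = {}
    for i, L in enumerate(lengths, start=1):
        n = max(2, anchors_per_chrom)
        cm = np.linspace(0.0, L, n)
        # rate heterogeneity: lognormal Mb-per-cM factors between anchors
        mb_per_cm = np.exp(rng.normal(0.0, 0.25, n - 1))
        bp = np.concatenate([[0.0], np.cumsum(np.diff(cm) * mb_per_cm * 1e6)])
        bp = np.round(bp).astype(np.int64)
        bp = np.maximum.accumulate(bp)
        bp += np.arange(n)  # guarantee strict increase after rounding
        anchors[str(i)] = (bp.astype(float), cm)
    return GeneticMap(anchors)


# ---------------------------------------------------------------------------
# pedigree structure
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Sex-free pedigree: each non-founder has exactly two parents.

    ``parents`` maps individual id -> (parent1, parent2) or None for
    founders.  Individuals are processed in a topological order, so every
    non-founder's parents must be present.
    """

    parents: dict[str, tuple[str, str] | None] = field(default_factory=dict)

    def add_founder(self, iid: str) -> str:
        self.parents[iid] = None
        return iid

    def add_child(self, iid: str, p1: str, p2: str) -> str:
        for p in (p1, p2):
            if p not in self.parents:
                raise PedigreeError(f"{iid}: unknown parent {p}")
        self.parents[iid] = (p1, p2)
        return iid

    @property
    def founders(self) -> list[str]:
        return [i for i, p in self.parents.items() if p is None]

    @property
    def members(self) -> list[str]:
        return list(self.parents)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        done: set[str] = set()
        pending = dict(self.parents)
        while pending:
            progressed = False
            for iid, par in list(pending.items()):
                if par is None or (par[0] in done and par[1] in done):
                    order.append(iid)
                    done.add(iid)
                    del pending[iid]
                    progressed = True
            if not progressed:
                raise PedigreeError("pedigree has a cycle or missing parents")
        return order

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tparent1\tparent2\n")
            for iid, par in self.parents.items():
                p1, p2 = par if par else ("0", "0")
                fh.write(f"{iid}\t{p1}\t{p2}\n")

    @classmethod
    def read(cls, path) -> "Pedigree":
        ped = cls()
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("id"):
                raise PedigreeError(f"{path}: expected 'id parent1 parent2' header")
            for line in fh:
                if line.strip():
                    f = line.rstrip("\n").split("\t")
                    if len(f) < 3:
                        raise PedigreeError(f"{path}: malformed row {line!r}")
                    rows.append((f[0], f[1], f[2]))
        for iid, p1, p2 in rows:
            ped.parents[iid] = None if p1 == "0" or p2 == "0" else (p1, p2)
        # validate
        for iid, par in ped.parents.items():
            if par is not None and (par[0] not in ped.parents
                                    or par[1] not in ped.parents):
                raise PedigreeError(f"{iid}: parent not in pedigree")
        ped.topological_order()
        return ped


def default_simulation_pedigree(generations: int = 15) -> tuple[Pedigree, dict]:
    """The fixed multi-generation test pedigree.

    One ancestral couple; in every generation the couple has two children,
    one of whom marries a fresh founder to form the next generation's
    couple.  With 15 generations this yields 16 founders + 30 children =
    46 members and C(46,2) = 1035 pairs, containing one full-sibling pair
    and two parent-offspring links per generation.

    Returns the pedigree and a dict of bookkeeping (members per role).
    """
    ped = Pedigree()
    f0 = ped.add_founder("F0a")
    m0 = ped.add_founder("F0b")
    couple = (f0, m0)
    sib_pairs = []
    for g in range(1, generations + 1):
        c1 = ped.add_child(f"G{g}a", *couple)
        c2 = ped.add_child(f"G{g}b", *couple)
        sib_pairs.append((c1, c2))
        if g < generations:
            spouse = ped.add_founder(f"S{g}")
            couple = (c1, spouse)
    info = {
        "n_members": len(ped.members),
        "n_founders": len(ped.founders),
        "sibling_pairs": sib_pairs,
    }
    return ped, info


def lineage_pedigree(d: int, a: int) -> tuple[Pedigree, tuple[str, str]]:
    """Minimal pedigree producing one pair separated by ``d`` meioses
    through ``a`` shared ancestors; returns (pedigree, pair ids).

    a=2: an ancestral couple with two children; each child's line is
    extended by fresh-founder marriages so the branch depths sum to d.
    a=1: two half-siblings through one shared founder, lines extended
    likewise.  a=0: direct descent over d meioses.
    """
    ped = Pedigree()
    if a == 2:
        if d < 2:
            raise ParameterError("a=2 requires d >= 2")
        pa = ped.add_founder("A1")
        pb = ped.add_founder("A2")
        left = ped.add_child("L0", pa, pb)
        right = ped.add_child("R0", pa, pb)
        k1 = (d - 2) // 2
        k2 = d - 2 - k1
        for i in range(k1):
            sp = ped.add_founder(f"LS{i}")
            left = ped.add_child(f"L{i + 1}", left, sp)
        for i in range(k2):
            sp = ped.add_founder(f"RS{i}")
            right = ped.add_child(f"R{i + 1}", right, sp)
        return ped, pair_key(left, right)
    if a == 1:
        if d < 2:
            raise ParameterError("a=1 requires d >= 2")
        shared = ped.add_founder("A1")
        sa = ped.add_founder("Ma")
        sb = ped.add_founder("Mb")
        left = ped.add_child("L0", shared, sa)
        right = ped.add_child("R0", shared, sb)
        k1 = (d - 2) // 2
        k2 = d - 2 - k1
        for i in range(k1):
            sp = ped.add_founder(f"LS{i}")
            left = ped.add_child(f"L{i + 1}", left, sp)
        for i in range(k2):
            sp = ped.add_founder(f"RS{i}")
            right = ped.add_child(f"R{i + 1}", right, sp)
        return ped, pair_key(left, right)
    if a == 0:
        if d < 1:
            raise ParameterError("a=0 requires d >= 1")
        anc = ped.add_founder("A1")
        cur = anc
        for i in range(d):
            sp = ped.add_founder(f"S{i}")
            cur = ped.add_child(f"D{i + 1}", cur, sp)
        return ped, pair_key(anc, cur)
    raise ParameterError("a must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# haplotype mosaics and meiosis
# ---------------------------------------------------------------------------
#
# A haplotype on one chromosome is stored as (bounds, labels): bounds is a
# strictly increasing float array starting at 0 and ending at the chromosome
# cM length; labels[i] is the founder-haplotype label on
# [bounds[i], bounds[i+1]).  A mosaic is {chrom: (hap0, hap1)}.

Haplotype = tuple[np.ndarray, np.ndarray]
Mosaic = dict[str, tuple[Haplotype, Haplotype]]


def founder_mosaic(genetic_map: GeneticMap, label0: int, label1: int) -> Mosaic:
    mos: Mosaic = {}
    for chrom in genetic_map.chromosomes:
        L = genetic_map.chrom_length_cM(chrom)
        bounds = np.array([0.0, L])
        mos[chrom] = (
            (bounds, np.array([label0], dtype=np.int64)),
            (bounds.copy(), np.array([label1], dtype=np.int64)),
        )
    return mos


def _recombine(hap_a: Haplotype, hap_b: Haplotype, xs: np.ndarray,
               start_with_a: bool, L: float) -> Haplotype:
    """Gamete alternating between hap_a and hap_b at crossover points xs."""
    cuts = np.concatenate([[0.0], xs, [L]])
    parts_b: list[np.ndarray] = []
    parts_l: list[np.ndarray] = []
    use_a = start_with_a
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi <= lo:
            continue
        b, l = (hap_a if use_a else hap_b)
        i0 = np.searchsorted(b, lo, side="right") - 1
        i1 = np.searchsorted(b, hi, side="left")
        seg_b = b[i0:i1 + 1].copy()
        seg_b[0] = lo
        seg_b[-1] = hi
        parts_b.append(seg_b[:-1])
        parts_l.append(l[i0:i1])
        use_a = not use_a
    bounds = np.concatenate(parts_b + [[L]])
    labels = np.concatenate(parts_l)
    # coalesce identical adjacent labels (invisible crossovers)
    if labels.size > 1:
        keep = np.concatenate([[True], labels[1:] != labels[:-1]])
        bounds = np.concatenate([bounds[:-1][keep], [L]])
        labels = labels[keep]
    return bounds, labels


def meiosis(parent: Mosaic, genetic_map: GeneticMap,
            rng: np.random.Generator,
            return_crossovers: bool = False):
    """One gamete from ``parent``: per chromosome, crossover count is
    Poisson(L_cM/100) with positions uniform in cM (no interference); the
    gamete alternates between the parent's two haplotypes, the starting
    haplotype chosen by a fair coin."""
    gamete: dict[str, Haplotype] = {}
    n_cross = 0
    for chrom in genetic_map.chromosomes:
        L = genetic_map.chrom_length_cM(chrom)
        hap_a, hap_b = parent[chrom]
        k = rng.poisson(L / 100.0) if L > 0 else 0
        xs = np.sort(rng.uniform(0.0, L, k)) if k else np.empty(0)
        n_cross += k
        start_with_a = bool(rng.integers(2))
        gamete[chrom] = _recombine(hap_a, hap_b, xs, start_with_a, L)
    if return_crossovers:
        return gamete, n_cross
    return gamete


def gene_drop(ped: Pedigree, genetic_map: GeneticMap,
              rng: np.random.Generator) -> dict[str, Mosaic]:
    """Simulate founder-haplotype mosaics for every pedigree member.

    Founders receive distinct integer labels (two per founder); every
    non-founder's two haplotypes are independent meiosis products of its
    parents' mosaics.
    """
    mosaics: dict[str, Mosaic] = {}
    label = 0
    for iid in ped.topological_order():
        par = ped.parents[iid]
        if par is None:
            mosaics[iid] = founder_mosaic(genetic_map, label, label + 1)
            label += 2
        else:
            g1 = meiosis(mosaics[par[0]], genetic_map, rng)
            g2 = meiosis(mosaics[par[1]], genetic_map, rng)
            mosaics[iid] = {c: (g1[c], g2[c]) for c in genetic_map.chromosomes}
    return mosaics


# ---------------------------------------------------------------------------
# true IBD extraction
# ---------------------------------------------------------------------------

def _match_profile(hapsA: tuple[Haplotype, Haplotype],
                   hapsB: tuple[Haplotype, Haplotype]):
    """Breakpoints and per-interval shared-haplotype count (0, 1 or 2)."""
    (ba0, la0), (ba1, la1) = hapsA
    (bb0, lb0), (bb1, lb1) = hapsB
    cuts = np.unique(np.concatenate([ba0, ba1, bb0, bb1]))
    mids = (cuts[:-1] + cuts[1:]) / 2.0
    a0 = la0[np.searchsorted(ba0, mids, side="right") - 1]
    a1 = la1[np.searchsorted(ba1, mids, side="right") - 1]
    b0 = lb0[np.searchsorted(bb0, mids, side="right") - 1]
    b1 = lb1[np.searchsorted(bb1, mids, side="right") - 1]
    # multiset intersection size of {a0,a1} and {b0,b1}
    direct = (a0 == b0).astype(np.int8) + (a1 == b1).astype(np.int8)
    crossed = (a0 == b1).astype(np.int8) + (a1 == b0).astype(np.int8)
    state = np.maximum(direct, crossed)
    return cuts, state


def _runs(cuts: np.ndarray, state: np.ndarray, predicate) -> list[tuple[float, float]]:
    mask = predicate(state)
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((float(cuts[i]), float(cuts[j + 1])))
            i = j + 1
        i += 1
    return runs


def true_ibd(mosaic_a: Mosaic, mosaic_b: Mosaic, genetic_map: GeneticMap,
             pair: tuple[str, str], mode: str = "ibd12") -> SegmentSet:
    """True IBD segments between two simulated individuals.

    Modes
    -----
    ``exclusive``
        Non-overlapping segments: IBD1 where exactly one haplotype is
        shared, IBD2 where both are.
    ``germline``
        Half-identity extents only: maximal stretches sharing at least one
        haplotype, all reported as IBD1 (detectors that cannot see IBD2).
    ``ibd12``
        The ``germline`` extents plus each IBD2 stretch reported
        separately as an additional overlapping segment (detectors that
        report diploid identity).
    """
    if mode not in ("exclusive", "germline", "ibd12"):
        raise ParameterError(f"unknown true_ibd mode {mode!r}")
    pair = pair_key(*pair)
    segs: list[IBDSegment] = []

    def emit(chrom, lo, hi, state):
        if hi - lo <= 1e-9:
            return
        cm0, cm1 = genetic_map.chrom_span_cM(chrom)
        s_cm, e_cm = cm0 + lo, cm0 + hi
        s_bp = int(round(genetic_map.interpolate_bp(chrom, s_cm)))
        e_bp = int(round(genetic_map.interpolate_bp(chrom, e_cm)))
        if e_bp <= s_bp:
            e_bp = s_bp + 1
        segs.append(IBDSegment(pair, chrom, s_bp, e_bp, s_cm, e_cm,
                               e_cm - s_cm, state))

    for chrom in genetic_map.chromosomes:
        if chrom not in mosaic_a or chrom not in mosaic_b:
            raise CoordinateError(f"mosaics lack chromosome {chrom}")
        cuts, state = _match_profile(mosaic_a[chrom], mosaic_b[chrom])
        if mode == "exclusive":
            for lo, hi in _runs(cuts, state, lambda s: s == 1):
                emit(chrom, lo, hi, IBD1)
            for lo, hi in _runs(cuts, state, lambda s: s == 2):
                emit(chrom, lo, hi, IBD2)
        else:
            for lo, hi in _runs(cuts, state, lambda s: s >= 1):
                emit(chrom, lo, hi, IBD1)
            if mode == "ibd12":
                for lo, hi in _runs(cuts, state, lambda s: s == 2):
                    emit(chrom, lo, hi, IBD2)
    return SegmentSet(segs, provenance=f"true_ibd:{mode}")


def simulate_pair(d: int, a: int, genetic_map: GeneticMap,
                  rng: np.random.Generator, mode: str = "ibd12") -> SegmentSet:
    """Gene-drop a minimal (d, a) lineage and return the pair's true IBD."""
    ped, pair = lineage_pedigree(d, a)
    mosaics = gene_drop(ped, genetic_map, rng)
    return true_ibd(mosaics[pair[0]], mosaics[pair[1]], genetic_map, pair,
                    mode=mode)


# ---------------------------------------------------------------------------
# detector-noise emulation and marker output
# ---------------------------------------------------------------------------

def add_noise(segset: SegmentSet, genetic_map: GeneticMap,
              rng: np.random.Generator, boundary_jitter_cM: float = 0.0,
              fp_rate: float = 0.0, fn_rate: float = 0.0) -> SegmentSet:
    """Emulate detector imperfection on true segments.

    Boundaries are jittered by N(0, boundary_jitter_cM) clipped to the
    chromosome; segments are dropped with probability ``fn_rate``; false
    segments are inserted at rate ``fp_rate`` per pair (Poisson), with
    exponential 3 cM lengths placed uniformly.  All defaults are 0, in
    which case the input is returned unchanged.
    """
    if not 0.0 <= fn_rate <= 1.0:
        raise ParameterError("fn_rate must lie in [0, 1]")
    if fp_rate < 0 or boundary_jitter_cM < 0:
        raise ParameterError("fp_rate and boundary_jitter_cM must be >= 0")
    if boundary_jitter_cM == 0.0 and fp_rate == 0.0 and fn_rate == 0.0:
        return segset
    out: list[IBDSegment] = []
    for s in segset:
        if fn_rate and rng.uniform() < fn_rate:
            continue
        lo, hi = s.start_cM, s.end_cM
        if boundary_jitter_cM:
            cm0, cm1 = genetic_map.chrom_span_cM(s.chrom)
            lo = float(np.clip(lo + rng.normal(0, boundary_jitter_cM), cm0, cm1))
            hi = float(np.clip(hi + rng.normal(0, boundary_jitter_cM), cm0, cm1))
            if hi - lo <= 1e-6:
                continue
        s_bp = int(round(genetic_map.interpolate_bp(s.chrom, lo)))
        e_bp = int(round(genetic_map.interpolate_bp(s.chrom, hi)))
        out.append(IBDSegment(s.pair, s.chrom, s_bp, max(e_bp, s_bp + 1),
                              lo, hi, hi - lo, s.state))
    if fp_rate:
        chroms = genetic_map.chromosomes
        weights = np.array([genetic_map.chrom_length_cM(c) for c in chroms])
        weights = weights / weights.sum()
        for pair in segset.pairs() or []:
            for _ in range(rng.poisson(fp_rate)):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                cm0, cm1 = genetic_map.chrom_span_cM(chrom)
                length = rng.exponential(3.0)
                lo = rng.uniform(cm0, max(cm0, cm1 - length))
                hi = min(cm1, lo + length)
                if hi - lo <= 1e-6:
                    continue
                s_bp = int(round(genetic_map.interpolate_bp(chrom, lo)))
                e_bp = int(round(genetic_map.interpolate_bp(chrom, hi)))
                out.append(IBDSegment(pair, chrom, s_bp, max(e_bp, s_bp + 1),
                                      lo, hi, hi - lo, IBD1))
    return SegmentSet(out, provenance=segset.provenance + "+noise")


def emit_markers(mosaics: dict[str, Mosaic], genetic_map: GeneticMap,
                 founder_haplotype_alleles: dict[int, dict[str, np.ndarray]],
                 positions_cM: dict[str, np.ndarray],
                 rng: np.random.Generator,
                 mutation_rate: float = 1e-7,
                 error_rate: float = 0.001):
    """Biallelic genotypes for every individual at the supplied positions.

    ``founder_haplotype_alleles`` maps founder-haplotype label ->
    {chrom: 0/1 allele array}; each individual's haplotype alleles are read
    off its mosaic, de-novo mutations are added per transmitted site with
    probability ``mutation_rate`` (allele flip), and genotyping errors flip
    called alleles with probability ``error_rate`` per site.  Returns
    {individual: {chrom: genotype array (0/1/2)}}.
    """
    if not (0.0 <= mutation_rate <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise ParameterError("rates must lie in [0, 1]")
    out: dict[str, dict[str, np.ndarray]] = {}
    for iid, mosaic in mosaics.items():
        geno: dict[str, np.ndarray] = {}
        for chrom, pos in positions_cM.items():
            cm0, _ = genetic_map.chrom_span_cM(chrom)
            rel = np.asarray(pos, dtype=float) - cm0
            alleles = np.zeros((2, rel.size), dtype=np.int8)
            for h, (bounds, labels) in enumerate(mosaic[chrom]):
                idx = np.searchsorted(bounds, rel, side="right") - 1
                idx = np.clip(idx, 0, labels.size - 1)
                site_labels = labels[idx]
                for lab in np.unique(site_labels):
                    sel = site_labels == lab
                    alleles[h, sel] = founder_haplotype_alleles[int(lab)][chrom][sel]
                if mutation_rate:
                    flips = rng.uniform(size=rel.size) < mutation_rate
                    alleles[h, flips] = 1 - alleles[h, flips]
            if error_rate:
                flips = rng.uniform(size=(2, rel.size)) < error_rate
                alleles[flips] = 1 - alleles[flips]
            geno[chrom] = alleles.sum(axis=0).astype(np.int8)
        out[iid] = geno
    return out


#: default cryptic-sharing conditions of the synthetic control population:
#: nominally unrelated pairs share on average CRYPTIC_COUNT_MEAN detectable
#: segments (>= 2.5 cM), with lengths 2.5 cM + Exp(CRYPTIC_MEAN_EXCESS_CM).
CRYPTIC_COUNT_MEAN = 4.0
CRYPTIC_MEAN_EXCESS_CM = 1.5


def synthetic_unrelated_cohort(n_pairs: int, genetic_map: GeneticMap,
                               rng: np.random.Generator,
                               count_mean: float = CRYPTIC_COUNT_MEAN,
                               mean_excess_cM: float = CRYPTIC_MEAN_EXCESS_CM,
                               min_length_cM: float = 2.5
                               ) -> tuple[SegmentSet, list[tuple[str, str]]]:
    """Synthetic control cohort of putatively unrelated pairs.

    Each pair receives Poisson(count_mean) cryptic-sharing segments with
    lengths min_length_cM + Exp(mean_excess_cM), placed uniformly across
    the genome (chromosome chosen proportional to genetic length, start
    uniform).  Returns the segments and the full pair manifest, including
    pairs that drew zero segments.
    """
    chroms = genetic_map.chromosomes
    clens = np.array([genetic_map.chrom_length_cM(c) for c in chroms])
    weights = clens / clens.sum()
    segs: list[IBDSegment] = []
    pairs: list[tuple[str, str]] = []
    for i in range(n_pairs):
        pair = pair_key(f"C{2 * i}", f"C{2 * i + 1}")
        pairs.append(pair)
        for _ in range(rng.poisson(count_mean)):
            length = min_length_cM + rng.exponential(mean_excess_cM)
            ci = rng.choice(len(chroms), p=weights)
            chrom, L = chroms[ci], clens[ci]
            length = min(length, L)
            cm0, _ = genetic_map.chrom_span_cM(chrom)
            lo = cm0 + rng.uniform(0.0, L - length) if L > length else cm0
            hi = lo + length
            s_bp = int(round(genetic_map.interpolate_bp(chrom, lo)))
            e_bp = int(round(genetic_map.interpolate_bp(chrom, hi)))
            segs.append(IBDSegment(pair, chrom, s_bp, max(e_bp, s_bp + 1),
                                   lo, hi, hi - lo, IBD1))
    return SegmentSet(segs, provenance="synthetic_unrelated"), pairs


def sample_crossover_counts(genetic_map: GeneticMap, n_meioses: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Crossover counts of ``n_meioses`` simulated meioses (one founder
    parent), used for calibration of the recombination process."""
    counts = np.empty(n_meioses, dtype=np.int64)
    mosaic = founder_mosaic(genetic_map, 0, 1)
    for i in range(n_meioses):
        _, k = meiosis(mosaic, genetic_map, rng, return_crossovers=True)
        counts[i] = k
    return counts
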