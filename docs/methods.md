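# Methods

## Relationship models

A relationship hypothesis is a pair (d, a): d total meioses along the
connecting path(s), a shared ancestors (2, 1 or 0). The reported degree
is d − 1 for a = 2 and d otherwise, so full siblings are 1st degree and
avuncular, grandparent and half-sibling pairs are all 2nd degree. Under
a hypothesis, the pair's IBD segments arise from a Poisson process over
a genome of c autosomes totalling 100·r cM:

| family | count mean | length law (cM) |
|---|---|---|
| generic (a ∈ {1, 2}) | a(rd + c)/2^(d−1) | Exp, mean 100/d (a=2) or 100/(d + c/r) (a=1) |
| ancestor–descendant (a=0, d>1) | (r(d−1) + c)/2^(d−1) | Exp, mean 100/((d−1) + c/r) |
| parent–offspring (a=0, d=1) | c (whole genome) | deterministic; threshold rule |
| full sibling (2, 2) | r + 3c/4 | gamma mixture over spliced joins (below) |
| avuncular (3, 2) | r + 3c/4 (= sibling) | Exp, mean 100/3 |
| sibling IBD2 | r + c/4 | Exp, mean 25 |

The 100/(d + c/r) form corrects the plain exponential for segments cut
at chromosome ends; it converges to 100/d as d grows. Full relatives
(a = 2) keep the plain form in classification — the boundary correction
empirically hurts close-relative accuracy with real detector output,
whose length estimates carry biases of the same order. The
ancestor–descendant substitution d → d − 1 reflects that recombinations
in the first meiosis never break pairwise sharing (a parent transmits a
gamete, which is one intact haplotype to compare against).

These forms satisfy the conservation identity
count × boundary-adjusted length = a·2^(1−d)·100·r — the expected IBD
mass, counting diploid-identical regions twice — exactly, and the test
suite verifies it against gene-dropping simulation for (d, a) ∈ {(1,0),
(2,0), (2,2), (3,2), (4,2), (6,2)} at 3 Monte-Carlo-SE tolerance. The
sibling and avuncular count forms were frozen against the same
simulator: the mean number of half-identity extents between simulated
siblings is 51.5 = r + 3c/4 at (r=35, c=22), and the mean number of
their IBD2 segments is 40.5 = r + c/4.

### Full-sibling length mixture

Detectors blind to diploid identity (GERMLINE-style) report a sibling's
IBD1 segments spliced together across intervening IBD2 stretches. With k
spliced joins a segment's length is modelled as Gamma(k + 1, 50 cM) —
50 cM being the plain sibling exponential mean — with geometric weights
w(k) ∝ q^k. The decay q = 0.0188 is a maximum-likelihood calibration
against 515,125 half-identity segment lengths from 10^4 gene-dropped
sibling pairs (seed 7), giving the mixture a 50.96 cM mean that matches
the simulated mean. A near-zero q (an almost-pure exponential) fits
best because chromosome-end truncation, which the gamma components
ignore, compresses the long spliced tail; the gamma-mixture family with
a 50 cM per-piece scale cannot reproduce the simulated length
distribution in fine detail (best Kolmogorov-Smirnov distance ≈ 0.026),
a known approximation the classifier tolerates easily since sibling
identification is dominated by segment counts and total sharing.

When IBD2 segments are reported explicitly (`use_ibd2_siblings`), the
sibling hypothesis additionally scores them as Poisson(r + c/4) counts
with 25 cM exponential lengths; every other hypothesis, and the null,
scores them as background segments arriving at rate
(background count mean)·T/(100·r) given total half-identity length T.

### Minimum segment length

Short segments are indistinguishable from deep cryptic ancestry, so
segments under t = 2.5 cM are discarded and every count mean is
multiplied by P(length ≥ t) under its length law, with densities
renormalized on [t, ∞). Exponential laws shift (memorylessness); the
sibling mixture is truncated numerically. Summary statistics quoted for
simulated IBD2 segments follow the same convention: their detectable
(≥ t) mean length is ~24 cM, a little under the 25 cM model value
because chromosome ends truncate real segments while the exponential
model ignores them; including sub-threshold fragments would give ~21.6.

## Background model and the test

Control pairs (a manifest of putatively unrelated pairs, including those
sharing nothing) yield a Poisson count mean and a shifted-exponential
length fit: mean excess = mean(length − t), the MLE. A histogram variant
on the retained control lengths is available (`kind="empirical"`); the
parametric default keeps the likelihood-ratio statistic smooth on sparse
control sets. A degenerate background (no control segment ≥ t) assigns
−∞ null log-likelihood to any observed segment, so any sharing is then
decisive evidence of relatedness.

For a pair with n segments, a hypothesis's likelihood attributes
n_p ∈ {0..n} segments to the relationship and n − n_p to the background;
the n_p longest are attributed, which attains the exhaustive-subset
optimum whenever the relationship's length density dominates the
background's at long lengths (the test suite checks equality against
brute-force enumeration for n ≤ 8). The decision statistic is
2(max log L − null log L), referred to chi-square with 2 df: one for
n_p, one for the (d, a) profile, which acts approximately as a single
parameter. The statistic is floored at zero — the alternative carries a
Poisson factor for attributing zero segments, so for null-like data the
raw gap can dip microscopically below zero at finite d_max. A 1-df
confidence cut is available (`confidence_df=1`) for the (d, a)
confidence set; 2 df is the default. Under simulation the test is
conservative: among background-drawn pairs the 0.001-level rejection
rate is well below nominal (the 0.1% p-value quantile sits near 0.01),
so α = 0.001 controls false positives with margin.

Ties across hypotheses resolve to the smaller d (the closer
relationship): deterministic and conservative for pedigree validation.
The parent-offspring threshold 0.75 + z·σ_sib uses σ_sib = 0.0435, the
standard deviation of the genome-wide half-identity fraction across the
same 10^4 simulated sibling pairs (seed 7); z = 2.33 concedes ~1% of
true siblings to the parent-offspring call by construction.

## Excess-IBD masking

The genome is tiled into 0.5 cM windows (a window well below the ≥ 5 cM
scale of reportable excess regions, so regions are resolved by ≥ 10
windows); observed control IBD per window is compared with the
uniform-sharing expectation (total observed × window/map length), and
windows with ratio > h (default 4) are coalesced into regions carrying
the length-weighted mean ratio. Applying a mask: a segment wholly
containing a region with ≥ b = 1 Mb flanks on both sides keeps its
extent but loses the region's cM length; any other crossing segment is
truncated at the boundary, scanning regions left to right so a segment
starting inside a region resumes past it; segments inside a region are
removed, as are truncation slivers under 1e-4 cM (base-pair rounding
guards). The summed masked length m lowers r to r − m/100, since
recombinations inside masked sequence are unobservable. Masking is off
by default. The packaged hg19 mask (14 regions, 119.92 cM) reflects
regions that accumulate artifactual IBD across detectors — centromeric,
assembly-gap and long-range-LD sequence.

## Gene-dropping simulator

Founders carry uniquely labelled haplotype pairs; each meiosis draws a
Poisson(L/100) crossover count per chromosome with uniform positions in
cM (no interference) and a fair-coin starting haplotype, and children's
mosaics are built down any acyclic two-parent pedigree. True IBD1/IBD2
segments are read off the founder-label mosaics exactly, and can be
emitted in the detector conventions: `exclusive` (disjoint IBD1/IBD2
runs), `germline` (half-identity extents only) or `ibd12` (extents plus
overlapping IBD2 segments). Optional noise: boundary jitter, segment
drop/insertion, and biallelic marker output with de-novo mutation
(default expected rate 1e-7 per transmitted site) and genotyping error
(0.001 per call).

The default synthetic map has 22 autosomes with human-profile lengths
summing to 3500 cM (r = 35) and mildly heterogeneous cM/Mb anchor
spacing, seeded and deterministic. The synthetic control cohort places
Poisson(4.0) segments per unrelated pair uniformly on the genome with
lengths 2.5 + Exp(1.5) cM — a few short detectable segments per pair,
the level of cryptic sharing seen among nominally unrelated members of
a homogeneous population.

What passing simulator-based tests shows — and what it does not: the
simulator produces exact Mendelian/recombinational ground truth, so it
validates the segment-count/length models, the attribution search and
the test's calibration under correct segment input. It does not emulate
detector boundary error, phasing switch error, population LD structure
or the artifact regions that motivate masking (those are planted
explicitly in masking tests), so real-data performance additionally
depends on detector quality, as the masking machinery anticipates.

## Problem sizes and numerics

Calibration statistics use 10^4 replicates (meioses or sibling pairs);
power checks use 100 pairs per degree against a background fitted from
500 simulated unrelated pairs; type-I calibration classifies 1,500–2,000
background-drawn pairs. Stochastic assertions use 3 Monte-Carlo-SE
tolerances, except quantities the models state only approximately
(sibling IBD2 mean length 25 cM), which carry 10% relative slack. The
sibling mixture truncates k at 30 (the k > 30 tail weight is < 1e-50 at
the calibrated q); log-densities use weighted log-sum-exp; Poisson
log-pmfs handle mean 0 as a point mass. Hypothesis-grid enumeration runs
d = 1..15 by default, and all randomness flows through
numpy.random.Generator seeds recorded in tests and scripts.

## Known limitations

Degree estimates beyond ~4th degree are accurate to ±1 degree rather
than exactly (the confidence set expresses this); (d, a) cannot separate
half-siblings from grandparents or avuncular pairs at equal degree
except through the family-specific sibling/avuncular forms; the
chi-square reference makes the test conservative rather than exact; and
joint count-length segment distributions (rather than independent
Poisson × exponential) would sharpen distant-relationship inference but
are not implemented.
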