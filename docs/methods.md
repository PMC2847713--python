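# Methods

## The X/autosome contrast

Because males are haploid for the non-pseudoautosomal X, a population of
N<sub>f</sub> females and N<sub>m</sub> males carries 2N<sub>f</sub> +
N<sub>m</sub> X chromosomes against 2(N<sub>f</sub> + N<sub>m</sub>)
autosomes. The X therefore drifts faster, and it spends two thirds of its
time in females, so X-vs-autosome contrasts are informative about
female-biased demography. Every module in this package is built around
that contrast: matched X and autosomal haplotype panels with males
contributing a single X row.

## Differentiation scans

delta is the absolute allele-frequency difference between two populations
at one SNP; frequencies are counted over non-missing chromosome copies
(males once on X). Sites with zero observed copies in either population
are dropped rather than scored. Hudson's pairwise F<sub>ST</sub> estimator
is used per site,

    fst = [ (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) ] / [ p1(1−p2) + p2(1−p1) ],

clipped to [0, 1]; the Weir–Cockerham alternative was considered but
Hudson's estimator is less sensitive to unequal sample sizes, which matter
here because X and autosomal copy counts differ by construction. "High"
calling is strict (value > threshold, so a value exactly at 0.9 is not
high), and a window is a high region when it holds at least one high SNP.

Ancestral states come from outgroup genotypes: an allele fixed across all
outgroup chromosome copies is ancestral; polymorphic or missing calls
leave the state unknown, with an optional override table (the equivalent
of a database lookup) filling gaps. "High derived frequency" in a
population is operationalised as derived-allele frequency ≥ 0.9 there,
with unknown-ancestral SNPs excluded from the denominator; the published
reference counts (26/159, 5/58) reproduce under this rule. Genic
enrichment is reported per delta decile ([0,0.1) … [0.9,1.0]) relative to
the panel-wide genic fraction, and the two-proportion comparison uses a
χ² test without Yates correction by default (correction available as an
option).

## TA/EX demographic grid inference

Under an infinite island model with populations of equal constant size,
X-linked and autosomal fixation indices are linked through the female
share of the effective population size x = N_f/N and of the migration
rate y = m_f/m, which enter only through c = (1 + y)/(2 − x). The package
instantiates the linearised relation as

    F'_X = M(x, y) F'_A,   F' = F/(1−F),   M(x, y) = (4/3)(2−x)/(1+y),

the unique form that depends on (x, y) through c alone and reduces to the
classic 4/3 ratio at x = y = 0.5. Every autosomal value is mapped through
this relation elementwise ("TA/EX" values) at each cell of the 99 × 99
grid over x, y ∈ {0.01, …, 0.99}. Counts of TA/EX values above the high
threshold exploit the transform's strict monotonicity (a single preimage
computation per cell); cells sharing c are computed once and are therefore
bit-identical, which also renders the count surfaces visibly banded along
equal-c diagonals and monotone in M. The rank-sum comparison against the
observed X list uses the tie-corrected normal approximation with
continuity correction (exact enumeration for tie-free combined n ≤ 20);
an all-constant input returns p = 1 with a logged warning. The one-sided
variant tests whether TA/EX values are stochastically smaller than the
observed X values — the direction of interest when asking whether the X
is more differentiated than drift alone predicts.

**Delta through an F<sub>ST</sub> map — a caveat.** Treating each delta
value as "the differentiation measure F" in the linearised map is an
interpretation, and a lossy one: delta scales roughly with √F while the
map rescales F itself, so the transformed-delta distribution is
systematically wider than the delta distribution actually generated at
F_X. In grid scans on synthetic data this shifts the non-rejection band
away from the true c. Parameter-recovery checks (and the acceptance
script) therefore run the grid scan on per-site Hudson F<sub>ST</sub>
values, for which the map is the identity relation and the band covers
the true combined term; delta surfaces remain available and reproduce the
banded structure, but their absolute band location should be read with
this bias in mind.

## AMOVA

Nested Excoffier–Quattro–Smouse sums of squares on pairwise distances:
d² between two units is the number of mismatching loci (haplotypic mode:
units are chromosome copies with 0/1 alleles; diploid mode: units are
individuals with 0/1/2 dosages, phase ignored). Pair sums are computed
from per-locus value counts (for a set S, Σ_{i<j∈S}[v_i ≠ v_j] =
C(|S|,2) − Σ_v C(m_v,2)) rather than from an explicit distance matrix;
the test suite checks this against a literal pairwise-loop oracle. Loci
are filtered per analysed group to those polymorphic within it and free
of missing calls, so different groupings use different locus counts
(reported as `n_loci_used`). Negative variance components are truncated
to zero before conversion to percentages (logged). Pseudofemales pair
random male X haplotypes without replacement within populations,
floor(n/2) pairs per population with any leftover male unused, fully
seed-determined. Bootstrap CIs resample loci with replacement (default
B = 20,000; the alternative of resampling units is available by flag as
the published procedure does not state which was used) and report 2.5/
97.5 percentiles.

## Selection scans

EHH at a flanking marker is Σ n_h(n_h−1)/(n_c(n_c−1)) over haplotype
classes identical from the core through that marker, computed outward in
both directions with an incremental partition refinement. iHH integrates
EHH by trapezoid over genetic distance (map-interpolated cM when a map is
given, else 1 cM/Mb) from the core to the first point strictly below the
cutoff (0.1), including that crossing point; when EHH stays at or above
the cutoff through the last marker on either side the score is undefined
— this is the boundary rule that leaves SNPs near chromosome ends
unscored. Raw iHS is ln(iHH_ancestral/iHH_derived); the high flag follows
the absolute-deviation rule |iHS − mean of same-derived-count SNPs| ≥ 2
(the frequency grouping is by exact observed derived-allele count, with
an optional binned mode for sparse data) rather than the usual
SD-standardised |iHS| ≥ 2. XP-EHH integrates *unpartitioned* EHH per
population with the same cutoff and boundary rules — each population
stops at its own cutoff crossing, a deliberate simplification that keeps
the iHH machinery shared — and standardises ln(iHH_A/iHH_B) to zero mean
and unit variance chromosome-wide.

Window aggregation: the iHS of a window is the ratio of flagged to scored
SNPs; XP-EHH windows take the mean standardised score with empty windows
set to 0 (their boundary convention); imported score tracks (e.g. CLR
values computed externally) take plain means with empty windows left
missing. Ranks are dense, ties broken by the smaller start coordinate,
and `top_regions` defaults to k = 10. The consecutive-window test
compares a candidate interval's mean to the means of all other same-length
sliding windows (the interval itself excluded); "elevated" means the
fraction strictly below exceeds 0.95. Haplotype-heterozygosity tracks use
the plug-in estimator H = 1 − Σ p̂² on windows of 5 consecutive SNPs
(n/(n−1) correction optional), positioned at the centre SNP, with the
ratio undefined where the denominator population is monomorphic.

## Synthetic data generator

The generator is the package's study system, not a fixture. Its defaults
describe a desk-scale analogue of a worldwide SNP panel: 6 populations
nested in 2 continental regions, 25 females + 25 males per population,
2,000 autosomal and 500 X markers, autosomal island-model differentiation
F_A = 0.10 (a worldwide-scale value), balanced female demography
x = y = 0.5, an outgroup pair fixed for the ancestral allele at 90% of
sites, and gene intervals covering ≈ 32% of markers (the genic share of
the published X panel).

Per locus an ancestral frequency is drawn Uniform(0.05, 0.95) (avoiding
near-fixed loci dominating the panels); each population's frequency is a
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) draw with F = F_A on
autosomes and F = the TA/EX image of F_A at the configured (x, y) on the
X; F → 0 degenerates to p itself. Haplotypes are mosaics of a 16-founder
pool per population: founder alleles are assigned by randomised rounding
of p·K (so the pool frequency equals the target to within 1/K — the
calibration that makes sample frequencies track the drawn frequencies
with correlation above 0.95), copying switches founders at exponential bp
distances (default rate 2.5 × 10⁻⁶/bp, ≈ 400-kb segments), and alleles
flip at 0.002/site. Equilibrium sampling was chosen over forward-time
simulation because it matches the island-model assumption exactly, is
fast, and makes parameter recovery well-posed.

Sweeps are planted, not evolved: a chosen fraction (default 0.8) of one
population's haplotypes is regenerated over a 2-Mb tract around the focal
marker from a pool of 2 founder haplotypes drawn from existing derived
carriers, forced derived at the core; non-carriers are set ancestral at
the core and otherwise untouched. Restricting the regeneration to a tract
is essential — regenerating whole chromosomes would spread the
homozygosity signal genome-wide and erase the local contrast a scan
detects.

What the generator does *not* emulate: linkage disequilibrium among
founders (founder alleles are drawn independently per site, so background
LD is purely copying-induced), realistic recombination-map heterogeneity,
ascertainment bias of genotyping arrays, mutation-model detail, and
serial-founder range expansions. Passing tests therefore demonstrate that
the statistics behave correctly under a clean island model with
haplotype-block structure, not that any particular empirical dataset
would reproduce published values.

## Problem sizes and numerical choices

The test suite and acceptance script use deliberately small panels chosen
as the smallest sizes at which each property is statistically stable:
parameter recovery uses 20 replicates of 5,000 autosomal + 1,250 X loci
in 2 populations of 50 diploids; sweep detection uses 600 X markers over
40 Mb (100 400-kb windows) with the planted-sweep defaults; AMOVA
direction checks use 8 populations of 16 diploids and 250 loci per panel.
The full 99 × 99 grid is always scanned; caching by the exact rational
value of c (integer-pair key) reduces it to one computation per distinct
combined term without changing any output. Windows are half-open,
anchored at the configured span start (so the packaged 148.8-Mb non-PAR
X layout reproduces 744 200-kb and 372 400-kb windows), and a marker on a
boundary belongs to the right-hand window. Seeds propagate through
`numpy.random.SeedSequence`; a single global seed spawns per-stage seeds
in a fixed order so stages re-run in isolation reproduce exactly.

## Known limitations

- The delta-through-F map bias described above: band *location* for delta
  surfaces is systematically shifted; use the F<sub>ST</sub> measure for
  inference about (x, y).
- AMOVA significance is not assessed (no permutation Φ-statistics); only
  bootstrap CIs over loci are provided.
- XP-EHH uses per-population cutoff stopping rather than a combined-
  population stopping rule; absolute scores are therefore not comparable
  with other implementations, though standardised ranks are.
- The haplotypic AMOVA treats distances as unweighted mismatch counts
  (appropriate for SNPs; no molecular weighting).
- Unphased heterozygous genotypes are rejected rather than phased;
  homozygous unphased diploid calls are accepted since phase is
  immaterial there.
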