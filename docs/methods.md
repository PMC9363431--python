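# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `parallelpeaks`, and what the synthetic-data tests
do and do not demonstrate about real data.

## Synthetic data: the drift model

Per-population allele frequencies are generated under a hierarchical
**Balding–Nichols** model. An ancestral derived-allele frequency `p0` is
drawn per site from Beta(a, b) (default a = 0.8, b = 2.0, skewing derived
alleles rare, as polarised site-frequency spectra do). Each branch of a
rooted population tree with drift coefficient `F ∈ [0, 1)` replaces the
parent frequency `p` by a draw from

    Beta(p (1-F)/F, (1-p) (1-F)/F)

which has mean `p` and variance `F p (1-p)`; `F = 0` copies the parent
exactly (never a division by zero), and fixed sites (p ∈ {0, 1}) stay
fixed. For two sister populations whose branches each carry drift `F`,
the population-level Hudson Fst is exactly `F` (within-pair heterozygosity
`2(1-F)p(1-p)` against between-pair `2p(1-p)`), which gives the generator
an analytically checkable calibration — the test suite verifies the
sampled-genotype estimate against a frequency-moment oracle on the same
draws.

Diploid genotypes are Binomial(2, p) per sample; the outgroup population
is fixed for the ancestral state so that outgroup-major-allele
polarisation is exact. Sites are uniformly spaced (a jitter option
exists); positions, frequencies and genotypes are all deterministic
functions of the config seed (three independent child streams of one
`SeedSequence`), and written datasets are byte-identical across reruns.

Planted features override the drifted frequencies inside their interval:

* **sweep** — `p' = p + intensity (1 - p)` in the target populations.
  Because frequency-level sweeps do not by themselves produce the
  rare-allele excess of a real hard sweep, a configurable fraction
  (default 0.8) of sites whose post-sweep target frequency lies in
  [0.25, 0.75] is removed inside the feature, inducing the negative
  Tajima's D the enrichment stage looks for.
* **shared_standing** — one identical elevated frequency in all targets.
* **introgression** — `p' = (1-m) p + m p_donor` with admixture
  proportion `m = intensity`.
* **inversion_block** — a diverged haplotype (a fixed Bernoulli(0.5)
  allele sequence drawn once per feature) segregates at frequency
  `intensity`; each target-population sample draws a karyotype
  k ~ Binomial(2, intensity) and carries k copies of the diverged
  sequence plus 2−k background draws. This produces the three-cluster
  local-PCA pattern of a real polymorphic inversion.

**What the generator does not emulate:** linkage and recombination along
chromosomes (sites are exchangeable given their frequencies), genotype
likelihood uncertainty, sequencing error, and coalescent genealogies.
Passing tests therefore demonstrate that the *estimators and inference
machinery* behave correctly on data with the assumed frequency structure;
they do not validate robustness to LD-induced autocorrelation beyond what
the planted block features create, nor to low-coverage genotyping noise.

## Window statistics

All coordinates are 0-based half-open internally (VCF converted on read,
BED written as-is). Windows sit on a fixed grid: size 5 kb, step 1 kb for
selection statistics; 50 kb non-overlapping for f_dM; window centre =
start + size/2. Windows with fewer than `min_sites` (default 10) usable
sites are null and excluded from z-scores. The default was chosen for
variance control on desk-scale simulations and is declared, not derived.

* **Hudson Fst** uses Bhatia's unbiased per-site components; the windowed
  value is the ratio of sums (the "weighted" estimator). Sites where
  either population has < 2 called haplotypes are skipped and counted.
* **PBS** clamps each windowed Fst into [0, 1−1e−9] before
  `T = -log(1-Fst)` (negative estimates are drift noise; `T` must be
  non-negative) and propagates any null input to all three branches.
* **z-scores** use the population standard deviation (ddof = 0) over all
  non-null windows of one transect; sd = 0 maps everything to 0. This is
  a normalisation, not an inference, so the convention is fixed for
  reproducibility.
* **π** sums per-site unbiased diversity `2p(1-p) n/(n-1)` (n = called
  haplotypes) over variant sites and divides by the full window length by
  default; an accessible-site denominator is available when a mask is
  supplied. Unlisted sites are treated as monomorphic.
* **Tajima's D** uses the classical constants for n haplotypes, with n
  fixed at the population's full haplotype count and only fully-called
  sites contributing; S = 0 windows are null.
* **Dxy** is computed per site as
  `[θ_AB C(nAB,2) − θ_A C(nA,2) − θ_B C(nB,2)] / (nA nB)` with
  **haplotype** counts. With haplotype counts this expression reduces
  exactly to the mean pairwise difference between one sequence from each
  population (verified against a brute-force all-pairs oracle to 1e−10);
  with diploid-individual counts it does not, so haplotype counts are
  the implemented reading.
* **Δπ** is π_high − π_low_distant when a distant lowland exists, else
  π_high − π_low. Transects lacking the distant population run in
  Fst-only mode (zFst instead of zPBS).

## HDRs, sharing and permutation nulls

Outlier windows are strictly `z > 4`. Each contributes
[centre − 50 kb, centre + 50 kb) clipped to the chromosome; overlapping
*or book-ended* intervals merge (half-open convention). Interval
arithmetic runs in a linearised genome coordinate space with a 1 bp
spacer between chromosomes so book-ended intervals on different
chromosomes never merge.

Sharing classes: *within-side SHDR* = overlap (at any position) with at
least one HDR of the same-side replicate transect; *allopatric SHDR* =
additionally overlaps at least one HDR in **each** opposite-side
transect.

The permutation null re-places the focal transect's intervals — same
number, same sizes, **before** merging — uniformly at random (chromosome
chosen proportional to length among chromosomes the interval fits on,
start uniform over valid positions), merges collisions, and recomputes
sharing against the *observed* partner sets; empirical
p = (1 + #{null ≥ observed}) / (n_perm + 1). Because the sharing
proportion is discrete, ties make this p conservative (super-uniform)
rather than exactly uniform under the null; the test suite checks
validity (rejection ≤ nominal at every level) rather than exact
uniformity. The null does not model heterogeneity in which genome regions
can participate in adaptation; no correction is attempted.

Jackknife CIs delete one contiguous genome block (default 1 Mb) at a
time, dropping focal HDRs whose midpoint falls in the block, with
SE² = (g−1)/g Σ(θ_i − θ̄)² and a normal-quantile CI. All HDRs in one
block is flagged degenerate.

## Selection-signature enrichment

Per SHDR: minimum Tajima's D (highland population), minimum Δπ, maximum
Dxy over member windows (a window belongs to the SHDR if its centre lies
inside). Nulls come from randomly placed interval sets of the observed
sizes; extrema are pooled across placed intervals (a size-stratified
option exists — pooling is exact when the observed sizes are equal and a
close approximation otherwise). The default tail assignment follows sweep
logic: minima of Tajima's D and Δπ are compared to the null-min 10th
percentile (sweeps depress both), the Dxy maximum to the null-max 90th
percentile (old sweeps and introgressed haplotypes elevate divergence).
The opposite pairing is available behind `sweep_tails=False` because the
two directions are both defensible for Δπ-like statistics in other
designs; the sweep-consistent pairing is the default as it matches the
expectations the scan is built around.

## Structure, local PCA, karyotypes

PCA operates on called dosages with mean imputation of missing values
and column centring, decomposed by full SVD with a deterministic sign
convention (largest-|loading| site positive). This substitutes called
genotypes for genotype-likelihood PCA, which is equivalent in the
high-confidence/synthetic regime this package targets. The global PCA
restricts sites to windows without high differentiation (an excluded
interval set), prunes to one site per 10 kb (greedy left-to-right), and
optionally subsamples a fraction of sites; divergent non-transect samples
(donor species, outgroup) are excluded so PC1 reflects structure among
the study populations. A configurable chromosome exclusion list covers
cases like an inversion chromosome distorting genome-wide structure.

The altitude model is OLS `local_PC1 ~ altitude_m + global_PC1` with
altitude in metres (a class-coded option exists). Relative predictor
importance is LMG partial R² — the average of each predictor's sequential
R² contribution over both orderings, which is exact for two predictors
and sums to the model R². Near-collinear predictors (|r| > 0.999) are
flagged and the association nulled.

Karyotype clustering is a deterministic 1-D k-means (k = 3, centres
initialised at the minimum, median and maximum PC1 score), labels ordered
along PC1 with the heterokaryotype in the middle; which homokaryotype is
the non-inverted arrangement is caller-supplied metadata. A 1-D
silhouette diagnostic flags non-trimodal score distributions (unimodal
data cluster near 0.5, clean karyotypes near 0.9; the warning threshold
is 0.75).

## f_dM

Per-site ABBA−BABA on derived-allele frequencies,
`num = (1−p1) p2 p3 (1−pO) − p1 (1−p2) p3 (1−pO)`, with the dynamic
denominator: at sites with p2 ≥ p1 (ties on this branch, fixed for
bit-reproducibility), pD = max(p2, p3) replaces both p2 and p3; at sites
with p2 < p1, pD = max(p1, p3) replaces p1 and p3 and the term is
negated. The windowed statistic Σnum/Σden lies in [−1, 1] and is
antisymmetric under P1↔P2. Ancestral states are polarised on the outgroup
major allele; sites where the outgroup minor-allele frequency exceeds 20%
are dropped. Windows need ≥ 20 informative sites (polarizable, with
derived variation in P1/P2/P3) to be non-null.

SHDR-level calls follow the relative rule: an SHDR is an f_dM outlier if
its maximum windowed f_dM exceeds the 90th percentile of |minimum f_dM|
across all SHDRs (SHDRs with positive minima contribute |min| too — the
literal reading of the rule). Overall enrichment is a one-sided
two-sample KS test of the maxima distribution against the |minima|
distribution, and the background comparison places SHDR-sized interval
sets 1,000 times and records the mean per-interval maximum. Note that
strong sweeps inflate f_dM at the swept windows even without gene flow
(a known property of D-like statistics), so the SHDR outlier percentages
measure *excess sharing relative to other SHDRs*, not introgression per
se; the quartet comparison (donor vs allopatric-conspecific P3) is what
separates the mechanisms.

## Pipeline and reproducibility

The pipeline expands one master seed into per-stage seeds by a fixed
counter; every stochastic operation accepts an explicit seed, and
re-running a stage reproduces its files byte-identically. A JSON manifest
records the config hash (which excludes the output directory), stage
list and seeds. Logging is line-structured (timestamp, stage, message) to
stderr and `run.log`.

## Problem sizes

The bundled analysis and the acceptance script run on a 12 Mb,
four-chromosome genome with 48,000 segregating sites and 14 populations
(4–6 diploids each), chosen so that the planted features occupy under
~10% of the genome — saturating the genome-wide z-normalisation with
signal suppresses the very outliers the scan calls, just as widespread
selection would in real data. Calibration batches use a reduced
two-transect, 0.8 Mb design over 50–100 replicates. These sizes keep the
full test suite and the acceptance run in the minutes range on one CPU
while leaving every statistic enough windows (~12,000 per transect on the
study design) for stable nulls.

## Known limitations

* No linkage: window autocorrelation in real data is stronger than the
  generator produces outside planted blocks, so real-data permutation
  nulls should use block sizes informed by the observed LD scale.
* The drift tree is a fixed forward model, not an inferred demography;
  absolute values of π/Tajima's D are not calibrated to any organism.
* Fst-only transects contribute zFst HDRs that are systematically more
  numerous than PBS HDRs (no distant-lowland control), as expected.
* Cross-species HDR comparison requires inputs already on one coordinate
  system; coordinate liftover is out of scope.
* The f_dM minimum-informative-site and outgroup-polymorphism thresholds
  follow common ABBA-BABA practice; they are declared defaults, not
  fitted quantities.
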