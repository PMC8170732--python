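# Methods

This note documents the statistical procedures implemented in `zebupop`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generators do and do not emulate, and the numerical
choices that matter for reproducibility.

## Data model and QC

A `GenotypePanel` holds an individuals × markers matrix of alt-allele
dosages in {0, 1, 2, missing} with a physical marker map (1-based base-pair
positions, strictly increasing per chromosome) and one breed label per
sample. Missing calls are a dedicated symbol (exposed as a boolean mask and
as NaN in the float dosage matrix); no numeric sentinel leaks into the
public model. For PLINK 1 files the A1 allele plays the alt role, so
dosages count A1 copies; for VCF they count ALT copies. Interval logic
downstream treats windows as half-open `[start, end)`.

QC thresholds are strict inequalities: samples are kept when their
non-missing fraction exceeds 0.9, markers when their minor-allele frequency
exceeds 0.05 in the stated sample group (the MAF scope is an explicit
argument because reasonable pipelines differ on whether pruning is
per-breed or pooled; the Ne procedure applies it per analyzed breed).
Breeds larger than 20 animals are randomly subsampled to 20 with a seeded
generator. An intensity-based GC-score criterion common in array QC is not
implementable from genotype files (no intensity data) and is therefore
absent, noted in the run log.

Allele-frequency tables record p and the number of non-missing alleles per
marker per group; a pooled frequency is exactly the sample-size-weighted
mean of per-breed frequencies when no calls are missing, which the tests
assert as an identity.

## Genomic relationship matrices and PCA

Two constructions, chosen per analysis scope:

* **VanRaden method 1**: `G = ZZ' / Σⱼ 2pⱼ(1−pⱼ)` with `Z = X − 2p`;
  positive semi-definite by construction.
* **Yang et al. (2010)**: off-diagonals scale each marker by its own
  `2pⱼ(1−pⱼ)`; the diagonal is
  `1 + (1/M) Σⱼ (x² − (1+2pⱼ)x + 2pⱼ²) / (2pⱼ(1−pⱼ))`.

Missing genotypes are mean-imputed per marker before either construction.
GRMs built across deeply diverged groups (e.g. both cattle species) skew
per-breed element summaries, so matrices are always built on an explicit
sample scope, and the centering/scaling frequencies are computed on that
scope's samples. Markers with `p(1−p) < 1e−6` on the scope are excluded
from both methods (division guard). On simulated panels the two methods
give near-identical diagonals (mean absolute difference below 0.02 at
desk-scale marker counts) and PC1 score vectors correlated above 0.99.

PCA takes the top-k eigenpairs of the GRM; scores are eigenvector ×
√eigenvalue. The sign of each component is fixed by making its
largest-magnitude loading positive, so repeated runs and both GRM variants
produce stable score tables.

Relatedness pruning removes, while any pair exceeds the 0.2 threshold, the
sample participating in the most offending pairs (ties: larger mean
off-diagonal, then larger sample index). This greedy policy is a documented
choice — the exclusion rule "drop one member of each pair" does not by
itself determine which member — and the output provably contains no
remaining pair above threshold.

## Allele-frequency correlations

For each breed pair, `R_obs` is the Pearson correlation of the two breed
frequency vectors on the shared (optionally MAF > 0.05-filtered) marker
set. Because each vector is estimated from finitely many animals, `R_obs`
is attenuated even when the true frequencies agree. With `Vp` the variance
of the pooled meta-population frequencies over the marker set and
`Ve = mean p(1−p)/(2n)` the mean binomial error variance of a breed's
estimates, the implemented expectation is the additive form

    R_exp = Vp / (Vp + Ve1 + Ve2),

and the variance-explained ratio is `R²obs/R²exp`. The exact attenuation
under identical true frequencies is the product form
`Vp / √((Vp+Ve1)(Vp+Ve2))`; the additive form is slightly conservative
(about 6% lower at n = 20 with uniform ancestral frequencies). Both are
exposed — the additive form as primary, the product form as
`expected_corr_product` for sensitivity analysis — and the tests verify the
product form against same-population resampling exactly, and the additive
form's conservative gap. The ratio can exceed 1 by sampling noise; on
low-divergence simulated breeds (F ≈ 0.01, n = 40) its mean falls in
[0.95, 1.05], while deeply diverged pools (F ≈ 0.3, n = 20) drive it well
below 0.8 — the two regimes that distinguish within-breed from
between-breed variance structure.

`Ve` averages per-marker binomial variances over markers; a Monte-Carlo
resampling test confirms this matches the empirical variance of repeated
n = 20 frequency estimates within 5%.

## F statistics

* **F_IS** (Nei): per polymorphic locus `1 − Ho/He` with `He = 2p(1−p)`,
  aggregated as the unweighted mean over loci; the SD across loci and the
  SE of the mean are both reported (diversity tables conventionally print
  "± SD"). The simple heterozygote-deficit form is used rather than the
  unbiased-ĥ variants; under simulated random mating the estimate is
  within ±0.02 of zero.
* **F_ST** (Weir–Cockerham 1984): the two-population variance components
  a, b, c per locus, aggregated as the ratio of sums `Σa / Σ(a+b+c)` (the
  estimator's recommended multi-locus form — not the mean of per-locus
  ratios, which is biased); per-locus values remain available. The
  estimator is exactly invariant to allele-label swaps and recovers
  planted Balding–Nichols divergence F ∈ {0.05, 0.1, 0.2} within ±0.02 at
  n = 50 and 20k markers.
* **f3 / f4**: per-locus products `(pA−pB)(pA−pC)` and `(pA−pB)(pC−pD)`
  averaged over loci, with standard errors from a weighted delete-one
  block jackknife over contiguous SNP blocks (default 1000 SNPs; a
  trailing short block is weighted by its SNP count; Busing et al. 1999
  weighted variance). The f3 finite-sample correction subtracts the
  unbiased variance estimate `p̂A(1−p̂A)/(2nA−1)` per locus and defaults
  on, with a flag to disable for exact algebraic tests. An f3 Z below −3
  is the conventional admixture call; the threshold is overridable.

## Runs of homozygosity

Sliding-window detection in five steps: windows of 20 SNPs advance one SNP
at a time; a window is homozygous when it contains at most 1 heterozygous
and 1 missing call (detectRUNS-style allowances, exposed in `ROHParams`);
a SNP is in-run when at least `1 − 0.05` of the windows covering it are
homozygous (SNPs near chromosome ends are covered by fewer windows and are
judged on those that exist); maximal in-run stretches become segments;
segments are split at inter-SNP gaps above 75 kb and must contain at least
20 SNPs *and* span at least 25 kb (two conjunctive minima). The alternative
reading of the window threshold (in-run when ≥ 5% of windows are
homozygous) is degenerate — nearly everything qualifies — and was rejected.
Coordinates are reported 1-based inclusive from first to last in-run SNP.

No LD or MAF pruning is applied before ROH scanning (pruning deletes
exactly the homozygous stretches being sought). `F_ROH` divides summed
segment length by the SNP-covered genome length (per chromosome, last
minus first marker position). Planted segments at twice the minimum length
are recovered with boundary error at most one window (20 SNPs): the
boundary retreats where windows begin to overlap flanking heterozygotes,
e.g. a run ending against a heterozygous region loses ~17 of 20 boundary
SNPs on a hand-traceable fixture. Detection is monotone in the window
threshold: loosening it never shrinks the total ROH length.

## Supervised ancestry and the taurine gate

With fixed reference frequencies `f_jk` (K populations) a sample's
ancestry vector q maximizes the binomial likelihood of its dosages; the
likelihood is concave in q, so multiplicative EM from the uniform start
finds the global optimum deterministically (no multi-start; monotonicity is
asserted in debug mode). Reference frequencies are clamped to
[1e−4, 1−1e−4]. Convergence is declared when the largest per-component
change of q falls below 1e−6: the likelihood flattens long before boundary
components finish their geometric decay toward 0, so a likelihood-based
stop would freeze small admixture fractions at inflated values.

The gate sums q over taurine-labeled reference columns and classifies an
animal as admixed when that total exceeds 0.01 (strict). Its resolving
power is bounded by estimator noise: at the implemented pool divergence the
ML taurine fraction of a truly pure animal is half-normal with SD ≈ 0.005
at 35k markers, so isolated pure animals can graze the 1% line. Real
taurine-ascertained arrays carry many near-fixed species differences and
push this floor far lower; the generator does not emulate that extreme, so
tests assert perfect sensitivity for planted fractions ≥ 0.05 and allow a
small false-positive margin on the pure class. Recent admixture (q varying
animal to animal) yields a wide, bimodal distribution of estimated taurine
totals, while an ancient event followed by random mating (every animal
drawing from one blended frequency pool) yields a tight unimodal
distribution — the contrast the gate's interpretation rests on.

## LD and effective population size

r² between two markers is the squared Pearson correlation of unphased
dosage vectors (the Rogers–Huff composite estimator — valid without
phasing) over samples with both calls present; zero-variance pairs are
skipped and counted. The inversion chain is

    r²adj = r² − 1/(2n),   Ne = (1/4c)(1/r²adj − 1),   t = 1/(2c),

with c the map distance at exactly 1 cM = 1 Mb (no map interpolation) and
n the per-bin mean of per-pair complete-case sample counts. Procedure per
breed: prune relatives (VanRaden GRM within breed, threshold 0.2), apply
the within-breed MAF > 0.05 filter, then

* **short range**: pairs up to 2 Mb in 80 half-open bins of 25 kb, with
  representative c at the bin midpoint (the generation range this probes
  is ~25–4000);
* **long range**: on the every-7th-marker thinned panel, pairs pooled
  harmonically so that t is the integer 1..25 — each pair is assigned
  t = round(1/(2d)) and the bin's representative c is 1/(2t). The harmonic
  scheme is the default because integer recent generations are the
  quantity of interest; an equal-width alternative (25 bins over 2–50 Mb,
  midpoint c) is selectable.

Bins with fewer than 100 pairs (default floor) or with r²adj outside
(0, 1) are dropped with a log entry; breeds analyzed with n ≤ 20 carry a
small-sample caution flag. Sved's `E[r²] = 1/(1+4Nc)` is an approximation:
its algebraic round trip is exact by construction (tested on a grid), but
the r² of a finite Wright–Fisher population deviates from the curve, and
inverting bin-mean r² skews individual estimates upward at low-information
bins. Empirically the median estimate over t ∈ [50, 500] recovers a
simulated constant Ne = 100 within ±30% across replicates, with individual
replicates scattering roughly 60–180 at the desk-scale genome size (two
10-Mb chromosomes, 50 samples).

## Synthetic data: what it does and does not emulate

* **Balding–Nichols panels**: each breed's frequency at each marker is a
  Beta draw around the ancestral frequency with parameter F; genotypes are
  Binomial(2, p) — HWE within breed, no LD, no mutation. The across-breed
  variance of breed frequencies approaches `F·p(1−p)` (asserted). F = 0
  degenerates to copying the ancestral vector.
* **Wright–Fisher engine**: forward-in-time diploid simulation with
  uniform recombination at 1 cM/Mb, free recombination between
  chromosomes, random mating with selfing, and no mutation — segregating
  sites exist only from initialization (independent Bernoulli haplotypes),
  so heterozygosity decays by `(1 − 1/(2Ne))` per generation (asserted
  against the closed form) and long runs progressively fix markers; panels
  must be seeded with enough initial markers to survive the intended
  depth. Burn-in defaults to 4 × max(Ne) generations, enough to approach
  drift–recombination equilibrium at the distances analyzed. Whole linked
  blocks occasionally fix by drift in small-genome replicates; consumers
  skip such replicates explicitly.
* **Admixed individuals**: each allele independently chooses pool a with
  probability q and is Bernoulli at that pool's frequency — a
  recent-admixture model with no linkage structure in ancestry.
* **Relatives**: offspring are produced by Mendelian transmission with
  recombination from naively phased parents (heterozygotes randomly
  assigned). Phase randomization leaves pedigree *expectations* intact
  (verified: parent–offspring and full-sib relationships average 0.500
  against true frequencies) but not within-chromosome haplotype realism.
* **Planted ROH**: genotypes inside a segment are set homozygous with the
  allele drawn at the local pooled frequency.

Not emulated: array ascertainment beyond an optional MAF floor (real
bovine arrays favor SNPs common in taurine breeds, which both biases MAF
spectra and sharpens species-ancestry estimation), mutation, selection,
X chromosomes, genotyping error, and map heterogeneity. Passing tests
therefore demonstrate estimator correctness under the stated models, not
robustness to those real-data features.

## Numerical and reproducibility choices

Every generator and the whole pipeline are pure functions of (config,
seed); a pipeline rerun is byte-identical (asserted). Random streams
derive from one root seed. Eigen-decomposition signs are fixed
deterministically. The Yang/VanRaden division guard is 1e−6 on `p(1−p)`.
The f3/f4 jackknife uses weighted blocks so a short trailing block does
not distort the SE. Degenerate inputs raise typed errors
(`FormatError`, `ConsistencyError`, `EmptyResultError`) rather than
returning silent NaNs; non-convergent EM results are flagged, not hidden.

Desk-scale defaults used throughout the tests and the acceptance script —
2–6 breeds, 20–50 samples per breed, 4k–35k markers, Ne ≤ 500 and ≤ 2000
simulated generations — keep the full battery within a few minutes on one
CPU while staying in the regimes where the estimators' published behavior
is expected to hold.
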