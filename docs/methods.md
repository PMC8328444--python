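# Methods

This note documents the models, estimators and numerical choices behind
`lcpanel`, and what the synthetic benchmarks do and do not establish.

## Read and error model

Sites are biallelic by construction, so base-calling error is collapsed to
two alleles: a read reports the true allele with probability 1−ε and the
other allele with probability ε (default ε = 0.01, a typical post-filter
substitution rate for short-read data). The same ε appears in the
simulator's read emission and in the genotype-likelihood formulas, keeping
the two self-consistent; this deviates deliberately from four-base mixture
models (ε/3 per alternative base), whose extra states add nothing once
sites are reduced to major/minor counts. No per-base qualities exist in
the simulation, so a base-quality floor is subsumed into ε.

Depth at an individual–site is Poisson with the individual's mean
coverage, drawn once per individual log-uniformly from 0.5–3.6× (the
low-coverage regime the package targets; log-uniform keeps the mass of
individuals at the shallow end, as real libraries do). Depth 0 is missing
and is encoded as the uniform likelihood triple plus an explicit mask.

## Synthetic study conditions

The generator plants four site classes on a cod-like genome
(4 chromosomes × 500 sites over 1 Mbp each by default, 100+100
individuals):

* **neutral** — Balding–Nichols divergence at baseline F<sub>ST</sub>
  0.006: each population's frequency is a Beta(p(1−F)/F, (1−p)(1−F)/F)
  draw around an ancestral p ~ U(0.05, 0.95).
* **block** (inversion analogue) — one latent biallelic "arrangement" per
  individual whose frequency diverges by F<sub>ST</sub> 0.3 via
  Balding–Nichols; all 25 block sites copy the arrangement genotype.
  This reproduces the clustered high-F<sub>ST</sub>, high-LD signature of
  a real inversion without simulating recombination suppression. Because
  a single Balding–Nichols draw governs the whole block, its realized
  divergence varies across seeds — exactly as one realized inversion
  differs between studies.
* **peak** — isolated outlier sites. These carry the nominal effect size
  *exactly*: frequencies are placed symmetrically around a mid-range
  ancestral value at the offset solving
  (2d)² / (2[p(1−p)+d²]) = F<sub>ST</sub>, with random sign. A
  Balding–Nichols draw at the same parameter often realizes near-zero
  divergence, which would make "recovery of planted outliers" a property
  of the draw rather than of the method; planted effect sizes are
  therefore deterministic per locus.
* **sex** — XY-like: females homozygous for the X variant, males
  heterozygous for a male-specific allele with probability 1−μ
  (μ = 0.02), erroneously homozygous otherwise. The leak keeps sex
  assignment from being trivially perfect.

What the generator does **not** emulate: linkage outside the block
(neutral sites are independent), realistic site ascertainment, reference
bias, mapping artifacts, indels, batch effects, and base-quality
variation. Tests passing on these data show the estimators are correct
and well calibrated under the stated model, not that the pipeline is
robust to artifacts real lcWGS data contain.

## SNP calling

MAF is the EM maximum-likelihood frequency under Hardy–Weinberg
(tolerance |Δf| < 10⁻⁶, ≤ 200 iterations, vectorized across sites).
Polymorphism is a likelihood-ratio test against the better of the two
monomorphic states (their maximum is the null MLE and makes the statistic
invariant to allele relabeling), referred to χ²(1). The HWE test profiles
the inbreeding coefficient F at the EM frequency over its feasibility
interval [max(−f/(1−f), −(1−f)/f), 1] by a 0.01-step grid plus
golden-section refinement — a derivative-free strategy that is robust for
this bounded 1-D problem. Filters: total depth in [50, 500], ≥ 150-of-222
individuals with data (scaled as ⌈0.68 N⌉ for other sample sizes, with the
absolute value available by flag), MAF ≥ 5%, SNP p < 10⁻⁶, HWE p ≤ 10⁻⁶
removed. Each criterion is an independent flag so filter order cannot
matter. Ties in major/minor at f = 0.5 break toward the smaller base code.

## Structure and the selection scan

The covariance between individuals iterates: expected dosages under
individual-frequency priors → standardized covariance (centered by the
*global* 2f; centering by the individual frequencies would subtract the
structure being estimated) → rank-K update of the individual frequencies
from the top-K eigenvectors, truncated to (1/2N, 1−1/2N), until
‖ΔΠ‖∞ < 10⁻⁴ or 100 iterations. Standardization uses global 2f(1−f)
throughout for stability at low coverage. K defaults to 2 and is
configurable; automatic K selection is out of scope.

The scan regresses each site's centered expected dosages on the top-K
eigenvectors, scales by the per-site residual SD, and — because
per-individual coverage and missingness give the z components a nonzero
genome-wide mean that is not a selection signal — centers the z vectors
across sites before the Mahalanobis statistic (z covariance estimated over
all sites; a singular estimate is ridged by 10⁻⁸ I with a warning).
Genomic control divides by λ = median(d)/χ²-median(K). On a structureless
20,000-site simulation at study coverage this yields 4.3–5.8% of p < 0.05
and λ within 0.98–1.03 across seeds. Significance uses Bonferroni α/n.

## SFS and F<sub>ST</sub>

SAF vectors come from the exact dynamic program over individuals with
multivariate-hypergeometric weights: the convolution accumulates
Σ<sub>configs</sub> Π L<sub>i</sub>(g<sub>i</sub>) C(2, g<sub>i</sub>)
and divides by C(2n, j). The denominator matters: without it the vector
is tilted by up to ~10¹³ toward mid-frequency classes, and the estimated
2D spectrum collapses onto a central blob that erases real
differentiation. Rows are max-scaled; missing individuals contribute
uniform triples rather than shrinking n, keeping vector lengths constant.

Spectra are EM mixtures (‖Δp‖₁ < 10⁻⁶, ≤ 500 iterations; the 2D E-step is
factorized through matrix products so the sites × classes² tensor is never
materialized). Folding collapses (j, 2n−j) onto minor-allele classes with
single weight on the central class; the F<sub>ST</sub> path uses unfolded
spectra with global-minor polarization, which is equivalent in this
two-population setting. Per-site components are posterior expectations of
the Hudson/Bhatia numerator and denominator — chosen over Reynolds for
robustness to unequal sample sizes — under the 2D-SFS prior; the global
estimate is the ratio of sums, and windows (1,000 bp / 100 bp step,
1-based inclusive, configurable; window units are base pairs) report the
same ratio over contained sites, omitting empty windows.

Known limitation: with only ~2,000 sites informing the 2D SFS at ~1.5×,
the posterior-expectation components are strongly shrunk toward the
genome-wide spectrum; per-site ratios remain well ordered (ranking and
window contrasts work) but per-site magnitudes are conservative. At 20×
the global estimate matches the genotype-based oracle to < 0.001.

## Random forests, GRRF, imputation

CART classification trees (Gini, bootstrap, grown to purity, minimum node
size 1, no depth limit or class weighting, majority leaves,
mtry = ⌊√p⌋) are implemented directly on dosage features in {0, 1, 2},
which admit only two split points per feature; numba kernels make
thousands of trees cheap. Importance is out-of-bag permutation mean
decrease accuracy averaged over trees with non-empty OOB. The GRRF
penalty is forest-level and incremental (a feature not yet used anywhere
in the forest so far has its gain multiplied by
λ_j = (1−γ) + γ·imp_j/max(imp), negatives floored at zero): this is the
variant that produces compact feature sets. One preliminary plain forest
guides all ten runs (independently seeded); selection is positive MDA in
any run, ranked by mean MDA with ties broken by locus id.

At desk scale (~2,000 candidate loci, 500 trees per forest — the default
for tests; 5,000 is supported) nearly every locus is used somewhere in a
forest, so the union-of-positive-MDA *selected set* is large; in a
study-scale regime (millions of candidates) most loci are never used and
have exactly zero importance, giving small selected sets. The *ranking*
by mean importance, which the recovery benchmarks test, behaves the same
way in both regimes.

Imputation initializes missing entries at the within-class mode and then
iterates forest fit → proximity (fraction of trees sharing a leaf) →
proximity-weighted average of observed entries per column, rounded to
{0, 1, 2}; observed entries never change. Positive-F<sub>ST</sub>
filtering precedes imputation. Because the response is the phenotype,
imputation leaks a small amount of class signal into noise loci
(measured: mean |corr with label| 0.074 vs 0.068 under class-blind mode
imputation at 22% missingness); this mirrors standard practice and is an
accepted bias of the workflow.

## Assignment

Folds are class-stratified (sizes differ by ≤ 1 overall and per class;
unstratified small folds can lose a class entirely) and seeded from
(run seed, K) so each K reuses its folds across panel sizes. The default
classifier is center/scale → top min(p, n−2, 10) training-set principal
components → linear discriminant with pooled covariance (ridge 10⁻⁸);
Gaussian naive Bayes and the package's forest are selectable. Assignment
rate is micro-averaged over individuals so fold-size imbalance cannot
bias it; the headline curve is the mean over K = 2..10 at panel sizes
5, 10, …, plus the full list when not a multiple of five. For the default
model the nested panels are evaluated incrementally via Gram-matrix
updates and an n × n eigendecomposition — algebraically identical to the
per-panel SVD, verified to machine precision.

Panel-restricted PCA reuses the likelihood covariance on the panel loci
and summarizes each group by the mean and covariance of its first two PC
scores (95% normal ellipses).

## Benchmark problem sizes

The validation scenarios use 2 × 50 diploids × 2,000 loci at 20× for
F<sub>ST</sub> recovery (tolerance ±0.02 against the genotype oracle),
12 runs of 1,000 loci at 5× for monotonicity, 5,000 sites at 30× for SFS
recovery (ℓ₁ < 0.02), 20,000 structureless sites for scan calibration,
and 100+100 individuals × 2,000 loci at 1.5× for the panel-recovery
scenarios (GRRF at 500 trees, 10 runs). These sizes make the full
benchmark suite run in minutes while leaving each check statistically
sharp; all scenario seeds derive from a single user seed.
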