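# Methods

## Model

A replicated time course for one gene in one condition is a set of vectors
m^r observed on per-replicate time grids (hours). Each replicate is modelled
as multivariate normal with a shared latent mean profile μ(t) and covariance

    Σ = v · exp(−|t − t′| / d) + σ² I .

The Ornstein–Uhlenbeck term captures systematic, temporally correlated
variability (cell-to-cell regulation state, batch drifts); the diagonal term
captures measurement noise. The latent mean has a zero-mean GP prior with
its own OU kernel, Σ₀ = ψ · exp(−|t − t′| / δ). Both kernels use the
length-scale-in-denominator parameterisation, so δ and d are in hours.

Conditioning on the replicates gives the posterior mean of the latent
profile on the union grid G of all replicate time points,

    μ̄ = (Σ₀(G,G)⁻¹ + Σ_r S_rᵀ Σ(g_r)⁻¹ S_r)⁻¹ (Σ_r S_rᵀ Σ(g_r)⁻¹ m^r),

where S_r selects replicate r's rows of G. When every replicate shares one
grid this is the textbook shrinkage form (Σ₀⁻¹ + N_r Σ⁻¹)⁻¹ N_r Σ⁻¹ m_a
with m_a the element-wise replicate average. The ragged form exists because
real treatment designs measure different conditions at different time
points (e.g. vehicle at 0/2/6/12/24 h but high dose only at 6/12 h).

### Empirical-Bayes fitting

The five hyperparameters θ = (δ, ψ, d, v, σ²) are given independent
Gamma(shape = 0.1, scale = 100) priors — deliberately vague, admitting
several orders of magnitude — and estimated by maximising the plug-in
objective

    log p(θ | m) = Σ_r log N(m^r ; μ̄(θ), Σ(θ)) + Σ_k log Gamma(θ_k | a, b).

This is an empirical plug-in rather than a true marginalisation over μ
(which would inflate the data covariance by Σ₀); the plug-in form is cheap,
and the quantities consumed downstream (likelihood ratios, rankings) are
robust to the distinction. Optimisation runs in log-parameter space with
L-BFGS-B, bounds [1e−6, 1e6] on every parameter, an analytic gradient
(the chain-rule terms through μ̄ reduce to quadratic forms in
s = Σ₀⁻¹μ̄; verified against finite differences in the test suite), and a
data-driven start (variances from the sample variance, length-scales at a
third of the observed span). Restarts perturb the start log-normally with
deterministic seeds derived from the optimizer seed and the gene id; the
search stops early once two independent starts agree to 1e−3 in objective.
Default 5 restarts; 150 iterations and a relative tolerance of 1e−7 per
start. Covariance factorisations use Cholesky with escalating diagonal
jitter (0 → 1e−10 → 1e−8 → 1e−6); all densities are computed in log space.
Non-convergence never raises: the best point found is returned flagged.

### Likelihood-ratio test

Differential expression between conditions A and B compares a single GP
fitted to the pooled replicates (null) against independent per-condition
fits (alternative); the alternative fits are warm-started from the null MAP
so optimiser noise cannot produce a negative statistic, and any residue is
clipped at zero. The statistic 2(ℓ_alt − ℓ_null) is referred to a χ²
distribution with

    df = 5 + |G_A| + |G_B| − |G_pooled| .

The count includes the extra plug-in mean profile freed by the split, not
just the 5 extra hyperparameters: because the plug-in likelihood re-fits
μ̄ under each hypothesis with only weak shrinkage, each refit behaves like
|G| free mean parameters, and a bare 5-df reference would be badly
anticonservative (measured ~50% false positives at p < 0.05 on null genes,
versus ~5% with the corrected count). The reference remains a Wilks-style
heuristic — the test suite asserts only coarse calibration (false-positive
fraction in [0, 0.15] at p < 0.05) — and every ranking-based result is
unaffected by the choice within a cohort sharing one design. Cohort-level
multiplicity uses Benjamini–Hochberg step-up control (statsmodels), applied
per test cohort.

## Simulator

The generator emulates a two-condition microarray time-course benchmark.
Per gene and condition: a smoothing parameter l is drawn from a gamma
distribution, a mean profile μ from GP(0, K_l) with the Gaussian kernel
K_l = exp(−(t−t′)²/l), and each replicate as μ + (its own draw from
GP(0, K_l)) + N(0, noise_sd²) — replicates therefore carry unit-variance
systematic variability plus iid noise, matching the model's two covariance
components. Non-DE genes share μ and l (shape-15 gamma) across conditions
exactly; DE genes draw both independently per condition, with the shape-25
gamma for condition 2. Defaults are the benchmark design: 1000 genes, 10
equally spaced times from 0 to 100 h inclusive, 4 replicates, DE labels
Bernoulli(0.5), noise sd 0.2, Gamma(15, 1) / Gamma(25, 1) smoothing.

At these settings the Gaussian kernel's correlation between adjacent grid
points is tiny (exp(−11.1²/15) ≈ 3·10⁻⁴), so mean profiles are effectively
rough; the per-replicate systematic component is what calibrates the pooled
baselines' null distribution. `systematic_scale=0` switches the replicates
to exact noisy copies of μ (useful for noise-level checks). What the
simulator does **not** emulate: probe effects, background/saturation,
intensity-dependent variance, missingness — so passing benchmarks show
ranking power under the model's own assumptions, not robustness to
array-specific artifacts.

The time axis of "10 equal intervals over 100 hours" is read as 10 equally
spaced points including both endpoints; the 11-point and 10..100 readings
were checked and shift the benchmark AUROCs by < 0.002.

## Benchmark

Methods score every gene of a simulated dataset; genes are ranked by
p-value (score 1 − p, ties from underflow broken by the statistic's
magnitude) and the ranking is scored by AUROC against the ground-truth
labels (Mann–Whitney convention, ties half). Baselines pool all
timepoint × replicate values per condition into one sample per group — the
natural "static test" reading — and apply a Student two-sample t-test
(Welch optional) or a Wilcoxon rank-sum (exact for untied n ≤ 20, normal
approximation with tie correction otherwise; the vectorised benchmark path
uses the normal approximation throughout, which cannot change a ranking).
Runs are reproducible from a single seed (per-dataset seeds from a
SeedSequence) and independent of method order; optional per-dataset JSON
checkpoints make long runs resumable.

## Marker screen

The five-test screen contrasts drug-responsive and non-responsive cell-line
groups: (1) vehicle controls of the two groups against each other; (2, 3)
responsive control vs responsive low/high dose; (4, 5) non-responsive
control vs non-responsive low/high dose. Cell lines within a group are
pooled as replicates of one GP (cell-line identity is not a covariate);
BH-FDR at 5% is applied within each test across probes; a probe is called a
marker iff it passes 1, passes 2 or 3, and fails both 4 and 5. Missing
replicates are imputed once, up front, from N(mean, sd²) of the observed
replicates in the same (cell line, dose, time) group, with a recorded seed,
so every test sees identical data; probes with fewer than two observed
replicates in a group are flagged and excluded, never silently dropped.
`make_table1_fixture` builds a synthetic ragged study (controls at
0/2/6/12/24 h, treated conditions at the dose-specific subsets, 4
replicates) with engineered probe classes — true markers plus four decoy
classes — whose amplitude (1.5) and smoothing (50 h², giving ≈0.5
correlation at a 6 h lag) produce strong but not saturated signal at noise
sd 0.2.

## Problem sizes and known limitations

- The default test suite and the acceptance script run the baselines at the
  full 100-dataset × 1000-gene scale (seconds, vectorised) and the GP test
  at 5 datasets × 200 genes (≈0.95 mean AUROC, a minute or two); the GP
  test's mean AUROC at this scale matches the full-scale figure to well
  within its across-dataset spread.
- σ² is weakly identified when v dominates and the grid spacing exceeds the
  data length-scale d: the OU term can absorb the nugget, and the
  Gamma(0.1, 100) prior (density unbounded at 0) then pulls the σ² MAP to
  the lower bound. On self-simulated data with v = 1, d = 20 h and an 11 h
  grid, v and d recover within a factor ~1.3 but σ̂² collapses; designs with
  finer sampling or smaller v/σ² identify it cleanly. For the same reason
  the posterior-mean RMSE on such data is bounded below by the replicate
  averaging floor √(v+σ²)/√N_r, not by σ alone.
- The χ²(df) reference is heuristic; for decision-critical FDR control on
  real data a permutation null remains the conservative alternative (out of
  scope here).
- Raw array processing (.cel normalisation) and probe→gene mapping are out
  of scope: the pipeline consumes already-normalised TSV matrices, and the
  documentation recommends log2-scale intensities (`--log2` applies
  log2(x+1)).
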