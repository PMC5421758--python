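# gptimediff

Gaussian-process differential analysis of replicated time-course gene
expression.

## The problem

Time-course expression experiments ask whether a gene's *temporal* profile
differs between two conditions — drug vs vehicle, responsive vs
non-responsive cell lines — not merely whether its average level shifts.
Static tests (two-sample t, Wilcoxon rank-sum) pool away the time axis and
lose exactly the structure of interest, while each measurement carries both
random noise and systematic, temporally correlated biological variability.
`gptimediff` is for analysts of replicated microarray or RNA time courses
(typically 3–10 time points, 3–4 replicates, possibly different time points
per condition) who want a calibrated, fast test for differential temporal
expression plus the surrounding screening machinery.

## The model

A gene's replicate profile m_i^r(t) is modelled as multivariate normal with
latent mean profile μ_i(t) and covariance

    Σ_i = v_i · exp(−|t−t′| / d_i) + σ_i² I,

an Ornstein–Uhlenbeck kernel (systematic variability) plus iid noise. The
mean profile itself has a zero-mean GP prior with OU covariance
Σ₀ = ψ_i · exp(−|t−t′| / δ_i). Conditioning on the data gives the shrinkage
posterior mean

    μ̄_i = (Σ₀⁻¹ + N_r Σ_i⁻¹)⁻¹ N_r Σ_i⁻¹ m_a,

(m_a the replicate average; a ragged-grid generalisation handles replicates
observed at different time points). Substituting μ̄_i into the likelihood and
multiplying by flat Gamma(0.1, 100) priors on the five hyperparameters
(δ, ψ, d, v, σ²) yields a marginal posterior that is maximised by bounded
multi-start L-BFGS-B with an analytic gradient.

Differential expression is decided by a likelihood-ratio test: one shared GP
for both conditions (null) against condition-specific GPs (alternative),
with the statistic 2(ℓ_alt − ℓ_null) referred to χ² with
df = 5 + |G_a| + |G_b| − |G_pooled| and Benjamini–Hochberg FDR control
across genes. A hierarchical-GP simulator (Gaussian-kernel mean functions,
gamma-distributed smoothing, per-replicate systematic variability, noise
sd 0.2) provides ground-truthed data for benchmarking, and a five-test
screen combines LRTs into marker calls for drug-insensitivity studies.

## Worked example

Simulate a small two-condition dataset and test one differentially
expressed gene:

```python
from gptimediff import SimConfig, simulate_dataset, lr_test

ds = simulate_dataset(SimConfig(n_genes=30, seed=1))
cond_a, cond_b = ds.time_course_pair(2)      # a DE gene in this dataset
res = lr_test(cond_a, cond_b)
print(f"LR = {res.lr_stat:.1f} (df {res.df}), p = {res.p_value:.3g}")
```

prints

```
LR = 75.2 (df 15), p = 5.16e-10
```

— the shared-GP null is rejected decisively: this gene's two conditions
need separate mean profiles. A non-DE gene from the same dataset (index 0)
gives `LR = 14.1 (df 15), p = 0.521`.

The same comparison at cohort scale, from the shell:

```
gptimediff benchmark --methods geagp,t_test,ranksum \
    --n-genes 200 --n-datasets 3 --seed 7 --out-dir bench/
```

writes per-dataset and summary CSVs in which the GP test reaches a mean
AUROC of ≈ 0.94 against the simulator's ground-truth labels while the
pooled t-test and rank-sum stay near 0.73 — the time-aware test recovers
differential genes the static tests cannot. Other commands: `simulate`,
`screen` (the five-test marker pipeline), `gp-test`, `rq`, `corr-screen`,
`make-fixture`; all honour `--seed` and write a resolved-config snapshot
next to their outputs.

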