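"""Hierarchical-GP simulator for two-condition time-course expression data.

Each gene/condition has a latent mean profile drawn from a zero-mean GP with
Gaussian (squared-exponential) kernel ``exp(-(t - t')^2 / l)``; the smoothing
parameter ``l`` is itself drawn from a gamma distribution.  Each replicate is
the mean profile plus its own systematic-variability draw from the same
Gaussian-kernel GP plus iid Gaussian noise — i.e. replicates are MVN(mu,
K_l + noise_sd^2 I) draws.  Non-differentially-expressed genes
share one mean profile (and one ``l``, drawn with shape 15) across both
conditions; differentially expressed genes get independent profiles per
condition, with ``l ~ Gamma(15, 1)`` in condition 1 and ``Gamma(25, 1)`` in
condition 2.  Defaults reflect the benchmark design: 1000 genes, 10 equally
spaced time points spanning 100 h, 4 replicates, ~50% DE, noise sd 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gp_core import TimeCourseSet, as_time_grid

#: jitter added to the Gaussian kernel before factorisation (near-singular
#: for large smoothing values)
MEAN_KERNEL_JITTER = 1e-8


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1000
    n_timepoints: int = 10
    horizon: float = 100.0
    n_replicates: int = 4
    de_fraction: float = 0.5
    noise_sd: float = 0.2
    #: amplitude multiplier of the per-replicate systematic-variability draw;
    #: 1.0 is the generative model (replicate covariance K_l + noise_sd^2 I),
    #: 0.0 makes replicates exact noisy copies of the mean profile
    systematic_scale: float = 1.0
    gamma_null: tuple = (15.0, 1.0)   # (shape, scale) for non-DE / condition-1 l
    gamma_alt: tuple = (25.0, 1.0)    # (shape, scale) for DE condition-2 l
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_timepoints < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.systematic_scale < 0:
            raise ValueError("systematic_scale must be >= 0")
        for shape, scale in (self.gamma_null, self.gamma_alt):
            if shape <= 0 or scale <= 0:
                raise ValueError("gamma shapes and scales must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Equally spaced sampling times from 0 to horizon inclusive."""
        return np.linspace(0.0, self.horizon, self.n_timepoints)


@dataclass
class SimulatedDataset:
    """values has shape (n_genes, 2 conditions, n_replicates, n_timepoints)."""

    times: np.ndarray
    values: np.ndarray
    de_labels: np.ndarray
    realized_l: np.ndarray       # (n_genes, 2)
    realized_mu: np.ndarray      # (n_genes, 2, n_timepoints)
    config: SimConfig

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def gene_id(self, gene: int) -> str:
        return f"g{gene:05d}"

    def time_course_pair(self, gene: int):
        """The gene's data as one TimeCourseSet per condition."""
        sets = []
        for cond in (0, 1):
            reps = [(self.times, self.values[gene, cond, r])
                    for r in range(self.config.n_replicates)]
            sets.append(TimeCourseSet(gene_id=self.gene_id(gene), replicates=reps,
                                      condition_label=f"cond{cond + 1}"))
        return tuple(sets)


def _gaussian_kernel_cholesky(grid: np.ndarray, smoothing: float) -> np.ndarray:
    """Lower Cholesky factor of exp(-(t-t')^2 / smoothing) with jitter."""
    diff = grid[:, None] - grid[None, :]
    kernel = np.exp(-(diff * diff) / smoothing)
    for jit in (MEAN_KERNEL_JITTER, 1e-6):
        try:
            return np.linalg.cholesky(kernel + jit * np.eye(grid.size))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("Gaussian kernel not factorisable")


def sample_mean_function(grid, smoothing: float, rng: np.random.Generator) -> np.ndarray:
    """One draw from GP(0, exp(-(t-t')^2 / smoothing)) on the grid.

    Each coordinate is marginally standard normal (up to the stabilising
    jitter).
    """
    if not (np.isfinite(smoothing) and smoothing > 0):
        raise ValueError(f"smoothing must be > 0, got {smoothing!r}")
    grid = as_time_grid(grid)
    return _gaussian_kernel_cholesky(grid, smoothing) @ rng.standard_normal(grid.size)


def simulate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Generate one two-condition dataset with ground-truth DE labels.

    Fully reproducible from ``config.seed``: DE membership is an independent
    Bernoulli(de_fraction) per gene, then draws proceed gene by gene in a
    fixed order.
    """
    rng = np.random.default_rng(config.seed)
    times = config.times
    n_g, n_r, n_t = config.n_genes, config.n_replicates, config.n_timepoints
    de_labels = rng.random(n_g) < config.de_fraction
    values = np.empty((n_g, 2, n_r, n_t))
    realized_l = np.empty((n_g, 2))
    realized_mu = np.empty((n_g, 2, n_t))
    a0, b0 = config.gamma_null
    a1, b1 = config.gamma_alt
    for g in range(n_g):
        l1 = rng.gamma(a0, b0)
        chol1 = _gaussian_kernel_cholesky(times, l1)
        mu1 = chol1 @ rng.standard_normal(n_t)
        if de_labels[g]:
            l2 = rng.gamma(a1, b1)
            chol2 = _gaussian_kernel_cholesky(times, l2)
            mu2 = chol2 @ rng.standard_normal(n_t)
        else:
            l2, mu2, chol2 = l1, mu1, chol1
        realized_l[g] = (l1, l2)
        realized_mu[g, 0], realized_mu[g, 1] = mu1, mu2
        for cond, (mu, chol) in enumerate(((mu1, chol1), (mu2, chol2))):
            # each replicate: its own systematic GP draw plus iid noise
            systematic = config.systematic_scale * (
                chol @ rng.standard_normal((n_t, n_r))).T
            noise = rng.normal(scale=config.noise_sd, size=(n_r, n_t)) \
                if config.noise_sd > 0 else 0.0
            values[g, cond] = mu + systematic + noise
    return SimulatedDataset(times=times, values=values, de_labels=de_labels,
                            realized_l=realized_l, realized_mu=realized_mu, config=config)


# ---------------------------------------------------------------------------
# writers (expression TSV + sample sheet + truth labels)
# ---------------------------------------------------------------------------

def dataset_to_frames(ds: SimulatedDataset):
    """Expression matrix, sample sheet and label frames for a dataset.

    Columns follow the pipeline's input convention: rows = genes, one column
    per (condition, replicate, time) sample.
    """
    n_g, _, n_r, n_t = ds.values.shape
    sample_ids, records, columns = [], [], []
    for cond in (0, 1):
        label = f"cond{cond + 1}"
        for r in range(n_r):
            for k, t in enumerate(ds.times):
                sid = f"{label}_r{r + 1}_t{t:g}"
                sample_ids.append(sid)
                records.append({"sample_id": sid, "cell_line": "sim",
                                "treatment": label, "dose_uM": 0.0,
                                "time_h": float(t), "replicate": r + 1})
                columns.append(ds.values[:, cond, r, k])
    matrix = pd.DataFrame(
        np.column_stack(columns), columns=sample_ids,
        index=pd.Index([ds.gene_id(g) for g in range(n_g)], name="probe_id"),
    )
    sheet = pd.DataFrame(records)
    labels = pd.DataFrame({"gene_id": matrix.index, "is_de": ds.de_labels.astype(int)})
    return matrix, sheet, labels


def write_dataset(ds: SimulatedDataset, out_dir) -> dict:
    """Write expression.tsv, samples.tsv and labels.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, sheet, labels = dataset_to_frames(ds)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "labels": out / "labels.tsv",
    }
    matrix.to_csv(paths["expression"], sep="\t")
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    labels.to_csv(paths["labels"], sep="\t", index=False)
    return paths
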