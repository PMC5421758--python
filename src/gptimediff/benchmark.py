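"""AUROC benchmark of DE-detection methods on simulated time courses.

Compares the GP likelihood-ratio test against the two "static" baselines —
a two-sample t-test and a Wilcoxon rank-sum test applied to all timepoint x
replicate values pooled per condition — by ranking genes by p-value and
scoring the ranking against the simulator's ground-truth DE labels with the
area under the ROC curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from pathlib import Path
from scipy import stats
from sklearn.metrics import roc_auc_score

from .difftest import lr_test
from .gp_core import OptimizerSettings, PriorConfig, TimeCourseSet
from .simulate import SimConfig, SimulatedDataset, simulate_dataset

logger = logging.getLogger("gptimediff")

METHODS = ("geagp", "t_test", "ranksum")


@dataclass
class BenchmarkResult:
    method: str
    per_dataset_auroc: np.ndarray
    mean_auroc: float
    sd_auroc: float


def _pooled(cond: TimeCourseSet) -> np.ndarray:
    return cond.all_values


def pooled_t_test(cond_a: TimeCourseSet, cond_b: TimeCourseSet,
                  equal_var: bool = True) -> float:
    """Two-sided two-sample t-test on all values pooled per condition."""
    a, b = _pooled(cond_a), _pooled(cond_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 pooled values per condition")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return 1.0 if not np.isfinite(p) else p


def pooled_ranksum(cond_a: TimeCourseSet, cond_b: TimeCourseSet) -> float:
    """Two-sided Wilcoxon rank-sum test on all values pooled per condition.

    Exact null distribution for small untied samples (both n <= 20); normal
    approximation with tie correction otherwise.
    """
    a, b = _pooled(cond_a), _pooled(cond_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 pooled values per condition")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return 1.0 if not np.isfinite(p) else p


def auroc(scores, labels) -> float:
    """AUROC with ties counted half (Mann-Whitney U / (n+ * n-))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# per-dataset gene scorers (vectorised where the test allows)
# ---------------------------------------------------------------------------

def _flat(values: np.ndarray) -> np.ndarray:
    """(n_genes, n_rep, n_t) -> (n_genes, n_rep * n_t)."""
    return values.reshape(values.shape[0], -1)

def _scores_from(p: np.ndarray, stat: np.ndarray) -> np.ndarray:
    """Larger = more likely DE: 1 - p, with p-value underflow (p == 0) broken
    by the magnitude of the underlying statistic."""
    score = 1.0 - p
    under = p == 0.0
    if under.any():
        score[under] = 1.0 + np.abs(stat[under])
    return score


def _score_t_test(ds: SimulatedDataset) -> np.ndarray:
    a, b = _flat(ds.values[:, 0]), _flat(ds.values[:, 1])
    res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return _scores_from(p, np.where(np.isfinite(res.statistic), res.statistic, 0.0))


def _score_ranksum(ds: SimulatedDataset) -> np.ndarray:
    a, b = _flat(ds.values[:, 0]), _flat(ds.values[:, 1])
    res = stats.ranksums(a, b, axis=1)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return _scores_from(p, np.where(np.isfinite(res.statistic), res.statistic, 0.0))


def _score_geagp(ds: SimulatedDataset, prior: PriorConfig,
                 optimizer: OptimizerSettings) -> np.ndarray:
    p = np.ones(ds.n_genes)
    lr = np.zeros(ds.n_genes)
    for g in range(ds.n_genes):
        cond_a, cond_b = ds.time_course_pair(g)
        try:
            res = lr_test(cond_a, cond_b, prior=prior, optimizer=optimizer)
            p[g], lr[g] = res.p_value, res.lr_stat
        except Exception as exc:  # a failed gene counts with p = 1
            logger.warning("geagp failed on gene %s: %s", ds.gene_id(g), exc)
    return _scores_from(p, lr)


_SCORERS = {"t_test": lambda ds, prior, opt: _score_t_test(ds),
            "ranksum": lambda ds, prior, opt: _score_ranksum(ds),
            "geagp": _score_geagp}


def dataset_seeds(seed: int, n_datasets: int) -> np.ndarray:
    """Deterministic per-dataset simulation seeds derived from one run seed."""
    return np.random.SeedSequence(seed).generate_state(n_datasets) % (2**31)


def run_benchmark(config: SimConfig, methods, n_datasets: int, seed: int = 0,
                  prior: PriorConfig = PriorConfig(),
                  optimizer: OptimizerSettings = OptimizerSettings(),
                  work_dir=None) -> list[BenchmarkResult]:
    """Simulate ``n_datasets`` datasets and AUROC-score each method on each.

    Results are independent of method order.  If ``work_dir`` is given,
    per-dataset AUROCs are checkpointed as JSON so an interrupted run resumes
    where it stopped; checkpoints with a mismatched seed are recomputed.
    """
    methods = list(methods)
    unknown = [m for m in methods if m not in _SCORERS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid: {sorted(_SCORERS)}")
    seeds = dataset_seeds(seed, n_datasets)
    per_method = {m: np.empty(n_datasets) for m in methods}
    work = Path(work_dir) if work_dir is not None else None
    if work is not None:
        work.mkdir(parents=True, exist_ok=True)

    for i, ds_seed in enumerate(seeds):
        ckpt = work / f"dataset_{i:04d}.json" if work is not None else None
        cached = {}
        if ckpt is not None and ckpt.exists():
            try:
                payload = json.loads(ckpt.read_text())
                if payload.get("seed") == int(ds_seed):
                    cached = payload.get("auroc", {})
                else:
                    logger.warning("checkpoint %s has stale seed; recomputing", ckpt)
            except (json.JSONDecodeError, OSError):
                logger.warning("corrupt checkpoint %s; recomputing", ckpt)
        todo = [m for m in methods if m not in cached]
        if todo:
            ds = simulate_dataset(replace(config, seed=int(ds_seed)))
            # run in canonical order so method order never changes results
            for m in sorted(todo):
                scores = _SCORERS[m](ds, prior, optimizer)
                cached[m] = auroc(scores, ds.de_labels)
            if ckpt is not None:
                ckpt.write_text(json.dumps({"seed": int(ds_seed), "auroc": cached}))
        for m in methods:
            per_method[m][i] = cached[m]
        logger.info("benchmark dataset %d/%d done", i + 1, n_datasets)

    results = []
    for m in methods:
        vals = per_method[m]
        results.append(BenchmarkResult(
            method=m, per_dataset_auroc=vals,
            mean_auroc=float(vals.mean()),
            sd_auroc=float(vals.std(ddof=1)) if n_datasets > 1 else 0.0,
        ))
    return results
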