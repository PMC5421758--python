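"""Gaussian-process model of replicated time-course expression profiles.

A gene's time-course measurements ``m_i^r(t)`` (replicate ``r``) are modelled
as draws from a multivariate normal with latent mean profile ``mu_i(t)`` and
covariance ``Sigma_i = v * exp(-|t - t'| / d) + sigma2 * I`` — an
Ornstein-Uhlenbeck kernel capturing systematic temporal correlation plus iid
Gaussian noise.  The latent mean itself carries a zero-mean GP prior with OU
covariance ``Sigma_0 = psi * exp(-|t - t'| / delta)``.  Conditioning on the
data and plugging the posterior-mean profile back into the likelihood gives a
marginal posterior over the five hyperparameters ``(delta, psi, d, v,
sigma2)``, each under a flat Gamma(shape=0.1, scale=100) prior.  MAP estimates
are found by bounded multi-start quasi-Newton optimisation in log-parameter
space.

Replicates may be observed on different ("ragged") time grids: the likelihood
is a product of per-replicate multivariate normals sharing hyperparameters,
and the posterior mean generalises to

    mu_bar = (Sigma0(G,G)^-1 + sum_r S_r' Sigma(g_r)^-1 S_r)^-1
             (sum_r S_r' Sigma(g_r)^-1 m_r)

on the union grid G, where S_r selects replicate r's rows of G.  With equal
grids this reduces exactly to the classical shrinkage form
``(Sigma0^-1 + N_r Sigma^-1)^-1 N_r Sigma^-1 m_a`` with ``m_a`` the
replicate-average vector.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.linalg.lapack import dpotrf, dpotri
from scipy.optimize import minimize
from scipy.special import gammaln

logger = logging.getLogger("gptimediff")

LOG2PI = float(np.log(2.0 * np.pi))

#: escalation schedule for diagonal jitter when a Cholesky factorisation fails
JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


class ParameterDomainError(ValueError):
    """A kernel or prior parameter outside its domain (must be > 0, finite)."""


class GPNumericalError(RuntimeError):
    """Covariance factorisation failed even after jitter escalation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def as_time_grid(times) -> np.ndarray:
    """Validate and return a strictly increasing, finite, non-negative grid."""
    grid = np.asarray(times, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("time grid must be a non-empty 1-D vector")
    if not np.all(np.isfinite(grid)) or np.any(grid < 0):
        raise ValueError("time grid values must be finite and >= 0")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    return grid


@dataclass(frozen=True)
class KernelParams:
    """The five GP hyperparameters of one fitted model.

    delta, d are OU length-scales in hours; psi, v, sigma2 are variances in
    squared expression units (psi: mean-prior, v: data, sigma2: noise).
    """

    delta: float
    psi: float
    d: float
    v: float
    sigma2: float

    def __post_init__(self):
        for name, val in self.__dict__.items():
            if not np.isfinite(val) or val <= 0:
                raise ParameterDomainError(
                    f"{name} must be strictly positive and finite, got {val!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.psi, self.d, self.v, self.sigma2])

    @classmethod
    def from_array(cls, arr) -> "KernelParams":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class PriorConfig:
    """Gamma(shape, scale) prior shared by all five hyperparameters."""

    shape: float = 0.1
    scale: float = 100.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterDomainError("gamma shape and scale must be > 0")

    def log_pdf(self, theta: np.ndarray) -> float:
        """Sum of log Gamma densities over the parameter vector."""
        a, b = self.shape, self.scale
        theta = np.asarray(theta, dtype=float)
        return float(
            np.sum((a - 1.0) * np.log(theta) - theta / b) - theta.size * (gammaln(a) + a * np.log(b))
        )


@dataclass
class TimeCourseSet:
    """One gene's replicated measurements in one condition.

    ``replicates`` is a list of ``(grid, values)`` pairs; grids may differ
    across replicates (ragged designs).
    """

    gene_id: str
    replicates: list
    condition_label: str = ""

    def __post_init__(self):
        if not self.replicates:
            raise ValueError(f"{self.gene_id}: at least one replicate required")
        checked = []
        for grid, values in self.replicates:
            grid = as_time_grid(grid)
            values = np.asarray(values, dtype=float)
            if values.shape != grid.shape:
                raise ValueError(
                    f"{self.gene_id}: values length {values.size} != grid length {grid.size}"
                )
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{self.gene_id}: non-finite expression values")
            checked.append((grid, values))
        self.replicates = checked

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def union_grid(self) -> np.ndarray:
        """Sorted union of all replicate time points."""
        return np.unique(np.concatenate([g for g, _ in self.replicates]))

    @property
    def all_values(self) -> np.ndarray:
        return np.concatenate([v for _, v in self.replicates])


def pool(sets) -> TimeCourseSet:
    """Combine the replicates of several TimeCourseSets into one (null model)."""
    sets = list(sets)
    if not sets:
        raise ValueError("nothing to pool")
    reps = [rep for s in sets for rep in s.replicates]
    gene = sets[0].gene_id
    label = "+".join(dict.fromkeys(s.condition_label for s in sets))
    return TimeCourseSet(gene_id=gene, replicates=reps, condition_label=label)


@dataclass(frozen=True)
class OptimizerSettings:
    """Multi-start bounded optimisation settings for MAP fitting."""

    n_restarts: int = 5
    maxiter: int = 150
    ftol: float = 1e-7
    seed: int = 0
    log_lower: float = float(np.log(1e-6))
    log_upper: float = float(np.log(1e6))


@dataclass
class FittedGP:
    """MAP fit of the GP model to one TimeCourseSet (possibly pooled)."""

    params: KernelParams
    eval_grid: np.ndarray
    posterior_mean: np.ndarray
    log_likelihood: float
    log_marginal_posterior: float
    converged: bool
    n_restarts_used: int


# ---------------------------------------------------------------------------
# kernels and covariances
# ---------------------------------------------------------------------------

def ou_covariance(grid_a, grid_b, variance: float, length_scale: float) -> np.ndarray:
    """Ornstein-Uhlenbeck kernel matrix: variance * exp(-|t - t'| / length_scale)."""
    if not (np.isfinite(variance) and variance > 0):
        raise ParameterDomainError(f"variance must be > 0, got {variance!r}")
    if not (np.isfinite(length_scale) and length_scale > 0):
        raise ParameterDomainError(f"length_scale must be > 0, got {length_scale!r}")
    a = as_time_grid(grid_a)
    b = as_time_grid(grid_b)
    return variance * np.exp(-np.abs(a[:, None] - b[None, :]) / length_scale)


def marginal_covariance(grid, params: KernelParams) -> np.ndarray:
    """Data covariance Sigma = v * OU(d) + sigma2 * I (strictly PD)."""
    grid = as_time_grid(grid)
    return ou_covariance(grid, grid, params.v, params.d) + params.sigma2 * np.eye(grid.size)


def _cholesky(mat: np.ndarray, context: str = "") -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter."""
    n = mat.shape[0]
    for jit in JITTERS:
        try:
            if jit:
                return np.linalg.cholesky(mat + jit * np.eye(n))
            return np.linalg.cholesky(mat)
        except np.linalg.LinAlgError:
            continue
    raise GPNumericalError(f"Cholesky factorisation failed{': ' + context if context else ''}")


def _chol_inverse(L: np.ndarray) -> np.ndarray:
    """Inverse of A from its lower Cholesky factor L."""
    inv_l = solve_triangular(L, np.eye(L.shape[0]), lower=True)
    return inv_l.T @ inv_l


def _inv_pd(mat: np.ndarray, eye: np.ndarray):
    """(inverse, log-determinant) of a PD matrix via direct LAPACK Cholesky,
    with the usual jitter escalation.  Low-overhead path for the optimiser's
    inner loop (matrices here are at most a few tens square)."""
    for jit in JITTERS:
        c, info = dpotrf(mat if jit == 0.0 else mat + jit * eye, lower=1)
        if info == 0:
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            inv, info2 = dpotri(c, lower=1)
            if info2 == 0:
                return inv + np.tril(inv, -1).T, logdet
    raise GPNumericalError("Cholesky factorisation failed in optimiser")


# ---------------------------------------------------------------------------
# precomputed per-gene design (grids, index maps, stacked values)
# ---------------------------------------------------------------------------

class _Design:
    """Replicates grouped by identical grid, with |dt| matrices precomputed.

    Grouping lets replicates sharing a grid reuse one Cholesky factor per
    objective evaluation, which dominates fitting cost.
    """

    __slots__ = ("gene_id", "union", "union_absdiff", "groups", "n_obs", "all_values")

    def __init__(self, data: TimeCourseSet):
        self.gene_id = data.gene_id
        self.union = data.union_grid
        self.union_absdiff = np.abs(self.union[:, None] - self.union[None, :])
        by_grid = {}
        for grid, values in data.replicates:
            by_grid.setdefault(tuple(grid), []).append(values)
        self.groups = []
        for key, vals in by_grid.items():
            grid = np.array(key)
            idx = np.searchsorted(self.union, grid)
            absdiff = np.abs(grid[:, None] - grid[None, :])
            self.groups.append((grid, idx, absdiff, np.vstack(vals)))
        self.all_values = data.all_values
        self.n_obs = self.all_values.size


def _data_cholesky(design: _Design, params: KernelParams):
    """Per-group lower Cholesky factors of Sigma = v*OU(d) + sigma2*I."""
    factors = []
    for grid, idx, absdiff, vals in design.groups:
        sigma = params.v * np.exp(-absdiff / params.d) + params.sigma2 * np.eye(grid.size)
        factors.append(_cholesky(sigma, design.gene_id))
    return factors


def _log_likelihood(design: _Design, mean_on_union: np.ndarray, params: KernelParams,
                    factors=None) -> float:
    if factors is None:
        factors = _data_cholesky(design, params)
    total = 0.0
    for (grid, idx, absdiff, vals), L in zip(design.groups, factors):
        n_rep, n_t = vals.shape
        resid = vals - mean_on_union[idx]          # (n_rep, n_t)
        z = solve_triangular(L, resid.T, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        total += -0.5 * n_rep * (n_t * LOG2PI + logdet) - 0.5 * float(np.sum(z * z))
    return total


def _posterior_mean(design: _Design, params: KernelParams, factors=None) -> np.ndarray:
    if factors is None:
        factors = _data_cholesky(design, params)
    n_u = design.union.size
    sigma0 = params.psi * np.exp(-design.union_absdiff / params.delta)
    prec = _chol_inverse(_cholesky(sigma0, design.gene_id))
    rhs = np.zeros(n_u)
    for (grid, idx, absdiff, vals), L in zip(design.groups, factors):
        w = _chol_inverse(L)                        # Sigma(g)^-1
        n_rep = vals.shape[0]
        prec[np.ix_(idx, idx)] += n_rep * w
        rhs[idx] += w @ vals.sum(axis=0)
    L_prec = _cholesky(prec, design.gene_id)
    z = solve_triangular(L_prec, rhs, lower=True)
    return solve_triangular(L_prec.T, z, lower=False)


# ---------------------------------------------------------------------------
# public likelihood / posterior surface
# ---------------------------------------------------------------------------

def gp_log_likelihood(data: TimeCourseSet, mean_on_union_grid, params: KernelParams) -> float:
    """Log-likelihood of all replicates given a mean profile on the union grid.

    A product of per-replicate multivariate normals: each replicate's residual
    is the data minus the mean restricted to that replicate's grid, with
    covariance ``marginal_covariance`` on that grid.
    """
    design = _Design(data)
    mean = np.asarray(mean_on_union_grid, dtype=float)
    if mean.shape != design.union.shape:
        raise ValueError("mean vector length must equal the union grid length")
    return _log_likelihood(design, mean, params)


def posterior_mean(data: TimeCourseSet, params: KernelParams) -> np.ndarray:
    """Posterior mean of the latent profile on the union grid (shrinkage form)."""
    return _posterior_mean(_Design(data), params)


def log_marginal_posterior(params: KernelParams, data: TimeCourseSet,
                           prior: PriorConfig = PriorConfig()) -> float:
    """Plug-in log marginal posterior: likelihood at the posterior-mean profile
    plus log Gamma prior densities of the five hyperparameters."""
    design = _Design(data)
    factors = _data_cholesky(design, params)
    mu = _posterior_mean(design, params, factors)
    return _log_likelihood(design, mu, params, factors) + prior.log_pdf(params.as_array())


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

def _default_start(design: _Design) -> np.ndarray:
    """Data-driven initial hyperparameters (variance from data, span/3 scales)."""
    var = float(np.var(design.all_values))
    var = max(var, 1e-3)
    span = float(design.union[-1] - design.union[0])
    scale = max(span / 3.0, 1.0)
    return np.array([scale, var, scale, var, 0.1 * var])


def _stable_seed(base_seed: int, gene_id: str) -> int:
    return (int(base_seed) * 1000003 + zlib.crc32(gene_id.encode())) % (2**31)


def fit_gp(data, prior: PriorConfig = PriorConfig(),
           optimizer: OptimizerSettings = OptimizerSettings(),
           warm_start: KernelParams | None = None) -> FittedGP:
    """MAP-fit the five hyperparameters by multi-start bounded L-BFGS-B.

    ``data`` is a TimeCourseSet or an iterable of them (pooled as replicates
    of one model).  The search runs in log-parameter space; restart points are
    deterministic log-normal perturbations of a data-driven start, seeded from
    the optimizer seed and the gene id.  ``warm_start`` adds one extra start
    (used by the likelihood-ratio test to initialise condition-specific fits
    from the shared fit).  Never raises on non-convergence: the best point
    found is returned with ``converged=False``.
    """
    if isinstance(data, TimeCourseSet):
        pooled = data
    else:
        pooled = pool(data)
    design = _Design(pooled)
    lo, hi = optimizer.log_lower, optimizer.log_upper
    bounds = [(lo, hi)] * 5
    prior_a, prior_b = prior.shape, prior.scale
    prior_const = 5.0 * (gammaln(prior_a) + prior_a * np.log(prior_b))

    n_u = design.union.size
    eye_u = np.eye(n_u)
    group_cache = [(idx, absdiff, vals, np.eye(grid.size), vals.sum(axis=0),
                    vals.shape[0], grid.size,
                    bool(grid.size == n_u))
                   for grid, idx, absdiff, vals in design.groups]
    big = (1e30, np.zeros(5))

    def neg_objective(log_theta: np.ndarray):
        """Value and analytic gradient (log-parameter space) of the negative
        log marginal posterior.

        The plug-in mean profile makes the gradient non-standard: writing
        s = Sigma0^-1 mu_bar (which equals d ll / d mu_bar) and u = P^-1 s
        with P the combined precision, the chain-rule terms through mu_bar
        reduce to quadratic forms in s, u and c_g = W_g (vsum_g - n_g
        mu_bar_g).  Correctness is pinned against finite differences in the
        test suite.
        """
        theta = np.exp(log_theta)
        delta, psi, d, v, sigma2 = theta
        try:
            sigma0 = psi * np.exp(-design.union_absdiff / delta)
            sigma0_inv, _ = _inv_pd(sigma0, eye_u)
            prec = sigma0_inv.copy()
            rhs = np.zeros(n_u)
            parts = []
            for idx, absdiff, vals, eye_g, vsum, n_rep, n_t, full in group_cache:
                ve = v * np.exp(-absdiff / d)
                w, logdet = _inv_pd(ve + sigma2 * eye_g, eye_g)
                if full:
                    prec += n_rep * w
                    rhs += w @ vsum
                else:
                    prec[np.ix_(idx, idx)] += n_rep * w
                    rhs[idx] += w @ vsum
                parts.append((idx, absdiff, vals, vsum, ve, w, logdet, n_rep, n_t))
            prec_inv, _ = _inv_pd(prec, eye_u)
            mu = prec_inv @ rhs
            s = sigma0_inv @ mu
            u = prec_inv @ s
            ll = 0.0
            g_v = g_d = g_s2 = 0.0
            for idx, absdiff, vals, vsum, ve, w, logdet, n_rep, n_t in parts:
                resid = vals - mu[idx]
                m_mat = resid.T @ resid
                wm = w @ m_mat
                ll += -0.5 * n_rep * (n_t * LOG2PI + logdet) - 0.5 * float(np.trace(wm))
                gmat = 0.5 * (wm @ w - n_rep * w)   # d ll / d Sigma at fixed mu
                c_vec = w @ (vsum - n_rep * mu[idx])
                wu = w @ u[idx]
                corr = np.outer(wu, c_vec)          # chain-rule term through mu
                eff = gmat - 0.5 * (corr + corr.T)
                g_v += float(np.sum(ve * eff))
                g_d += float(np.sum(ve * absdiff * eff)) / d
                g_s2 += sigma2 * float(np.trace(eff))
            w0u = sigma0_inv @ u
            # mean-prior kernels, log-space: dSigma0/dlog psi = Sigma0;
            # dSigma0/dlog delta = Sigma0 * |dt| / delta
            g_psi = float(w0u @ (sigma0 @ s))
            g_delta = float(w0u @ ((sigma0 * design.union_absdiff / delta) @ s))
            ll_grad = np.array([g_delta, g_psi, g_d, g_v, g_s2])
            prior_grad = (prior_a - 1.0) - theta / prior_b
            log_prior = float(np.sum((prior_a - 1.0) * log_theta - theta / prior_b)) - prior_const
            val = -(ll + log_prior)
            if not np.isfinite(val):
                return big
            return val, -(ll_grad + prior_grad)
        except GPNumericalError:
            return big

    starts = [np.log(_default_start(design))]
    if warm_start is not None:
        starts.append(np.log(warm_start.as_array()))
    rng = np.random.default_rng(_stable_seed(optimizer.seed, design.gene_id))
    base = starts[0]
    for _ in range(max(optimizer.n_restarts - 1, 0)):
        starts.append(np.clip(base + rng.normal(scale=1.5, size=5), lo, hi))

    best_x, best_val, converged, n_used = None, np.inf, False, 0
    for x0 in starts:
        res = minimize(neg_objective, np.clip(x0, lo, hi), method="L-BFGS-B",
                       jac=True, bounds=bounds,
                       options={"maxiter": optimizer.maxiter, "ftol": optimizer.ftol})
        n_used += 1
        agreed = np.isfinite(res.fun) and abs(res.fun - best_val) < 1e-3
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
        converged = converged or bool(res.success)
        # two independent starts landing on the same optimum: stop early
        if agreed and n_used >= 2:
            break

    if best_x is None or not np.isfinite(best_val):  # pragma: no cover - defensive
        best_x = starts[0]
        best_val = neg_objective(best_x)[0]
        converged = False

    params = KernelParams.from_array(np.exp(best_x))
    factors = _data_cholesky(design, params)
    mu = _posterior_mean(design, params, factors)
    ll = _log_likelihood(design, mu, params, factors)
    if not converged:
        logger.warning("fit_gp: no restart converged for gene %s", design.gene_id)
    return FittedGP(
        params=params,
        eval_grid=design.union,
        posterior_mean=mu,
        log_likelihood=ll,
        log_marginal_posterior=-best_val,
        converged=converged,
        n_restarts_used=n_used,
    )
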