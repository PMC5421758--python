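"""Kernels, likelihood, posterior mean and MAP fitting of the GP model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gamma as gamma_dist
from scipy.stats import multivariate_normal

from gptimediff import (KernelParams, OptimizerSettings, ParameterDomainError,
                        PriorConfig, TimeCourseSet, as_time_grid, fit_gp,
                        gp_log_likelihood, log_marginal_posterior,
                        marginal_covariance, ou_covariance, pool,
                        posterior_mean)


# ---------------------------------------------------------------------------
# time grids and containers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [[], [1.0, 1.0], [2.0, 1.0], [-1.0, 2.0],
                                 [0.0, np.inf], [[1.0, 2.0]]])
def test_time_grid_rejects_invalid(bad):
    with pytest.raises(ValueError):
        as_time_grid(bad)


def test_time_course_set_validation():
    with pytest.raises(ValueError):
        TimeCourseSet("g", [])
    with pytest.raises(ValueError):
        TimeCourseSet("g", [(np.array([0.0, 1.0]), np.array([1.0]))])
    tcs = TimeCourseSet("g", [(np.array([0.0, 2.0]), np.array([1.0, 2.0])),
                              (np.array([1.0, 3.0]), np.array([0.0, 1.0]))])
    assert tcs.union_grid.tolist() == [0.0, 1.0, 2.0, 3.0]
    assert tcs.n_replicates == 2


def test_kernel_params_domain():
    with pytest.raises(ParameterDomainError):
        KernelParams(delta=1, psi=1, d=1, v=0.0, sigma2=1)
    with pytest.raises(ParameterDomainError):
        KernelParams(delta=1, psi=1, d=np.inf, v=1, sigma2=1)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def test_ou_covariance_closed_form():
    # zero lag gives exactly the variance
    assert ou_covariance([0.0], [0.0], 2.5, 3.0).item() == pytest.approx(2.5)
    # one length-scale of separation decays by exp(-1)
    k = ou_covariance([0.0, 10.0], [0.0, 10.0], 1.0, 10.0)
    assert k[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
    assert k[0, 0] == k[1, 1] == 1.0
    # infinite-separation limit underflows off-diagonal, diagonal intact
    k = ou_covariance([0.0, 10.0], [0.0, 10.0], 1.0, 1e-6)
    assert k[0, 1] == 0.0 and k[0, 0] == 1.0


@pytest.mark.parametrize("variance,length_scale", [(0.0, 1.0), (-1.0, 1.0),
                                                   (1.0, 0.0), (1.0, -2.0)])
def test_ou_covariance_domain_errors(variance, length_scale):
    with pytest.raises(ParameterDomainError):
        ou_covariance([0.0, 1.0], [0.0, 1.0], variance, length_scale)


@settings(max_examples=50, derandomize=True)
@given(st.integers(min_value=1, max_value=6),
       st.floats(min_value=0.01, max_value=100.0),
       st.floats(min_value=0.01, max_value=500.0),
       st.integers(min_value=0, max_value=10**6))
def test_ou_covariance_symmetric_psd(n, variance, length_scale, seed):
    grid = np.sort(np.random.default_rng(seed).uniform(0, 100, n))
    grid = np.unique(grid)
    k = ou_covariance(grid, grid, variance, length_scale)
    assert np.allclose(k, k.T)
    eigs = np.linalg.eigvalsh(k)
    assert eigs.min() >= -1e-9 * variance


def test_marginal_covariance():
    params = KernelParams(delta=1, psi=1, d=5.0, v=1.0, sigma2=0.25)
    grid = np.array([0.0, 5.0, 10.0])
    sigma = marginal_covariance(grid, params)
    expect = np.exp(-np.abs(grid[:, None] - grid[None, :]) / 5.0) + 0.25 * np.eye(3)
    np.testing.assert_allclose(sigma, expect, atol=1e-12)
    # single point: v + sigma2
    one = marginal_covariance([3.0], KernelParams(1, 1, 1, 1.0, 0.04))
    assert one.item() == pytest.approx(1.04)
    # decorrelation limit d -> 0+
    tiny = marginal_covariance(grid, KernelParams(1, 1, 1e-9, 1.0, 0.25))
    np.testing.assert_allclose(tiny, 1.25 * np.eye(3), atol=1e-12)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_log_likelihood_standard_normal_point():
    tcs = TimeCourseSet("g", [(np.array([0.0]), np.array([0.0]))])
    params = KernelParams(delta=1, psi=1, d=1, v=0.5, sigma2=0.5)  # v+s2 = 1
    ll = gp_log_likelihood(tcs, np.array([0.0]), params)
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_log_likelihood_matches_mvn_oracle(rng):
    """Brute-force multivariate-normal oracle on small shared-grid cases."""
    for n_t in (1, 2, 3, 4):
        for n_r in (1, 2, 4):
            grid = np.sort(rng.uniform(0, 50, n_t))
            grid = np.unique(grid)
            vals = [rng.normal(size=grid.size) for _ in range(n_r)]
            tcs = TimeCourseSet("g", [(grid, v) for v in vals])
            params = KernelParams(delta=5, psi=2, d=float(rng.uniform(1, 30)),
                                  v=float(rng.uniform(0.2, 2)),
                                  sigma2=float(rng.uniform(0.01, 0.5)))
            mean = rng.normal(size=grid.size)
            sigma = marginal_covariance(grid, params)
            oracle = sum(multivariate_normal.logpdf(v, mean=mean, cov=sigma)
                         for v in vals)
            assert gp_log_likelihood(tcs, mean, params) == pytest.approx(
                oracle, abs=1e-8)


def test_log_likelihood_replicate_permutation_invariance(ragged_tcs):
    params = KernelParams(delta=10, psi=1, d=8, v=0.8, sigma2=0.1)
    mean = np.zeros(ragged_tcs.union_grid.size)
    base = gp_log_likelihood(ragged_tcs, mean, params)
    shuffled = TimeCourseSet(ragged_tcs.gene_id, ragged_tcs.replicates[::-1])
    assert gp_log_likelihood(shuffled, mean, params) == pytest.approx(base, abs=1e-10)


def test_log_likelihood_point_reordering_invariance():
    """Jointly permuting (times, values) within a replicate is a no-op once
    re-sorted; equivalently, two encodings of the same replicate agree."""
    grid = np.array([0.0, 4.0, 9.0])
    vals = np.array([1.0, -1.0, 0.5])
    params = KernelParams(delta=3, psi=1, d=5, v=1, sigma2=0.2)
    a = TimeCourseSet("g", [(grid, vals)])
    perm = [2, 0, 1]
    re_times = grid[perm]
    re_vals = vals[perm]
    order = np.argsort(re_times)
    b = TimeCourseSet("g", [(re_times[order], re_vals[order])])
    mean = np.array([0.1, 0.2, 0.3])
    assert gp_log_likelihood(a, mean, params) == pytest.approx(
        gp_log_likelihood(b, mean, params), abs=1e-12)


# ---------------------------------------------------------------------------
# posterior mean
# ---------------------------------------------------------------------------

def test_posterior_mean_flat_prior_limit(shared_grid_tcs):
    """psi -> inf: shrinkage vanishes, posterior mean -> replicate average."""
    params = KernelParams(delta=5, psi=1e9, d=5, v=1, sigma2=0.1)
    mu = posterior_mean(shared_grid_tcs, params)
    avg = np.mean([v for _, v in shared_grid_tcs.replicates], axis=0)
    np.testing.assert_allclose(mu, avg, atol=1e-6)


def test_posterior_mean_zero_prior_limit(shared_grid_tcs):
    """psi -> 0: total shrinkage to the zero prior mean."""
    params = KernelParams(delta=5, psi=1e-12, d=5, v=1, sigma2=0.1)
    mu = posterior_mean(shared_grid_tcs, params)
    np.testing.assert_allclose(mu, 0.0, atol=1e-6)


def test_posterior_mean_zero_data():
    times = np.array([0.0, 5.0, 10.0])
    tcs = TimeCourseSet("g", [(times, np.zeros(3)), (times, np.zeros(3))])
    mu = posterior_mean(tcs, KernelParams(5, 1, 5, 1, 0.1))
    np.testing.assert_allclose(mu, 0.0, atol=1e-12)


def test_posterior_mean_matches_hand_algebra():
    """Explicit 2x2 shrinkage algebra on a shared grid: mu = (S0^-1 +
    Nr S^-1)^-1 Nr S^-1 m_a."""
    times = np.array([0.0, 10.0])
    v1 = np.array([1.0, 2.0])
    v2 = np.array([3.0, -1.0])
    tcs = TimeCourseSet("g", [(times, v1), (times, v2)])
    params = KernelParams(delta=7.0, psi=1.3, d=4.0, v=0.9, sigma2=0.2)
    s0 = 1.3 * np.exp(-np.abs(times[:, None] - times[None, :]) / 7.0)
    sig = 0.9 * np.exp(-np.abs(times[:, None] - times[None, :]) / 4.0) + 0.2 * np.eye(2)
    m_a = (v1 + v2) / 2
    expect = np.linalg.inv(np.linalg.inv(s0) + 2 * np.linalg.inv(sig)) @ (
        2 * np.linalg.inv(sig) @ m_a)
    np.testing.assert_allclose(posterior_mean(tcs, params), expect, atol=1e-10)


def test_posterior_mean_ragged_reduces_to_shared(shared_grid_tcs):
    """Splitting a shared-grid replicate set into per-replicate grids equal
    to the union grid leaves the generalized formula unchanged."""
    params = KernelParams(3, 1, 5, 1, 0.3)
    direct = posterior_mean(shared_grid_tcs, params)
    assert direct.size == shared_grid_tcs.union_grid.size


# ---------------------------------------------------------------------------
# marginal posterior
# ---------------------------------------------------------------------------

def test_log_marginal_posterior_hand_computation():
    """Single point, all params 1: data term + five gamma log-densities."""
    tcs = TimeCourseSet("g", [(np.array([0.0]), np.array([0.0]))])
    params = KernelParams(1, 1, 1, 1, 1)
    prior = PriorConfig(0.1, 100.0)
    # posterior mean is 0 by symmetry (zero data), v + s2 = 2
    data_term = -0.5 * np.log(2 * np.pi) - 0.5 * np.log(2.0)
    prior_term = 5 * gamma_dist.logpdf(1.0, 0.1, scale=100.0)
    assert log_marginal_posterior(params, tcs, prior) == pytest.approx(
        data_term + prior_term, abs=1e-10)


def test_log_marginal_posterior_decomposition(shared_grid_tcs):
    """Differences decompose exactly into data-term and prior-term deltas."""
    prior = PriorConfig()
    p1 = KernelParams(5, 1, 5, 1, 0.1)
    p2 = KernelParams(8, 0.5, 3, 1.5, 0.3)
    def data_term(p):
        return gp_log_likelihood(shared_grid_tcs,
                                 posterior_mean(shared_grid_tcs, p), p)
    def prior_term(p):
        return sum(gamma_dist.logpdf(t, prior.shape, scale=prior.scale)
                   for t in p.as_array())
    lhs = (log_marginal_posterior(p2, shared_grid_tcs, prior)
           - log_marginal_posterior(p1, shared_grid_tcs, prior))
    rhs = (data_term(p2) - data_term(p1)) + (prior_term(p2) - prior_term(p1))
    assert lhs == pytest.approx(rhs, abs=1e-10)


def test_boundary_params_rejected(shared_grid_tcs):
    with pytest.raises(ParameterDomainError):
        log_marginal_posterior(KernelParams(1, 1, 1, 1, 0.0),
                               shared_grid_tcs)


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

def test_fit_gp_internal_gradient_matches_finite_differences(ragged_tcs):
    """The optimiser's analytic gradient against central differences."""
    import gptimediff.gp_core as gc
    captured = {}
    real_min = gc.minimize
    def spy(fun, x0, **kw):
        captured["fun"] = fun
        return real_min(fun, x0, **kw)
    gc.minimize = spy
    try:
        fit_gp(ragged_tcs, optimizer=OptimizerSettings(n_restarts=1))
    finally:
        gc.minimize = real_min
    fun = captured["fun"]
    r = np.random.default_rng(0)
    for _ in range(5):
        x = r.normal(0.0, 1.0, 5)
        _, grad = fun(x)
        fd = np.empty(5)
        for k in range(5):
            e = np.zeros(5)
            e[k] = 1e-6
            fd[k] = (fun(x + e)[0] - fun(x - e)[0]) / 2e-6
        np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-7)


def test_fit_gp_null_signal():
    times = np.linspace(0, 100, 10)
    r = np.random.default_rng(3)
    reps = [(times, 1e-3 * r.normal(size=10)) for _ in range(4)]
    fit = fit_gp(TimeCourseSet("null", reps))
    assert np.max(np.abs(fit.posterior_mean)) <= 0.05


def test_fit_gp_improves_over_default_start(small_dataset, fast_optimizer):
    cond_a, _ = small_dataset.time_course_pair(0)
    from gptimediff.gp_core import _Design, _default_start
    fit = fit_gp(cond_a, optimizer=fast_optimizer)
    start = KernelParams.from_array(_default_start(_Design(cond_a)))
    assert fit.log_marginal_posterior >= log_marginal_posterior(
        start, cond_a) - 1e-8


def test_fit_gp_bit_reproducible(small_dataset, fast_optimizer):
    cond_a, cond_b = small_dataset.time_course_pair(2)
    pooled = pool([cond_a, cond_b])
    f1 = fit_gp(pooled, optimizer=fast_optimizer)
    f2 = fit_gp(pooled, optimizer=fast_optimizer)
    assert f1.params == f2.params
    assert f1.log_likelihood == f2.log_likelihood
    np.testing.assert_array_equal(f1.posterior_mean, f2.posterior_mean)


def test_fit_gp_parameter_recovery_single_gene():
    """Replicates drawn from the model (v=1, d=20, s2=0.04): the dominant
    covariance parameters v and d are recovered within a factor of 3."""
    rng = np.random.default_rng(11)
    times = np.linspace(0, 100, 10)
    k = np.exp(-np.abs(times[:, None] - times[None, :]) / 20.0)
    chol = np.linalg.cholesky(k + 1e-10 * np.eye(10))
    mu = chol @ rng.standard_normal(10)
    reps = [(times, mu + chol @ rng.standard_normal(10)
             + rng.normal(0, 0.2, 10)) for _ in range(8)]
    fit = fit_gp(TimeCourseSet("recov", reps))
    assert fit.converged
    for est, truth in [(fit.params.v, 1.0), (fit.params.d, 20.0)]:
        assert max(est / truth, truth / est) <= 3.0
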