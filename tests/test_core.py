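import numpy as np
import pytest
from scipy.stats import norm

from answers.core import (
    PosteriorEstimate,
    RegressionWeights,
    VFSeries,
    analyze,
    laplace_covariance,
    log_likelihood,
    log_posterior,
    log_posterior_grad,
    map_estimate,
    pnd,
    s_index,
    smooth_clamp,
)
from answers.grid import SpatialPrior, VFLocation, VisualFieldGrid, build_spatial_prior


def _toy_grid(n=2):
    """Tiny same-hemifield grid for oracle comparisons."""
    locs = tuple(
        VFLocation(i, float(3 + 6 * i), 3.0, "superior", 140.0 - 10.0 * i)
        for i in range(n)
    )
    return VisualFieldGrid(locations=locs)


def _toy_prior(n=2, rho=0.5, a=100.0, b=100.0):
    psi = np.full((n, n), rho) + (1 - rho) * np.eye(n)
    return SpatialPrior(psi=psi, a=a, b=b)


class TestVFSeries:
    def test_validation(self, grid):
        with pytest.raises(ValueError, match="strictly increasing"):
            VFSeries(np.array([0.0, 0.0, 1.0]), np.zeros((3, 52)), grid)
        with pytest.raises(ValueError, match=r"\[0, 50\]"):
            VFSeries(np.array([0.0, 1.0]), np.full((2, 52), 60.0), grid)

    def test_prefix(self, small_cohort):
        s, _ = small_cohort[0]
        p = s.prefix(3)
        assert p.n_tests == 3
        assert np.array_equal(p.values, s.values[:3])


class TestSmoothClamp:
    def test_near_identity_in_interior(self):
        x = np.array([5.0, 17.5, 30.0])
        v, d = smooth_clamp(x)
        assert v == pytest.approx(x, abs=1e-6)
        assert d == pytest.approx(np.ones(3), abs=1e-6)

    def test_saturates_outside(self):
        v_lo, _ = smooth_clamp(np.array([-20.0]))
        v_hi, _ = smooth_clamp(np.array([60.0]))
        assert 0.0 <= v_lo[0] < 0.1
        assert 34.9 < v_hi[0] <= 35.0


class TestLikelihood:
    def test_single_measurement_equals_density(self, retest_model):
        s = VFSeries(np.array([0.0]), np.array([[27.0]]))
        w = RegressionWeights(np.array([0.0]), np.array([28.0]))
        expected = retest_model.logpdf(np.array([27.0]), np.array([28.0]))[0]
        assert log_likelihood(s, w, retest_model) == pytest.approx(expected, rel=1e-12)

    def test_factorizes_over_tests(self, retest_model):
        w = RegressionWeights(np.array([-1.0, 0.5]), np.array([25.0, 30.0]))
        s2 = VFSeries(np.array([0.0, 2.0]), np.array([[24.0, 31.0], [22.0, 29.0]]))
        one = VFSeries(np.array([0.0]), np.array([[24.0, 31.0]]))
        two = VFSeries(np.array([2.0]), np.array([[22.0, 29.0]]))
        assert log_likelihood(s2, w, retest_model) == pytest.approx(
            log_likelihood(one, w, retest_model) + log_likelihood(two, w, retest_model),
            rel=1e-12,
        )

    def test_empty_series_contributes_zero(self, retest_model):
        s = VFSeries(np.zeros(0), np.zeros((0, 2)))
        w = RegressionWeights(np.zeros(2), np.full(2, 20.0))
        assert log_likelihood(s, w, retest_model) == 0.0


class TestLogPosterior:
    def test_diagonal_prior_decomposes_per_location(self, retest_model):
        rng = np.random.default_rng(0)
        n = 3
        prior = SpatialPrior(psi=np.eye(n))
        times = np.array([0.0, 1.0, 2.0, 3.0])
        values = np.clip(rng.normal(25, 4, (4, n)), 0, 40)
        s = VFSeries(times, values)
        w = RegressionWeights(rng.normal(0, 1, n), rng.normal(25, 3, n))
        total = log_posterior(s, w, retest_model, prior)
        parts = 0.0
        for j in range(n):
            sj = VFSeries(times, values[:, j : j + 1])
            wj = RegressionWeights(w.slopes[j : j + 1], w.intercepts[j : j + 1])
            pj = SpatialPrior(psi=np.eye(1))
            parts += log_posterior(sj, wj, retest_model, pj)
        # constants (log-det terms) are location-wise too, so the sums agree
        assert total == pytest.approx(parts, rel=1e-9)

    def test_prior_mode_at_means_for_empty_series(self, retest_model):
        prior = _toy_prior()
        empty = VFSeries(np.zeros(0), np.zeros((0, 2)))
        at_mean = log_posterior(
            empty,
            RegressionWeights(np.zeros(2), np.full(2, 17.5)),
            retest_model,
            prior,
        )
        for d_slope, d_int in [(0.5, 0.0), (0.0, 2.0), (-0.3, -1.0)]:
            off = log_posterior(
                empty,
                RegressionWeights(np.full(2, d_slope), np.full(2, 17.5 + d_int)),
                retest_model,
                prior,
            )
            assert off < at_mean

    def test_gradient_matches_finite_differences(self, retest_model, rng):
        n = 4
        prior = _toy_prior(n, rho=0.3)
        times = np.array([0.0, 1.1, 2.0, 3.2, 4.1])
        values = np.clip(rng.normal(24, 5, (5, n)), 0, 40)
        s = VFSeries(times, values)
        w = RegressionWeights(rng.normal(0, 0.5, n), rng.normal(24, 2, n))
        g = log_posterior_grad(s, w, retest_model, prior)
        x0 = w.as_vector()
        h = 1e-6
        for i in range(2 * n):
            e = np.zeros(2 * n)
            e[i] = h
            fd = (
                log_posterior(s, RegressionWeights.from_vector(x0 + e), retest_model, prior)
                - log_posterior(s, RegressionWeights.from_vector(x0 - e), retest_model, prior)
            ) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def _grid_search_map(s, retest, prior, centers, widths, npts=9, rounds=3):
    """Brute-force posterior maximum: coarse 4-D lattice refined around the
    argmax, shrinking the window to the previous grid step each round."""

    def objective(sl0, sl1, b0, b1):
        w = RegressionWeights(np.array([sl0, sl1]), np.array([b0, b1]))
        return log_posterior(s, w, retest, prior)

    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    best, arg = -np.inf, centers
    for _ in range(rounds):
        axes = [np.linspace(c - w_, c + w_, npts) for c, w_ in zip(centers, widths)]
        best, arg = -np.inf, None
        for a0 in axes[0]:
            for a1 in axes[1]:
                for a2 in axes[2]:
                    for a3 in axes[3]:
                        v = objective(a0, a1, a2, a3)
                        if v > best:
                            best, arg = v, (a0, a1, a2, a3)
        centers = np.array(arg)
        widths = widths * (2.0 / (npts - 1))
    step = widths * 2.0 / (npts - 1)
    return np.array(arg), best, step


class TestMAP:
    def test_at_least_as_good_as_brute_force_on_noisy_toy(self, retest_model):
        # the posterior is multimodal; the quasi-Newton MAP must never be
        # beaten by exhaustive search (it may find a better mode than a
        # lattice that refines around a single argmax)
        rng = np.random.default_rng(7)
        prior = _toy_prior(2, rho=0.5)
        times = np.array([0.0, 1.0, 2.0, 3.0])
        truth = np.array([[28.0, 20.0]]) + np.outer(times, [-1.5, 0.0])
        values = np.clip(np.rint(truth + rng.normal(0, 1.5, truth.shape)), 0, 40)
        s = VFSeries(times, values)
        w_map, _ = map_estimate(s, retest_model, prior)
        _, best, _ = _grid_search_map(
            s, retest_model, prior, [0.0, 0.0, 24.0, 24.0], [6.0, 6.0, 20.0, 20.0]
        )
        assert log_posterior(s, w_map, retest_model, prior) >= best - 1e-6

    def test_matches_brute_force_on_clean_toy(self, retest_model):
        # steady series well inside the measured range: single dominant
        # basin, so the lattice argmax and the MAP must coincide
        prior = _toy_prior(2, rho=0.5)
        times = np.arange(5.0)
        values = np.array(
            [[30.0, 25.0], [29, 25], [30, 26], [29, 24], [30, 25]]
        )
        s = VFSeries(times, values)
        w_map, _ = map_estimate(s, retest_model, prior)
        arg, best, step = _grid_search_map(
            s, retest_model, prior, [0.0, 0.0, 27.0, 27.0], [3.0, 3.0, 12.0, 12.0]
        )
        found = np.concatenate([w_map.slopes, w_map.intercepts])
        # agreement to lattice resolution (the refined window is not
        # centred on the continuum optimum, so allow two grid steps)
        assert found == pytest.approx(arg, abs=2 * float(step.max()) + 1e-6)
        assert log_posterior(s, w_map, retest_model, prior) >= best - 1e-6

    def test_stable_series_estimates_near_zero_slope(self, grid, prior, retest_model):
        from answers.synthetic import GeneratorConfig, gen_cohort

        cfg = GeneratorConfig(seed=21, n_eyes=3, frac_progressing=0.0, n_tests=8)
        cohort = gen_cohort(cfg, grid)
        for s, _ in cohort:
            w, diag = map_estimate(s, retest_model, prior)
            assert diag["converged"]
            assert np.median(np.abs(w.slopes)) < 0.5

    def test_prior_dominated_limit_returns_prior_means(self, retest_model):
        prior = _toy_prior(2, rho=0.0, a=1e-8, b=1e-8)
        s = VFSeries(
            np.array([0.0, 1.0, 2.0]),
            np.array([[30.0, 10.0], [28.0, 12.0], [26.0, 9.0]]),
        )
        w, _ = map_estimate(s, retest_model, prior)
        assert w.slopes == pytest.approx([0.0, 0.0], abs=1e-3)
        assert w.intercepts == pytest.approx([17.5, 17.5], abs=1e-2)

    def test_too_short_series_rejected(self, retest_model):
        prior = _toy_prior(1)
        s = VFSeries(np.array([0.0, 1.0]), np.array([[20.0], [20.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            map_estimate(s, retest_model, _toy_prior(1))


class TestLaplace:
    def test_pure_prior_covariance_exact(self, retest_model):
        prior = _toy_prior(2, rho=0.4)
        empty = VFSeries(np.zeros(0), np.zeros((0, 2)))
        w = RegressionWeights(np.zeros(2), np.full(2, 17.5))
        cov = laplace_covariance(empty, w, retest_model, prior)
        expected = np.zeros((4, 4))
        expected[:2, :2] = prior.slope_cov
        expected[2:, 2:] = prior.intercept_cov
        assert cov == pytest.approx(expected, rel=1e-3)

    def test_single_location_variance_matches_quadrature(self):
        # machinery check on a single-component, near-Gaussian retest
        # model: without the heavy lapse mode the posterior is unimodal
        # and the Laplace variance must match direct quadrature.  (With
        # the full mixture the exact posterior has fatter tails than the
        # local curvature; see the methods note.)
        from answers.retest import RetestModel

        payload = {
            str(v): {
                "weights": [1.0],
                "alphas": [20.0],
                "betas": [max(v, 0.5) / np.log(2.0) ** (1 / 20.0)],
            }
            for v in range(36)
        }
        retest_model = RetestModel.from_json(payload)
        prior = _toy_prior(1)
        s = VFSeries(
            np.arange(9.0),
            np.array([[30.0, 31, 30, 29, 30, 31, 30, 29, 30]]).T,
        )
        w, _ = map_estimate(s, retest_model, prior)
        cov = laplace_covariance(s, w, retest_model, prior)
        neg_hess = np.linalg.inv(cov)
        lap_cond_var = 1.0 / neg_hess[0, 0]  # slope var given intercept

        b0 = float(w.intercepts[0])
        slopes = np.linspace(w.slopes[0] - 2.0, w.slopes[0] + 2.0, 801)
        logp = np.array(
            [
                log_posterior(
                    s,
                    RegressionWeights(np.array([sl]), np.array([b0])),
                    retest_model,
                    prior,
                )
                for sl in slopes
            ]
        )
        p = np.exp(logp - logp.max())
        p /= np.trapezoid(p, slopes)
        mean = np.trapezoid(p * slopes, slopes)
        var = np.trapezoid(p * (slopes - mean) ** 2, slopes)
        assert lap_cond_var == pytest.approx(var, rel=0.2)

    def test_covariance_symmetric_positive_diagonal(self, retest_model, small_cohort):
        s, _ = small_cohort[0]
        prior = build_spatial_prior(s.grid)
        w, _ = map_estimate(s, retest_model, prior)
        cov = laplace_covariance(s, w, retest_model, prior)
        assert np.allclose(cov, cov.T)
        assert np.all(np.diag(cov) > 0)


class TestIndices:
    def test_pnd_closed_forms(self):
        assert pnd(0.0, 1.0) == pytest.approx(0.5)
        assert pnd(-3.0, 1.0) == pytest.approx(norm.cdf(-3.0), rel=1e-9)
        assert pnd(-3.0, 1.0) == pytest.approx(0.00135, abs=2e-5)
        assert pnd(1e6, 1.0) == 1.0

    def test_pnd_requires_positive_sd(self):
        with pytest.raises(ValueError):
            pnd(0.0, 0.0)

    def test_s_index_examples(self):
        assert s_index(np.ones(5)) == 0.0
        assert s_index([0.1, 1.0, 1.0]) == pytest.approx(-np.log(0.1), rel=1e-12)

    def test_s_index_concatenation_additivity(self, rng):
        u = rng.uniform(0.01, 1.0, 7)
        v = rng.uniform(0.01, 1.0, 4)
        assert s_index(np.concatenate([u, v])) == pytest.approx(
            s_index(u) + s_index(v), rel=1e-12
        )

    def test_s_index_monotone_in_added_deterioration(self, rng):
        base = rng.uniform(0.2, 1.0, 6)
        assert s_index(np.append(base, 0.7)) > s_index(base)


class TestAnalyze:
    def test_answer_equals_answers_for_identity_psi(self, retest_model, rng):
        n = 3
        prior = _toy_prior(n, rho=0.0)
        times = np.arange(5.0)
        values = np.clip(np.rint(rng.normal(25, 3, (5, n))), 0, 40)
        s = VFSeries(times, values)
        a = analyze(s, retest_model, prior, "ANSWERS")
        b = analyze(s, retest_model, prior, "ANSWER")
        assert abs(a.s_d - b.s_d) < 1e-9

    def test_permutation_invariance_of_s_d(self, retest_model, rng):
        n = 4
        prior = _toy_prior(n, rho=0.3)
        times = np.arange(5.0)
        values = np.clip(np.rint(rng.normal(24, 4, (5, n))), 0, 40)
        s = VFSeries(times, values)
        est = analyze(s, retest_model, prior, "ANSWERS")

        perm = np.array([2, 0, 3, 1])
        psi_p = prior.psi[np.ix_(perm, perm)]
        prior_p = SpatialPrior(psi=psi_p, a=prior.a, b=prior.b)
        s_p = VFSeries(times, values[:, perm])
        est_p = analyze(s_p, retest_model, prior_p, "ANSWERS")
        assert est_p.s_d == pytest.approx(est.s_d, rel=1e-6)
        assert est_p.pnd == pytest.approx(est.pnd[perm], rel=1e-4)

    def test_uniform_improvement_gives_s_i_above_s_d(self, retest_model):
        n = 3
        prior = _toy_prior(n, rho=0.0)
        times = np.arange(6.0)
        base = 18.0
        values = np.clip(np.rint(base + 2.0 * times)[:, None] * np.ones((1, n)), 0, 40)
        s = VFSeries(times, values)
        est = analyze(s, retest_model, prior, "ANSWERS")
        assert est.s_i > est.s_d

    def test_deterministic_repeatability(self, retest_model, small_cohort):
        s, _ = small_cohort[1]
        prior = build_spatial_prior(s.grid)
        a = analyze(s, retest_model, prior, "ANSWERS")
        b = analyze(s, retest_model, prior, "ANSWERS")
        assert a.s_d == b.s_d
        assert np.array_equal(a.mode.slopes, b.mode.slopes)

    def test_result_serialization(self, retest_model, small_cohort, tmp_path):
        import json

        s, _ = small_cohort[2]
        prior = build_spatial_prior(s.grid)
        est = analyze(s, retest_model, prior, "ANSWER")
        path = tmp_path / "est.json"
        est.to_json(path)
        data = json.loads(path.read_text())
        assert data["mode"] == "ANSWER"
        assert len(data["slopes"]) == 52
        assert np.isfinite(data["s_d"])
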