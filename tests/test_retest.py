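import json
import math

import numpy as np
import pytest
from scipy.integrate import quad

from answers.retest import (
    RetestModel,
    RetestPairs,
    WeibullComponent,
    WeibullMixture,
    em_fit,
    fit_retest_model,
    select_k,
    transform_dls,
    weibull_pdf,
)
from answers.synthetic import GeneratorConfig, gen_retest_pairs


class TestWeibullDensity:
    def test_exponential_special_case(self):
        assert weibull_pdf(1.0, 1.0, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_vanishes_at_origin_for_shape_above_one(self):
        assert weibull_pdf(0.0, 2.0, 5.0) == 0.0

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            weibull_pdf(-0.1, 2.0, 5.0)

    def test_integrates_to_one(self):
        total, err = quad(lambda y: weibull_pdf(y, 2.0, 10.0), 0.0, 200.0)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestFloorTransform:
    def test_identity_above_knot(self):
        assert transform_dls(20.0) == 20.0
        assert transform_dls(1.0) == 1.0

    def test_continuous_and_c1_at_knot(self):
        h = 1e-7
        left = (transform_dls(1.0) - transform_dls(1.0 - h)) / h
        right = (transform_dls(1.0 + h) - transform_dls(1.0)) / h
        assert left == pytest.approx(right, abs=1e-5)
        assert left == pytest.approx(1.0, abs=1e-5)

    def test_zero_maps_to_positive_value(self):
        assert transform_dls(0.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_dls(-1.0)


class TestEMFit:
    def test_single_component_recovery_matches_grid_mle(self, rng):
        y = 20.0 * rng.weibull(3.0, 5000)
        mix, _ = em_fit(y, 1)
        # independent oracle: dense grid search over (shape, scale)
        shapes = np.linspace(2.0, 4.0, 81)
        scales = np.linspace(17.0, 23.0, 121)
        ll = np.array(
            [
                [np.sum(np.log(weibull_pdf(y, a, b))) for b in scales]
                for a in shapes
            ]
        )
        ia, ib = np.unravel_index(np.argmax(ll), ll.shape)
        assert mix.components[0].alpha == pytest.approx(shapes[ia], rel=0.05)
        assert mix.components[0].beta == pytest.approx(scales[ib], rel=0.02)
        assert mix.components[0].alpha == pytest.approx(3.0, rel=0.05)
        assert mix.components[0].beta == pytest.approx(20.0, rel=0.02)

    def test_two_component_weight_recovery(self, rng):
        y = np.concatenate(
            [25.0 * rng.weibull(5.0, 3500), 5.0 * rng.weibull(1.5, 1500)]
        )
        mix, _ = em_fit(y, 2, seed=0)
        assert sorted(mix.weights) == pytest.approx([0.3, 0.7], abs=0.05)

    def test_loglikelihood_monotone_ascent(self, rng):
        y = np.concatenate([30.0 * rng.weibull(8.0, 800), 4.0 * rng.weibull(1.2, 400)])
        _, _, history = em_fit(y, 2, seed=1, return_history=True)
        assert len(history) > 1
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-9)

    def test_requires_enough_data(self):
        with pytest.raises(ValueError, match="at least"):
            em_fit(np.ones(5) * 2.0, 1)

    def test_rejects_nonpositive_data(self):
        with pytest.raises(ValueError):
            em_fit(np.array([0.0, 1.0, 2.0] * 10), 1)


class TestSelectK:
    def test_bimodal_data_selects_two(self, rng):
        y = np.concatenate(
            [28.0 * rng.weibull(9.0, 1300), 3.0 * rng.weibull(1.3, 700)]
        )
        y = rng.permutation(y)
        assert select_k(y, k_max=3, seed=0) == 2

    def test_single_weibull_selects_one(self, rng):
        y = 20.0 * rng.weibull(3.0, 2000)
        assert select_k(y, k_max=3, seed=0) == 1

    def test_kmax_one_returns_one(self, rng):
        y = 20.0 * rng.weibull(3.0, 200)
        assert select_k(y, k_max=1, seed=0) == 1


@pytest.fixture(scope="module")
def fitted_small_model():
    cfg = GeneratorConfig(seed=5, n_eyes=12, n_repeats=8)
    pairs = gen_retest_pairs(cfg)
    return fit_retest_model(pairs, k_components=2, seed=0)


class TestRetestModel:
    def test_pair_count_formula(self):
        cfg = GeneratorConfig(seed=0, n_eyes=30, n_repeats=12)
        pairs = gen_retest_pairs(cfg)
        assert pairs.n_test_pairs() == 30 * math.comb(12, 2) == 1980

    def test_every_level_has_mixture(self, fitted_small_model):
        assert sorted(fitted_small_model.level_mixtures) == list(range(36))

    def test_density_integrates_to_one_at_fitted_levels(self, fitted_small_model):
        for v in (0, 10, 25, 35):
            mix = fitted_small_model.level_mixtures[v]
            total, _ = quad(lambda y: mix.pdf(y), 0.0, 400.0, limit=300)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_logpdf_smooth_in_predicted_level(self, fitted_small_model):
        mus = np.linspace(0.0, 35.0, 1401)
        lp = fitted_small_model.logpdf(np.full_like(mus, 22.0), mus)
        assert np.all(np.isfinite(lp))
        d = np.diff(lp) / np.diff(mus)
        assert np.all(np.isfinite(d))
        assert np.abs(d).max() < 100.0

    def test_gradient_matches_finite_differences(self, fitted_small_model):
        y = np.array([18.0, 3.0, 31.0, 0.0])
        mu = np.array([20.0, 5.5, 30.2, 1.3])
        _, g = fitted_small_model.logpdf_grad(y, mu)
        h = 1e-6
        fd = (fitted_small_model.logpdf(y, mu + h) - fitted_small_model.logpdf(y, mu - h)) / (2 * h)
        assert g == pytest.approx(fd, abs=1e-4)

    def test_retest_interval_wider_at_damaged_levels(self, retest_model):
        q20 = retest_model.quantiles(20.0, [0.05, 0.95])
        q32 = retest_model.quantiles(32.0, [0.05, 0.95])
        assert q20[1] - q20[0] > q32[1] - q32[0]

    def test_json_round_trip(self, fitted_small_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_small_model.to_json(path)
        back = RetestModel.from_json(path)
        for v in range(36):
            a = fitted_small_model.level_mixtures[v]
            b = back.level_mixtures[v]
            assert a.weights == b.weights
            assert a.components == b.components
        mus = np.array([0.0, 7.7, 31.2])
        ys = np.array([5.0, 9.0, 30.0])
        assert back.logpdf(ys, mus) == pytest.approx(
            fitted_small_model.logpdf(ys, mus), rel=1e-12
        )

    def test_mixture_weights_validated(self):
        with pytest.raises(ValueError):
            WeibullMixture(weights=(0.5, 0.4), components=(
                WeibullComponent(1.0, 1.0), WeibullComponent(2.0, 2.0)))

    def test_pairs_value_range_validated(self):
        import pandas as pd

        with pytest.raises(ValueError):
            RetestPairs(pd.DataFrame({"baseline_dls": [60.0], "retest_dls": [10.0]}))
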