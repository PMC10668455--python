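import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import longdens as ld
from longdens.empirical_bayes import PAPER_DEFAULT_CUTS
from longdens.lmm import build_design


def grid_posterior_mean(x, z, y, params, half_width=4.0, n_grid=401):
    """Independent Bayes oracle: 2-D quadrature of prior x likelihood."""
    sds = np.sqrt(np.diag(params.G))
    g0 = np.linspace(-half_width * sds[0], half_width * sds[0], n_grid)
    g1 = np.linspace(-half_width * sds[1], half_width * sds[1], n_grid)
    B0, B1 = np.meshgrid(g0, g1, indexing="ij")
    Ginv = np.linalg.inv(params.G)
    quad = (
        Ginv[0, 0] * B0**2 + 2 * Ginv[0, 1] * B0 * B1 + Ginv[1, 1] * B1**2
    )
    mu = x @ params.beta + z[0] * B0 + z[1] * B1
    loglik = -0.5 * (y - mu) ** 2 / params.sigma2
    w = np.exp(-0.5 * quad + loglik)
    w /= w.sum()
    return np.array([(w * B0).sum(), (w * B1).sum()])


def henderson_blup(X, Z, y, params):
    """Independent BLUP oracle via Henderson's mixed-model equations:
    b = (Z'Z/s2 + G^-1)^-1 Z'(y - X beta)/s2."""
    Ginv = np.linalg.inv(params.G)
    A = Z.T @ Z / params.sigma2 + Ginv
    return np.linalg.solve(A, Z.T @ (y - X @ params.beta) / params.sigma2)


class TestPosterior:
    def test_empty_history_returns_prior(self, true_params):
        b, C = ld.eb_posterior(np.empty((0, 7)), np.empty((0, 2)), [], true_params)
        assert np.array_equal(b, np.zeros(2))
        assert np.array_equal(C, true_params.G)

    def test_degenerate_prior_pins_to_zero(self, true_params):
        p = ld.LmmParams(beta=true_params.beta, G=np.zeros((2, 2)),
                         sigma2=0.2, centering=10.0)
        X, Z = build_design([50.0, 55.0], [25.0, 25.0], 10.0)
        b, C = ld.eb_posterior(X, Z, [4.0, 4.0], p)
        assert np.allclose(b, 0.0)
        assert np.allclose(C, 0.0)

    def test_single_observation_matches_grid_oracle(self, true_params):
        X, Z = build_design(57.0, 28.0, true_params.centering)
        y = 3.0
        b, _ = ld.eb_posterior(X, Z, [y], true_params)
        oracle = grid_posterior_mean(X[0], Z[0], y, true_params)
        assert np.abs(b - oracle).max() < 1e-4

    def test_posterior_covariance_shrinks_with_history(self, true_params):
        """Loewner-monotone: more observations never increase b_cov."""
        rng = np.random.default_rng(3)
        ages = 50 + np.cumsum(rng.uniform(1, 2, 6))
        X, Z = build_design(ages, np.full(6, 26.0), true_params.centering)
        y = 2.5 + rng.normal(0, 0.5, 6)
        prev = true_params.G
        for k in range(1, 7):
            _, C = ld.eb_posterior(X[:k], Z[:k], y[:k], true_params)
            assert np.linalg.eigvalsh(prev - C).min() > -1e-10
            prev = C


class TestPrediction:
    def test_no_history_gives_population_mean(self, true_params):
        x, _ = build_design(60.0, 30.0, true_params.centering)
        pred = ld.predict_longitudinal_density([], 60.0, 30.0, true_params)
        assert pred == pytest.approx(float(x[0] @ true_params.beta), abs=1e-12)

    def test_dense_blup_oracle(self, true_params):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 11))
            ages = 45 + np.cumsum(rng.uniform(0.8, 2.2, n))
            bmis = np.clip(27 + rng.normal(0, 4, n), 16, 35)
            y = np.clip(np.round(2.5 + rng.normal(0, 0.8, n)), 1, 4)
            X, Z = build_design(ages, bmis, true_params.centering)
            hist = list(zip(ages, bmis, y))
            pred = ld.predict_longitudinal_density(
                hist, ages[-1], bmis[-1], true_params
            )
            b = henderson_blup(X, Z, y, true_params)
            expected = X[-1] @ true_params.beta + Z[-1] @ b
            assert abs(pred - expected) < 1e-8

    def test_shrinkage_toward_saturated_reading(self, true_params):
        # 20 identical maximal readings at constant design: the estimate
        # sits strictly between the population mean and 4, and lands
        # within 0.05 of 4 once the prior dominates the residual noise
        p = ld.LmmParams(beta=true_params.beta,
                         G=np.array([[2.0, 0.0], [0.0, 0.01]]),
                         sigma2=0.01, centering=10.0)
        hist = [(50.0, 25.0, 4.0)] * 20
        x, _ = build_design(50.0, 25.0, 10.0)
        pop = float(x[0] @ p.beta)
        pred = ld.predict_longitudinal_density(hist, 50.0, 25.0, p)
        assert pop < pred < 4.0
        assert 4.0 - pred < 0.05


class TestSequential:
    def test_single_screen_one_estimate(self, tiny_cohort, true_params):
        c = ld.impute_bmi(tiny_cohort)
        est = ld.sequential_estimates(c, true_params)
        assert len(est) == c.n_screens
        assert est.groupby("woman_id")["n_obs_used"].first().tolist() == [1, 1]
        assert est.groupby("woman_id")["n_obs_used"].last().tolist() == [3, 2]

    def test_no_lookahead(self, true_params):
        screens = pd.DataFrame(
            {
                "woman_id": ["w"] * 4,
                "exam_time": [0.0, 1.5, 3.0, 4.5],
                "age": [50.0, 51.5, 53.0, 54.5],
                "bmi": [25.0] * 4,
                "birads": [3.0, 2.0, 3.0, 2.0],
            }
        )
        outcomes = pd.DataFrame(
            {"woman_id": ["w"], "exit_time": [6.0], "event": [0],
             "censor_reason": ["admin_end"]}
        )
        full = ld.CohortTable(screens, outcomes)
        head = ld.CohortTable(
            screens.iloc[:3],
            outcomes,
        )
        e_full = ld.sequential_estimates(full, ld.SimConfig().lmm_params())
        e_head = ld.sequential_estimates(head, ld.SimConfig().lmm_params())
        assert np.allclose(
            e_full["value"].to_numpy()[:3], e_head["value"].to_numpy(), atol=1e-12
        )

    def test_flipflop_readings_are_smoothed(self, true_params):
        screens = pd.DataFrame(
            {
                "woman_id": ["w"] * 4,
                "exam_time": [0.0, 1.5, 3.0, 4.5],
                "age": [50.0, 51.5, 53.0, 54.5],
                "bmi": [25.0] * 4,
                "birads": [3.0, 2.0, 3.0, 2.0],
            }
        )
        outcomes = pd.DataFrame(
            {"woman_id": ["w"], "exit_time": [6.0], "event": [0],
             "censor_reason": ["admin_end"]}
        )
        est = ld.sequential_estimates(
            ld.CohortTable(screens, outcomes), true_params
        )
        assert est["value"].max() - est["value"].min() < 1.0

    def test_shrinkage_bound_constant_design(self, true_params):
        """|estimate - pop mean| <= |running mean reading - pop mean|."""
        readings = [4.0, 4.0, 3.0, 4.0, 4.0]
        n = len(readings)
        screens = pd.DataFrame(
            {
                "woman_id": ["w"] * n,
                # constant age within tolerance so the design is constant
                "exam_time": np.arange(n) * 0.01,
                "age": 55.0 + np.arange(n) * 0.01,
                "bmi": [25.0] * n,
                "birads": readings,
            }
        )
        outcomes = pd.DataFrame(
            {"woman_id": ["w"], "exit_time": [6.0], "event": [0],
             "censor_reason": ["admin_end"]}
        )
        est = ld.sequential_estimates(
            ld.CohortTable(screens, outcomes), true_params
        )
        x, _ = build_design(55.0, 25.0, true_params.centering)
        pop = float(x[0] @ true_params.beta)
        run_mean = np.cumsum(readings) / np.arange(1, n + 1)
        assert np.all(
            np.abs(est["value"].to_numpy() - pop) <= np.abs(run_mean - pop) + 1e-6
        )

    def test_g_zero_reduces_to_fixed_surface(self, sim_cohort, true_params):
        p = ld.LmmParams(beta=true_params.beta, G=np.zeros((2, 2)),
                         sigma2=true_params.sigma2, centering=10.0)
        est = ld.sequential_estimates(sim_cohort, p)
        s = sim_cohort.screens
        X, _ = build_design(s["age"].to_numpy(), s["bmi"].to_numpy(), 10.0)
        assert np.allclose(est["value"].to_numpy(), X @ p.beta, atol=1e-10)

    def test_exclusive_variant_ignores_current_reading(self, true_params):
        screens = pd.DataFrame(
            {
                "woman_id": ["w"] * 2,
                "exam_time": [0.0, 2.0],
                "age": [50.0, 52.0],
                "bmi": [25.0] * 2,
                "birads": [4.0, 4.0],
            }
        )
        outcomes = pd.DataFrame(
            {"woman_id": ["w"], "exit_time": [6.0], "event": [0],
             "censor_reason": ["admin_end"]}
        )
        c = ld.CohortTable(screens, outcomes)
        excl = ld.sequential_estimates(c, true_params, inclusive=False)
        x, _ = build_design(50.0, 25.0, true_params.centering)
        assert excl["value"].iloc[0] == pytest.approx(
            float(x[0] @ true_params.beta)
        )
        assert excl["n_obs_used"].tolist() == [0, 1]


class TestCategorize:
    @pytest.mark.parametrize("value, cat", [(3.7, 8), (1.49, 1), (2.0, 3)])
    def test_published_boundaries(self, value, cat):
        assert ld.categorize(value, ld.CutPoints.paper_default()) == cat

    def test_category4_is_paired(self):
        cuts = ld.CutPoints.paper_default()
        vals = np.linspace(0.5, 4.5, 101)
        c8 = ld.categorize(vals, cuts)
        assert np.array_equal(np.ceil(c8 / 2), np.ceil(c8 / 2).astype(int))

    @given(st.floats(min_value=-2, max_value=8), st.floats(min_value=-2, max_value=8))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_value(self, a, b):
        cuts = ld.CutPoints.paper_default()
        lo, hi = sorted([a, b])
        assert ld.categorize(lo, cuts) <= ld.categorize(hi, cuts)


class TestDeriveCutpoints:
    def test_uniform_equal_quarters(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 40000)
        b = np.repeat([1, 2, 3, 4], 10000)
        cuts = ld.derive_cutpoints(v, b)
        assert np.abs(
            np.array(cuts.thresholds) - np.arange(1, 8) / 8.0
        ).max() < 0.01

    def test_self_consistency_of_proportions(self, sim_cohort, sim_estimates):
        """Derived cuts reproduce the baseline BI-RADS proportions.

        Categories 1-2 together match BI-RADS A at baseline (within 1/n
        per category), with an equal split inside each pair.
        """
        _, cuts, est = sim_estimates
        base = est.groupby("woman_id").first()
        n = len(base)
        c8 = base["category8"].to_numpy()
        counts = np.bincount(c8, minlength=9)[1:]
        birads0 = sim_cohort.screens.groupby("woman_id")["birads"].first()
        target = np.array([(birads0 == k).sum() for k in (1, 2, 3, 4)])
        pair_prop = counts.reshape(4, 2).sum(axis=1) / n
        assert np.abs(pair_prop - target / n).max() <= 2.0 / n
        # equal split inside each pair, to within one woman per category
        assert np.abs(counts[::2] - counts[1::2]).max() <= 2

    def test_degenerate_all_one_category(self):
        rng = np.random.default_rng(1)
        v = rng.normal(2.0, 0.3, 100)
        cuts = ld.derive_cutpoints(v, np.ones(100))
        t = np.array(cuts.thresholds)
        assert np.all(np.diff(t) > 0)  # still strictly increasing
        # p1 = 1: only the first cut is an interior quantile (the median)
        assert t[0] == pytest.approx(np.quantile(v, 0.5, method="inverted_cdf"))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 8"):
            ld.derive_cutpoints([1.0] * 5, [1, 2, 3, 4, 1])

    def test_json_round_trip(self, tmp_path):
        cuts = ld.CutPoints.paper_default()
        cuts.to_json(tmp_path / "c.json")
        back = ld.CutPoints.from_json(tmp_path / "c.json")
        assert back.thresholds == PAPER_DEFAULT_CUTS
        assert back.provenance == "paper_default"
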