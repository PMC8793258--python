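"""Lin-Ying additive hazards: hand oracle, recovery, rescaling, interactions."""

import numpy as np
import pandas as pd
import pytest

from lifemet.additive_hazard import (
    AdditiveHazardModel,
    SurvivalData,
    fit_additive_hazard,
    hls_rd,
    subgroup_interaction,
)
from lifemet.regression import CovariateSpec


def brute_force_lin_ying(time, event, Z, weights=None):
    """Independent oracle: assemble the estimating equation directly.

    A = sum_i w_i int_0^{T_i} (Z_i - Zbar_w(t)) Z_i' dt  evaluated by
    explicit segment-by-segment integration over the pooled time grid;
    b = sum over events of w_i (Z_i - Zbar_w(T_i)).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[0] != time.size:
        Z = Z.T
    w = np.ones_like(time) if weights is None else np.asarray(weights, float)
    n, p = Z.shape
    grid = np.concatenate([[0.0], np.sort(np.unique(time))])
    A = np.zeros((p, p))
    b = np.zeros(p)
    for k in range(1, grid.size):
        t0, t1 = grid[k - 1], grid[k]
        at_risk = time >= t1  # risk set on (t0, t1]
        if not at_risk.any():
            continue
        zbar = (w[at_risk, None] * Z[at_risk]).sum(0) / w[at_risk].sum()
        for i in np.where(at_risk)[0]:
            A += w[i] * np.outer(Z[i] - zbar, Z[i]) * (t1 - t0)
        for i in np.where((time == t1) & (event == 1))[0]:
            b += w[i] * (Z[i] - zbar)
    return np.linalg.solve(A, b)


class TestHandOracle:
    def test_four_subject_hand_example(self):
        # 4 subjects, 1 binary covariate, no ties
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        beta_hand = brute_force_lin_ying(time, event, x)
        fit = AdditiveHazardModel(time, event, pd.DataFrame({"x": x})).fit()
        np.testing.assert_allclose(fit.params["x"], beta_hand[0], rtol=1e-10)

    def test_two_covariates_with_weights_vs_oracle(self):
        rng = np.random.default_rng(11)
        n = 25
        time = rng.uniform(0.5, 10, n)
        event = rng.integers(0, 2, n)
        event[0] = 1  # ensure at least one event
        Z = rng.normal(size=(n, 2))
        w = rng.uniform(0.5, 2.5, n)
        beta_hand = brute_force_lin_ying(time, event, Z, w)
        fit = AdditiveHazardModel(
            time, event, pd.DataFrame(Z, columns=["a", "b"]), w
        ).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), beta_hand, rtol=1e-8)

    def test_tied_event_times_match_oracle(self):
        time = np.array([2.0, 2.0, 3.0, 3.0, 5.0])
        event = np.array([1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        beta_hand = brute_force_lin_ying(time, event, x)
        fit = AdditiveHazardModel(time, event, pd.DataFrame({"x": x})).fit()
        np.testing.assert_allclose(fit.params["x"], beta_hand[0], rtol=1e-6)


class TestRecovery:
    def test_simulation_recovery_within_3se(self):
        rng = np.random.default_rng(12)
        n = 20_000
        x = rng.normal(size=n)
        lam = np.maximum(0.03 + 0.01 * x, 1e-6)
        t = np.minimum(rng.exponential(1 / lam), 12.0)
        ev = (t < 12.0).astype(int)
        fit = AdditiveHazardModel(t, ev, pd.DataFrame({"x": x})).fit()
        assert abs(fit.params["x"] - 0.01) < 3 * fit.bse["x"]

    def test_crude_rate_difference_limit(self):
        """With a binary covariate the estimate converges to the
        difference in events-per-person-time between groups."""
        rng = np.random.default_rng(13)
        n = 50_000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.05 + 0.02 * x
        t = rng.exponential(1 / lam)
        fit = AdditiveHazardModel(t, np.ones(n, int), pd.DataFrame({"x": x})).fit()
        crude = 1 / t[x == 1].mean() - 1 / t[x == 0].mean()
        assert fit.params["x"] == pytest.approx(crude, abs=0.003)
        assert fit.params["x"] == pytest.approx(0.02, abs=0.003)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(14)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(10, n)
        ev = rng.integers(0, 2, n)
        ev[:5] = 1
        w = rng.uniform(0.5, 2, n)
        f1 = AdditiveHazardModel(t, ev, pd.DataFrame({"x": x}), w).fit()
        f2 = AdditiveHazardModel(t, ev, pd.DataFrame({"x": x}), 5.0 * w).fit()
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-12)
        np.testing.assert_allclose(f1.cov, f2.cov, atol=1e-12)


class TestDegenerate:
    def test_constant_covariate_errors(self):
        with pytest.raises(np.linalg.LinAlgError, match="degenerate"):
            AdditiveHazardModel(
                np.array([1.0, 2.0]), np.array([1, 0]),
                pd.DataFrame({"x": [3.0, 3.0]}),
            )

    def test_zero_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            AdditiveHazardModel(
                np.array([1.0, 2.0]), np.array([0, 0]),
                pd.DataFrame({"x": [0.0, 1.0]}),
            )

    def test_nonpositive_time_errors(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalData(np.array([0.0, 1.0]), np.array([1, 0]),
                         pd.DataFrame({"x": [0.0, 1.0]}))


class TestRateDifferences:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(15)
        n = 2000
        x = rng.normal(size=n)
        lam = np.maximum(0.02 + 0.002 * x, 1e-8)
        t = np.minimum(rng.exponential(1 / lam), 14.0)
        ev = (t < 14.0).astype(int)
        return AdditiveHazardModel(t, ev, pd.DataFrame({"x": x})).fit()

    def test_span_one_equals_per_unit(self, fitted):
        rd1 = fitted.rd_for_exposure("x")
        rd2 = fitted.rd_for_exposure("x", span=1.0)
        assert rd1.rd == rd2.rd
        assert rd1.ci == rd2.ci

    def test_span_rescales_rd_and_ci(self, fitted):
        rd1 = fitted.rd_for_exposure("x")
        rd39 = fitted.rd_for_exposure("x", span=39.1)
        assert rd39.rd == pytest.approx(39.1 * rd1.rd)
        assert rd39.ci[1] - rd39.ci[0] == pytest.approx(39.1 * (rd1.ci[1] - rd1.ci[0]))

    def test_missing_exposure_errors(self, fitted):
        with pytest.raises(KeyError):
            fitted.rd_for_exposure("not_there")

    def test_sign_flip_under_negated_exposure(self):
        rng = np.random.default_rng(16)
        n = 1000
        x = rng.normal(size=n)
        lam = np.maximum(0.05 + 0.01 * x, 1e-8)
        t = rng.exponential(1 / lam)
        ev = np.ones(n, int)
        f1 = AdditiveHazardModel(t, ev, pd.DataFrame({"x": x})).fit()
        f2 = AdditiveHazardModel(t, ev, pd.DataFrame({"x": -x})).fit()
        rd1, rd2 = f1.rd_for_exposure("x"), f2.rd_for_exposure("x")
        assert rd2.rd == pytest.approx(-rd1.rd, rel=1e-8)
        assert rd2.ci[0] == pytest.approx(-rd1.ci[1], rel=1e-6)


class TestHlsRd:
    def test_null_preset_rd_near_zero(self, null_cohort):
        part, _, outc, _ = null_cohort
        keep = ((outc.prevalent_diabetes == 0) & (outc.lost_to_follow_up == 0)).to_numpy()
        res, rds = hls_rd(
            outc.loc[keep, "follow_up_years"],
            outc.loc[keep, "incident_diabetes"],
            part.loc[keep, "hls_total"],
            part.loc[keep].reset_index(drop=True),
            CovariateSpec("M2"),
            part.loc[keep, "weight"],
        )
        rd = rds[0]
        se = (rd.ci[1] - rd.ci[0]) / (2 * 1.96)
        assert abs(rd.rd) < 3 * se

    def test_mediated_preset_recovery_and_sign_consistency(self, prospective):
        part, adj, outc, truth = prospective
        res, rds = hls_rd(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], part, CovariateSpec("M2"), part["weight"],
        )
        rd = rds[0]
        se = (rd.ci[1] - rd.ci[0]) / (2 * 1.96)
        assert abs(rd.rd - truth.true_total_rd) < 3 * se
        # categorical coding agrees in sign (monotone protective truth)
        _, rds_cat = hls_rd(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], part, CovariateSpec("M2"), part["weight"],
            categorical=True,
        )
        assert rds_cat[1].rd < 0  # high vs low


class TestInteraction:
    def test_independent_modifier_interaction_near_zero(self, null_cohort):
        part, _, outc, _ = null_cohort
        rng = np.random.default_rng(17)
        mod = rng.integers(0, 2, len(part)).astype(float)
        out = subgroup_interaction(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"].astype(float), mod, part, CovariateSpec("M1"),
            part["weight"],
        )
        se = (out["ci"][1] - out["ci"][0]) / (2 * 1.96)
        assert abs(out["interaction_rd_per_10k_py"]) < 3 * se

    def test_constructed_effect_modification_recovered(self):
        rng = np.random.default_rng(18)
        n = 20_000
        x = rng.normal(size=n)
        g = rng.integers(0, 2, n).astype(float)
        lam = np.maximum(0.03 + 0.005 * x + 0.005 * x * g, 1e-8)
        t = np.minimum(rng.exponential(1 / lam), 10.0)
        ev = (t < 10.0).astype(int)
        X = pd.DataFrame({"exposure": x, "modifier": g, "exposure_x_modifier": x * g})
        fit = AdditiveHazardModel(t, ev, X).fit()
        assert abs(fit.params["exposure_x_modifier"] - 0.005) < 3 * fit.bse[
            "exposure_x_modifier"
        ]

    def test_collinear_modifier_rank_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        ev = np.array([1, 1, 0, 1])
        x = np.array([0.0, 1.0, 0.0, 1.0])
        df = pd.DataFrame({"age": [50.0, 60, 55, 45], "sex": ["male"] * 4,
                           "education": ["<=hs"] * 4})
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            subgroup_interaction(t, ev, x, x, df, CovariateSpec("M1"))

    def test_single_value_modifier_rejected(self):
        t = np.array([1.0, 2.0])
        ev = np.array([1, 0])
        df = pd.DataFrame({"age": [50.0, 60.0], "sex": ["male", "female"],
                           "education": ["<=hs", ">hs"]})
        with pytest.raises(ValueError, match="subgroup"):
            subgroup_interaction(t, ev, np.array([0.5, 1.0]), np.array([1.0, 1.0]),
                                 df, CovariateSpec("M1"))


def test_functional_entry_point():
    rng = np.random.default_rng(19)
    n = 200
    x = rng.normal(size=n)
    t = rng.exponential(5, n)
    ev = rng.integers(0, 2, n)
    ev[0] = 1
    data = SurvivalData(t, ev, pd.DataFrame({"x": x}))
    res = fit_additive_hazard(data)
    assert "x" in res.params.index
    assert res.summary().loc["x", "p"] <= 1.0
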