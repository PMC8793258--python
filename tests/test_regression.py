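"""Survey-weighted linear and Poisson models, q-values, metabolome screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from lifemet.regression import (
    CovariateSpec,
    qvalues,
    screen_metabolome,
    weighted_lm,
    weighted_poisson_rate,
)


def _design(*cols, n=None):
    n = n or len(cols[0])
    X = pd.DataFrame({"const": np.ones(n)})
    for i, c in enumerate(cols):
        X[f"x{i}"] = c
    return X


class TestWeightedLM:
    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 1 + 2 * x + rng.normal(size=50)
        f1 = weighted_lm(y, _design(x), np.full(50, 3.7))
        f2 = weighted_lm(y, _design(x), None)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)
        np.testing.assert_allclose(f1.cov, f2.cov, atol=1e-10)

    def test_integer_weights_equal_duplication(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 0.5 - x + rng.normal(size=30)
        w = rng.integers(1, 4, 30).astype(float)
        fw = weighted_lm(y, _design(x), w)
        rep = np.repeat(np.arange(30), w.astype(int))
        fd = weighted_lm(y[rep], _design(x[rep]), None)
        np.testing.assert_allclose(fw.params, fd.params, atol=1e-10)

    def test_exact_fit_coefficient_one(self):
        x = np.linspace(-2, 2, 20)
        f = weighted_lm(x, _design(x))
        assert f.params["x0"] == pytest.approx(1.0)
        assert f.params["const"] == pytest.approx(0.0, abs=1e-12)
        assert f.bse["x0"] == pytest.approx(0.0, abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        w = rng.uniform(0.5, 2, 40)
        f1 = weighted_lm(y, _design(x), w)
        f2 = weighted_lm(y, _design(x), 17.3 * w)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)
        np.testing.assert_allclose(f1.cov, f2.cov, atol=1e-8)

    def test_collinear_columns_named(self):
        x = np.arange(10.0)
        X = _design(x)
        X["x_copy"] = x
        with pytest.raises(np.linalg.LinAlgError, match="x_copy|x0"):
            weighted_lm(x, X)


class TestWeightedPoisson:
    def test_no_covariates_closed_form(self):
        rng = np.random.default_rng(3)
        events = rng.poisson(0.3, 200)
        py = rng.uniform(1, 15, 200)
        f = weighted_poisson_rate(events, py, _design(np.zeros(200)).iloc[:, :1])
        assert np.exp(f.params["const"]) == pytest.approx(
            events.sum() / py.sum(), rel=1e-10
        )

    def test_weighted_closed_form(self):
        rng = np.random.default_rng(4)
        events = rng.poisson(0.2, 100)
        py = rng.uniform(1, 10, 100)
        w = rng.uniform(0.5, 3, 100)
        f = weighted_poisson_rate(events, py, _design(np.zeros(100)).iloc[:, :1], w)
        assert np.exp(f.params["const"]) == pytest.approx(
            (w * events).sum() / (w * py).sum(), rel=1e-10
        )

    def test_duplication_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        py = rng.uniform(2, 12, 60)
        events = rng.poisson(py * 0.05 * np.exp(0.3 * x))
        w = rng.integers(1, 4, 60).astype(float)
        fw = weighted_poisson_rate(events, py, _design(x), w)
        rep = np.repeat(np.arange(60), w.astype(int))
        fd = weighted_poisson_rate(events[rep], py[rep], _design(x[rep]))
        np.testing.assert_allclose(fw.params, fd.params, atol=1e-8)

    def test_rr_recovery_multiplicative_truth(self):
        """Piecewise-exponential truth with RR 0.7 per exposure point."""
        rng = np.random.default_rng(6)
        n = 5000
        x = rng.integers(0, 6, n).astype(float)
        lam = 0.02 * 0.7**x
        t = np.minimum(rng.exponential(1 / lam), 14.0)
        ev = (t < 14.0).astype(int)
        f = weighted_poisson_rate(ev, t, _design(x))
        rr = np.exp(f.params["x0"])
        se = f.bse["x0"]
        assert abs(np.log(rr) - np.log(0.7)) < 3 * se

    def test_negative_person_years_rejected(self):
        with pytest.raises(ValueError, match="person-years"):
            weighted_poisson_rate([1], [0.0], _design(np.zeros(1)).iloc[:, :1])


class TestQvalues:
    def test_hand_bh_worked_example(self):
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(qvalues(np.ones(3)), np.ones(3))

    def test_matches_independent_bh_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = rng.integers(5, 200)
            p = rng.uniform(size=m)
            q = qvalues(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=37)
        perm = rng.permutation(37)
        np.testing.assert_allclose(qvalues(p)[perm], qvalues(p[perm]), atol=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_q_monotone_in_p(self, plist):
        p = np.asarray(plist)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_storey_pi0_with_positive_lambda(self):
        p = np.array([0.01, 0.2, 0.6, 0.9])
        q0 = qvalues(p, lambda_=0.0)
        q5 = qvalues(p, lambda_=0.5)
        assert (q5 <= q0 + 1e-12).all()  # pi0 <= 1 shrinks q

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.2]))


class TestScreen:
    def test_planted_effect_recovered(self, null_cohort):
        from lifemet.metabolites import fasting_adjust

        part, mat, _, _ = null_cohort
        adj = fasting_adjust(mat, part["fasting_hours"].to_numpy())
        hls = part["hls_total"].to_numpy().astype(float)
        # plant a 0.11-per-point association into one metabolite
        rng = np.random.default_rng(9)
        planted = adj.values.copy()
        planted["amino_acid_1"] = 0.11 * hls + rng.normal(0, 0.3, len(hls))
        adj2 = type(adj)(
            values=planted, groups=adj.groups, fasting_adjusted=True
        )
        out = screen_metabolome(
            adj2, hls, CovariateSpec("M2"), part, part["weight"].to_numpy()
        )
        row = out.set_index("metabolite").loc["amino_acid_1"]
        assert row["md"] == pytest.approx(0.11, abs=0.03)
        assert row["selected"]
        assert row["ci_lower"] < row["md"] < row["ci_upper"]

    def test_constant_hls_gives_no_selections(self, null_cohort):
        from lifemet.metabolites import fasting_adjust

        part, mat, _, _ = null_cohort
        adj = fasting_adjust(mat, part["fasting_hours"].to_numpy())
        hls = np.full(len(part), 2.0)
        out = screen_metabolome(
            adj, hls, CovariateSpec("M1"), part, part["weight"].to_numpy()
        )
        # constant exposure is collinear with the intercept: every fit errors,
        # and the screen records rather than raises
        assert out["error"].notna().all()
        assert not out["selected"].any()

    def test_null_preset_false_selection_rate(self):
        """Mean false selections under the null ~ m * FDR (pi0 = 1)."""
        from lifemet import generate_cohort, scenario_presets
        from lifemet.metabolites import fasting_adjust

        counts = []
        for seed in range(12):
            part, mat, _, _ = generate_cohort(
                scenario_presets("null", seed=300 + seed, n_participants=400)
            )
            adj = fasting_adjust(mat, part["fasting_hours"].to_numpy())
            out = screen_metabolome(
                adj,
                part["hls_total"].to_numpy().astype(float),
                CovariateSpec("M1"),
                part,
                part["weight"].to_numpy(),
            )
            counts.append(out["selected"].sum())
        mean_false = np.mean(counts)
        # expectation 49 * 0.025 ~ 1.2; generous band for 12 replicates
        assert mean_false < 49 * 0.025 * 3 + 1


def test_covariate_spec_terms():
    assert CovariateSpec("M1").terms == ("age", "sex", "education")
    m2 = CovariateSpec("M2").terms
    assert set(m2) >= {"age", "sex", "education", "hypertension",
                       "total_cholesterol", "lipid_lowering"}
    with pytest.raises(ValueError):
        CovariateSpec("M3")
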