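"""Percent explained, BCa bootstrap, product-of-coefficients NIEs."""

import numpy as np
import pandas as pd
import pytest

from lifemet.mediation import (
    bca_interval,
    consistency_check,
    decompose_by_group,
    mediate_relevant,
    nie_product,
    percent_explained,
    percentile_interval,
)
from lifemet.regression import CovariateSpec


class TestPercentExplained:
    @pytest.mark.parametrize(
        "rd_adj,expected",
        [
            (-4.45, 45.9),
            (-4.49, 45.4),
            (-6.38, 22.5),
            (-6.12, 25.6),
            (-5.20, 36.8),
            (-5.10, 38.0),
            (-6.24, 24.2),
            (-3.91, 52.5),
        ],
    )
    def test_attenuation_worked_examples(self, rd_adj, expected):
        """Attenuations of a -8.23/10k PY reference rate difference."""
        assert round(percent_explained(-8.23, rd_adj), 1) == expected

    def test_no_attenuation_is_zero(self):
        assert percent_explained(-8.23, -8.23) == 0.0

    def test_scale_invariance_and_no_clamping(self):
        assert percent_explained(-8.0, -4.0) == percent_explained(-0.8, -0.4) == 50.0
        assert percent_explained(-8.0, 4.0) == 150.0
        assert percent_explained(-8.0, -16.0) == -100.0

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="zero"):
            percent_explained(0.0, -1.0)


class TestBca:
    def test_reduces_to_percentile_when_symmetric(self):
        # exactly half the replicates below theta -> z0 = 0; constant
        # jackknife -> a = 0
        boot = np.linspace(-1, 1, 400) + 5.0
        jk = np.full(30, 5.0)
        assert bca_interval(5.0, boot, jk) == pytest.approx(
            percentile_interval(boot), abs=1e-6
        )

    def test_bias_shifts_interval(self):
        rng = np.random.default_rng(0)
        boot = rng.normal(1.0, 1.0, 2000)  # bootstrap centred above theta
        jk = np.full(20, 0.0)
        lo_b, hi_b = bca_interval(0.0, boot, jk)
        lo_p, hi_p = percentile_interval(boot)
        assert lo_b < lo_p and hi_b < hi_p  # correction pulls toward theta

    def test_empty_boot_errors(self):
        with pytest.raises(ValueError):
            bca_interval(0.0, np.array([]), np.array([0.0]))


class TestNieProduct:
    def test_zero_alpha_gives_zero_nie_with_covering_ci(self):
        res = nie_product(0.0, 0.01, 2e-4, 1e-9, rd_before=-8.0, seed=1)
        assert res.nie == 0.0
        assert res.ci[0] < 0 < res.ci[1]

    def test_product_recovery_at_scale(self):
        # planted alpha*theta with tiny estimation noise
        res = nie_product(0.25, 1e-8, -5.3333e-4, 1e-14, rd_before=-8.0,
                          seed=2, mediator="m")
        assert res.nie == pytest.approx(0.25 * -5.3333e-4 * 1e4, rel=1e-6)
        assert res.relative == pytest.approx(res.nie / -8.0)

    def test_ci_converges_in_resamples(self):
        # expected width at R=1e3 (averaged over independent draws) is
        # within 5% of the width at R=1e5
        a, va, t, vt = 0.2, 0.02**2, -4e-4, (1e-4) ** 2
        w1 = np.mean(
            [
                np.diff(nie_product(a, va, t, vt, -8.0, R=1_000, seed=s).ci)
                for s in range(10)
            ]
        )
        r2 = nie_product(a, va, t, vt, -8.0, R=100_000, seed=99)
        w2 = r2.ci[1] - r2.ci[0]
        assert abs(w1 - w2) < 0.05 * w2

    def test_sign_identity(self):
        res = nie_product(-0.3, 1e-10, 4e-4, 1e-16, rd_before=-8.0, seed=5)
        assert np.sign(res.nie) == np.sign(-0.3) * np.sign(4e-4)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            nie_product(0.1, -1.0, 1e-4, 1e-9, rd_before=-8.0)


@pytest.fixture(scope="module")
def mediated_fit_inputs(prospective):
    part, adj, outc, truth = prospective
    mediators = [
        n for n, t in zip(adj.names, truth.true_hazard_coefs) if t != 0
    ]
    return part, adj, outc, truth, mediators


class TestDecomposition:
    def test_mediated_preset_percent_recovered(self, mediated_fit_inputs):
        part, adj, outc, truth, mediators = mediated_fit_inputs
        res = decompose_by_group(
            outc["follow_up_years"],
            outc["incident_diabetes"],
            part["hls_total"],
            {"relevant": adj.values[mediators]},
            part,
            CovariateSpec("M2"),
            part["weight"],
            B=300,
            seed=11,
            jackknife=False,
        )[0]
        assert res.ci[0] < truth.true_percent_explained < res.ci[1]
        assert res.percent_explained == pytest.approx(
            percent_explained(res.rd_ref, res.rd_adj)
        )

    def test_null_group_explains_nothing(self, mediated_fit_inputs):
        part, adj, outc, truth, mediators = mediated_fit_inputs
        null_group = [n for n in adj.group_members("energy") if n not in mediators]
        res = decompose_by_group(
            outc["follow_up_years"],
            outc["incident_diabetes"],
            part["hls_total"],
            {"energy_null": adj.values[null_group]},
            part,
            CovariateSpec("M2"),
            part["weight"],
            B=250,
            seed=12,
            jackknife=False,
        )[0]
        assert res.ci[0] < 0 < res.ci[1] or abs(res.percent_explained) < 30

    def test_minimum_bootstrap_enforced(self, mediated_fit_inputs):
        part, adj, outc, _, mediators = mediated_fit_inputs
        with pytest.raises(ValueError, match="200"):
            decompose_by_group(
                outc["follow_up_years"], outc["incident_diabetes"],
                part["hls_total"], {"m": adj.values[mediators]},
                part, CovariateSpec("M2"), part["weight"], B=50,
            )


class TestMediateRelevant:
    def test_consistency_with_group_decomposition(self, mediated_fit_inputs):
        """The paper's own check: summed relative NIEs ~ group percent."""
        part, adj, outc, truth, mediators = mediated_fit_inputs
        med = mediate_relevant(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], adj.values[mediators], part,
            CovariateSpec("M2"), part["weight"], seed=13,
        )
        group = decompose_by_group(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], {"relevant": adj.values[mediators]},
            part, CovariateSpec("M2"), part["weight"],
            B=250, seed=14, jackknife=False,
        )[0]
        report = consistency_check(med, group, tolerance=15.0)
        assert report["consistent"], report

    def test_single_mediator_sum_is_identity(self, mediated_fit_inputs):
        part, adj, outc, truth, mediators = mediated_fit_inputs
        one = mediators[:1]
        med = mediate_relevant(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], adj.values[one], part,
            CovariateSpec("M2"), part["weight"], seed=15,
        )
        group = decompose_by_group(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], {"one": adj.values[one]},
            part, CovariateSpec("M2"), part["weight"],
            B=250, seed=16, jackknife=False,
        )[0]
        report = consistency_check(med, group, tolerance=1e9)
        assert report["sum_relative_percent"] == pytest.approx(
            100.0 * med[0].relative
        )

    def test_mismatched_sets_rejected(self, mediated_fit_inputs):
        part, adj, outc, truth, mediators = mediated_fit_inputs
        med = mediate_relevant(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], adj.values[mediators[:1]], part,
            CovariateSpec("M2"), part["weight"], seed=17,
        )
        group = decompose_by_group(
            outc["follow_up_years"], outc["incident_diabetes"],
            part["hls_total"], {"relevant": adj.values[mediators]},
            part, CovariateSpec("M2"), part["weight"],
            B=250, seed=18, jackknife=False,
        )[0]
        with pytest.raises(ValueError, match="differ"):
            consistency_check(med, group)
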