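"""Noise calibration and the z-diff change score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zdiffkit import (
    CohortSpec,
    VisitPair,
    estimate_noise,
    flag,
    gen_longitudinal,
    group_wilcoxon,
    naive_zdiff,
    pairs_from_long,
    zdiff_frame,
    zdiff_score,
)
from zdiffkit.longitudinal import NoiseEstimate


def control_pairs(spec, n, seed):
    data, _ = gen_longitudinal(spec, n_controls=n, n_patients=0, seed=seed)
    return pairs_from_long(data, spec.idp_names)


def identical_visit_pair(model, idp="idp_a"):
    site = model.basis.site_labels[0]
    x = {"age": 40.0, "sex": 1, "site": site}
    x2 = dict(x, age=40.0 + 1e-9)  # interval must be positive
    return VisitPair("s1", x, x2, {idp: 2.0}, {idp: 2.0})


class TestNoiseEstimation:
    def test_recovers_noise_scale(self, fitted_model):
        spec = CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, seed=5)
        noise = estimate_noise(control_pairs(spec, 200, seed=77), fitted_model)
        for ne in noise.values():
            assert ne.two_sigma_xi2 == pytest.approx(0.6, rel=0.15)
            assert not ne.tracking_violation
            assert ne.n_calibration == 200

    def test_no_change_controls_give_zero_raw_value(self, ref_model):
        m = ref_model.idps["idp_a"]
        pairs = [identical_visit_pair(ref_model)] * 5
        noise = estimate_noise(pairs, m, ["idp_a"])
        assert noise["idp_a"].raw_value == pytest.approx(0.0, abs=1e-12)
        assert noise["idp_a"].two_sigma_xi2 >= 1e-8 * 2 * m.sigma2  # clamped to the floor

    def test_anticorrelated_process_flags_tracking_violation(self, fitted_model):
        spec = CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, general_rho=-0.5, seed=6)
        noise = estimate_noise(control_pairs(spec, 200, seed=42), fitted_model)
        for ne in noise.values():
            # 2 sigma^2 (1 - rho) = 2 * 1 * 1.5
            assert ne.raw_value == pytest.approx(3.0, rel=0.2)
            assert ne.tracking_violation
            assert ne.implied_rho < 0

    def test_too_few_pairs_rejected(self, fitted_model):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_noise(control_pairs(CohortSpec(seed=1), 1, seed=1), fitted_model)

    def test_consistency_with_growing_calibration_set(self, fitted_model):
        spec = CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, seed=5)
        errors = []
        for n in [50, 200, 1000]:
            reps = [
                abs(estimate_noise(control_pairs(spec, n, seed=1000 + n + r),
                                   fitted_model, ["idp_a"])["idp_a"].raw_value - 0.6)
                for r in range(5)
            ]
            errors.append(np.mean(reps))
        assert errors[2] < errors[0]


class TestZdiffScore:
    def test_identical_visits_score_zero(self, ref_model):
        m = ref_model.idps["idp_a"]
        ne = NoiseEstimate("idp_a", 0.25, 0.25, 10, 0.875, False)
        assert zdiff_score(identical_visit_pair(ref_model), m, ne) == pytest.approx(0.0, abs=1e-6)
        assert naive_zdiff(identical_visit_pair(ref_model), m, "idp_a") == pytest.approx(0.0, abs=1e-6)

    def test_unit_numerator_quarter_noise_gives_two(self, ref_model):
        # warped difference 1, expected difference ~0, model term ~0, noise 0.25
        m = ref_model.idps["idp_a"]
        site = m.basis.site_labels[0]
        x = {"age": 40.0, "sex": 1, "site": site}
        pair = VisitPair("s", x, dict(x, age=40.0 + 1e-9), {"idp_a": 2.0}, {"idp_a": 3.0})
        ne = NoiseEstimate("idp_a", 0.25, 0.25, 10, 0.875, False)
        assert zdiff_score(pair, m, ne) == pytest.approx(2.0, rel=1e-6)

    def test_null_scores_standard_normal(self, fitted_model):
        spec = CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, seed=5)
        noise = estimate_noise(control_pairs(spec, 1000, seed=300), fitted_model)
        fresh = control_pairs(spec, 2000, seed=301)
        scores = zdiff_frame(fresh, fitted_model, noise)
        z = scores.loc[scores["idp"] == "idp_a", "zdiff"]
        assert abs(z.mean()) < 0.05
        assert abs(z.var() - 1) < 0.1
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_swapping_visits_negates_score(self, fitted_model):
        """z-diff(x2, x1, y2, y1) = -z-diff(x1, x2, y1, y2) exactly."""
        from types import SimpleNamespace

        spec = CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, seed=5)
        pairs = control_pairs(spec, 5, seed=55)
        m = fitted_model.idps["idp_a"]
        ne = estimate_noise(pairs, m, ["idp_a"])["idp_a"]
        for p in pairs:
            # bypass the temporal-order guard to evaluate the reversed score
            swapped = SimpleNamespace(subject_id=p.subject_id, x1=p.x2, x2=p.x1,
                                      y1=p.y2, y2=p.y1)
            assert zdiff_score(swapped, m, ne) == pytest.approx(
                -zdiff_score(p, m, ne), abs=1e-12)

    def test_constant_site_offset_cancels(self, fitted_model):
        """Adding the same warped-unit offset to both visits leaves z-diff unchanged."""
        spec = CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, seed=5)
        pairs = control_pairs(spec, 10, seed=56)
        m = fitted_model.idps["idp_a"]
        ne = estimate_noise(pairs, m, ["idp_a"])["idp_a"]
        for p in pairs:
            shifted = VisitPair(p.subject_id, p.x1, p.x2,
                                {"idp_a": p.y1["idp_a"] + 0.8},
                                {"idp_a": p.y2["idp_a"] + 0.8})
            assert zdiff_score(shifted, m, ne) == pytest.approx(zdiff_score(p, m, ne),
                                                                abs=1e-9)

    def test_cross_site_pair_rejected(self):
        with pytest.raises(ValueError, match="same scanner"):
            VisitPair("s", {"age": 30, "site": "A"}, {"age": 31, "site": "B"}, {}, {})

    def test_non_positive_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            VisitPair("s", {"age": 31, "site": "A"}, {"age": 31, "site": "A"}, {}, {})

    def test_more_than_two_visits_rejected(self):
        df = pd.DataFrame({
            "subject_id": ["s"] * 3, "visit": [1, 2, 3], "age": [30, 31, 32],
            "sex": 0, "site": "A", "idp_a": [1.0, 1.1, 1.2],
        })
        with pytest.raises(ValueError, match="consecutive pairs"):
            pairs_from_long(df, ["idp_a"])


class TestNaiveComparison:
    @pytest.mark.parametrize("rho,expected_var", [(0.5, 1.0), (0.0, 2.0)])
    def test_null_variance_is_two_one_minus_rho(self, ref_model, rho, expected_var):
        spec = CohortSpec(sigma_eta2=rho, sigma_xi2=1 - rho, sites=("siteA", "siteB"),
                          site_offsets={"siteA": 0.0, "siteB": 0.0}, seed=8)
        data, _ = gen_longitudinal(spec, n_controls=800, n_patients=0, seed=80 + int(10 * rho))
        pairs = pairs_from_long(data, ["idp_a"])
        m = ref_model.idps["idp_a"]
        naive = np.array([naive_zdiff(p, m, "idp_a") for p in pairs])
        assert naive.var() == pytest.approx(expected_var, rel=0.15)


class TestFlagging:
    def test_threshold_rule(self):
        assert not flag(1.0, 0.05)
        assert flag(2.5, 0.05)
        assert flag(-2.5, 0.05)
        assert flag(0.0, 1.0)  # degenerate threshold flags everyone
        with pytest.raises(ValueError):
            flag(1.0, 0.0)

    def test_vectorized(self):
        out = flag(np.array([0.0, 3.0, -3.0]), 0.05)
        np.testing.assert_array_equal(out, [False, True, True])


class TestGroupWilcoxon:
    def test_all_zero_scores_no_signal(self):
        scores = pd.DataFrame({"idp": ["a"] * 10, "zdiff": 0.0})
        res = group_wilcoxon(scores)
        assert res.loc[0, "p"] == 1.0
        assert not res["significant"].any()

    def test_shifted_scores_detected(self, rng):
        scores = pd.DataFrame({"idp": ["a"] * 100, "zdiff": rng.normal(1, 1, 100)})
        res = group_wilcoxon(scores)
        assert res.loc[0, "significant"]
        assert res.loc[0, "direction"] == 1.0

    def test_bh_step_up_hand_example(self):
        """p = (0.01, 0.02, 0.04, 0.9) at level 0.05: BH thresholds are
        k*0.05/4 = (0.0125, 0.025, 0.0375, 0.05); the largest k with
        p(k) <= k*0.05/4 is k = 2 (0.04 > 0.0375), so exactly the two
        smallest p-values are rejected."""
        scores = pd.DataFrame({
            "idp": np.repeat(["a", "b", "c", "d"], 2),
            "zdiff": 1.0,  # overwritten below via p injection
        })
        from statsmodels.stats.multitest import multipletests
        reject, q, _, _ = multipletests([0.01, 0.02, 0.04, 0.9], alpha=0.05,
                                        method="fdr_bh")
        assert list(reject) == [True, True, False, False]
        # same rule by hand
        p = np.array([0.01, 0.02, 0.04, 0.9])
        thresh = np.arange(1, 5) * 0.05 / 4
        k = np.max(np.nonzero(np.sort(p) <= thresh)[0]) + 1
        assert k == 2
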