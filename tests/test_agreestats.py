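"""Repeatability, Bland-Altman and trending statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eelvkit import agreestats
from eelvkit.errors import DataError, InsufficientDataError
from eelvkit.simkit import generate_paired_series


def pair_frame(pairs):
    return pd.DataFrame(
        {"value_1": [p[0] for p in pairs], "value_2": [p[1] for p in pairs]}
    )


class TestRepeatability:
    def test_closed_form_single_pair(self):
        r = agreestats.repeatability(pair_frame([(490.0, 510.0)]), n_boot=0)
        assert r.cv_pct[0] == pytest.approx(2.828, abs=0.001)
        assert r.precision_pct[0] == pytest.approx(5.657, abs=0.001)
        assert r.lsc_pct[0] == pytest.approx(7.840, abs=0.001)
        assert r.ci95_precision_pct is None  # a single pair has no CI

    def test_identical_replicates_are_exactly_repeatable(self):
        r = agreestats.repeatability(pair_frame([(500.0, 500.0)] * 4),
                                     n_boot=100, seed=0)
        assert r.median_cv_pct == r.median_precision_pct == r.median_lsc_pct == 0.0

    def test_lsc_precision_ratio_is_structural(self, rng):
        values = rng.uniform(300, 1100, size=(20, 2))
        r = agreestats.repeatability(pair_frame(values), n_boot=0)
        np.testing.assert_allclose(
            r.lsc_pct / r.precision_pct, agreestats.LSC_OVER_PRECISION, rtol=1e-12
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DataError):
            agreestats.repeatability(pair_frame([(-5.0, 3.0)]), n_boot=0)

    def test_bca_interval_contains_point_estimate_and_is_stable(self, rng):
        values = rng.uniform(300, 1100, size=(27, 2))
        values[:, 1] = values[:, 0] * (1 + rng.normal(0, 0.04, 27))
        reps = pair_frame(values)
        r_small = agreestats.repeatability(reps, n_boot=2_000, seed=5)
        r_big = agreestats.repeatability(reps, n_boot=10_000, seed=5)
        lo, hi = r_big.ci95_precision_pct
        assert lo <= r_big.median_precision_pct <= hi
        # bootstrap stability: 2k vs 10k replicates within one point
        np.testing.assert_allclose(r_small.ci95_precision_pct,
                                   r_big.ci95_precision_pct, atol=1.0)
        np.testing.assert_allclose(r_small.ci95_lsc_pct,
                                   r_big.ci95_lsc_pct, atol=1.0)


class TestBlandAltman:
    def test_identity_methods_agree_perfectly(self):
        ref = np.linspace(300, 1100, 12)
        s = pd.DataFrame({"subject": [0, 1] * 6, "value_test": ref,
                          "value_ref": ref})
        r = agreestats.bland_altman(s, n_sim=500, seed=0)
        assert r.mean_bias == pytest.approx(0.0, abs=1e-9)
        assert r.bias_slope == pytest.approx(0.0, abs=1e-12)
        assert r.percentage_error_pct == pytest.approx(0.0, abs=1e-9)
        assert r.pi95_halfwidth == pytest.approx(0.0, abs=1e-6)

    def test_constructed_percentage_error(self):
        # bias alternates +/-10 around a reference mean of 100
        s = pd.DataFrame(
            {
                "subject": [0, 0, 1, 1] * 3,
                "value_ref": [100.0] * 12 + np.tile([-1, 1], 6) * 1e-9,
                "value_test": [110.0, 90.0] * 6,
            }
        )
        r = agreestats.bland_altman(s, n_sim=0)
        sd = np.std([10.0, -10.0] * 6, ddof=1)
        assert r.sd_bias == pytest.approx(sd, rel=1e-6)
        assert r.percentage_error_pct == pytest.approx(2 * sd / 100.0 * 100, rel=1e-6)

    def test_recovers_generating_line(self):
        s = generate_paired_series(seed=0)
        r = agreestats.bland_altman(s, n_sim=0)
        assert r.conversion_slope == pytest.approx(0.92, abs=0.05)
        assert r.conversion_intercept == pytest.approx(36.0, abs=25.0)

    def test_single_subject_falls_back_with_warning(self):
        s = generate_paired_series(n_subjects=1, n_obs=10, seed=1)
        with pytest.warns(UserWarning, match="single subject"):
            r = agreestats.bland_altman(s, n_sim=200, seed=0)
        assert r.pi95_halfwidth is not None

    def test_constant_reference_is_rank_deficient(self):
        s = pd.DataFrame({"subject": [0, 1] * 3, "value_test": range(6),
                          "value_ref": [500.0] * 6})
        with pytest.raises(np.linalg.LinAlgError):
            agreestats.bland_altman(s, n_sim=0)


def delta_frame(d_test, d_ref):
    return pd.DataFrame({"d_test": d_test, "d_ref": d_ref})


class TestFourQuadrant:
    def test_all_concordant(self):
        s = pd.DataFrame(
            {
                "subject": [0] * 3 + [1] * 3,
                "order": [0, 1, 2] * 2,
                "value_test": [400, 600, 500, 300, 450, 350],
                "value_ref": [420, 640, 510, 310, 470, 330],
            }
        )
        deltas, rate, ci = agreestats.four_quadrant(s)
        assert len(deltas) == 4
        assert rate == 100.0
        assert ci[0] < 100.0 <= ci[1]

    def test_half_discordant(self):
        s = pd.DataFrame(
            {
                "subject": [0] * 5,
                "order": range(5),
                "value_test": [100, 200, 100, 200, 100],
                "value_ref": [100, 200, 300, 400, 500],
            }
        )
        _, rate, _ = agreestats.four_quadrant(s)
        assert rate == 50.0

    def test_invariant_to_positive_rescaling(self):
        s = generate_paired_series(seed=2)
        _, rate1, _ = agreestats.four_quadrant(s)
        s2 = s.assign(value_test=s.value_test * 3.7, value_ref=s.value_ref * 0.2)
        _, rate2, _ = agreestats.four_quadrant(s2)
        assert rate1 == rate2

    def test_no_consecutive_pairs(self):
        s = pd.DataFrame({"subject": [0, 1], "order": [0, 0],
                          "value_test": [1.0, 2.0], "value_ref": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            agreestats.four_quadrant(s)


class TestWilson:
    def test_perfect_proportion(self):
        lo, hi = agreestats.wilson_ci(25, 25)
        assert lo == pytest.approx(100 * 25 / (25 + 1.96**2), abs=0.05)
        assert hi == 100.0

    def test_zero_proportion_mirrors(self):
        lo, hi = agreestats.wilson_ci(0, 25)
        assert lo == 0.0
        assert hi == pytest.approx(100 - 86.7, abs=0.1)

    def test_midpoint_contains_half(self):
        lo, hi = agreestats.wilson_ci(5, 10)
        assert lo < 50.0 < hi

    def test_zero_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            agreestats.wilson_ci(0, 0)


class TestPolar:
    def test_identity_deltas_have_zero_bias(self):
        bias, sd, loa = agreestats.polar_trend(
            delta_frame([10, 20, -15, 5.0], [10, 20, -15, 5.0])
        )
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert loa == pytest.approx(0.0, abs=1e-12)

    def test_constructed_rotation_recovered(self):
        radius = np.array([10.0, 20.0, 15.0, 5.0])
        ang = np.radians(45.0 + 10.0)
        bias, _, _ = agreestats.polar_trend(
            delta_frame(radius * np.sin(ang), radius * np.cos(ang))
        )
        assert bias == pytest.approx(10.0, abs=0.1)

    def test_opposite_deltas_are_90_degrees_off(self):
        for d in (12.0, -12.0):
            bias, _, _ = agreestats.polar_trend(delta_frame([d], [-d]))
            assert abs(bias) == pytest.approx(90.0)

    def test_joint_decrease_reflected_to_identity(self):
        bias, _, _ = agreestats.polar_trend(delta_frame([-30.0], [-30.0]))
        assert bias == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-25, 25))
    @settings(max_examples=50, deadline=None)
    def test_rotation_covariance(self, phi):
        """Rotating all (first-quadrant) delta pairs by phi shifts the
        angular bias by phi."""
        radius = np.array([10.0, 14.0, 20.0])
        base = np.radians([40.0, 45.0, 50.0])
        b0, _, _ = agreestats.polar_trend(
            delta_frame(radius * np.sin(base), radius * np.cos(base))
        )
        b1, _, _ = agreestats.polar_trend(
            delta_frame(radius * np.sin(base + np.radians(phi)),
                        radius * np.cos(base + np.radians(phi)))
        )
        assert b1 - b0 == pytest.approx(phi, abs=1e-9)

    def test_zero_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            bias, _, _ = agreestats.polar_trend(
                delta_frame([0.0, 10.0], [0.0, 10.0])
            )
        assert bias == 0.0
        with pytest.raises(InsufficientDataError), pytest.warns(UserWarning):
            agreestats.polar_trend(delta_frame([0.0], [0.0]))

    def test_percentile_loa_option(self):
        rng = np.random.default_rng(0)
        ang = np.radians(45.0 + rng.normal(0, 10, 200))
        bias, sd, loa_sd = agreestats.polar_trend(
            delta_frame(10 * np.sin(ang), 10 * np.cos(ang))
        )
        _, _, loa_pct = agreestats.polar_trend(
            delta_frame(10 * np.sin(ang), 10 * np.cos(ang)), method="percentile"
        )
        assert loa_sd == pytest.approx(1.96 * sd, rel=1e-4)
        assert loa_pct == pytest.approx(loa_sd, rel=0.2)
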