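"""Derivative transform, peak calling, boundary calibration and the
classification/retest logic."""

import numpy as np
import pytest

from fxscreen import (
    BoundaryCalibration,
    MeltCurve,
    NoiseModel,
    TmResponseModel,
    analyze_curve,
    calibrate_boundary,
    call_peaks,
    classify,
    neg_first_derivative,
    screen_with_retest,
    simulate_melt_curve,
)
from fxscreen.melt_screen import CalibrationError
from fxscreen.synthetic_signals import melt_temperature_grid

from conftest import female, male


def _curve(F, **kw):
    return MeltCurve("t", melt_temperature_grid(), np.asarray(F, float), **kw)


class TestNegFirstDerivative:
    def test_constant_fluorescence_gives_zero(self):
        prof = neg_first_derivative(_curve(np.full(61, 500.0)))
        assert np.allclose(prof.neg_deriv, 0.0)

    def test_linear_decrease_gives_constant_slope(self):
        T = melt_temperature_grid()
        prof = neg_first_derivative(_curve(1000.0 - 2.0 * T))
        # interior points; the smoothing window's edge padding perturbs the
        # first/last few values of a non-periodic series
        assert np.allclose(prof.neg_deriv[4:-4], 2.0, atol=1e-9)
        prof_raw = neg_first_derivative(_curve(1000.0 - 2.0 * T), smoothing=None)
        assert np.allclose(prof_raw.neg_deriv, 2.0, atol=1e-9)

    def test_sigmoid_peak_location_matches_analytic(self):
        """Argmax of -dF/dT for a noiseless sigmoid lands within half a
        grid step of the analytic transition centre."""
        T = melt_temperature_grid()
        F = 100 + 800 / (1 + np.exp((T - 85.0) / 0.8))
        prof = call_peaks(neg_first_derivative(_curve(F)))
        assert prof.last_peak_tm == pytest.approx(85.0, abs=0.25)

    def test_non_uniform_grid_rejected(self):
        T = np.concatenate([np.arange(65, 80, 0.5), np.arange(80, 95, 0.7)])
        with pytest.raises(ValueError, match="uniform"):
            neg_first_derivative(MeltCurve("t", T, np.zeros_like(T)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            neg_first_derivative(MeltCurve("t", np.arange(5.0), np.zeros(5)))


class TestCallPeaks:
    def test_two_transition_female_curve(self):
        prof = analyze_curve(simulate_melt_curve(female(29, 128)))
        assert len(prof.peaks) == 2
        assert prof.last_peak_tm == max(p[0] for p in prof.peaks)
        assert prof.last_peak_tm > 92.0

    def test_flat_profile_flagged(self):
        prof = analyze_curve(simulate_melt_curve(male(30), prep=(0.5, 2.0)))
        assert prof.qc_flag == "flat"
        assert prof.last_peak_tm is None

    def test_single_transition_single_peak(self):
        prof = analyze_curve(simulate_melt_curve(male(30)))
        assert len(prof.peaks) == 1
        assert prof.last_peak_tm == pytest.approx(prof.peaks[0][0])


class TestCalibrateBoundary:
    def _controls(self, noise=None, seed=None):
        reps = (46, 48, 52, 54)
        out = []
        for i, n in enumerate(reps):
            out.append(
                simulate_melt_curve(
                    male(n, sample_id=f"ctrl{n}"),
                    noise=noise,
                    seed=None if seed is None else seed + i,
                )
            )
        return out

    def test_noiseless_band_matches_analytic_tms(self, tm_model):
        cal = calibrate_boundary(self._controls())
        assert cal.lower_tm == pytest.approx(tm_model.tm(46), abs=0.1)
        assert cal.upper_tm == pytest.approx(tm_model.tm(54), abs=0.1)

    def test_requires_four_controls(self):
        with pytest.raises(CalibrationError):
            calibrate_boundary(self._controls()[:3])

    def test_flat_control_raises_naming_it(self):
        curves = self._controls()
        curves[1] = simulate_melt_curve(male(48, sample_id="ctrl48"), prep=(0.5, 2.0))
        with pytest.raises(CalibrationError, match="ctrl48"):
            calibrate_boundary(curves)

    def test_jittered_controls_keep_positive_band_width(self):
        for seed in range(100):
            cal = calibrate_boundary(self._controls(noise=NoiseModel(), seed=1000 + 7 * seed))
            assert cal.upper_tm - cal.lower_tm > 0


class TestClassify:
    CAL = BoundaryCalibration(lower_tm=89.9, upper_tm=90.6, margin=0.3)

    @pytest.mark.parametrize(
        "tm, expected",
        [
            (90.6, "indeterminate"),  # exactly on the upper boundary
            (90.6 + 0.3 + 1e-9, "expanded"),
            (89.9 - 0.3 - 1e-9, "non_expanded"),
            (90.2, "indeterminate"),
        ],
    )
    def test_band_rule(self, tm, expected):
        assert classify(tm, self.CAL) == expected

    def test_expanded_male_against_default_calibration(self, tm_model):
        cal = calibrate_boundary(
            [simulate_melt_curve(male(n)) for n in (46, 48, 52, 54)]
        )
        prof = analyze_curve(simulate_melt_curve(male(110)))
        assert classify(prof.last_peak_tm, cal) == "expanded"

    def test_wider_margin_only_moves_calls_to_indeterminate(self):
        """Raising the margin can only turn decided calls indeterminate,
        never flip expanded to non-expanded or vice versa."""
        rng = np.random.default_rng(0)
        tms = rng.uniform(85.0, 94.0, size=200)
        for m_small, m_big in [(0.0, 0.3), (0.3, 1.0), (1.0, 3.0)]:
            a = BoundaryCalibration(89.9, 90.6, m_small)
            b = BoundaryCalibration(89.9, 90.6, m_big)
            for tm in tms:
                c1, c2 = classify(tm, a), classify(tm, b)
                if c1 != c2:
                    assert c2 == "indeterminate"


class TestRetestPolicy:
    def _cal(self):
        return calibrate_boundary(
            [simulate_melt_curve(male(n)) for n in (46, 48, 52, 54)]
        )

    def test_low_dna_sample_recovered_at_higher_volume(self):
        """Flat at 2 and 5 uL, analyzable at 7.5 uL: two retests, then a
        non-expanded call (the low-concentration rescue narrative)."""
        cal = self._cal()
        src = lambda vol: simulate_melt_curve(male(28), prep=(0.4, vol))
        call = screen_with_retest(src, cal)
        assert call.call == "non_expanded"
        assert call.retest_count == 2

    def test_good_sample_needs_no_retest(self):
        cal = self._cal()
        src = lambda vol: simulate_melt_curve(male(30), prep=(25.0, vol))
        call = screen_with_retest(src, cal)
        assert call.call == "non_expanded"
        assert call.retest_count == 0

    def test_all_volumes_flat_is_qc_fail(self):
        cal = self._cal()
        src = lambda vol: simulate_melt_curve(male(30), prep=(0.05, vol))
        call = screen_with_retest(src, cal)
        assert call.call == "qc_fail"
        assert call.tm is None


def test_adding_normal_allele_never_unexpands_a_call():
    """Sex neutrality: adding a normal allele to an expanded genotype never
    produces a non-expanded call (noiseless, default parameters).  When the
    normal transition merges with a barely-expanded one the call may become
    indeterminate — which still reflexes to sizing — but never negative."""
    cal = calibrate_boundary(
        [simulate_melt_curve(male(n)) for n in (46, 48, 52, 54)]
    )
    for exp in (76, 110, 200, 545):
        for nl in (20, 30, 44):
            solo = analyze_curve(simulate_melt_curve(male(exp)))
            duo = analyze_curve(simulate_melt_curve(female(nl, exp)))
            assert classify(solo.last_peak_tm, cal) == "expanded"
            assert classify(duo.last_peak_tm, cal) != "non_expanded"
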