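"""Generator physics: melt-transition superposition, ladder construction,
regular-PCR sizes, and seeded determinism."""

import numpy as np
import pytest

from fxscreen import (
    NoiseModel,
    TmResponseModel,
    simulate_melt_curve,
    simulate_regular_trace,
    simulate_tppcr_trace,
)
from fxscreen.melt_screen import analyze_curve
from fxscreen.synthetic_signals import (
    PERIOD_BP,
    REGULAR_FLANK_BP,
    TP_FLANK_BP,
    melt_temperature_grid,
)

from conftest import female, male


def test_default_grid_is_61_half_degree_steps():
    T = melt_temperature_grid()
    assert len(T) == 61
    assert T[0] == 65.0 and T[-1] == 95.0
    assert np.allclose(np.diff(T), 0.5)


def test_tm_response_is_strictly_increasing(tm_model):
    n = np.arange(1, 1000)
    tms = tm_model.tm(n)
    assert np.all(np.diff(tms) > 0)
    assert tms[-1] < tm_model.tm_sat


def test_short_allele_anchor_tm(tm_model):
    """An 8-repeat allele melts at the unusually low anchor of ~83.4 degC."""
    prof = analyze_curve(simulate_melt_curve(male(8)))
    assert prof.last_peak_tm == pytest.approx(83.42, abs=0.25)


def test_jitter_sd_is_monotone_in_concentration():
    nm = NoiseModel()
    concs = [50.0, 25.0, 15.0, 8.0, 2.0]
    sds = [nm.tm_jitter_sd(c) for c in concs]
    assert sds == sorted(sds)
    assert nm.tm_jitter_sd(30.0) == pytest.approx(0.11)
    assert nm.tm_jitter_sd(8.0) == pytest.approx(0.53)


def test_amplitude_scale_monotone_in_mass():
    nm = NoiseModel()
    masses = [0.5, 2.0, 10.0, 50.0, 500.0]
    scales = [nm.amplitude_scale(m) for m in masses]
    assert scales == sorted(scales)
    assert all(0 <= s < 1 for s in scales)


def test_stochastic_simulation_requires_seed():
    with pytest.raises(ValueError, match="seed"):
        simulate_melt_curve(male(30), noise=NoiseModel(), seed=None)


def test_identical_seed_gives_bit_identical_curves():
    a = simulate_melt_curve(male(110), noise=NoiseModel(), seed=1234)
    b = simulate_melt_curve(male(110), noise=NoiseModel(), seed=1234)
    c = simulate_melt_curve(male(110), noise=NoiseModel(), seed=1235)
    assert np.array_equal(a.fluorescence, b.fluorescence)
    assert not np.array_equal(a.fluorescence, c.fluorescence)


def test_female_superposition_closure():
    """A noiseless female curve equals the mean of the two corresponding
    male single-allele curves exactly (shared baseline, half weight each)."""
    f = simulate_melt_curve(female(29, 128))
    m1 = simulate_melt_curve(male(29))
    m2 = simulate_melt_curve(male(128))
    baseline = 100.0
    expected = baseline + 0.5 * ((m1.fluorescence - baseline) + (m2.fluorescence - baseline))
    assert np.allclose(f.fluorescence, expected, atol=1e-9)


def test_identical_alleles_change_amplitude_only():
    hom = simulate_melt_curve(female(29, 29))
    hemi = simulate_melt_curve(male(29))
    p_hom, p_hemi = analyze_curve(hom), analyze_curve(hemi)
    assert p_hom.last_peak_tm == pytest.approx(p_hemi.last_peak_tm, abs=1e-6)
    assert len(p_hom.peaks) == len(p_hemi.peaks) == 1


def test_downstream_tm_strictly_increasing_in_repeat_count(tm_model):
    """Estimated last-peak Tm follows the analytic ordering for noiseless
    single-allele curves (spacing chosen above the estimator resolution)."""
    ns = [5, 10, 20, 30, 54, 76, 110, 200, 545]
    tms = [
        analyze_curve(simulate_melt_curve(male(n))).last_peak_tm for n in ns
    ]
    assert all(b > a for a, b in zip(tms, tms[1:]))
    for n, est in zip(ns, tms):
        assert est == pytest.approx(tm_model.tm(n), abs=0.25)


def test_low_template_profile_is_flat():
    """Below the flat threshold the -dF/dT maximum stays under the floor."""
    curve = simulate_melt_curve(male(30), prep=(1.0, 2.0))  # 2 ng template
    prof = analyze_curve(curve)
    assert prof.qc_flag == "flat"
    assert prof.peaks == []


class TestTPPCRLadder:
    def test_single_allele_peak_counts(self):
        from fxscreen.ce_sizing import _ladder_peaks

        for n in [1, 5, 36, 120, 250]:
            trace = simulate_tppcr_trace(male(n))
            pos, _ = _ladder_peaks(trace, peak_floor=0.005)
            assert len(pos) == n
            assert pos[0] == 1 and pos[-1] == n

    def test_ladder_positions_on_3bp_register(self):
        trace = simulate_tppcr_trace(male(10))
        from fxscreen.ce_sizing import _ladder_peaks

        pos, _ = _ladder_peaks(trace, peak_floor=0.005)
        assert np.array_equal(pos, np.arange(1, 11))

    def test_full_mutation_extends_past_200(self):
        trace = simulate_tppcr_trace(female(32, 423))
        from fxscreen.ce_sizing import _ladder_peaks

        pos, amp = _ladder_peaks(trace, peak_floor=0.005)
        assert pos[-1] >= 200
        # the short allele contributes a step drop at 32
        i = list(pos).index(32)
        assert amp[i + 1] <= 0.5 * amp[i]

    def test_mosaic_component_has_partial_amplitude(self):
        trace = simulate_tppcr_trace(female(29, 130, mosaic=[(250, 0.2)]))
        from fxscreen.ce_sizing import _ladder_peaks

        pos, amp = _ladder_peaks(trace, peak_floor=0.005)
        assert pos[-1] >= 200

    def test_tppcr_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_tppcr_trace(male(30), noise_sd=5.0)


class TestRegularPCR:
    def test_closed_form_peak_position(self):
        """28 repeats -> 209 + 84 - 12 = 281 bp."""
        trace = simulate_regular_trace(male(28))
        peak_bp = trace.sizes[np.argmax(trace.intensities)]
        assert peak_bp == pytest.approx(281.0, abs=0.5)

    def test_full_mutation_dropout(self):
        trace = simulate_regular_trace(male(545))
        assert trace.intensities.max() == 0.0

    def test_female_with_fm_allele_keeps_normal_peak_only(self):
        trace = simulate_regular_trace(female(29, 288))
        from scipy.signal import find_peaks

        idx, _ = find_peaks(trace.intensities, height=0.05 * trace.intensities.max())
        assert len(idx) == 1
        assert trace.sizes[idx[0]] == pytest.approx(
            REGULAR_FLANK_BP + PERIOD_BP * 29 - 12, abs=0.5
        )
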