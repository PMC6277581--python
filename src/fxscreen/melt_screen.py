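"""First-tier melt-curve screening: -dF/dT transform, peak calling,
boundary calibration against the intermediate/gray-zone controls, and
expansion classification with the low-template retest policy.

The decision statistic is the **last-peak Tm**: the temperature of the
highest-temperature -dF/dT peak before the signal falls to baseline.  It
tracks the largest repeat species in the reaction, which is what makes the
screen sex-neutral — a normal allele in a carrier female adds an earlier
peak but never displaces the last one.  Four genomic controls spanning the
46-54-repeat intermediate/gray zone are melted in every run; their
last-peak Tms bracket the decision band.  Samples melting clearly above
the band are expansion-positive, clearly below are negative, and anything
inside the guarded band is indeterminate and reflexed to CE sizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .synthetic_signals import MeltCurve

__all__ = [
    "MeltPeakProfile",
    "BoundaryCalibration",
    "ScreenCall",
    "CalibrationError",
    "neg_first_derivative",
    "call_peaks",
    "calibrate_boundary",
    "classify",
    "screen_with_retest",
    "analyze_curve",
    "DEFAULT_SMOOTHING",
    "DEFAULT_PROMINENCE_FRACTION",
    "DEFAULT_ABSOLUTE_FLOOR",
    "DEFAULT_MIN_SEPARATION",
    "DEFAULT_MARGIN",
    "DEFAULT_VOLUMES",
]

# Savitzky-Golay smoothing of the fluorescence series before differencing:
# 7 points (3 degC) of quadratic local fit suppress acquisition noise
# without flattening a 0.8 degC-wide transition sampled at 0.5 degC.
DEFAULT_SMOOTHING: tuple[int, int] = (7, 2)
#: peak prominence floor as a fraction of the profile's maximum -dF/dT
DEFAULT_PROMINENCE_FRACTION = 0.10
#: absolute -dF/dT floor (signal/degC); peaks below it are baseline noise.
#: Under the default amplitude law this puts the flat/analyzable template
#: mass cutoff at ~2.5 ng.
DEFAULT_ABSOLUTE_FLOOR = 60.0
#: minimum separation between called peaks (degC)
DEFAULT_MIN_SEPARATION = 1.0
#: guard margin (degC) beyond the control Tm extremes required to call a
#: sample expanded/non-expanded rather than indeterminate
DEFAULT_MARGIN = 0.3
#: template volumes (uL) tried in order by the retest policy
DEFAULT_VOLUMES: tuple[float, ...] = (2.0, 5.0, 7.5)


class CalibrationError(RuntimeError):
    """Raised when the IM/GZ boundary controls cannot calibrate a run."""


@dataclass
class MeltPeakProfile:
    """-dF/dT profile with called peaks and the last-peak Tm."""

    sample_id: str
    temperatures: np.ndarray
    neg_deriv: np.ndarray
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    #: (Tm degC, height, prominence) per called peak, ascending Tm
    last_peak_tm: float | None = None
    qc_flag: str = "ok"  # "ok" | "flat" | "noisy"
    #: unsmoothed derivative, used for sub-grid Tm refinement (smoothing
    #: biases the vertex near the top of the acquisition ramp)
    neg_deriv_raw: np.ndarray | None = None


@dataclass(frozen=True)
class BoundaryCalibration:
    """Decision band from the four IM/GZ (46-54 repeat) control wells."""

    lower_tm: float
    upper_tm: float
    margin: float = DEFAULT_MARGIN
    control_tms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.lower_tm > self.upper_tm:
            raise ValueError("lower_tm must not exceed upper_tm")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


@dataclass
class ScreenCall:
    """Per-sample first-tier outcome."""

    sample_id: str
    call: str  # "expanded" | "non_expanded" | "indeterminate" | "qc_fail"
    tm: float | None = None
    retest_count: int = 0
    qc_flag: str = "ok"


def neg_first_derivative(
    curve: MeltCurve,
    smoothing: tuple[int, int] | None = DEFAULT_SMOOTHING,
) -> MeltPeakProfile:
    """Transform a melt curve to its -dF/dT profile (peaks not yet called).

    Fluorescence is optionally smoothed by a moving-window least-squares
    polynomial (Savitzky-Golay) before central differencing on the grid;
    endpoints use one-sided differences.  The derivative is reported at
    the acquisition grid points.

    Raises
    ------
    ValueError
        For a non-uniform grid, fewer than 7 points, or a smoothing
        window longer than the series.
    """
    T, F = curve.temperatures, curve.fluorescence
    if len(T) < 7:
        raise ValueError("melt curve needs at least 7 grid points")
    steps = np.diff(T)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise ValueError("melt temperature grid must be uniform")
    raw = -np.gradient(F, T)
    if smoothing is not None:
        window, order = smoothing
        if window > len(T):
            raise ValueError("smoothing window exceeds number of grid points")
        # 'nearest' edge padding: the default polynomial edge fit distorts
        # transitions melting near the top of the acquisition ramp
        F = savgol_filter(F, window, order, mode="nearest")
    neg = -np.gradient(F, T)
    return MeltPeakProfile(curve.sample_id, T.copy(), neg, neg_deriv_raw=raw)


def _parabolic_refine(T: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid vertex of the parabola through (i-1, i, i+1); (Tm, height)."""
    if i <= 0 or i >= len(y) - 1:
        return float(T[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(T[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    step = T[1] - T[0]
    tm = float(T[i] + delta * step)
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return tm, height


def call_peaks(
    profile: MeltPeakProfile,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    absolute_floor: float = DEFAULT_ABSOLUTE_FLOOR,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> MeltPeakProfile:
    """Call -dF/dT peaks and the last-peak Tm on a derivative profile.

    Local maxima must exceed both the relative prominence floor (a
    fraction of the profile maximum) and the absolute floor, and be
    separated by at least ``min_separation``.  The last-peak Tm is the
    highest-temperature qualifying peak, refined to sub-grid resolution by
    3-point parabolic interpolation.  With no qualifying peak the profile
    is flagged ``flat``.
    """
    T, y = profile.temperatures, profile.neg_deriv
    step = T[1] - T[0]
    rel_floor = prominence_fraction * float(y.max(initial=0.0))
    height_floor = max(rel_floor, absolute_floor)
    distance = max(1, int(round(min_separation / step)))
    # pad with baseline zeros so the prominence of a peak near the end of
    # the acquisition window is measured against baseline, not against the
    # truncated (still elevated) edge of the ramp.  The absolute floor
    # separates real transitions from flat/low-template profiles and so
    # applies to peak height; prominence is gated only relatively, because
    # the fat sech^2 tails of neighbouring transitions limit valley depth.
    padded = np.concatenate(([0.0], y, [0.0]))
    idx, _ = find_peaks(padded, height=height_floor, prominence=rel_floor,
                        distance=distance)
    idx = idx - 1
    # refine on the raw derivative when available: re-centre on the local
    # raw maximum within one grid step of the smoothed peak
    y_ref = profile.neg_deriv_raw if profile.neg_deriv_raw is not None else y
    peaks = []
    for i in idx:
        i = int(i)
        if y_ref is not y:
            lo, hi = max(0, i - 1), min(len(y_ref), i + 2)
            i = lo + int(np.argmax(y_ref[lo:hi]))
        tm, height = _parabolic_refine(T, y_ref, i)
        prom = float(y[int(np.clip(i, 0, len(y) - 1))] - max(y.min(), 0.0))
        peaks.append((tm, height, prom))
    peaks.sort(key=lambda p: p[0])
    out = replace_profile(profile, peaks=peaks)
    if not peaks:
        out.qc_flag = "flat"
        out.last_peak_tm = None
        return out
    out.last_peak_tm = peaks[-1][0]
    # baseline-noise check: signal off-peak should be quiet relative to the peak
    off_peak = np.ones_like(y, dtype=bool)
    for tm, _, _ in peaks:
        off_peak &= np.abs(T - tm) > 3.0
    if off_peak.any() and np.median(np.abs(y[off_peak])) > 0.25 * y.max():
        out.qc_flag = "noisy"
    else:
        out.qc_flag = "ok"
    return out


def replace_profile(profile: MeltPeakProfile, **kw) -> MeltPeakProfile:
    return MeltPeakProfile(
        sample_id=profile.sample_id,
        temperatures=profile.temperatures,
        neg_deriv=profile.neg_deriv,
        peaks=kw.get("peaks", list(profile.peaks)),
        last_peak_tm=kw.get("last_peak_tm", profile.last_peak_tm),
        qc_flag=kw.get("qc_flag", profile.qc_flag),
        neg_deriv_raw=profile.neg_deriv_raw,
    )


def analyze_curve(
    curve: MeltCurve,
    smoothing: tuple[int, int] | None = DEFAULT_SMOOTHING,
    **peak_kwargs,
) -> MeltPeakProfile:
    """Convenience: derivative transform followed by peak calling."""
    return call_peaks(neg_first_derivative(curve, smoothing), **peak_kwargs)


def calibrate_boundary(
    control_curves: Sequence[MeltCurve],
    margin: float = DEFAULT_MARGIN,
    smoothing: tuple[int, int] | None = DEFAULT_SMOOTHING,
) -> BoundaryCalibration:
    """Calibrate the IM/GZ decision band from the four boundary controls.

    The lower and upper band edges are the minimum and maximum last-peak
    Tm over the four 46-54-repeat control wells of the same run.

    Raises
    ------
    CalibrationError
        If fewer than four controls are supplied or any control profile
        fails QC (no callable peak).
    """
    if len(control_curves) < 4:
        raise CalibrationError(
            f"need all four IM/GZ boundary controls, got {len(control_curves)}"
        )
    tms = []
    for curve in control_curves:
        prof = analyze_curve(curve, smoothing)
        if prof.qc_flag != "ok" or prof.last_peak_tm is None:
            raise CalibrationError(
                f"control {curve.sample_id!r} failed QC ({prof.qc_flag})"
            )
        tms.append(prof.last_peak_tm)
    return BoundaryCalibration(
        lower_tm=min(tms), upper_tm=max(tms), margin=margin, control_tms=tuple(tms)
    )


def classify(tm: float, cal: BoundaryCalibration) -> str:
    """Classify a last-peak Tm against the calibrated IM/GZ band.

    ``expanded`` strictly above ``upper_tm + margin``, ``non_expanded``
    strictly below ``lower_tm - margin``, otherwise ``indeterminate``
    (reflexed to CE sizing downstream).
    """
    if not np.isfinite(tm):
        raise ValueError("tm must be finite")
    if tm > cal.upper_tm + cal.margin:
        return "expanded"
    if tm < cal.lower_tm - cal.margin:
        return "non_expanded"
    return "indeterminate"


def screen_with_retest(
    curve_source: Callable[[float], MeltCurve],
    cal: BoundaryCalibration,
    volumes: Sequence[float] = DEFAULT_VOLUMES,
    smoothing: tuple[int, int] | None = DEFAULT_SMOOTHING,
    **peak_kwargs,
) -> ScreenCall:
    """Screen one sample, escalating template volume on flat profiles.

    ``curve_source(volume)`` produces the melt curve at a given template
    volume.  Volumes are tried in order; the first volume yielding a
    non-flat profile is classified and returned with the number of
    retests performed.  If every volume yields a flat profile the sample
    is a QC failure.
    """
    if not volumes:
        raise ValueError("volumes must be non-empty")
    sample_id = None
    retests = 0
    for i, vol in enumerate(volumes):
        curve = curve_source(vol)
        sample_id = curve.sample_id
        prof = analyze_curve(curve, smoothing, **peak_kwargs)
        if prof.qc_flag != "flat" and prof.last_peak_tm is not None:
            return ScreenCall(
                sample_id=sample_id,
                call=classify(prof.last_peak_tm, cal),
                tm=prof.last_peak_tm,
                retest_count=i,
                qc_flag=prof.qc_flag,
            )
        retests = i
    return ScreenCall(sample_id=sample_id or "?", call="qc_fail", tm=None,
                      retest_count=retests, qc_flag="flat")
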