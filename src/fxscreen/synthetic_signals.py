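"""Synthetic melt-curve and electropherogram generators.

Real instrument data for the dried-blood-spot TP-PCR screen are not
publicly deposited, so the pipeline is exercised end to end on synthetic
signals that reproduce the assay's qualitative physics:

* **Melt curves** — post-PCR dissociation of the TP-PCR product pool.
  Each repeat species contributes one decreasing sigmoidal fluorescence
  transition centred at a repeat-length-dependent melting temperature
  Tm(n); longer CGG tracts are more GC-stable and melt later, saturating
  for very large expansions.  Female curves are superpositions of both
  allelic transitions; mosaic components contribute at their mass
  fraction.  DNA template mass controls signal amplitude (low-input
  preparations give near-flat profiles) and concentration controls
  replicate-to-replicate Tm jitter.
* **TP-PCR electropherograms** — a 3-bp ladder, one peak per repeat
  position up to each template's repeat count, with geometrically
  decaying amplitude.  Shorter templates amplify preferentially, so each
  successive (longer) species contributes at roughly half the amplitude
  of the previous one, producing the step drops that allow biallelic and
  mosaic deconvolution downstream.  Full mutations extend the ladder past
  the 200-repeat position until decay buries it in the floor.
* **Regular (repeat-spanning) PCR electropherograms** — one amplicon peak
  per allele at ``209 + 3 n`` bp shifted by a GC mobility offset
  (default −12 bp ≙ −4 repeats); alleles at or beyond the dropout
  threshold (default 200 repeats) fail to amplify and leave no peak.

All stochastic generators require an explicit integer seed; identical
seed and parameters yield bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repeat_model import Genotype

__all__ = [
    "MELT_T_MIN",
    "MELT_T_MAX",
    "MELT_T_STEP",
    "TP_FLANK_BP",
    "REGULAR_FLANK_BP",
    "PERIOD_BP",
    "LADDER_DECAY",
    "MeltCurve",
    "TmResponseModel",
    "NoiseModel",
    "Electropherogram",
    "melt_temperature_grid",
    "simulate_melt_curve",
    "simulate_tppcr_trace",
    "simulate_regular_trace",
]

# melt ramp: 65-95 degC inclusive in 0.5 degC increments (61 points)
MELT_T_MIN = 65.0
MELT_T_MAX = 95.0
MELT_T_STEP = 0.5

#: bp register of the TP-PCR ladder: the peak for repeat position k sits at
#: ``TP_FLANK_BP + PERIOD_BP * k``.  The absolute register is an assay
#: calibration constant; only the 3-bp spacing and the peak count carry
#: meaning.
TP_FLANK_BP = 100.0
#: combined flank length of the repeat-spanning amplicon: size = 209 + 3 n
REGULAR_FLANK_BP = 209.0
PERIOD_BP = 3.0
#: per-period geometric amplitude decay of the TP-PCR ladder
LADDER_DECAY = 0.985

#: fluorescence amplitude of a unit-weight, saturating-template transition
MELT_AMPLITUDE = 1000.0
#: constant background fluorescence
MELT_BASELINE = 100.0
#: template mass (ng) at which amplitude reaches half saturation
AMPLITUDE_HALF_SAT_NG = 10.0


def melt_temperature_grid() -> np.ndarray:
    """The default 65-95 degC, 0.5 degC acquisition grid (61 points)."""
    n = int(round((MELT_T_MAX - MELT_T_MIN) / MELT_T_STEP)) + 1
    return MELT_T_MIN + MELT_T_STEP * np.arange(n)


@dataclass
class MeltCurve:
    """Raw (temperature, fluorescence) trace for one well."""

    sample_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    dna_conc: float = 25.0  # ng/uL
    template_volume: float = 2.0  # uL

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence grids differ in length")
        if np.any(self.fluorescence < 0):
            raise ValueError("fluorescence must be non-negative")

    @property
    def template_mass_ng(self) -> float:
        return self.dna_conc * self.template_volume


@dataclass(frozen=True)
class TmResponseModel:
    """Saturating-exponential repeat-length -> melting-temperature response.

    ``Tm(n) = tm_sat - (tm_sat - tm_min) * exp(-n / tau)`` is strictly
    increasing in n and saturates for large expansions, reproducing the
    ordering Tm(normal) < Tm(premutation) < Tm(full mutation).  Defaults
    are calibrated so an 8-repeat allele melts at 83.42 degC (the shortest
    allele observed in the reference cohort) while keeping the 46-54-repeat
    boundary controls clearly separated from both the normal range
    (<= 44 repeats) and premutation alleles (>= 55).
    """

    tm_min: float = 80.908464
    tm_sat: float = 93.2
    tau: float = 35.0
    transition_width: float = 0.8  # degC

    def __post_init__(self) -> None:
        if not (self.tm_min < self.tm_sat):
            raise ValueError("tm_min must be below tm_sat")
        if self.tau <= 0 or self.transition_width <= 0:
            raise ValueError("tau and transition_width must be positive")

    def tm(self, repeats: float) -> float:
        """Analytic melting temperature of an n-repeat product pool (degC)."""
        return self.tm_sat - (self.tm_sat - self.tm_min) * np.exp(-repeats / self.tau)


@dataclass(frozen=True)
class NoiseModel:
    """Concentration-dependent measurement noise of the melt assay.

    Replicate Tm jitter is constant (``jitter_sd_high``) at or above
    ``conc_high`` ng/uL and increases linearly in 1/concentration down to
    ``jitter_sd_low`` at ``conc_low`` ng/uL, extrapolating below (capped).
    Signal amplitude saturates with template mass; preparations below
    ``flat_threshold_ng`` of template yield profiles whose peaks fall
    under the downstream prominence floor (a "flat" profile).
    """

    jitter_sd_high: float = 0.11  # degC at conc >= conc_high
    jitter_sd_low: float = 0.53  # degC at conc == conc_low
    conc_high: float = 25.0  # ng/uL
    conc_low: float = 8.0  # ng/uL
    #: jitter saturates at very low template: peak-position error is bounded
    #: by the transition width, so the linear 1/conc trend is capped here
    jitter_sd_cap: float = 0.6  # degC
    baseline_drift_sd: float = 1.0  # fluorescence units
    flat_threshold_ng: float = 2.5  # template mass below which profiles are flat

    def tm_jitter_sd(self, conc: float) -> float:
        """Replicate Tm standard deviation (degC) at a DNA concentration."""
        if conc <= 0:
            raise ValueError("concentration must be positive")
        x = 1.0 / conc
        x_hi, x_lo = 1.0 / self.conc_high, 1.0 / self.conc_low
        if x <= x_hi:
            return self.jitter_sd_high
        slope = (self.jitter_sd_low - self.jitter_sd_high) / (x_lo - x_hi)
        return min(self.jitter_sd_high + slope * (x - x_hi), self.jitter_sd_cap)

    def amplitude_scale(self, template_ng: float) -> float:
        """Saturating amplitude factor in [0, 1) as a function of template mass."""
        if template_ng < 0:
            raise ValueError("template mass must be non-negative")
        return template_ng / (template_ng + AMPLITUDE_HALF_SAT_NG)

    @property
    def is_stochastic(self) -> bool:
        return self.jitter_sd_high > 0 or self.jitter_sd_low > 0 or self.baseline_drift_sd > 0

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """Deterministic variant: no jitter, no drift (amplitude law kept)."""
        return cls(jitter_sd_high=0.0, jitter_sd_low=0.0, baseline_drift_sd=0.0)


@dataclass
class Electropherogram:
    """CE trace of intensity versus fragment size (bp)."""

    sample_id: str
    sizes: np.ndarray
    intensities: np.ndarray
    dialect: str  # "tp_pcr" or "regular_pcr"
    size_standard: str = "internal-500/1000"

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.sizes.shape != self.intensities.shape:
            raise ValueError("size and intensity arrays differ in length")
        if len(self.sizes) > 1 and np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if self.dialect not in ("tp_pcr", "regular_pcr"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


def _sigmoid_drop(T: np.ndarray, tm: float, width: float) -> np.ndarray:
    # decreasing logistic: 1 at low T, 0 above the transition
    return 1.0 / (1.0 + np.exp((T - tm) / width))


def simulate_melt_curve(
    genotype: Genotype,
    prep: tuple[float, float] = (25.0, 2.0),
    model: TmResponseModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> MeltCurve:
    """Simulate one melt-curve well for a genotype.

    Parameters
    ----------
    prep
        ``(dna_conc ng/uL, template_volume uL)`` of the reaction; their
        product is the template mass governing amplitude, and the
        concentration governs Tm jitter.
    noise
        ``None`` disables all noise (and makes ``seed`` optional).
    seed
        Required whenever the noise model is stochastic.
    """
    model = model or TmResponseModel()
    dna_conc, volume = prep
    if dna_conc <= 0:
        raise ValueError("dna_conc must be positive")
    stochastic = noise is not None and noise.is_stochastic
    if stochastic and seed is None:
        raise ValueError("a seed is required for stochastic melt simulation")
    rng = np.random.default_rng(seed) if stochastic else None

    T = melt_temperature_grid()
    mass = dna_conc * volume
    amp_scale = (noise or NoiseModel.noiseless()).amplitude_scale(mass)

    jitter = 0.0
    if stochastic and noise.tm_jitter_sd(dna_conc) > 0:
        # one draw per curve: run-to-run thermal calibration shift
        jitter = rng.normal(0.0, noise.tm_jitter_sd(dna_conc))

    F = np.full_like(T, MELT_BASELINE)
    for allele, weight in genotype.all_components():
        tm = model.tm(allele.repeats) + jitter
        F += MELT_AMPLITUDE * weight * amp_scale * _sigmoid_drop(
            T, tm, model.transition_width
        )
    if stochastic and noise.baseline_drift_sd > 0:
        slope = rng.normal(0.0, noise.baseline_drift_sd)
        F += slope * (T - T.mean()) / (T[-1] - T[0])
        F += rng.normal(0.0, noise.baseline_drift_sd, size=T.shape)
    F = np.clip(F, 0.0, None)
    return MeltCurve(genotype.sample_id, T, F, dna_conc=dna_conc, template_volume=volume)


def _component_lengths_weights(genotype: Genotype) -> tuple[list[int], list[float]]:
    """Unique repeat lengths with rank-halving amplification weights.

    Shorter templates amplify preferentially in TP-PCR; modelling each
    successively longer species at half the amplitude of the previous one
    guarantees a >= 50% amplitude step at every species boundary, which is
    what the downstream deconvolution keys on.
    """
    lengths = sorted({a.repeats for a, _ in genotype.all_components()})
    weights = [0.5**rank for rank in range(len(lengths))]
    total = sum(weights)
    return lengths, [w / total for w in weights]


def simulate_tppcr_trace(
    genotype: Genotype,
    seed: int | None = None,
    noise_sd: float = 0.0,
    peak_sigma_bp: float = 0.6,
    grid_step_bp: float = 0.5,
    max_size_bp: float = 3000.0,
    amplitude: float = 1000.0,
) -> Electropherogram:
    """Simulate a TP-PCR CE ladder trace for a genotype.

    One Gaussian peak per repeat position k (at ``TP_FLANK_BP + 3 k`` bp)
    up to each species' repeat count, amplitude decaying geometrically
    along the ladder and halving at each species boundary (short-template
    amplification bias).  ``noise_sd`` adds white intensity noise (requires
    a seed when positive); the default trace is noiseless.
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    lengths, weights = _component_lengths_weights(genotype)
    end = min(TP_FLANK_BP + PERIOD_BP * max(lengths) + 15.0, max_size_bp)
    sizes = np.arange(60.0, end + grid_step_bp / 2, grid_step_bp)
    y = np.zeros_like(sizes)
    # cumulative weight of species still extending at ladder position k
    max_k = int(min(max(lengths), (sizes[-1] - TP_FLANK_BP) // PERIOD_BP))
    alive = np.zeros(max_k + 1)
    for L, w in zip(lengths, weights):
        alive[1 : min(L, max_k) + 1] += w
    positions = TP_FLANK_BP + PERIOD_BP * np.arange(max_k + 1)
    for k in range(1, max_k + 1):
        if alive[k] <= 0:
            continue
        y += alive[k] * LADDER_DECAY ** (k - 1) * np.exp(
            -0.5 * ((sizes - positions[k]) / peak_sigma_bp) ** 2
        )
    y *= amplitude
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
        y = np.clip(y, 0.0, None)
    return Electropherogram(genotype.sample_id, sizes, y, dialect="tp_pcr")


def simulate_regular_trace(
    genotype: Genotype,
    mobility_offset_bp: float = -12.0,
    dropout_threshold: int = 200,
    seed: int | None = None,
    noise_sd: float = 0.0,
    peak_sigma_bp: float = 1.0,
    grid_step_bp: float = 0.5,
    amplitude: float = 1000.0,
) -> Electropherogram:
    """Simulate a regular (repeat-spanning) PCR CE trace.

    Each repeat species below ``dropout_threshold`` yields one Gaussian
    amplicon peak at ``209 + 3 n + mobility_offset_bp``; GC-rich amplicons
    migrate anomalously fast, hence the default −12 bp (−4 repeat) offset.
    Species at or beyond the threshold fail to amplify (large-expansion
    dropout), which is why this assay cannot serve as a standalone screen.
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    sizes = np.arange(150.0, 950.0 + grid_step_bp / 2, grid_step_bp)
    y = np.zeros_like(sizes)
    for allele, weight in genotype.all_components():
        if allele.repeats >= dropout_threshold:
            continue  # FM dropout: no amplifiable product
        pos = REGULAR_FLANK_BP + PERIOD_BP * allele.repeats + mobility_offset_bp
        y += amplitude * weight * np.exp(-0.5 * ((sizes - pos) / peak_sigma_bp) ** 2)
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
        y = np.clip(y, 0.0, None)
    return Electropherogram(genotype.sample_id, sizes, y, dialect="regular_pcr")
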