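"""Second-tier CE repeat sizing: TP-PCR ladder peak counting and
regular-PCR amplicon size conversion.

TP-PCR ladder counting is the definitive sizing route: each 3-bp ladder
peak marks one repeat position, so the repeat count of a species is simply
the position of the last peak before its amplitude step.  Species
boundaries are called at sustained amplitude drops (biallelic and mosaic
deconvolution), and any qualifying peak at or beyond the 200-repeat
position flags a full mutation, reported as ">200" rather than a point
estimate.

Regular (repeat-spanning) PCR sizes an amplicon via
``repeats = (bp - 209) / 3``; GC-driven anomalous mobility makes this
underestimate the true count by ~4 repeats, corrected after rounding.
Its blind spot — large expansions do not amplify at all — is flagged as
suspected dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .repeat_model import RepeatCategory, category_of
from .synthetic_signals import (
    Electropherogram,
    PERIOD_BP,
    REGULAR_FLANK_BP,
    TP_FLANK_BP,
)

__all__ = [
    "LadderCall",
    "RegularSizeCall",
    "EmptyTraceError",
    "count_ladder",
    "regular_size",
    "concordance",
    "FM_REPEAT_THRESHOLD",
]

#: repeat position at which a ladder extension indicates a full mutation
FM_REPEAT_THRESHOLD = 200
#: a species boundary is an amplitude drop to <= this ratio ...
BOUNDARY_DROP_RATIO = 0.5
#: ... sustained over at least this many ladder periods
BOUNDARY_SUSTAIN_PERIODS = 3
#: ladder segments separated by this many silent periods are distinct species
MOSAIC_GAP_PERIODS = 10


class EmptyTraceError(RuntimeError):
    """No ladder peaks above the floor: failed CE (e.g. insufficient DNA)."""


@dataclass
class LadderCall:
    """Result of TP-PCR ladder counting for one sample."""

    sample_id: str
    allele_sizes: list[int]  # distinct species below 200 repeats, ascending
    fm_flag: bool  # ladder extends to/beyond the 200-repeat position
    mosaic_flag: bool  # >= 2 distinct expanded species
    category: RepeatCategory  # category of the largest detected species
    max_position: int = 0  # last ladder position above floor

    def __post_init__(self) -> None:
        self.allele_sizes = sorted(self.allele_sizes)
        if self.fm_flag and self.category != RepeatCategory.FM:
            raise ValueError("fm_flag implies FM category")


@dataclass
class RegularSizeCall:
    """Result of regular-PCR amplicon sizing for one sample."""

    sample_id: str
    amplicon_bp: list[float]
    repeats_uncorrected: list[float]
    repeats_corrected: list[int]
    dropout_suspected: bool


def _ladder_peaks(trace: Electropherogram, peak_floor: float):
    """Detected ladder peaks as (repeat_position, amplitude) arrays."""
    y = trace.intensities
    if y.max(initial=0.0) <= 0:
        raise EmptyTraceError(f"{trace.sample_id}: empty TP-PCR trace")
    floor = peak_floor * float(y.max())
    idx, _ = find_peaks(y, height=floor)
    if idx.size == 0:
        raise EmptyTraceError(f"{trace.sample_id}: no ladder peaks above floor")
    positions = np.round((trace.sizes[idx] - TP_FLANK_BP) / PERIOD_BP).astype(int)
    amps = y[idx]
    keep = positions >= 1
    # collapse accidental duplicates on the same repeat position
    pos_out, amp_out = [], []
    for p, a in zip(positions[keep], amps[keep]):
        if pos_out and p == pos_out[-1]:
            amp_out[-1] = max(amp_out[-1], a)
        else:
            pos_out.append(int(p))
            amp_out.append(float(a))
    return np.array(pos_out), np.array(amp_out)


def count_ladder(
    trace: Electropherogram,
    period_bp: float = PERIOD_BP,
    peak_floor: float = 0.005,
) -> LadderCall:
    """Size a sample by counting TP-PCR ladder peaks.

    Peaks on the 3-bp ladder register are detected above ``peak_floor``
    (fraction of the trace maximum).  A species end is called where the
    ladder amplitude drops to half or less, sustained for at least three
    periods; the final peak always ends the largest resolvable species.
    Any peak at or beyond the 200-repeat position raises ``fm_flag`` (the
    species is reported as ">200", never as a point estimate).
    ``mosaic_flag`` marks two or more distinct expanded (>= 55 repeat)
    species, whether separated by an amplitude step or by a silent gap.

    Raises
    ------
    EmptyTraceError
        If no peaks pass the floor (failed CE).
    """
    if trace.dialect != "tp_pcr":
        raise ValueError(f"count_ladder needs a tp_pcr trace, got {trace.dialect!r}")
    pos, amp = _ladder_peaks(trace, peak_floor)
    max_position = int(pos[-1])

    # species boundaries: sustained >=50% amplitude drops, plus the final peak
    ends: list[int] = []
    gap_separated = False
    for j in range(len(pos)):
        if j == len(pos) - 1:
            ends.append(int(pos[j]))
            break
        if pos[j + 1] - pos[j] >= MOSAIC_GAP_PERIODS:
            ends.append(int(pos[j]))
            gap_separated = True
            continue
        window = amp[j + 1 : j + 1 + BOUNDARY_SUSTAIN_PERIODS]
        if window.size and np.all(window <= BOUNDARY_DROP_RATIO * amp[j]):
            ends.append(int(pos[j]))

    allele_sizes = [e for e in ends if e < FM_REPEAT_THRESHOLD]
    fm_flag = max_position >= FM_REPEAT_THRESHOLD
    expanded_species = sum(1 for e in ends if e >= 55)
    mosaic_flag = expanded_species >= 2 or (gap_separated and expanded_species >= 1)

    if fm_flag:
        category = RepeatCategory.FM
    else:
        category = category_of(max(ends))
    return LadderCall(
        sample_id=trace.sample_id,
        allele_sizes=allele_sizes,
        fm_flag=fm_flag,
        mosaic_flag=mosaic_flag,
        category=category,
        max_position=max_position,
    )


def regular_size(
    trace: Electropherogram,
    flank_bp: float = REGULAR_FLANK_BP,
    period_bp: float = PERIOD_BP,
    correction_repeats: int = 4,
    sex: str | None = None,
    peak_floor: float = 0.05,
) -> RegularSizeCall:
    """Convert regular-PCR amplicon sizes to repeat counts.

    Per detected amplicon peak: ``repeats_uncorrected = (bp - 209) / 3``
    and ``repeats_corrected = round(uncorrected) + 4`` (GC mobility
    correction).  Dropout is suspected when a male trace shows no peak or
    a female trace shows a single peak — a single amplicon cannot
    distinguish a homozygous normal female from a carrier whose expanded
    allele failed to amplify.  Without a stated sex, any peakless trace
    is suspect.
    """
    if trace.dialect != "regular_pcr":
        raise ValueError(f"regular_size needs a regular_pcr trace, got {trace.dialect!r}")
    y = trace.intensities
    peaks_bp: list[float] = []
    if y.max(initial=0.0) > 0:
        idx, _ = find_peaks(y, height=peak_floor * float(y.max()))
        step = trace.sizes[1] - trace.sizes[0] if len(trace.sizes) > 1 else 1.0
        for i in idx:
            # centroid refinement over the local neighbourhood
            lo, hi = max(0, i - 3), min(len(y), i + 4)
            w = y[lo:hi]
            peaks_bp.append(float(np.sum(trace.sizes[lo:hi] * w) / np.sum(w)))
    uncorrected = [(bp - flank_bp) / period_bp for bp in peaks_bp]
    corrected = [int(round(u)) + correction_repeats for u in uncorrected]
    if sex == "M":
        dropout = len(peaks_bp) == 0
    elif sex == "F":
        dropout = len(peaks_bp) <= 1
    else:
        dropout = len(peaks_bp) == 0
    return RegularSizeCall(
        sample_id=trace.sample_id,
        amplicon_bp=peaks_bp,
        repeats_uncorrected=uncorrected,
        repeats_corrected=corrected,
        dropout_suspected=dropout,
    )


@dataclass
class ConcordanceReport:
    sample_id: str
    pairs: list[tuple[int, int, int]]  # (ladder, regular_corrected, diff)
    unmatched_ladder: list[int]
    fm_only_in_ladder: bool
    concordant: bool
    note: str = ""


def concordance(ladder: LadderCall, regular: RegularSizeCall) -> ConcordanceReport:
    """Compare TP-PCR ladder sizes with corrected regular-PCR sizes.

    Alleles are paired by nearest size; a pair differing by more than one
    repeat is discordant.  A full-mutation ladder extension with regular-
    PCR dropout is expected behaviour and reported as concordant-with-
    dropout rather than a discrepancy.
    """
    if ladder.sample_id != regular.sample_id:
        raise ValueError("concordance requires calls for the same sample")
    remaining = list(regular.repeats_corrected)
    pairs: list[tuple[int, int, int]] = []
    unmatched: list[int] = []
    for a in ladder.allele_sizes:
        if not remaining:
            unmatched.append(a)
            continue
        j = int(np.argmin([abs(r - a) for r in remaining]))
        r = remaining.pop(j)
        pairs.append((a, r, r - a))
    fm_only = ladder.fm_flag and regular.dropout_suspected
    concordant = all(abs(d) <= 1 for _, _, d in pairs) and not unmatched
    note = ""
    if fm_only:
        note = "FM ladder extension with regular-PCR dropout (expected)"
    elif ladder.fm_flag and not regular.dropout_suspected:
        concordant = False
        note = "FM ladder extension but regular PCR shows all alleles"
    return ConcordanceReport(
        sample_id=ladder.sample_id,
        pairs=pairs,
        unmatched_ladder=unmatched,
        fm_only_in_ladder=fm_only,
        concordant=concordant,
        note=note,
    )
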