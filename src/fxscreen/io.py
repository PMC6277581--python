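"""Plain-text readers and writers for melt curves, CE traces and calls.

Melt curves travel as CSV in either a *long* dialect
(``sample_id,temperature,fluorescence``) or a *wide* dialect (a
``temperature`` column plus one column per well).  CE traces are
two-column CSV (``size_bp,intensity``) with the dialect recorded in the
filename or passed explicitly.  Flat key-value YAML files configure the
simulation/analysis parameters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .melt_screen import ScreenCall
from .synthetic_signals import Electropherogram, MeltCurve, NoiseModel, TmResponseModel

__all__ = [
    "read_melt_curves",
    "write_melt_curves_long",
    "write_melt_curves_wide",
    "read_trace",
    "write_trace",
    "write_screen_calls",
    "load_params_yaml",
]


def read_melt_curves(path: str | Path, dna_conc: float = 25.0,
                     template_volume: float = 2.0) -> list[MeltCurve]:
    """Read melt curves from CSV, auto-detecting the long or wide dialect."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if {"sample_id", "temperature", "fluorescence"} <= set(cols):
        curves = []
        for sid, grp in df.groupby(cols["sample_id"], sort=False):
            grp = grp.sort_values(cols["temperature"])
            curves.append(
                MeltCurve(
                    str(sid),
                    grp[cols["temperature"]].to_numpy(float),
                    grp[cols["fluorescence"]].to_numpy(float),
                    dna_conc=dna_conc,
                    template_volume=template_volume,
                )
            )
        return curves
    if "temperature" in cols:
        tcol = cols["temperature"]
        T = df[tcol].to_numpy(float)
        return [
            MeltCurve(str(c), T, df[c].to_numpy(float), dna_conc=dna_conc,
                      template_volume=template_volume)
            for c in df.columns
            if c != tcol
        ]
    raise ValueError(f"{path}: unrecognised melt CSV layout (columns {list(df.columns)})")


def write_melt_curves_long(curves: Iterable[MeltCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "temperature": c.temperatures,
                "fluorescence": c.fluorescence,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_melt_curves_wide(curves: list[MeltCurve], path: str | Path) -> None:
    if not curves:
        raise ValueError("no curves to write")
    T = curves[0].temperatures
    for c in curves[1:]:
        if not np.array_equal(c.temperatures, T):
            raise ValueError("wide dialect requires a shared temperature grid")
    data = {"temperature": T}
    data.update({c.sample_id: c.fluorescence for c in curves})
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace(path: str | Path, dialect: str, sample_id: str | None = None) -> Electropherogram:
    """Read a two-column (size_bp, intensity) CE trace CSV."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        sizes = df[cols["size_bp"]].to_numpy(float)
        inten = df[cols["intensity"]].to_numpy(float)
    except KeyError:
        raise ValueError(f"{path}: expected columns size_bp,intensity") from None
    sid = sample_id or Path(path).stem
    return Electropherogram(sid, sizes, inten, dialect=dialect)


def write_trace(trace: Electropherogram, path: str | Path) -> None:
    pd.DataFrame({"size_bp": trace.sizes, "intensity": trace.intensities}).to_csv(
        path, index=False
    )


def write_screen_calls(calls: Iterable[ScreenCall], path: str | Path) -> None:
    """Write per-sample first-tier calls as TSV."""
    rows = [
        {
            "sample_id": c.sample_id,
            "call": c.call,
            "tm": "" if c.tm is None else f"{c.tm:.3f}",
            "qc_flag": c.qc_flag,
            "retest_count": c.retest_count,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_params_yaml(path: str | Path):
    """Build :class:`~fxscreen.cohort_pipeline.SimParams` from flat YAML.

    Recognised keys are the field names of ``TmResponseModel`` (prefixed
    ``tm_``... as-is), ``NoiseModel``, and ``SimParams`` scalars
    (``margin``, ``default_conc``, ``volumes``, ``control_repeats``).
    Unknown keys raise, to catch typos.
    """
    from .cohort_pipeline import SimParams

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    tm_fields = {f for f in TmResponseModel.__dataclass_fields__}
    noise_fields = {f for f in NoiseModel.__dataclass_fields__}
    sim_fields = {"margin", "default_conc", "volumes", "control_repeats",
                  "control_conc", "control_volume"}
    tm_kw, noise_kw, sim_kw = {}, {}, {}
    for k, v in raw.items():
        if k in tm_fields:
            tm_kw[k] = v
        elif k in noise_fields:
            noise_kw[k] = v
        elif k in sim_fields:
            sim_kw[k] = tuple(v) if isinstance(v, list) else v
        else:
            raise ValueError(f"{path}: unknown parameter {k!r}")
    return SimParams(
        tm_model=TmResponseModel(**tm_kw), noise=NoiseModel(**noise_kw), **sim_kw
    )
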