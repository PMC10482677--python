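"""Indirect-calorimetry arithmetic over time-binned metabolic-cage records.

The respiratory exchange ratio (RER) is VCO2/VO2: near 1.0 when carbohydrate
is the dominant fuel and near 0.7 for fat.  Whole-body substrate oxidation
rates are the standard linear combinations of gas exchange,

    glucose oxidation = ((4.585 * VCO2) - (3.226 * VO2)) * 4
    fat oxidation     = ((1.695 * VO2) - (1.701 * VCO2)) * 9,

applied to the numeric columns as given; units are carried through from the
input metadata unchanged.  Values are divided by each animal's lean mass for
between-animal comparison.  Negative oxidation rates (possible at extreme
RER) are reported as-is and flagged, never clipped, so phase means stay
unbiased.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

REQUIRED_COLUMNS = ("animal_id", "time_bin", "vo2", "vco2", "lean_mass")


def rer(vo2, vco2):
    """Respiratory exchange ratio VCO2/VO2 (scalar or vectorized)."""
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 <= 0):
        raise InputError("vo2 must be positive")
    return np.asarray(vco2, dtype=float) / vo2 if vo2.ndim else float(vco2) / float(vo2)


def glucose_oxidation(vo2, vco2):
    """Glucose oxidation rate from gas exchange; may be negative at low RER."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    out = ((4.585 * vco2) - (3.226 * vo2)) * 4
    return float(out) if out.ndim == 0 else out


def fat_oxidation(vo2, vco2):
    """Fat oxidation rate from gas exchange; ~0 at RER = 1, negative above."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    out = ((1.695 * vo2) - (1.701 * vco2)) * 9
    return float(out) if out.ndim == 0 else out


def lean_mass_correct(values, lean_mass):
    """Divide values elementwise by (broadcastable) positive lean mass."""
    lean_mass = np.asarray(lean_mass, dtype=float)
    if np.any(lean_mass <= 0):
        raise InputError("lean_mass must be positive")
    out = np.asarray(values, dtype=float) / lean_mass
    return float(out) if out.ndim == 0 else out


def _validate(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise InputError(f"calorimetry table lacks columns {missing}")
    if (records["vo2"] <= 0).any():
        raise InputError("vo2 must be positive in every record")
    if (records["vco2"] < 0).any():
        raise InputError("vco2 must be non-negative")
    if (records["lean_mass"] <= 0).any():
        raise InputError("lean_mass must be positive")


def assign_phases(records: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Label records with fed/fasted/refed phases from an explicit schedule.

    ``schedule`` has columns phase, start, end; a record with ``time_bin`` in
    [start, end) gets that phase.  Unscheduled bins are labelled "unassigned".
    """
    for col in ("phase", "start", "end"):
        if col not in schedule.columns:
            raise InputError(f"schedule lacks column {col!r}")
    out = records.copy()
    phase = pd.Series("unassigned", index=out.index, dtype=object)
    for row in schedule.itertuples():
        mask = (out["time_bin"] >= row.start) & (out["time_bin"] < row.end)
        phase[mask] = row.phase
    out["phase"] = phase
    return out


def analyze(records: pd.DataFrame) -> pd.DataFrame:
    """Add RER, oxidation rates and lean-mass-corrected columns per record."""
    _validate(records)
    out = records.copy()
    out["rer"] = rer(out["vo2"], out["vco2"])
    out["glucose_oxidation"] = glucose_oxidation(out["vo2"], out["vco2"])
    out["fat_oxidation"] = fat_oxidation(out["vo2"], out["vco2"])
    out["glucose_oxidation_per_lean"] = lean_mass_correct(out["glucose_oxidation"], out["lean_mass"])
    out["fat_oxidation_per_lean"] = lean_mass_correct(out["fat_oxidation"], out["lean_mass"])
    out["negative_oxidation_flag"] = (out["glucose_oxidation"] < 0) | (out["fat_oxidation"] < 0)
    return out


def phase_summary(analyzed: pd.DataFrame) -> pd.DataFrame:
    """Per-animal per-phase means of RER and corrected oxidation rates."""
    if "phase" not in analyzed.columns:
        raise InputError("records carry no phase column; run assign_phases first")
    grouped = (
        analyzed.groupby(["animal_id", "phase"], sort=True)[
            ["rer", "glucose_oxidation_per_lean", "fat_oxidation_per_lean"]
        ]
        .mean()
        .reset_index()
    )
    return grouped
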