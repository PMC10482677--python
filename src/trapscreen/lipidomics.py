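"""Shotgun-lipidomics postprocessing: identification filters and mol%.

The module starts from an identified, internal-standard-scaled intensity
table (one row per sample x lipid species) and applies the standard
quality filters — a species is retained only when its signal-to-noise ratio
exceeds 5 and its signal exceeds 5-fold the level in the matched process
blank, both strictly — then expresses abundances as the molar percentage of
all retained species in the sample (mol%) and contrasts conditions at the
species or class level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

LIPID_CLASSES = frozenset(
    {
        "CE", "Cer", "CL", "DAG", "HexCer", "LPA", "LPC", "LPE", "LPG", "LPI",
        "LPS", "PA", "PC", "PE", "PG", "PI", "PS", "SM", "TAG",
        "PC O-", "PE O-", "LPC O-", "LPE O-",
    }
)

REQUIRED_COLUMNS = ("sample_id", "species", "lipid_class", "amount", "signal_to_noise", "blank_amount")


def _validate(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise InputError(f"lipidomics table lacks columns {missing}")
    if (records["amount"] < 0).any():
        raise InputError("amounts must be non-negative")
    if (records["signal_to_noise"] < 0).any():
        raise InputError("signal-to-noise must be non-negative")
    bad = set(records["lipid_class"]) - LIPID_CLASSES
    if bad:
        raise InputError(f"unknown lipid classes {sorted(bad)}")


def filter_identifications(
    records: pd.DataFrame, sn_min: float = 5.0, blank_fold: float = 5.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the identification quality filters (both inequalities strict).

    Returns the retained rows and a report with per-rule rejection counts
    (a row failing both rules is counted under both).
    """
    _validate(records)
    sn_ok = records["signal_to_noise"] > sn_min
    blank_ok = records["amount"] > blank_fold * records["blank_amount"]
    keep = sn_ok & blank_ok
    report = {
        "n_input": int(len(records)),
        "n_retained": int(keep.sum()),
        "n_rejected_sn": int((~sn_ok).sum()),
        "n_rejected_blank": int((~blank_ok).sum()),
    }
    return records[keep].reset_index(drop=True), report


def mol_percent(records: pd.DataFrame, by: str = "species") -> pd.DataFrame:
    """Express abundances as mol% of the per-sample total of retained species.

    ``by`` is "species" or "class"; per-sample values sum to 100 (to 1e-9).
    Samples whose retained total is zero are dropped with a flag column in
    ``attrs['zero_total_samples']``.
    """
    if by not in ("species", "class"):
        raise InputError(f"'by' must be 'species' or 'class', got {by!r}")
    _validate(records)
    key = "species" if by == "species" else "lipid_class"
    sums = records.groupby(["sample_id", key], sort=True)["amount"].sum().reset_index()
    totals = sums.groupby("sample_id")["amount"].transform("sum")
    zero_samples = sorted(sums.loc[totals == 0, "sample_id"].unique())
    sums = sums[totals > 0].copy()
    sums["mol_percent"] = 100.0 * sums["amount"] / totals[totals > 0]
    out = sums.drop(columns="amount").reset_index(drop=True)
    out.attrs["zero_total_samples"] = zero_samples
    out.attrs["by"] = by
    return out


def contrast_conditions(
    table_a: pd.DataFrame, table_b: pd.DataFrame, pseudocount: str = "none"
) -> pd.DataFrame:
    """Per-species change in mol% between two conditions.

    Inputs are species-level mol% tables (as from :func:`mol_percent`); each
    condition is averaged over its samples, then joined on the species
    vocabulary (outer join).  Species present in only one condition are
    marked via ``status`` and excluded from the log2 ratio unless the
    Haldane-style pseudocount policy is chosen, which is stamped in
    ``attrs``.  Swapping the inputs negates both the difference and the
    ratio.
    """
    key = "species"
    for name, t in (("A", table_a), ("B", table_b)):
        if key not in t.columns or "mol_percent" not in t.columns:
            raise InputError(f"table {name} is not a species-level mol%% table")
    a = table_a.groupby(key)["mol_percent"].mean().rename("mol_percent_a")
    b = table_b.groupby(key)["mol_percent"].mean().rename("mol_percent_b")
    if not (set(a.index) & set(b.index)):
        raise InputError("conditions share no species")
    m = pd.concat([a, b], axis=1, join="outer")
    status = np.where(
        m["mol_percent_a"].isna(), "absent_in_A", np.where(m["mol_percent_b"].isna(), "absent_in_B", "shared")
    )
    eps = 0.0 if pseudocount == "none" else 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        if pseudocount == "none":
            ratio = np.log2(m["mol_percent_a"] / m["mol_percent_b"])
        else:
            ratio = np.log2((m["mol_percent_a"].fillna(0) + eps) / (m["mol_percent_b"].fillna(0) + eps))
    out = pd.DataFrame(
        {
            "species": m.index,
            "mol_percent_a": m["mol_percent_a"].to_numpy(),
            "mol_percent_b": m["mol_percent_b"].to_numpy(),
            "delta_mol_percent": (m["mol_percent_a"].fillna(0) - m["mol_percent_b"].fillna(0)).to_numpy(),
            "log2_ratio": np.asarray(ratio),
            "mean_mol_percent": np.nanmean(
                np.vstack([m["mol_percent_a"].to_numpy(), m["mol_percent_b"].to_numpy()]), axis=0
            ),
            "status": status,
        }
    ).reset_index(drop=True)
    out.loc[out["status"] != "shared", "log2_ratio"] = (
        out.loc[out["status"] != "shared", "log2_ratio"] if pseudocount != "none" else np.nan
    )
    out.attrs["pseudocount"] = pseudocount
    return out


def class_contrast(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Class-level mean mol% per condition and their difference."""
    key = "lipid_class"
    a = table_a.groupby(key)["mol_percent"].mean().rename("mol_percent_a")
    b = table_b.groupby(key)["mol_percent"].mean().rename("mol_percent_b")
    m = pd.concat([a, b], axis=1, join="outer").fillna(0.0)
    m["delta_mol_percent"] = m["mol_percent_a"] - m["mol_percent_b"]
    return m.reset_index()
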