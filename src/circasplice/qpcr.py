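"""Validation arithmetic for QPCR and RT-PCR data.

Relative quantification from Ct or relative-concentration values,
normalizer (Actb-style) correction, fold change versus a reference group,
the exon/transcript splicing index, and gel-band percent inclusion.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantities",
    "relative_expression",
    "splicing_index",
    "percent_inclusion",
]

REQUIRED_COLUMNS = ("sample_id", "target", "mode", "value")


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def quantities(table: pd.DataFrame) -> pd.Series:
    """Linear-scale quantity per row: efficiency**(-Ct) for Ct rows, the
    given value for relative-concentration rows."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"QPCR table missing column {col!r}")
    eff = table["efficiency"] if "efficiency" in table.columns else pd.Series(2.0, index=table.index)
    if (eff <= 1).any():
        raise ValueError("efficiency must be > 1")
    out = np.empty(len(table))
    mode = table["mode"].str.lower()
    is_ct = mode == "ct"
    is_conc = mode.isin(["conc", "concentration", "rel"])
    if not (is_ct | is_conc).all():
        bad = table.loc[~(is_ct | is_conc), "mode"].iloc[0]
        raise ValueError(f"unknown QPCR mode {bad!r}")
    ct_vals = table.loc[is_ct, "value"].to_numpy(dtype=float)
    if (ct_vals < 0).any():
        raise ValueError("Ct values must be >= 0")
    out[is_ct.to_numpy()] = np.power(
        eff[is_ct].to_numpy(dtype=float), -ct_vals
    )
    conc_vals = table.loc[is_conc, "value"].to_numpy(dtype=float)
    if (conc_vals <= 0).any():
        raise ValueError("relative concentrations must be > 0")
    out[is_conc.to_numpy()] = conc_vals
    return pd.Series(out, index=table.index, name="quantity")


def relative_expression(
    table: pd.DataFrame,
    target: str,
    normalizer: str,
    reference_group: Sequence[str],
) -> pd.DataFrame:
    """Normalized expression of ``target`` and fold versus the reference group.

    Per sample: normalized = quantity(target)/quantity(normalizer); fold =
    normalized divided by the geometric mean of the normalized values over
    the reference-group samples.
    """
    q = quantities(table)
    frame = table.assign(quantity=q)
    by = frame.pivot_table(index="sample_id", columns="target", values="quantity")
    for name in (target, normalizer):
        if name not in by.columns:
            raise KeyError(f"target {name!r} absent from the table")
        if by[name].isna().any():
            missing = by.index[by[name].isna()].tolist()
            raise ValueError(f"samples missing {name!r} measurement: {missing[:5]}")
    ref = [s for s in reference_group if s in by.index]
    if not ref:
        raise ValueError("reference group is empty or not present in the table")
    normalized = by[target] / by[normalizer]
    ref_level = _geometric_mean(normalized.loc[ref].to_numpy())
    return pd.DataFrame(
        {
            "sample_id": by.index,
            "target": target,
            "normalized": normalized.to_numpy(),
            "fold": (normalized / ref_level).to_numpy(),
        }
    ).reset_index(drop=True)


def splicing_index(
    exon_expr: pd.DataFrame,
    transcript_expr: pd.DataFrame,
    reference_group: Sequence[str],
) -> pd.DataFrame:
    """Per-sample alternative-splicing value: exon normalized over transcript
    normalized (any shared normalizer cancels), plus fold vs the reference
    group's geometric mean."""
    e = exon_expr.set_index("sample_id")["normalized"]
    t = transcript_expr.set_index("sample_id")["normalized"]
    if set(e.index) != set(t.index):
        raise ValueError("exon and transcript tables must cover the same samples")
    as_value = e / t.loc[e.index]
    ref = [s for s in reference_group if s in as_value.index]
    if not ref:
        raise ValueError("reference group is empty or not present")
    ref_level = _geometric_mean(as_value.loc[ref].to_numpy())
    return pd.DataFrame(
        {
            "sample_id": as_value.index,
            "as_value": as_value.to_numpy(),
            "as_fold": (as_value / ref_level).to_numpy(),
        }
    ).reset_index(drop=True)


def percent_inclusion(bands: pd.DataFrame) -> float:
    """Percent exon inclusion from one lane's included/skipped band pair.

    Signals are size-corrected to molar units (area/length); inclusion is
    100 x included / (included + skipped).
    """
    for col in ("isoform", "area", "length"):
        if col not in bands.columns:
            raise ValueError(f"band table missing column {col!r}")
    if (bands["area"] < 0).any():
        raise ValueError("band areas must be >= 0")
    if (bands["length"] <= 0).any():
        raise ValueError("band lengths must be > 0")
    iso = bands["isoform"].str.lower()
    incl = bands.loc[iso == "included"]
    skip = bands.loc[iso == "skipped"]
    if len(incl) != 1 or len(skip) != 1:
        raise ValueError("need exactly one included and one skipped band")
    molar_incl = float(incl["area"].iloc[0] / incl["length"].iloc[0])
    molar_skip = float(skip["area"].iloc[0] / skip["length"].iloc[0])
    total = molar_incl + molar_skip
    if total == 0:
        raise ValueError("both molar signals are zero")
    return 100.0 * molar_incl / total
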