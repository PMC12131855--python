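"""Relative-abundance quantification and normalization.

Peak areas exported per glycan and sample are converted to relative
abundances (percent of the sample's total glycan signal), then median
normalized per sample and log2 transformed before differential testing.
Technical quality is monitored with %CV of control-analyte replicate
series (dextran ladder DP3–DP10 in the LC-MS workflow this mirrors).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "impute_zeros",
    "median_normalize_log",
    "qc_cv",
    "read_area_matrix",
    "read_metadata",
    "METADATA_REQUIRED",
]

ZERO_POLICIES = ("half-min", "drop", "pseudocount")


def relative_abundance(areas: pd.DataFrame) -> pd.DataFrame:
    """Peak areas → percent of total per sample column.

    value = area / column total × 100.  Missing values stay missing and do
    not contribute to the total.  Scale-invariant per sample and
    idempotent (up to the constant 100 rescaling).
    """
    if (areas.fillna(0) < 0).any().any():
        raise ValueError("peak areas must be non-negative")
    totals = areas.sum(axis=0, skipna=True)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(
            f"sample(s) with zero total area: {list(dead.index)}"
        )
    return areas.div(totals, axis=1) * 100.0


def impute_zeros(
    rel: pd.DataFrame, policy: str = "half-min", pseudocount: float = 1e-3
) -> pd.DataFrame:
    """Replace zeros/missing values ahead of the log transform.

    ``half-min`` (default): per glycan, half its minimum positive value
    across samples; a glycan with no positive values falls back to half
    the matrix-wide minimum positive value.  ``pseudocount`` adds a fixed
    epsilon to zeros; ``drop`` leaves them as NaN (excluded downstream).
    """
    if policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}, got {policy!r}")
    out = rel.copy().astype(float)
    mask = out.isna() | (out == 0)
    if policy == "drop":
        return out.where(~mask)
    if policy == "pseudocount":
        return out.where(~mask, other=pseudocount)
    positive = out.where(out > 0)
    global_fill = np.nanmin(positive.values) / 2.0 if np.isfinite(
        np.nanmin(positive.values)) else np.nan
    fills = (positive.min(axis=1, skipna=True) / 2.0).fillna(global_fill)
    return out.where(~mask, other=pd.DataFrame(
        np.broadcast_to(fills.values[:, None], out.shape),
        index=out.index, columns=out.columns,
    ))


def median_normalize_log(
    rel: pd.DataFrame, zero_policy: str = "half-min", min_values: int = 3
) -> pd.DataFrame:
    """Median normalize per sample, then log2.

    Each sample column is scaled by its median (non-missing, after zero
    imputation); the scaling is applied on the log2 scale (subtracting
    the median log2 value), which is identical for an odd number of
    glycans and guarantees a per-sample median log2 of exactly 0 also for
    an even number.
    """
    imputed = impute_zeros(rel, zero_policy)
    counts = imputed.notna().sum(axis=0)
    thin = counts[counts < min_values]
    if len(thin):
        raise ValueError(
            f"sample(s) with fewer than {min_values} usable values: {list(thin.index)}"
        )
    logs = np.log2(imputed)
    return logs - logs.median(axis=0, skipna=True)


def qc_cv(
    control_areas: pd.DataFrame, threshold: float = 10.0
) -> pd.DataFrame:
    """%CV per control analyte over replicate columns.

    Returns a table with columns ``cv_percent`` (100·sd/mean, sample sd)
    and ``flagged`` (CV ≥ ``threshold``, default 10%)."""
    if control_areas.shape[1] < 2:
        raise ValueError("need at least 2 replicates for %CV")
    means = control_areas.mean(axis=1)
    if (means == 0).any():
        bad = list(means[means == 0].index)
        raise ValueError(f"control analyte(s) with zero mean: {bad}")
    cv = 100.0 * control_areas.std(axis=1, ddof=1) / means
    return pd.DataFrame({"cv_percent": cv, "flagged": cv >= threshold})


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

METADATA_REQUIRED = ["sample_id", "group"]
GROUPS = ("negative", "positive")


def read_area_matrix(path) -> pd.DataFrame:
    """Read a glycans × samples peak-area CSV (wide: first column
    glycan_id; or long: columns glycan_id, sample_id, area)."""
    df = pd.read_csv(path)
    if {"glycan_id", "sample_id", "area"} <= set(df.columns):
        wide = df.pivot(index="glycan_id", columns="sample_id", values="area")
        wide.columns.name = None
        return wide
    if df.columns[0] != "glycan_id":
        raise ValueError(
            f"{path}: expected first column 'glycan_id' or long format "
            "(glycan_id, sample_id, area)"
        )
    out = df.set_index("glycan_id")
    if out.index.duplicated().any():
        raise ValueError(f"{path}: duplicate glycan ids")
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata CSV: sample_id, group (positive/negative),
    optional age, sex (M/F), binary comorbidity columns, region."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df.set_index("sample_id", drop=False)
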