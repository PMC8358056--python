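"""Relative quantification of qPCR data by the Livak 2^-ddCt method.

dCt = Ct(target) - Ct(reference) per sample, replicates averaged on the Ct
scale; ddCt = dCt(sample) - mean dCt(calibrator group); fold change =
2^-ddCt with amplification efficiency fixed at 2. A pooled-variance
two-sample Student's t-test compares replicate fold changes between a
treated group and the calibrator, with significance stars at 0.05 / 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample_id", "group", "target_ct", "reference_ct", "replicate")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    cts = records[["target_ct", "reference_ct"]].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise ValueError("Ct values must be positive and finite")
    return records


def relative_expression(
    records: pd.DataFrame, calibrator: str = "control"
) -> pd.DataFrame:
    """Per-sample fold changes relative to the calibrator group.

    Returns one row per sample with delta_ct, delta_delta_ct, fold_change
    and the standard error of per-replicate fold changes. When a ``gene``
    column is present each gene is normalised independently.
    """
    records = _validate(records)
    if "gene" in records.columns:
        parts = [
            relative_expression(g.drop(columns="gene"), calibrator).assign(gene=name)
            for name, g in records.groupby("gene", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)

    if calibrator not in set(records["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not present")

    per_rep = records.assign(
        dct=records["target_ct"].astype(float) - records["reference_ct"].astype(float)
    )
    # Livak: average replicates on the Ct scale before exponentiation
    per_sample = (
        per_rep.groupby(["sample_id", "group"], sort=True)["dct"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "delta_ct", "count": "n_replicates"})
    )
    cal_dct = float(
        per_sample.loc[per_sample["group"] == calibrator, "delta_ct"].mean()
    )
    per_sample["delta_delta_ct"] = per_sample["delta_ct"] - cal_dct
    per_sample["fold_change"] = 2.0 ** (-per_sample["delta_delta_ct"])

    # replicate-level folds give the dispersion estimate for error bars
    per_rep["fold_rep"] = 2.0 ** (-(per_rep["dct"] - cal_dct))
    se = (
        per_rep.groupby(["sample_id", "group"])["fold_rep"]
        .agg(lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0)
        .rename("se")
        .reset_index()
    )
    return per_sample.merge(se, on=["sample_id", "group"])


def replicate_fold_changes(
    records: pd.DataFrame, calibrator: str = "control"
) -> pd.DataFrame:
    """Per-replicate fold changes (for group-level significance testing)."""
    records = _validate(records)
    if calibrator not in set(records["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not present")
    dct = records["target_ct"].astype(float) - records["reference_ct"].astype(float)
    out = records.loc[:, ["sample_id", "group", "replicate"]].copy()
    cal_mean = float(dct[records["group"] == calibrator].mean())
    out["fold_change"] = 2.0 ** (-(dct - cal_mean))
    return out


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    stars: str  # '**' p<0.01, '*' p<0.05, 'ns' otherwise


def compare_groups(
    treated: Sequence[float], control: Sequence[float]
) -> GroupComparison:
    """Pooled-variance (classic Student) two-sided two-sample t-test."""
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return GroupComparison(statistic=float(t), p_value=float(p), stars=stars)
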