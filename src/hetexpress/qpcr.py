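"""Relative quantification of qPCR data by the 2^-ddCt method.

Technical replicates are averaged on the Ct scale; per sample,
dCt = Ct_target - Ct_reference; ddCt subtracts the calibrator group's mean
dCt; the fold change is 2 ** (-ddCt).  Amplification efficiency is fixed at 2
(the method's defining assumption); no efficiency-corrected variant is
offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ValidationError


@dataclass
class FoldChangeResult:
    """Per-sample fold changes and per-group mean +/- SD, relative to a calibrator."""

    calibrator_group: str
    per_sample: pd.DataFrame  # sample_id, group, delta_ct, ddct, fold_change
    per_group: pd.DataFrame  # group, n, mean_fold_change, sd_fold_change


def ddct_fold_change(cts: pd.DataFrame, calibrator_group: str) -> FoldChangeResult:
    """Compute 2^-ddCt fold changes from a long-format Ct table.

    ``cts`` needs columns sample_id, group, gene ('target'/'reference'), ct
    (and optionally replicate).  Every sample must carry both genes; the
    calibrator group anchors ddCt = 0 on average, so its mean ddCt is exactly
    zero and its geometric-mean fold change is 1.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(cts.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    if calibrator_group not in set(cts["group"]):
        raise ValidationError(f"calibrator group {calibrator_group!r} absent from Ct table")

    # average technical replicates on the Ct scale
    mean_ct = cts.groupby(["sample_id", "group", "gene"], sort=False)["ct"].mean().reset_index()
    wide = mean_ct.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct", aggfunc="first"
    ).reset_index()
    for col in ("target", "reference"):
        if col not in wide.columns or wide[col].isna().any():
            bad = (
                wide.loc[wide[col].isna(), "sample_id"].iloc[0]
                if col in wide.columns
                else wide["sample_id"].iloc[0]
            )
            raise ValidationError(f"sample {bad!r} lacks a {col} gene Ct")

    wide["delta_ct"] = wide["target"] - wide["reference"]
    calib_mean = wide.loc[wide["group"] == calibrator_group, "delta_ct"].mean()
    wide["ddct"] = wide["delta_ct"] - calib_mean
    wide["fold_change"] = np.power(2.0, -wide["ddct"])

    per_sample = wide[["sample_id", "group", "delta_ct", "ddct", "fold_change"]].copy()
    per_group = (
        per_sample.groupby("group", sort=False)["fold_change"]
        .agg(n="count", mean_fold_change="mean", sd_fold_change=lambda v: v.std(ddof=1))
        .reset_index()
    )
    per_group["sd_fold_change"] = per_group["sd_fold_change"].fillna(0.0)
    return FoldChangeResult(calibrator_group, per_sample, per_group)
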