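"""Mid-parent heterosis percentage and its significance test.

Mid-parent heterosis of a trait is the excess of the hybrid mean over the
average of the two parental-line means, expressed as a percentage of that
average:

    H% = 100 * (F1_bar - MP) / MP,        MP = (P1_bar + P2_bar) / 2.

Significance is assessed with a Student t statistic that treats the parental
means as fixed and the hybrid observations as the only source of sampling
noise.  Writing H (as a fraction) and s for the sample SD of the n1 hybrid
observations,

    t = H * (P1_bar + P2_bar) * sqrt(n1) / (2 * s),   df = n1 - 1,

which is algebraically the one-sample t-test of the hybrid mean against the
mid-parent constant.  A variant reading that places an extra sqrt(2) in the
standard error is available via ``t_variant="sqrt2"``; it only rescales t by
1/sqrt(2) and rarely changes a verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CROSS_GROUPS, PARENT_GROUPS, PhenotypeTable, ValidationError

T_VARIANTS = ("delta", "sqrt2")


class UndefinedHeterosisError(ValueError):
    """Mid-parent value is zero: H% is a division by zero, not infinity."""


@dataclass
class HeterosisResult:
    """Heterosis estimate and test for one cross (one sex)."""

    cross: str
    f1_mean: float
    midparent: float
    heterosis_pct: float
    t_value: float
    df: int
    p_value: float
    n1: int
    s_f1: float
    degenerate_variance: bool = False

    @property
    def significant(self) -> bool:
        """p < 0.05 (the conventional single-star level)."""
        return self.p_value < 0.05

    @property
    def extremely_significant(self) -> bool:
        """p < 0.01 (double-star level)."""
        return self.p_value < 0.01


def heterosis_percent(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """Mid-parent heterosis in percent.

    Raises :class:`UndefinedHeterosisError` when the mid-parent value is zero
    (the ratio is undefined; returning infinity would poison downstream
    arithmetic silently).
    """
    midparent = (p1_mean + p2_mean) / 2.0
    if midparent == 0:
        raise UndefinedHeterosisError("mid-parent value is zero; H% undefined")
    return 100.0 * (f1_mean - midparent) / midparent


def heterosis_t_from_summary(
    f1_mean: float,
    f1_sd: float,
    n1: int,
    p1_mean: float,
    p2_mean: float,
    cross: str = "F1A",
    t_variant: str = "delta",
) -> HeterosisResult:
    """Heterosis test from summary statistics (hybrid mean, SD, n).

    The default ``delta`` variant is the one-sample t of the hybrid mean
    against the fixed mid-parent value; ``sqrt2`` divides t by sqrt(2).
    """
    if t_variant not in T_VARIANTS:
        raise ValidationError(f"t_variant must be one of {T_VARIANTS}")
    if n1 < 2:
        raise ValidationError(f"need at least 2 hybrid observations, got {n1}")
    if f1_sd < 0:
        raise ValidationError("negative SD")
    midparent = (p1_mean + p2_mean) / 2.0
    h_pct = heterosis_percent(f1_mean, p1_mean, p2_mean)
    df = n1 - 1
    degenerate = False
    if f1_sd == 0:
        degenerate = True
        if h_pct == 0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, h_pct)
            p = 0.0
    else:
        t = (h_pct / 100.0) * (p1_mean + p2_mean) * math.sqrt(n1) / (2.0 * f1_sd)
        if t_variant == "sqrt2":
            t /= math.sqrt(2.0)
        p = 2.0 * stats.t.sf(abs(t), df)
    return HeterosisResult(
        cross=cross,
        f1_mean=float(f1_mean),
        midparent=float(midparent),
        heterosis_pct=float(h_pct),
        t_value=float(t),
        df=df,
        p_value=float(p),
        n1=int(n1),
        s_f1=float(f1_sd),
        degenerate_variance=degenerate,
    )


def heterosis_t_test(
    f1_values: Sequence[float],
    p1_mean: float,
    p2_mean: float,
    cross: str = "F1A",
    t_variant: str = "delta",
) -> HeterosisResult:
    """Heterosis test from individual hybrid observations."""
    values = np.asarray(f1_values, dtype=float)
    if values.size < 2:
        raise ValidationError(f"need at least 2 hybrid observations, got {values.size}")
    return heterosis_t_from_summary(
        f1_mean=float(values.mean()),
        f1_sd=float(values.std(ddof=1)),
        n1=int(values.size),
        p1_mean=p1_mean,
        p2_mean=p2_mean,
        cross=cross,
        t_variant=t_variant,
    )


def heterosis_report(
    pheno: PhenotypeTable, sex: str, t_variant: str = "delta"
) -> list[HeterosisResult]:
    """One :class:`HeterosisResult` per cross present in the table for ``sex``."""
    for parent in PARENT_GROUPS:
        if len(pheno.group_values(parent, sex=sex)) == 0:
            raise ValidationError(f"missing parental group {parent} for sex {sex}")
    p1 = float(pheno.group_values("P1", sex=sex).mean())
    p2 = float(pheno.group_values("P2", sex=sex).mean())
    results = []
    for cross in CROSS_GROUPS:
        values = pheno.group_values(cross, sex=sex)
        if values.size == 0:
            continue
        results.append(heterosis_t_test(values, p1, p2, cross=cross, t_variant=t_variant))
    if not results:
        raise ValidationError(f"no cross group present for sex {sex}")
    return results


class HeterosisModel:
    """Mid-parent heterosis model over an individual-level phenotype table.

    Statsmodels-style usage::

        model = HeterosisModel(pheno_table)          # or .from_dataframe(df)
        res = model.fit(sex="F")
        print(res.summary())
    """

    def __init__(self, phenotypes: PhenotypeTable, t_variant: str = "delta"):
        if t_variant not in T_VARIANTS:
            raise ValidationError(f"t_variant must be one of {T_VARIANTS}")
        self.phenotypes = phenotypes
        self.t_variant = t_variant

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, t_variant: str = "delta") -> "HeterosisModel":
        return cls(PhenotypeTable(df), t_variant=t_variant)

    def fit(self, sex: str = "F") -> "HeterosisResults":
        per_cross = heterosis_report(self.phenotypes, sex=sex, t_variant=self.t_variant)
        return HeterosisResults(self, sex, per_cross)


@dataclass
class HeterosisResults:
    """Fitted heterosis estimates for every cross of one sex."""

    model: HeterosisModel
    sex: str
    per_cross: list[HeterosisResult] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cross": r.cross,
                "sex": self.sex,
                "n1": r.n1,
                "f1_mean": r.f1_mean,
                "s_f1": r.s_f1,
                "midparent": r.midparent,
                "heterosis_pct": r.heterosis_pct,
                "t_value": r.t_value,
                "df": r.df,
                "p_value": r.p_value,
            }
            for r in self.per_cross
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.as_frame()
        lines = [
            "Mid-parent heterosis",
            "=" * 72,
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "=" * 72,
            f"t variant: {self.model.t_variant}; two-sided p, df = n1 - 1",
        ]
        return "\n".join(lines)
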