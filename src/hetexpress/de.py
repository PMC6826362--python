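"""Expression filtering and negative-binomial Wald differential expression.

The engine is deliberately self-contained and transparent rather than a
re-implementation of any particular DE package: per-gene NB dispersions are
estimated by method of moments pooled within groups (no shrinkage toward a
trend), group means are compared on library-size-normalized counts, and the
Wald statistic is the log2 fold change over its delta-method standard error
under the NB variance function var = mu + alpha * mu**2.

A "mid-parent" pseudo-group is supported as a contrast denominator: the cross
mean is tested against the average of the two parental group means, with the
variance propagated from both parental groups.  This is the contrast that
operationalizes additivity in the inheritance-mode classification.

Multiple testing is corrected per contrast with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CountMatrix, SampleSheet, ValidationError, GROUPS, PARENT_GROUPS

logger = logging.getLogger(__name__)

MIDPARENT = "MID"
LOG2 = np.log(2.0)

#: The standard contrast battery: the parental contrast, each cross against
#: each parent, and each cross against the mid-parent pseudo-group.
DEFAULT_CONTRASTS: tuple["ContrastSpec", ...]


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-sided comparison: log2(numerator / denominator).

    ``denominator`` may be the pseudo-group ``"MID"`` (average of the two
    parental group means)."""

    name: str
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator not in GROUPS:
            raise ValidationError(f"unknown numerator group {self.numerator!r}")
        if self.denominator not in GROUPS + (MIDPARENT,):
            raise ValidationError(f"unknown denominator group {self.denominator!r}")


DEFAULT_CONTRASTS = (
    ContrastSpec("P2_vs_P1", "P2", "P1"),
    ContrastSpec("F1A_vs_P1", "F1A", "P1"),
    ContrastSpec("F1A_vs_P2", "F1A", "P2"),
    ContrastSpec("F1B_vs_P1", "F1B", "P1"),
    ContrastSpec("F1B_vs_P2", "F1B", "P2"),
    ContrastSpec("F1A_vs_MID", "F1A", MIDPARENT),
    ContrastSpec("F1B_vs_MID", "F1B", MIDPARENT),
)


@dataclass
class ContrastResult:
    """Per-gene DE statistics for one contrast.

    ``table`` is indexed by gene id with columns ``log2fc``, ``se``, ``stat``,
    ``pvalue`` and ``padj`` (BH within this contrast)."""

    name: str
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# FPKM and filtering
# ---------------------------------------------------------------------------


def compute_fpkm(
    counts: CountMatrix, library_sizes: Mapping[str, float] | str = "column-sum"
) -> pd.DataFrame:
    """FPKM_{g,s} = count_{g,s} * 1e9 / (length_g * library_size_s).

    ``library_sizes`` is either an explicit per-sample mapping or the string
    ``"column-sum"`` to use total counts per sample.
    """
    if isinstance(library_sizes, str):
        if library_sizes != "column-sum":
            raise ValidationError(f"unknown library size rule {library_sizes!r}")
        libs = counts.library_sizes.astype(float)
    else:
        libs = pd.Series({s: float(library_sizes[s]) for s in counts.sample_ids})
    if (libs <= 0).any():
        bad = libs.index[libs <= 0][0]
        raise ValidationError(f"non-positive library size for sample {bad!r}")
    lengths = counts.gene_lengths.astype(float)
    fpkm = counts.counts.astype(float).mul(1e9).div(lengths, axis=0).div(libs, axis=1)
    return fpkm


def filter_low_expression(fpkm: pd.DataFrame, threshold: float = 1.0) -> list[str]:
    """Genes retained by the low-expression filter.

    A gene is kept iff its mean FPKM across *all* samples is >= ``threshold``
    (i.e. genes with average FPKM below the threshold are removed).
    """
    mean_fpkm = fpkm.mean(axis=1)
    return fpkm.index[mean_fpkm >= threshold].tolist()


# ---------------------------------------------------------------------------
# Normalization and dispersion
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix, method: str = "median-of-ratios") -> pd.Series:
    """Per-sample scaling factors.

    ``median-of-ratios`` (default): the classic per-sample median of count
    ratios to the per-gene geometric-mean reference (computed over genes with
    no zero count).  Chosen as the default because it is robust to
    composition bias — a handful of strongly shifted genes (e.g.
    over-dominant genes inflating the cross libraries) moves column totals
    but not the median ratio.  ``column-ratio``: each column's total count
    divided by the geometric mean of all column totals; simpler, but biased
    whenever differential expression is not balanced across groups.
    """
    totals = counts.library_sizes.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    if method == "column-ratio":
        geo = np.exp(np.log(totals).mean())
        return totals / geo
    if method == "median-of-ratios":
        mat = counts.counts.to_numpy(dtype=float)
        positive = (mat > 0).all(axis=1)
        if not positive.any():
            raise ValidationError("median-of-ratios needs at least one all-positive gene")
        logs = np.log(mat[positive])
        ref = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - ref, axis=0))
        return pd.Series(factors, index=counts.counts.columns)
    raise ValidationError(f"unknown normalization method {method!r}")


def normalize_counts(counts: CountMatrix, method: str = "median-of-ratios") -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    return counts.counts.astype(float).div(size_factors(counts, method), axis=1)


def estimate_dispersions(
    counts: CountMatrix,
    samples: SampleSheet,
    alpha_floor: float = 1e-8,
    normalization: str = "median-of-ratios",
    moderation: str = "median-max",
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, pooled within groups.

    For each gene, within-group sample variances of normalized counts are
    pooled with their degrees of freedom, and

        alpha = max(alpha_floor, (pooled_var - pooled_mean) / pooled_mean**2).

    Genes with degenerate variance (or at/below the Poisson limit) land on the
    floor.

    With ``moderation="median-max"`` (the default) each gene's dispersion is
    additionally floored at the experiment-wide median of the raw estimates.
    The raw moment estimate is roughly unbiased but noisy at typical replicate
    numbers, and genes whose dispersion happens to be underestimated dominate
    the false-positive rate of the downstream Wald test; taking the maximum of
    the per-gene and central values restores calibration at a small, uniform
    cost in power.  ``moderation="none"`` returns the raw per-gene estimates.
    """
    norm = normalize_counts(counts, normalization)
    num = np.zeros(len(norm))
    df_total = 0
    mean_acc = np.zeros(len(norm))
    n_total = 0
    for group in GROUPS:
        cols = samples.samples_of(group)
        cols = [c for c in cols if c in norm.columns]
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        num += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        df_total += len(cols) - 1
        mean_acc += sub.sum(axis=1)
        n_total += len(cols)
    if df_total == 0:
        raise ValidationError("no group with >= 2 samples; cannot estimate dispersion")
    pooled_var = num / df_total
    pooled_mean = mean_acc / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / np.square(pooled_mean)
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    alpha = np.maximum(alpha, alpha_floor)
    if moderation == "median-max":
        alpha = np.maximum(alpha, float(np.median(alpha)))
    elif moderation != "none":
        raise ValidationError(f"unknown moderation {moderation!r}")
    return pd.Series(alpha, index=norm.index, name="alpha")


def estimate_dispersion(
    counts: CountMatrix, samples: SampleSheet, gene: str, alpha_floor: float = 1e-8
) -> float:
    """Dispersion for a single gene (convenience wrapper)."""
    return float(estimate_dispersions(counts, samples, alpha_floor).loc[gene])


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------


def _group_mean_and_var(
    norm: pd.DataFrame, samples: SampleSheet, group: str, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in samples.samples_of(group) if c in norm.columns]
    if len(cols) < 2:
        raise ValidationError(f"contrast side {group} has {len(cols)} sample(s); need >= 2")
    sub = norm[cols].to_numpy()
    m = sub.mean(axis=1)
    # variance of the group mean under NB noise, evaluated at the estimate
    var_mean = (m + alpha * np.square(m)) / len(cols)
    return m, var_mean


def nb_wald_test(
    counts: CountMatrix,
    samples: SampleSheet,
    contrast: ContrastSpec,
    dispersions: pd.Series,
    pseudo_mean: float = 0.5,
    normalization: str = "median-of-ratios",
) -> ContrastResult:
    """Wald test of log2(numerator mean / denominator mean) for every gene.

    Group means are computed on normalized counts; a pseudo-mean ``c`` guards
    the log against zero means: log2FC = log2((m_num + c) / (m_den + c)).
    The delta-method SE combines the NB variance of each side's mean; for the
    mid-parent denominator the parental variances are averaged with weight
    1/4 each (variance of the mean of two independent group means).  p-values
    are two-sided Gaussian; BH adjustment is applied within the contrast.
    """
    norm = normalize_counts(counts, normalization)
    alpha = dispersions.reindex(norm.index).to_numpy(dtype=float)
    if np.isnan(alpha).any():
        missing = norm.index[np.isnan(alpha)][0]
        raise ValidationError(f"no dispersion estimate for gene {missing!r}")

    m_num, var_num = _group_mean_and_var(norm, samples, contrast.numerator, alpha)
    if contrast.denominator == MIDPARENT:
        m_p1, var_p1 = _group_mean_and_var(norm, samples, "P1", alpha)
        m_p2, var_p2 = _group_mean_and_var(norm, samples, "P2", alpha)
        m_den = (m_p1 + m_p2) / 2.0
        var_den = (var_p1 + var_p2) / 4.0
    else:
        m_den, var_den = _group_mean_and_var(norm, samples, contrast.denominator, alpha)

    c = float(pseudo_mean)
    log2fc = np.log2(m_num + c) - np.log2(m_den + c)
    se = np.sqrt(
        var_num / np.square((m_num + c) * LOG2) + var_den / np.square((m_den + c) * LOG2)
    )
    se = np.maximum(se, 1e-12)
    stat = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=norm.index,
    )
    return ContrastResult(contrast.name, table)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrasts(
    counts: CountMatrix,
    samples: SampleSheet,
    specs: Sequence[ContrastSpec] = DEFAULT_CONTRASTS,
    pseudo_mean: float = 0.5,
    normalization: str = "median-of-ratios",
    alpha_floor: float = 1e-8,
) -> dict[str, ContrastResult]:
    """Run the contrast battery on a (already expression-filtered) matrix.

    BH is applied within each contrast separately, matching the practice of
    running each pairwise comparison as an independent analysis.
    """
    if len(counts.gene_ids) == 0:
        logger.warning("no genes passed the expression filter; empty contrast results")
        return {spec.name: ContrastResult(spec.name, _empty_table()) for spec in specs}
    samples.validate_against(counts)
    dispersions = estimate_dispersions(counts, samples, alpha_floor, normalization)
    return {
        spec.name: nb_wald_test(
            counts, samples, spec, dispersions, pseudo_mean, normalization
        )
        for spec in specs
    }


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["log2fc", "se", "stat", "pvalue", "padj"])


class NBExpressionModel:
    """Negative-binomial DE model over a reciprocal-cross count matrix.

    Statsmodels-style facade over the functional engine::

        model = NBExpressionModel(counts, samples)
        res = model.fit()                  # filter + dispersions + contrasts
        res.contrast("P2_vs_P1").table     # per-gene statistics
        print(res.summary())
    """

    def __init__(
        self,
        counts: CountMatrix,
        samples: SampleSheet,
        fpkm_threshold: float = 1.0,
        pseudo_mean: float = 0.5,
        normalization: str = "median-of-ratios",
        alpha_floor: float = 1e-8,
    ):
        samples.validate_against(counts)
        self.counts = counts
        self.samples = samples
        self.fpkm_threshold = fpkm_threshold
        self.pseudo_mean = pseudo_mean
        self.normalization = normalization
        self.alpha_floor = alpha_floor

    def fit(self, specs: Sequence[ContrastSpec] = DEFAULT_CONTRASTS) -> "NBExpressionResults":
        fpkm = compute_fpkm(self.counts)
        retained = filter_low_expression(fpkm, self.fpkm_threshold)
        filtered = self.counts.subset_genes(retained)
        results = run_contrasts(
            filtered,
            self.samples,
            specs,
            pseudo_mean=self.pseudo_mean,
            normalization=self.normalization,
            alpha_floor=self.alpha_floor,
        )
        dispersions = (
            estimate_dispersions(filtered, self.samples, self.alpha_floor, self.normalization)
            if retained
            else pd.Series(dtype=float)
        )
        return NBExpressionResults(
            model=self,
            retained_genes=retained,
            n_input_genes=len(self.counts.gene_ids),
            dispersions=dispersions,
            contrasts=results,
        )


@dataclass
class NBExpressionResults:
    model: NBExpressionModel
    retained_genes: list[str]
    n_input_genes: int
    dispersions: pd.Series
    contrasts: dict[str, ContrastResult] = field(default_factory=dict)

    def contrast(self, name: str) -> ContrastResult:
        if name not in self.contrasts:
            raise KeyError(f"no contrast {name!r}; have {sorted(self.contrasts)}")
        return self.contrasts[name]

    def n_significant(self, alpha: float = 0.05) -> dict[str, int]:
        return {
            name: int((res.table["padj"] < alpha).sum()) for name, res in self.contrasts.items()
        }

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Negative-binomial Wald differential expression",
            "=" * 60,
            f"genes in: {self.n_input_genes}; retained after mean-FPKM >= "
            f"{self.model.fpkm_threshold}: {len(self.retained_genes)}",
            f"significant genes per contrast (BH-adjusted p < {alpha}):",
        ]
        for name, n in self.n_significant(alpha).items():
            lines.append(f"  {name:<12} {n}")
        lines.append("=" * 60)
        return "\n".join(lines)
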