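"""Self-evaluation utilities: mode-recovery and test-calibration simulations.

These run the full engine on synthetic data with known ground truth and
measure how well the planted structure is recovered — the package's own
benchmark, used by the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountMatrix, SampleSheet
from .de import (
    ContrastSpec,
    compute_fpkm,
    estimate_dispersions,
    filter_low_expression,
    nb_wald_test,
    run_contrasts,
)
from .modes import ModeCall, classify_all
from .simulate import SimulationConfig, generate_counts


@dataclass
class RecoveryReport:
    """Per-mode recovery of planted inheritance categories in one cross."""

    cross: str
    n_genes: int
    n_retained: int
    recovery: dict[str, float]  # planted mode -> fraction receiving that category
    conserved_false_call_rate: float  # conserved genes assigned any real category
    calls: list[ModeCall]
    truth: pd.DataFrame


def mode_recovery(
    config: SimulationConfig,
    cross: str = "F1A",
    alpha: float = 0.05,
    fpkm_threshold: float = 1.0,
) -> RecoveryReport:
    """Simulate, run filtering + contrasts + classification, score vs truth.

    Recovery of a planted mode is the fraction of *all* genes planted in that
    mode (whether or not they survive the expression filter) whose call in
    ``cross`` carries the matching category.  The conserved false-call rate is
    the fraction of planted-conserved genes assigned any of the five real
    categories (unclassified or ``other`` both count as correct nulls).
    """
    counts, samples, truth = generate_counts(config)
    fpkm = compute_fpkm(counts)
    retained = filter_low_expression(fpkm, fpkm_threshold)
    filtered = counts.subset_genes(retained)
    results = run_contrasts(filtered, samples)
    calls = classify_all(results, cross=cross, alpha=alpha)
    call_category = {c.gene_id: c.category for c in calls}

    mode_to_category = {
        "additive": "additive",
        "high_parent": "high_parent",
        "low_parent": "low_parent",
        "over": "over",
        "under": "under",
    }
    recovery: dict[str, float] = {}
    for mode, category in mode_to_category.items():
        planted = truth.index[truth["mode"] == mode]
        if len(planted) == 0:
            continue
        hits = sum(call_category.get(g) == category for g in planted)
        recovery[mode] = hits / len(planted)

    conserved = truth.index[truth["mode"] == "conserved"]
    if len(conserved) > 0:
        false_calls = sum(
            call_category.get(g, "other") not in (None, "other") for g in conserved
        )
        false_rate = false_calls / len(conserved)
    else:
        false_rate = float("nan")
    return RecoveryReport(
        cross=cross,
        n_genes=len(truth),
        n_retained=len(retained),
        recovery=recovery,
        conserved_false_call_rate=false_rate,
        calls=calls,
        truth=truth,
    )


def wald_type1_error(
    n_genes: int = 5000,
    n_per_group: int = 6,
    mean: float = 100.0,
    dispersion: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the NB Wald test under the null.

    Simulates ``n_genes`` genes with identical means in two groups of
    ``n_per_group`` NB(mean, dispersion) samples, runs the full engine
    (normalization, moment dispersion, Wald), and reports the fraction of raw
    p-values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion, size=(n_genes, n_samples))
    mat = rng.poisson(lam).astype(np.int64)
    gene_ids = [f"N{i}" for i in range(n_genes)]
    sample_ids = [f"P1_{i}" for i in range(n_per_group)] + [
        f"P2_{i}" for i in range(n_per_group)
    ]
    counts = CountMatrix(
        pd.DataFrame(mat, index=gene_ids, columns=sample_ids),
        pd.Series(1000, index=pd.Index(gene_ids)),
    )
    sheet = SampleSheet(
        {s: ("P1" if s.startswith("P1") else "P2") for s in sample_ids}
    )
    dispersions = estimate_dispersions(counts, sheet)
    res = nb_wald_test(counts, sheet, ContrastSpec("P2_vs_P1", "P2", "P1"), dispersions)
    return float((res.table["pvalue"] < alpha).mean())


def heterosis_type1_error(
    n_reps: int = 2000,
    n1: int = 10,
    p1_mean: float = 2.0,
    p2_mean: float = 1.0,
    sd: float = 0.4,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical size of the heterosis t-test under H0 (F1 mean = mid-parent).

    Vectorized: draws ``n_reps`` Gaussian F1 samples centred at the mid-parent
    and reports the fraction of two-sided p-values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    midparent = (p1_mean + p2_mean) / 2.0
    draws = rng.normal(midparent, sd, size=(n_reps, n1))
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    t = (means - midparent) * np.sqrt(n1) / sds
    p = 2.0 * stats.t.sf(np.abs(t), n1 - 1)
    return float((p < alpha).mean())
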