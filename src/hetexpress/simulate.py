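"""Synthetic reciprocal-cross data with known ground-truth inheritance modes.

The generator emulates a four-group design (two purebred parental lines plus
both cross directions) at bulk RNA-seq scale: negative-binomial counts around
mode-specific group means, plus truncated-Gaussian phenotypes.  Every gene is
planted in one of six expression inheritance modes:

``conserved``
    all four group means equal (the null; most of the transcriptome);
``additive``
    parents differ by ``parent_log2_diff`` on the log2 scale, both crosses sit
    at the parental arithmetic mean;
``high_parent`` / ``low_parent``
    crosses equal the higher / lower parent;
``over`` / ``under``
    crosses shifted ``dominance_log2_shift`` log2 units above the higher /
    below the lower parent.

Counts follow NB with variance mu + alpha * mu**2 (the standard count-model
parameterization), drawn via the gamma-Poisson mixture.  A fixed seed makes
every output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CROSS_GROUPS,
    GROUPS,
    CountMatrix,
    PhenotypeTable,
    SampleSheet,
    ValidationError,
)

MODES = ("conserved", "additive", "high_parent", "low_parent", "over", "under")

#: Reference library size at which ``baseline_mean`` is the expected count.
REFERENCE_LIBRARY_SIZE = 1_000_000

#: Default group composition of the planted transcriptome: dominance modes
#: outnumber over-/under-dominance (the typical non-additive spectrum in
#: crosses), with conserved genes as the bulk null background.
DEFAULT_GENES_PER_MODE = {
    "conserved": 600,
    "additive": 100,
    "high_parent": 100,
    "low_parent": 100,
    "over": 50,
    "under": 50,
}

#: Default per-group abdominal-fat-percentage (mean, sd) for female birds:
#: fat-line parent ~1.9%, lean-line parent ~0%, crosses above the mid-parent.
DEFAULT_PHENOTYPE_MEANS_SDS = {
    "P1": (1.86, 0.35),
    "P2": (0.00, 0.00),
    "F1A": (2.14, 0.40),
    "F1B": (1.65, 0.70),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic reciprocal-cross experiment.

    Attributes
    ----------
    seed
        RNG seed; fixed seed implies bit-identical output.
    n_per_group
        Biological replicates per group (int, or mapping group -> int).
    genes_per_mode
        Number of genes planted in each inheritance mode.
    baseline_mean
        Median expected count of a gene at the reference library size (1e6);
        per-gene baselines are drawn log-normally around it.
    baseline_log_sd
        SD of the per-gene log-normal baseline draw (natural-log scale).
    parent_log2_diff
        Magnitude of the log2 expression difference between the parental
        lines for every non-conserved gene; which parent is the higher one is
        drawn 50/50 per gene (both lines harbor up- and down-regulated genes,
        which also keeps library compositions balanced across groups).
    dominance_log2_shift
        log2 shift of the crosses above the higher parent (``over``) or below
        the lower parent (``under``).
    dispersion
        NB dispersion alpha in var = mu + alpha * mu**2.
    library_sizes
        Optional explicit per-sample library sizes; by default drawn uniformly
        in [0.8e6, 1.2e6] to mimic modest depth variation between libraries.
    length_range
        (min, max) transcript length in bp, drawn uniformly per gene.
    f1b_extra_log2_shift
        Optional cross-specific log2 shift applied to the second cross's mean,
        breaking reciprocal symmetry (e.g. to exercise asymmetric mode calls).
        Zero by default: the two cross directions share identical means.
    phenotype_means_sds
        Per-group (mean, sd) of the phenotype; Gaussian noise truncated at 0
        (the trait is a percentage).
    phenotype_sexes
        Sexes to generate phenotype records for.
    """

    seed: int = 0
    n_per_group: int | Mapping[str, int] = 6
    genes_per_mode: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_MODE)
    )
    baseline_mean: float = 100.0
    baseline_log_sd: float = 1.0
    parent_log2_diff: float = 2.0
    dominance_log2_shift: float = 1.5
    dispersion: float = 0.05
    library_sizes: Sequence[int] | None = None
    length_range: tuple[int, int] = (200, 3000)
    f1b_extra_log2_shift: float = 0.0
    phenotype_means_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MEANS_SDS)
    )
    phenotype_sexes: tuple[str, ...] = ("F",)

    def group_n(self, group: str) -> int:
        if isinstance(self.n_per_group, Mapping):
            return int(self.n_per_group[group])
        return int(self.n_per_group)

    def validate(self) -> None:
        unknown = set(self.genes_per_mode) - set(MODES)
        if unknown:
            raise ValidationError(f"unknown modes in genes_per_mode: {sorted(unknown)}")
        if sum(self.genes_per_mode.values()) <= 0:
            raise ValidationError("zero genes requested")
        if any(v < 0 for v in self.genes_per_mode.values()):
            raise ValidationError("negative gene count in genes_per_mode")
        for g in GROUPS:
            if self.group_n(g) < 2:
                raise ValidationError(
                    f"n_per_group for {g} is {self.group_n(g)}; at least 2 needed for contrasts"
                )
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        for g, (_, sd) in self.phenotype_means_sds.items():
            if sd < 0:
                raise ValidationError(f"negative phenotype sd for group {g}")


def mode_group_means(mode: str, baseline: float, parent_log2_diff: float,
                     dominance_log2_shift: float) -> dict[str, float]:
    """Noiseless group means implied by an inheritance mode.

    The two parents straddle ``baseline`` symmetrically on the log2 scale
    (``parent_log2_diff`` may be signed: positive puts P1 on top); the cross
    means then follow the mode definition exactly (arithmetic mid-parent for
    ``additive``, higher/lower parent for the dominance modes, shifted beyond
    the parental range for over-/under-dominance).
    """
    if mode == "conserved":
        return {g: baseline for g in GROUPS}
    half = parent_log2_diff / 2.0
    p1 = baseline * 2.0 ** half
    p2 = baseline * 2.0 ** (-half)
    hi, lo = max(p1, p2), min(p1, p2)
    if mode == "additive":
        f1 = (p1 + p2) / 2.0
    elif mode == "high_parent":
        f1 = hi
    elif mode == "low_parent":
        f1 = lo
    elif mode == "over":
        f1 = hi * 2.0 ** dominance_log2_shift
    elif mode == "under":
        f1 = lo * 2.0 ** (-dominance_log2_shift)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return {"P1": p1, "P2": p2, "F1A": f1, "F1B": f1}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) via the gamma-Poisson mixture."""
    if alpha <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=mean * alpha)
    return rng.poisson(lam)


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Simulate a count matrix, its sample sheet, and the ground-truth table.

    Returns
    -------
    counts : CountMatrix
    samples : SampleSheet
    truth : DataFrame
        One row per gene: ``gene_id``, ``mode`` and the four noiseless group
        means (``mean_P1`` ... ``mean_F1B``) at the reference library size.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for group in GROUPS:
        for i in range(config.group_n(group)):
            sid = f"{group}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = group
    n_samples = len(sample_ids)

    if config.library_sizes is not None:
        if len(config.library_sizes) != n_samples:
            raise ValidationError(
                f"library_sizes has {len(config.library_sizes)} entries for {n_samples} samples"
            )
        lib_sizes = np.asarray(config.library_sizes, dtype=float)
        if (lib_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
    else:
        lib_sizes = rng.uniform(0.8, 1.2, size=n_samples) * REFERENCE_LIBRARY_SIZE
    lib_factor = lib_sizes / REFERENCE_LIBRARY_SIZE

    gene_rows = []
    for mode in MODES:  # fixed mode order keeps gene ids stable across configs
        for _ in range(int(config.genes_per_mode.get(mode, 0))):
            gene_rows.append(mode)
    n_genes = len(gene_rows)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    baselines = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=n_genes)
    )
    # which parent sits on top, per gene (50/50); keeps group library
    # compositions balanced and exercises both subtype directions
    parent_sign = rng.choice([-1.0, 1.0], size=n_genes)

    truth_records = []
    mean_matrix = np.empty((n_genes, n_samples))
    group_of_sample = np.array([groups[s] for s in sample_ids])
    for i, (gid, mode) in enumerate(zip(gene_ids, gene_rows)):
        means = mode_group_means(
            mode,
            baselines[i],
            parent_sign[i] * config.parent_log2_diff,
            config.dominance_log2_shift,
        )
        if config.f1b_extra_log2_shift and mode != "conserved":
            means["F1B"] = means["F1B"] * 2.0 ** config.f1b_extra_log2_shift
        truth_records.append(
            {
                "gene_id": gid,
                "mode": mode,
                "mean_P1": means["P1"],
                "mean_P2": means["P2"],
                "mean_F1A": means["F1A"],
                "mean_F1B": means["F1B"],
            }
        )
        mean_matrix[i, :] = [means[g] for g in group_of_sample]

    scaled_means = mean_matrix * lib_factor[np.newaxis, :]
    counts = _nb_draw(rng, scaled_means, config.dispersion).astype(np.int64)

    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1] + 1, size=n_genes),
        index=pd.Index(gene_ids, name="gene_id"),
        name="length_bp",
    )
    count_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    truth = pd.DataFrame(truth_records).set_index("gene_id")
    return CountMatrix(count_df, lengths), SampleSheet(groups), truth


def generate_phenotypes(config: SimulationConfig) -> PhenotypeTable:
    """Simulate individual phenotypes: Gaussian around each group mean with the
    configured SD, truncated at zero (the trait is a non-negative percentage)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # decoupled from the count stream
    rows = []
    for sex in config.phenotype_sexes:
        for group, (mean, sd) in config.phenotype_means_sds.items():
            if group not in GROUPS:
                raise ValidationError(f"unknown phenotype group {group!r}")
            n = config.group_n(group)
            values = np.clip(rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean), 0, None)
            for i, v in enumerate(values):
                rows.append(
                    {
                        "individual_id": f"{group}_{sex}_{i + 1}",
                        "group": group,
                        "sex": sex,
                        "trait": float(v),
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
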