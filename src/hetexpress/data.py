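"""Core data containers and readers/writers for the tabular formats the pipeline touches.

The analysis operates on a four-group reciprocal-cross design: two purebred
parental lines (``P1``, ``P2``) and the two cross directions (``F1A`` = P1 sire
x P2 dam, ``F1B`` = P2 sire x P1 dam).  External labels (e.g. breed codes like
CC/RR/CR/RC) are mapped onto this fixed internal vocabulary at read time so the
statistics below are not tied to any particular organism or breed naming.

All on-disk formats are plain text: TSV for counts, gene lengths, sample
sheets and Ct tables; CSV or TSV for phenotypes; GMT for gene-set collections.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal group vocabulary: two parental lines and the two reciprocal crosses.
GROUPS = ("P1", "P2", "F1A", "F1B")
PARENT_GROUPS = ("P1", "P2")
CROSS_GROUPS = ("F1A", "F1B")
SEXES = ("F", "M")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant (duplicates, negatives, ...)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with gene ids as the index and sample ids as columns.
        Values must be non-negative integers (sequencing reads are counts;
        fractional values indicate a unit mistake and are rejected).
    gene_lengths
        Series of positive transcript lengths in bp, indexed by gene id.
        Every gene in ``counts`` must have a length.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {idx[g]!r}, sample {self.counts.columns[s]!r}"
            )
        missing = idx.difference(self.gene_lengths.index)
        if len(missing) > 0:
            raise ValidationError(f"genes without a length entry: {missing[:5].tolist()}")
        self.gene_lengths = self.gene_lengths.loc[idx].astype(np.int64)
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths[self.gene_lengths <= 0].index[0]
            raise ValidationError(f"non-positive length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        """Restrict to ``genes``, preserving the given order."""
        return CountMatrix(self.counts.loc[list(genes)], self.gene_lengths.loc[list(genes)])


@dataclass
class SampleSheet:
    """Assignment of each sample to one of the four design groups."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")

    def samples_of(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
        return [s for s, g in self.groups.items() if g == group]

    def validate_against(self, counts: CountMatrix, min_per_group: int = 2) -> None:
        sheet = set(self.groups)
        matrix = set(counts.sample_ids)
        if sheet != matrix:
            raise ValidationError(
                f"sample sheet / count matrix mismatch: only in sheet {sorted(sheet - matrix)[:5]}, "
                f"only in matrix {sorted(matrix - sheet)[:5]}"
            )
        for group in GROUPS:
            n = len(self.samples_of(group))
            if 0 < n < min_per_group:
                raise ValidationError(
                    f"group {group} has {n} sample(s); at least {min_per_group} required"
                )


@dataclass
class PhenotypeTable:
    """Individual-level trait records (e.g. abdominal fat percentage)."""

    records: pd.DataFrame  # columns: individual_id, group, sex, trait

    REQUIRED = ("individual_id", "group", "sex", "trait")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = self.records
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ValidationError(
                f"unknown group labels {sorted(bad_groups)}; map external labels via group_map"
            )
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex labels {sorted(bad_sex)}; expected {SEXES}")
        trait = pd.to_numeric(df["trait"], errors="coerce")
        if trait.isna().any() or not np.isfinite(trait).all():
            raise ValidationError("non-numeric or non-finite trait values")
        if (trait < 0).any():
            ind = df.loc[trait < 0, "individual_id"].iloc[0]
            raise ValidationError(f"negative trait value for individual {ind!r}")
        self.records = df.assign(trait=trait.astype(float)).reset_index(drop=True)

    def subset(self, sex: str | None = None, group: str | None = None) -> pd.DataFrame:
        df = self.records
        if sex is not None:
            df = df[df["sex"] == sex]
        if group is not None:
            df = df[df["group"] == group]
        return df

    def group_values(self, group: str, sex: str | None = None) -> np.ndarray:
        return self.subset(sex=sex, group=group)["trait"].to_numpy()


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. pathway memberships."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, lengths_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus a gene-length TSV.

    The count file has a header row of sample ids with gene ids in the first
    column.  Counts must be integral; a fractional value such as ``12.5`` is a
    :class:`FormatError` naming the offending cell (it usually means an FPKM
    table was supplied where raw counts were expected).  Genes missing from
    the length table are dropped with a warning.
    """
    path, lengths_path = Path(path), Path(lengths_path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s) in {path.name}: {dupes[:5]}")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            gene = raw.index[vals.isna()][0]
            raise FormatError(
                f"non-numeric count {raw.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        frac = vals % 1 != 0
        if frac.any():
            gene = raw.index[frac][0]
            raise FormatError(
                f"non-integer count {raw.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        if (vals < 0).any():
            gene = raw.index[vals < 0][0]
            raise FormatError(f"negative count at gene {gene!r}, sample {col!r}")
        numeric[col] = vals.astype(np.int64)

    lengths = read_gene_lengths(lengths_path)
    missing = numeric.index.difference(lengths.index)
    if len(missing) > 0:
        logger.warning(
            "dropping %d gene(s) lacking a length entry (e.g. %s)",
            len(missing),
            missing[:3].tolist(),
        )
        numeric = numeric.drop(index=missing)
    return CountMatrix(numeric, lengths)


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["gene_id", "length_bp"]:
        raise FormatError(
            f"{Path(path).name}: expected header 'gene_id\\tlength_bp', got {list(df.columns[:2])}"
        )
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene id in length table")
    lengths = df.set_index("gene_id")["length_bp"]
    if (pd.to_numeric(lengths, errors="coerce").fillna(-1) <= 0).any():
        raise ValidationError("gene lengths must be positive integers")
    return lengths.astype(np.int64)


def write_count_matrix(cm: CountMatrix, path: str | Path, lengths_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    cm.gene_lengths.rename("length_bp").rename_axis("gene_id").to_csv(lengths_path, sep="\t")


def read_sample_sheet(path: str | Path, group_map: Mapping[str, str] | None = None) -> SampleSheet:
    """Read a two-column TSV (``sample_id``, ``group``), applying ``group_map``
    to translate external group labels into the internal P1/P2/F1A/F1B set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise FormatError("sample sheet needs header 'sample_id\\tgroup'")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample id in sample sheet")
    mapping = dict(group_map or {})
    groups = {
        row.sample_id: mapping.get(row.group, row.group) for row in df.itertuples(index=False)
    }
    return SampleSheet(groups)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(sheet.groups), "group": list(sheet.groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, group_map: Mapping[str, str] | None = None) -> PhenotypeTable:
    """Read an individual-level phenotype table (CSV or TSV, sniffed from the
    file extension).  Columns: individual_id, group, sex, trait."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "group": str, "sex": str})
    if group_map:
        df["group"] = df["group"].map(lambda g: group_map.get(g, g))
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.records.to_csv(path, sep=sep, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    then member gene ids.  Duplicate members within a line are deduplicated."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{Path(path).name}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r} at line {lineno}")
            members = frozenset(m for m in fields[2:] if m)
            sets[name] = GeneSet(name, description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: TSV with columns sample_id, group, gene, ct,
    replicate; ``gene`` is 'target' or 'reference'."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    required = ["sample_id", "group", "gene", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"Ct table missing columns: {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any() or not np.isfinite(ct).all():
        raise ValidationError("non-finite Ct value in Ct table")
    bad = set(df["gene"]) - {"target", "reference"}
    if bad:
        raise ValidationError(f"gene column must be 'target' or 'reference'; got {sorted(bad)}")
    return df.assign(ct=ct.astype(float))
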