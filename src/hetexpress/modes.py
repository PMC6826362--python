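"""Classification of genes into inheritance-mode types and categories.

For each cross, every gene that is differentially expressed in at least one
pairwise contrast (parents, cross vs P1, cross vs P2) is assigned one of
twelve types, which collapse into five biological categories:

=============  =========================================================
category       types  — defining pattern (all at BH-adjusted p < alpha)
=============  =========================================================
additive       I, XII — parents differ, cross indistinguishable from the
                        mid-parent value and its point estimate strictly
                        between the parents (I when P1 > P2, XII when
                        P2 > P1)
high_parent    II, IV — cross matches the higher parent and is
                        significantly above the lower (II: higher = P1)
low_parent     IX, XI — cross matches the lower parent and is
                        significantly below the higher (IX: lower = P1)
over           V, VI, VIII — cross significantly above BOTH parents
                        (V: P1 > P2, VIII: P2 > P1, VI: parents equal)
under          III, VII, X — cross significantly below BOTH parents
                        (III: P1 > P2, X: P2 > P1, VII: parents equal)
other          none   — any pattern no rule covers (e.g. above one parent
                        and below the other, or a lone parental difference
                        with the cross off the mid-parent)
=============  =========================================================

Additivity is operationalized with an explicit mid-parent Wald contrast (the
cross's mean tested against the average of the parental means).  Where the
additive rule and a dominance rule could both fire (a cross indistinguishable
from both the mid-parent and one parent), the dominance pattern wins: in the
twelve-bin scheme the pattern "cross equals one parent, differs from the
other" is the definition of the dominance bins, whereas additivity is the
residual intermediate state, so the mid-parent test only decides genes that
match no pairwise dominance pattern.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data import CROSS_GROUPS, ValidationError
from .de import ContrastResult

CALLS = ("up", "down", "ns")
TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")
CATEGORIES = ("additive", "high_parent", "low_parent", "over", "under", "other")
NONADDITIVE_CATEGORIES = ("high_parent", "low_parent", "over", "under")

TYPE_TO_CATEGORY = {
    "I": "additive",
    "XII": "additive",
    "II": "high_parent",
    "IV": "high_parent",
    "IX": "low_parent",
    "XI": "low_parent",
    "V": "over",
    "VI": "over",
    "VIII": "over",
    "III": "under",
    "VII": "under",
    "X": "under",
}


@dataclass(frozen=True)
class Evidence:
    """Direction calls for one gene in one cross.

    ``parents`` is the call of the P2-vs-P1 contrast (``up`` = P2 higher);
    ``f1_vs_p1`` / ``f1_vs_p2`` are the cross against each parent;
    ``f1_vs_mid`` is the cross against the mid-parent pseudo-group.
    ``sign_f1_vs_p1`` / ``sign_f1_vs_p2`` carry the sign (+1/0/-1) of the
    fold-change point estimates, needed for the strictly-between condition of
    additivity even when a call is non-significant.
    """

    parents: str
    f1_vs_p1: str
    f1_vs_p2: str
    f1_vs_mid: str
    sign_f1_vs_p1: int
    sign_f1_vs_p2: int

    def __post_init__(self) -> None:
        for name in ("parents", "f1_vs_p1", "f1_vs_p2", "f1_vs_mid"):
            if getattr(self, name) not in CALLS:
                raise ValidationError(f"{name} call must be one of {CALLS}")
        for call, sign in (
            (self.f1_vs_p1, self.sign_f1_vs_p1),
            (self.f1_vs_p2, self.sign_f1_vs_p2),
        ):
            if sign not in (-1, 0, 1):
                raise ValidationError("signs must be -1, 0 or +1")
            if call == "up" and sign <= 0 or call == "down" and sign >= 0:
                raise ValidationError(f"call {call!r} inconsistent with estimate sign {sign}")


@dataclass
class ModeCall:
    gene_id: str
    cross: str
    type_label: str  # one of TYPES or "none"
    category: str
    evidence: Evidence


def _direction(log2fc: float, padj: float, alpha: float) -> str:
    if padj < alpha:
        return "up" if log2fc > 0 else "down"
    return "ns"


def call_directions(
    parent_row: Mapping[str, float],
    f1_vs_p1_row: Mapping[str, float],
    f1_vs_p2_row: Mapping[str, float],
    f1_vs_mid_row: Mapping[str, float],
    alpha: float = 0.05,
) -> Evidence:
    """Map the four contrast rows of one gene to an :class:`Evidence` tuple.

    Each row needs ``log2fc`` and ``padj``; significance is the strict
    inequality padj < alpha."""
    rows = {
        "parents": parent_row,
        "f1_vs_p1": f1_vs_p1_row,
        "f1_vs_p2": f1_vs_p2_row,
        "f1_vs_mid": f1_vs_mid_row,
    }
    for name, row in rows.items():
        if row is None or "log2fc" not in row or "padj" not in row:
            raise ValidationError(f"missing contrast row {name!r}")

    def sign(x: float) -> int:
        return int(x > 0) - int(x < 0)

    return Evidence(
        parents=_direction(parent_row["log2fc"], parent_row["padj"], alpha),
        f1_vs_p1=_direction(f1_vs_p1_row["log2fc"], f1_vs_p1_row["padj"], alpha),
        f1_vs_p2=_direction(f1_vs_p2_row["log2fc"], f1_vs_p2_row["padj"], alpha),
        f1_vs_mid=_direction(f1_vs_mid_row["log2fc"], f1_vs_mid_row["padj"], alpha),
        sign_f1_vs_p1=sign(f1_vs_p1_row["log2fc"]),
        sign_f1_vs_p2=sign(f1_vs_p2_row["log2fc"]),
    )


def classify_gene(evidence: Evidence, gene_id: str = "", cross: str = "F1A") -> ModeCall:
    """Assign the twelve-type label (or ``none``) to one evidence tuple.

    The rule set is exhaustive and mutually exclusive over all consistent
    evidence tuples; pairwise dominance patterns take precedence over the
    mid-parent additivity test (see module docstring)."""
    ev = evidence
    p1_higher = ev.parents == "down"  # P2_vs_P1 down <=> P1 > P2
    p2_higher = ev.parents == "up"
    parents_sig = ev.parents != "ns"

    type_label = "none"

    # over-dominance: significantly above both parents
    if ev.f1_vs_p1 == "up" and ev.f1_vs_p2 == "up":
        type_label = "V" if p1_higher else ("VIII" if p2_higher else "VI")

    # under-dominance: significantly below both parents
    if type_label == "none" and ev.f1_vs_p1 == "down" and ev.f1_vs_p2 == "down":
        type_label = "III" if p1_higher else ("X" if p2_higher else "VII")

    # high-parent dominance: indistinguishable from the higher parent,
    # significantly above the lower
    if type_label == "none" and parents_sig:
        if p1_higher and ev.f1_vs_p1 == "ns" and ev.f1_vs_p2 == "up":
            type_label = "II"
        elif p2_higher and ev.f1_vs_p2 == "ns" and ev.f1_vs_p1 == "up":
            type_label = "IV"

    # low-parent dominance: indistinguishable from the lower parent,
    # significantly below the higher
    if type_label == "none" and parents_sig:
        if p2_higher and ev.f1_vs_p1 == "ns" and ev.f1_vs_p2 == "down":
            type_label = "IX"  # lower parent = P1
        elif p1_higher and ev.f1_vs_p2 == "ns" and ev.f1_vs_p1 == "down":
            type_label = "XI"  # lower parent = P2

    # additivity: parents differ, cross at the mid-parent, estimate strictly
    # between the parents (below the higher, above the lower)
    if type_label == "none" and parents_sig and ev.f1_vs_mid == "ns":
        if p1_higher:
            between = ev.sign_f1_vs_p1 < 0 < ev.sign_f1_vs_p2
        else:
            between = ev.sign_f1_vs_p2 < 0 < ev.sign_f1_vs_p1
        if between:
            type_label = "I" if p1_higher else "XII"

    category = TYPE_TO_CATEGORY.get(type_label, "other")
    return ModeCall(gene_id, cross, type_label, category, ev)


def classify_all(
    results: Mapping[str, ContrastResult], cross: str, alpha: float = 0.05
) -> list[ModeCall]:
    """Classify every differentially expressed gene of one cross.

    ``results`` must contain the parental contrast ``P2_vs_P1`` and, for the
    requested cross X, ``X_vs_P1``, ``X_vs_P2`` and ``X_vs_MID``.  A gene
    enters classification iff it is significant (padj < alpha) in at least one
    of the three pairwise contrasts; genes non-significant everywhere are the
    conserved background and receive no call.
    """
    if cross not in CROSS_GROUPS:
        raise ValidationError(f"cross must be one of {CROSS_GROUPS}")
    needed = ["P2_vs_P1", f"{cross}_vs_P1", f"{cross}_vs_P2", f"{cross}_vs_MID"]
    for name in needed:
        if name not in results:
            raise ValidationError(f"missing contrast {name!r} in results")
    parent_t = results["P2_vs_P1"].table
    p1_t = results[f"{cross}_vs_P1"].table
    p2_t = results[f"{cross}_vs_P2"].table
    mid_t = results[f"{cross}_vs_MID"].table

    calls: list[ModeCall] = []
    for gene in parent_t.index:
        rows = {}
        for label, tbl in (("parents", parent_t), ("p1", p1_t), ("p2", p2_t), ("mid", mid_t)):
            if gene not in tbl.index:
                raise ValidationError(f"gene {gene!r} missing from contrast table {label}")
            rows[label] = tbl.loc[gene]
        deg = any(rows[k]["padj"] < alpha for k in ("parents", "p1", "p2"))
        if not deg:
            continue
        ev = call_directions(rows["parents"], rows["p1"], rows["p2"], rows["mid"], alpha)
        calls.append(classify_gene(ev, gene_id=str(gene), cross=cross))
    return calls


@dataclass
class CategorySummary:
    """Category counts for one cross, with proportions among non-additive genes."""

    cross: str
    counts: dict[str, int]  # keys: CATEGORIES minus "other" plus "other" optional
    proportions: dict[str, float] | None  # over the non-additive total; None if total 0

    @property
    def nonadditive_total(self) -> int:
        return sum(self.counts[c] for c in NONADDITIVE_CATEGORIES)


def aggregate_categories(
    type_counts: Sequence[int] | Mapping[str, int], cross: str = "F1A"
) -> CategorySummary:
    """Collapse twelve type counts into the five categories.

    ``type_counts`` is either a mapping keyed by roman numeral or a sequence
    of twelve integers in order I..XII.  Proportions are reported over the
    non-additive total (high/low-parent dominance plus over/under-dominance);
    when that total is zero, proportions are ``None``.
    """
    if isinstance(type_counts, Mapping):
        counts = {t: int(type_counts.get(t, 0)) for t in TYPES}
    else:
        seq = list(type_counts)
        if len(seq) != 12:
            raise ValidationError(f"expected 12 type counts, got {len(seq)}")
        counts = {t: int(v) for t, v in zip(TYPES, seq)}
    if any(v < 0 for v in counts.values()):
        raise ValidationError("type counts must be non-negative")

    cat_counts = {c: 0 for c in CATEGORIES if c != "other"}
    for t, c in TYPE_TO_CATEGORY.items():
        cat_counts[c] += counts[t]
    total_na = sum(cat_counts[c] for c in NONADDITIVE_CATEGORIES)
    if total_na > 0:
        proportions = {c: cat_counts[c] / total_na for c in NONADDITIVE_CATEGORIES}
    else:
        proportions = None
    return CategorySummary(cross=cross, counts=cat_counts, proportions=proportions)


def summarize_calls(calls: Iterable[ModeCall], cross: str) -> CategorySummary:
    """Category summary directly from a list of :class:`ModeCall`."""
    type_counter = Counter(c.type_label for c in calls if c.cross == cross)
    summary = aggregate_categories({t: type_counter.get(t, 0) for t in TYPES}, cross=cross)
    summary.counts["other"] = type_counter.get("none", 0)
    return summary


def shared_category_genes(
    calls_a: Iterable[ModeCall], calls_b: Iterable[ModeCall], category: str
) -> set[str]:
    """Gene ids holding ``category`` in both crosses (e.g. shared over-dominant genes)."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    in_a = {c.gene_id for c in calls_a if c.category == category}
    in_b = {c.gene_id for c in calls_b if c.category == category}
    return in_a & in_b


def calls_to_frame(calls: Iterable[ModeCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "cross": c.cross,
            "type": c.type_label,
            "category": c.category,
            "parents": c.evidence.parents,
            "f1_vs_p1": c.evidence.f1_vs_p1,
            "f1_vs_p2": c.evidence.f1_vs_p2,
            "f1_vs_mid": c.evidence.f1_vs_mid,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=[
        "gene_id", "cross", "type", "category", "parents", "f1_vs_p1", "f1_vs_p2", "f1_vs_mid",
    ])
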