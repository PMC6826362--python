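"""Hypergeometric over-representation analysis of a gene list against gene sets.

The universe is the tested population (here: genes passing the expression
filter), not the whole genome.  For each set with K members inside the
universe, the one-sided p-value of observing k or more of the n study genes in
the set is the upper hypergeometric tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n),

and BH FDR is computed across all tested sets.  Sets with no member in the
universe are skipped (they carry no testable signal), not counted as tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .data import GeneSetCollection, ValidationError
from .de import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    description: str
    k: int  # study genes in the set (within the universe)
    n_study: int  # study-list size within the universe
    K: int  # set size within the universe
    N: int  # universe size
    p_value: float
    fdr: float
    overlap: frozenset[str]


def hypergeom_ora(
    study: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
) -> list[EnrichmentResult]:
    """Over-representation of ``study`` genes in each gene set.

    Study genes outside the universe are dropped with a warning; memberships
    are restricted to the universe before testing.  Results are sorted by
    p-value ascending.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    study = set(study)
    outside = study - universe
    if outside:
        logger.warning(
            "%d study gene(s) outside the universe dropped (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
        study = study & universe
    if not study:
        raise ValidationError("no study genes remain after restriction to the universe")

    N, n = len(universe), len(study)
    results: list[EnrichmentResult] = []
    for gs in sets:
        members = gs.genes & universe
        K = len(members)
        if K == 0:
            continue  # untestable; skipping keeps it out of the BH family
        overlap = frozenset(study & members)
        k = len(overlap)
        # upper tail including the observed count: P(X >= k) = sf(k - 1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(gs.name, gs.description, k, n, K, N, min(p, 1.0), 1.0, overlap)
        )
    if results:
        fdrs = bh_adjust([r.p_value for r in results])
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def significant_sets(
    results: Sequence[EnrichmentResult], fdr_threshold: float = 0.05
) -> list[str]:
    """Set names with FDR strictly below the threshold, ordered by p ascending."""
    kept = [r for r in results if r.fdr < fdr_threshold]
    kept.sort(key=lambda r: (r.p_value, r.set_name))
    return [r.set_name for r in kept]
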