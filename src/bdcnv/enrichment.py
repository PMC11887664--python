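"""Local over-representation analysis (ORA).

One-sided hypergeometric upper-tail test of overlap between a selected
gene list and each gene set, with Benjamini–Hochberg FDR applied within
each collection separately (FDRs are reported per category).  The
reference universe defaults to the genes of the supplied gene-model file
intersected with the collection's annotated genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .sv_io import GeneSetCollection
from .types import EnrichmentResult

log = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated genes in the term, n: selected genes,
    k: overlap.  Computed via the survival function (stable in log space).
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up FDR, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def run_ora(
    selected_genes: Iterable[str],
    collections: Sequence[GeneSetCollection],
    universe: Iterable[str],
    min_term_size: int = 2,
    restrict_universe_to_annotated: bool = True,
) -> list[EnrichmentResult]:
    """ORA of a selected gene list against one or more GMT collections.

    Per collection: the universe is optionally intersected with the
    collection's annotated genes (the default, approximating a
    reference-set ORA), terms smaller than ``min_term_size`` within the
    universe are skipped, only terms with overlap k >= 1 are reported, and
    BH-FDR is applied within the collection.  Results are sorted by FDR
    then p then term id.
    """
    universe_all = frozenset(universe)
    if not universe_all:
        raise ValueError("empty gene universe")
    selected_all = frozenset(selected_genes) & universe_all
    if not selected_all:
        log.warning("selected gene list is empty after universe intersection")
        return []
    results: list[EnrichmentResult] = []
    for coll in collections:
        if restrict_universe_to_annotated:
            uni = universe_all & coll.all_genes()
        else:
            uni = universe_all
        sel = selected_all & uni
        if not uni or not sel:
            continue
        batch: list[EnrichmentResult] = []
        for term in sorted(coll.sets):
            members = coll.sets[term] & uni
            if len(members) < min_term_size:
                continue
            overlap = sel & members
            if not overlap:
                continue
            p = hypergeom_tail(len(overlap), len(members), len(sel), len(uni))
            batch.append(
                EnrichmentResult(
                    term_id=term,
                    term_name=coll.descriptions.get(term, term),
                    collection=coll.name,
                    k=len(overlap),
                    K=len(members),
                    n=len(sel),
                    N=len(uni),
                    p_value=p,
                    overlap_genes=tuple(sorted(overlap)),
                )
            )
        fdrs = bh_adjust([r.p_value for r in batch])
        for r, fdr in zip(batch, fdrs):
            r.fdr = fdr
        results.extend(batch)
    results.sort(key=lambda r: (r.fdr, r.p_value, r.collection, r.term_id))
    return results
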