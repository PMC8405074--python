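"""Local Fisher-exact gene-set enrichment over a GMT library.

One-sided (enrichment-only) Fisher exact test: the P-value of an overlap
of k genes between a query of size n and a term of size K in a universe of
N genes is the hypergeometric upper tail P(X >= k).  P-values are BH
adjusted across the library and results ranked by adjusted P then overlap
size — adjusted P below alpha with the largest overlaps first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust
from .io_formats import GeneSetLibrary

__all__ = ["EnrichmentRow", "fisher_enrich", "enrich_library"]


@dataclass
class EnrichmentRow:
    term: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_N: int
    p: float
    p_adj: float
    overlap_genes: tuple[str, ...]

    @property
    def overlap(self) -> str:
        """Table convention: 'k/K'."""
        return f"{self.overlap_k}/{self.set_size_K}"


def fisher_enrich(
    query: set[str], term_set: set[str], universe_N: int
) -> tuple[int, float]:
    """Overlap count and one-sided Fisher exact (hypergeometric tail) P.

    P = P(X >= k) with X ~ Hypergeom(N, K, n); k = 0 is allowed and gives
    P = 1 (the certain event).
    """
    if not query:
        raise ValueError("empty query gene set")
    n, K = len(query), len(term_set)
    if universe_N < max(n, K):
        raise ValueError("universe smaller than query or term set")
    k = len(query & term_set)
    p = float(hypergeom.sf(k - 1, universe_N, K, n))
    return k, min(p, 1.0)


def enrich_library(
    query: set[str],
    library: GeneSetLibrary,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Fisher-exact enrichment of a query against every library term.

    The universe defaults to the union of all library genes; query genes
    outside the universe are dropped with a warning.  Rows are BH adjusted
    across the whole library, filtered to adjusted P < alpha, and sorted
    by adjusted P ascending then overlap descending.
    """
    if len(library) == 0:
        raise ValueError("empty gene-set library")
    if universe is None:
        universe = library.all_genes()
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    query_in = query & universe
    if not query_in:
        raise ValueError("no query genes in the universe")
    n_universe = len(universe)

    rows = []
    for term, gs in library:
        term_in = gs.genes & universe
        k, p = fisher_enrich(query_in, term_in, n_universe)
        rows.append((term, k, len(term_in), p, tuple(sorted(query_in & term_in))))
    p_adj = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentRow(
            term=term,
            overlap_k=k,
            set_size_K=size,
            query_size_n=len(query_in),
            universe_N=n_universe,
            p=p,
            p_adj=float(pa),
            overlap_genes=genes,
        )
        for (term, k, size, p, genes), pa in zip(rows, p_adj)
    ]
    out = [r for r in out if r.p_adj < alpha]
    out.sort(key=lambda r: (r.p_adj, -r.overlap_k, r.term))
    return out


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "overlap": [r.overlap for r in rows],
            "p": [r.p for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "genes": [",".join(r.overlap_genes) for r in rows],
        }
    )
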