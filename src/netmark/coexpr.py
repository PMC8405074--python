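"""Mutual-information co-expression network inference with DPI pruning.

The classic ARACNE recipe: score every gene pair by mutual information,
keep pairs above a permutation-null significance threshold, then apply the
data-processing-inequality (DPI) sweep — in every triangle the weakest
edge is the candidate indirect interaction and is removed when its MI
falls below ``(1 - epsilon)`` times the weaker of the other two.  The
module of a seed gene is the seed plus its first neighbors in the pruned
network.

MI is estimated by the plug-in estimator on an equal-frequency B x B
contingency table.  The automatic bin count follows the Sturges rule
B = floor(log2 n) + 1: the plug-in estimator carries an upward bias of
roughly (B - 1)^2 / (2n) nats, so B must grow much slower than sqrt(n)
for independent pairs to score near zero and for DPI's multiplicative
tolerance to act on signal rather than bias.  The estimator has a
closed-form check: a bijection between x and y gives MI = log B exactly
when n is a multiple of B.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import ExpressionMatrix

__all__ = [
    "CoexprConfig",
    "MIResult",
    "mutual_information",
    "auto_bins",
    "mi_threshold",
    "apply_dpi",
    "infer_network",
    "seed_module",
]


@dataclass(frozen=True)
class CoexprConfig:
    """ARACNE-style inference parameters.

    ``n_bins``: bins per axis of the MI contingency table, or None for
    the Sturges rule floor(log2 n) + 1.  ``n_permutations``: null draws behind the MI
    significance threshold.  ``dpi_tolerance``: epsilon in [0,1]; 0 prunes
    the weakest edge of every triangle, 1 disables pruning.
    """

    n_bins: int | None = None
    n_permutations: int = 100
    mi_alpha: float = 0.05
    dpi_tolerance: float = 0.1
    max_null_pairs: int = 30

    def validate(self) -> None:
        if self.n_permutations < 20:
            raise ValueError("n_permutations must be >= 20")
        if not 0.0 < self.mi_alpha < 1.0:
            raise ValueError("mi_alpha must be in (0, 1)")
        if not 0.0 <= self.dpi_tolerance <= 1.0:
            raise ValueError("dpi_tolerance must be in [0, 1]")


def auto_bins(n: int) -> int:
    """Sturges bin count: floor(log2 n) + 1 (never below 3)."""
    return max(3, int(np.floor(np.log2(n))) + 1)


@dataclass
class MIResult:
    gene_a: str
    gene_b: str
    mi: float
    passed_threshold: bool
    removed_by_dpi: bool


def _bin_assign(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per observation.

    Ranks are taken with a stable sort, so ties are broken by original
    position — deterministic for a fixed input vector.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in MI (nats) on the equal-frequency BxB contingency table."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has undefined MI")
    b = int(n_bins) if n_bins else auto_bins(x.size)
    return _mi_from_bins(_bin_assign(x, b), _bin_assign(y, b), b)


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, b: int) -> float:
    joint = np.zeros((b, b))
    np.add.at(joint, (bx, by), 1.0)
    joint /= bx.size
    # marginals from the per-vector bin counts (not the joint) so the
    # result is bit-for-bit symmetric in (x, y)
    px = np.bincount(bx, minlength=b) / bx.size
    py = np.bincount(by, minlength=b) / by.size
    nz = joint > 0
    ratio = joint[nz] / np.outer(px, py)[nz]
    # summing in sorted order makes the result exactly symmetric in (x, y):
    # transposing the table permutes the terms but not their sorted sequence
    return float(np.sum(np.sort(joint[nz] * np.log(ratio))))


def mi_threshold(
    matrix: ExpressionMatrix,
    cfg: CoexprConfig = CoexprConfig(),
    seed: int = 0,
) -> float:
    """MI significance threshold from a permutation null.

    For a subsample of gene pairs, sample labels of one member are
    permuted and MI recomputed; the threshold is the (1 - mi_alpha)
    quantile of the pooled null MIs (upper-bounding interpolation, so the
    pass rate of true null pairs stays at or below mi_alpha).
    """
    cfg.validate()
    n = len(matrix.samples)
    if n < 8:
        raise ValueError("need at least 8 samples for a permutation null")
    rng = np.random.default_rng((int(seed) % (2**31), 97))
    genes = matrix.genes
    b = cfg.n_bins or auto_bins(n)
    values = matrix.values.to_numpy()
    bins = np.stack([_bin_assign(values[i], b) for i in range(len(genes))])

    pairs = list(itertools.combinations(range(len(genes)), 2))
    if len(pairs) > cfg.max_null_pairs:
        idx = rng.choice(len(pairs), size=cfg.max_null_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    null = np.empty(len(pairs) * cfg.n_permutations)
    k = 0
    for i, j in pairs:
        for _ in range(cfg.n_permutations):
            perm = rng.permutation(n)
            null[k] = _mi_from_bins(bins[i], bins[j][perm], b)
            k += 1
    return float(np.quantile(null, 1.0 - cfg.mi_alpha, method="higher"))


def apply_dpi(graph: nx.Graph, epsilon: float) -> tuple[nx.Graph, set]:
    """Data-processing-inequality sweep over an MI-weighted graph.

    For every triangle (i, j, k) the edge (i, j) is marked for removal if
    MI(i,j) < min(MI(i,k), MI(j,k)) * (1 - epsilon).  Marking is computed
    against the original weights and removals applied only after all
    triangles are scanned, so the result is independent of edge order.
    Returns (pruned copy, set of removed edges as frozensets).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    factor = 1.0 - epsilon
    marked: set[frozenset] = set()
    for i, j, data in graph.edges(data=True):
        w_ij = data["mi"]
        for k in set(graph.neighbors(i)) & set(graph.neighbors(j)):
            w_ik = graph.edges[i, k]["mi"]
            w_jk = graph.edges[j, k]["mi"]
            if w_ij < min(w_ik, w_jk) * factor:
                marked.add(frozenset((i, j)))
                break
    pruned = graph.copy()
    pruned.remove_edges_from(tuple(e) for e in marked)
    return pruned, marked


def infer_network(
    matrix: ExpressionMatrix,
    cfg: CoexprConfig = CoexprConfig(),
    seed: int = 0,
) -> tuple[nx.Graph, list[MIResult]]:
    """All-pairs MI -> permutation threshold -> DPI prune.

    Returns the surviving co-expression graph plus a per-pair audit of
    every scored pair (MI, whether it passed the threshold, whether DPI
    removed it).
    """
    cfg.validate()
    genes = matrix.genes
    n = len(matrix.samples)
    if n < 8:
        raise ValueError("need at least 8 samples")
    b = cfg.n_bins or auto_bins(n)
    values = matrix.values.to_numpy()
    bins = np.stack([_bin_assign(values[i], b) for i in range(len(genes))])

    threshold = mi_threshold(matrix, cfg, seed=seed)

    full = nx.Graph()
    full.add_nodes_from(genes)
    mi_pairs: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(len(genes)), 2):
        mi = _mi_from_bins(bins[i], bins[j], b)
        mi_pairs[frozenset((genes[i], genes[j]))] = mi
        if mi > threshold:
            full.add_edge(genes[i], genes[j], mi=mi)
    pruned, removed = apply_dpi(full, cfg.dpi_tolerance)

    audit = [
        MIResult(
            gene_a=min(pair),
            gene_b=max(pair),
            mi=mi,
            passed_threshold=full.has_edge(*tuple(pair)) or pair in removed,
            removed_by_dpi=pair in removed,
        )
        for pair, mi in mi_pairs.items()
    ]
    return pruned, audit


def seed_module(net: nx.Graph, seed: str) -> set[str]:
    """Seed gene plus its first neighbors in the inferred network."""
    if seed not in net:
        raise ValueError(f"seed gene {seed!r} not in network")
    return {seed} | set(net.neighbors(seed))
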