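"""First analysis cycle: topological reweighting of a signature network.

Scores every node of an interaction network by connectivity degree and
(unnormalized Brandes) betweenness centrality, checks the degree
distribution for a power-law-like fat tail via R-square of the log-log
fit, and selects "central" genes as the union of hub genes (by a degree
rule) and the top betweenness quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "DegreeRule",
    "TopKDegree",
    "DegreeThreshold",
    "CentralGeneSet",
    "degree_map",
    "betweenness_map",
    "powerlaw_r2",
    "tail_inclusive_quantile",
    "select_central",
]


@dataclass(frozen=True)
class TopKDegree:
    """Hub rule: the k highest-degree nodes (ties broken by symbol)."""

    k: int


@dataclass(frozen=True)
class DegreeThreshold:
    """Hub rule: every node with degree >= value (value may be fractional)."""

    value: float


DegreeRule = TopKDegree | DegreeThreshold


@dataclass
class CentralGeneSet:
    hubs: set[str]
    high_betweenness: set[str]

    @property
    def central(self) -> set[str]:
        return self.hubs | self.high_betweenness


def degree_map(net: nx.Graph) -> dict[str, int]:
    """Simple-graph degree of every node."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    return dict(net.degree())


def betweenness_map(net: nx.Graph) -> dict[str, float]:
    """Brandes betweenness: unnormalized, endpoints excluded, each
    unordered source-target pair counted once.  Disconnected graphs are
    handled naturally (unreachable pairs contribute nothing)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(net, normalized=False)


def powerlaw_r2(degrees) -> float:
    """R-square of the least-squares log(frequency) vs log(degree) fit.

    The degree histogram is taken over observed positive degrees; a high
    R-square indicates a fat-tailed (power-law-like) degree distribution.
    A zero-variance response (all frequencies equal) is defined as 0.
    Requires at least 3 distinct positive degree values.
    """
    deg = np.asarray([d for d in degrees if d > 0], dtype=float)
    uniq, counts = np.unique(deg, return_counts=True)
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct positive degree values")
    x = np.log(uniq)
    y = np.log(counts.astype(float))
    if np.allclose(y, y[0]):
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def tail_inclusive_quantile(values, q: float) -> float:
    """Cutoff selecting the top fraction ``q``, ties at the cutoff included.

    Returns the value ``c`` such that at least ceil(q*n) items satisfy
    ``item >= c``; every item equal to ``c`` is selected with it.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty value list")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"quantile must be in (0, 1], got {q}")
    k = math.ceil(q * vals.size)
    return float(np.sort(vals)[::-1][k - 1])


def select_central(
    net: nx.Graph,
    betweenness_quantile: float = 0.20,
    degree_rule: DegreeRule = TopKDegree(6),
) -> CentralGeneSet:
    """Central cancer-signature genes: hub genes by the degree rule,
    united with the top betweenness quantile (ties at the boundary
    included)."""
    deg = degree_map(net)
    btw = betweenness_map(net)

    cutoff = tail_inclusive_quantile(btw.values(), betweenness_quantile)
    # ties at the cutoff are included, but a node mediating no shortest
    # paths is never "high betweenness" even when the cutoff lands at 0
    high_btw = {n for n, b in btw.items() if b >= cutoff and b > 0}

    if isinstance(degree_rule, TopKDegree):
        ranked = sorted(net.nodes(), key=lambda n: (-deg[n], n))
        hubs = set(ranked[: degree_rule.k])
    elif isinstance(degree_rule, DegreeThreshold):
        hubs = {n for n, d in deg.items() if d >= degree_rule.value}
    else:  # pragma: no cover - exhaustive by type
        raise TypeError(f"unknown degree rule {degree_rule!r}")
    if not hubs:
        warnings.warn(
            f"degree rule {degree_rule!r} selects no hub genes", stacklevel=2
        )
    return CentralGeneSet(hubs=hubs, high_betweenness=high_btw)
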