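"""Differential coexpression network (DCN) construction.

The DCN keeps the interactome pairs whose expression profiles are strongly
correlated (|Pearson r| >= delta) in the treated condition, and weights
each surviving edge by the differential-expression significance of its two
endpoints:

    w_ij = (sqrt(L_i) + sqrt(L_j)) / (2 * sqrt(max_{l in V} L_l)),

with L_g = -log P_g and V the node set of the thresholded network. The
weight is 1 exactly when both endpoints carry the network's most
significant P-value and 0 when both P-values are 1; the logarithm base
cancels in the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import networkx as nx
import numpy as np

from .containers import EdgeList, ExpressionStudy, canonical_pair
from .stats import P_FLOOR

log = logging.getLogger(__name__)

WEIGHT_FORMS = ("sum_of_roots", "root_of_sum")


@dataclass
class WeightedNetwork:
    """Undirected gene graph with edge weights in [0, 1]."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if w is None or not (0.0 <= w <= 1.0):
                raise ValueError(f"edge ({u}, {v}) weight {w!r} outside [0, 1]")

    @classmethod
    def from_edge_weights(cls, weights: Mapping[tuple[str, str], float]) -> "WeightedNetwork":
        g = nx.Graph()
        for (a, b), w in weights.items():
            g.add_edge(a, b, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight"):
            a, b = canonical_pair(u, v)
            yield a, b, w

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def neighbors(self, v: str) -> list[str]:
        return list(self.graph.neighbors(v))

    def weighted_degree(self, v: str) -> float:
        return float(self.graph.degree(v, weight="weight"))

    def to_edge_list(self) -> EdgeList:
        el = EdgeList()
        for a, b, w in self.edges():
            el.add(a, b, w)
        return el


def edge_correlations(study: ExpressionStudy, edge_list: EdgeList,
                      condition: str = "treated") -> dict[tuple[str, str], float]:
    """Pearson correlation over one condition's samples for interactome pairs.

    Pairs with an endpoint absent from the study are dropped (logged count),
    as are pairs with a zero-variance endpoint.
    """
    samples = study.samples_in(condition)
    if len(samples) < 3:
        raise ValueError(f"condition {condition!r} has {len(samples)} samples; need >= 3")
    mat = study.matrix_for(condition)
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    index = study.gene_index()

    kept_i, kept_j, kept_pairs = [], [], []
    n_missing = n_zerovar = 0
    for a, b in sorted(edge_list.pairs):
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            n_missing += 1
            continue
        if norms[ia] == 0.0 or norms[ib] == 0.0:
            n_zerovar += 1
            continue
        kept_i.append(ia)
        kept_j.append(ib)
        kept_pairs.append((a, b))
    if n_missing:
        log.info("dropped %d interactome pairs with endpoints absent from the study", n_missing)
    if n_zerovar:
        log.warning("dropped %d pairs with a zero-variance endpoint", n_zerovar)
    if not kept_pairs:
        return {}
    ci = centered[kept_i]
    cj = centered[kept_j]
    r = (ci * cj).sum(axis=1) / (norms[np.array(kept_i)] * norms[np.array(kept_j)])
    r = np.clip(r, -1.0, 1.0)
    return dict(zip(kept_pairs, r.tolist()))


def _edge_weight(li: float, lj: float, lmax: float, form: str) -> float:
    if form == "sum_of_roots":
        w = (math.sqrt(li) + math.sqrt(lj)) / (2.0 * math.sqrt(lmax))
    elif form == "root_of_sum":
        w = math.sqrt(li + lj) / (2.0 * math.sqrt(lmax))
    else:
        raise ValueError(f"unknown weight form {form!r}; choose from {WEIGHT_FORMS}")
    return min(max(w, 0.0), 1.0)


def build_dcn(correlations: Mapping[tuple[str, str], float],
              de_result: Mapping[str, float], delta: float = 0.9,
              weight_form: str = "sum_of_roots",
              log_base: float = math.e) -> WeightedNetwork:
    """Threshold correlations at |r| >= delta and weight edges by DE significance.

    ``log_base`` only rescales L = -log P by a constant, which cancels in
    the weight ratio; it is exposed to make that invariance checkable.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    kept = {p: r for p, r in correlations.items() if abs(r) >= delta}
    if not kept:
        raise ValueError(f"no interactome pair has |r| >= {delta}: empty DCN")
    nodes = sorted({g for p in kept for g in p})
    missing = [g for g in nodes if g not in de_result]
    if missing:
        raise ValueError(f"genes without DE P-values: {missing[:5]}...")
    scale = math.log(log_base)
    L = {g: -math.log(max(de_result[g], P_FLOOR)) / scale for g in nodes}
    lmax = max(L.values())
    if lmax == 0.0:
        raise ValueError("all DE P-values equal 1; edge weights are undefined")
    weights = {
        canonical_pair(*p): _edge_weight(L[p[0]], L[p[1]], lmax, weight_form)
        for p in kept
    }
    net = WeightedNetwork.from_edge_weights(weights)
    log.info("DCN: %d nodes, %d edges at delta = %g", net.n_nodes, net.n_edges, delta)
    return net
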