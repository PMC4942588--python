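"""Module identification in the DCN.

Three stages: (1) seed prioritization by iterative score propagation on the
symmetrically degree-normalized weighted adjacency, z-scored, with the top
1% of genes taken as seeds; (2) greedy module expansion from each seed by
boundary-entropy minimization (additions require an entropy decrease,
``dH > 0``); (3) refinement by a minimum-size filter and Jaccard merging of
overlapping candidates.

Module entropy H(C) is the average, over members v, of the binary entropy
of p_v = (weighted degree of v into C) / (total weighted degree of v). A
low H means members' edge weight is concentrated inside the module, i.e. a
sharply bounded, internally connected module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import WeightedNetwork

log = logging.getLogger(__name__)

#: numerical slack when comparing entropy changes for tie-breaking
_TIE_TOL = 1e-12


@dataclass
class SeedRanking:
    """Propagation scores, z-scores and the selected seed list."""

    scores: dict[str, float]
    zscores: dict[str, float]
    seeds: list[str]


@dataclass
class GeneModule:
    """A connected gene set grown from a seed, with its entropy score."""

    module_id: str
    seed: str
    members: set[str]
    entropy: float
    trace: list[tuple[str, float]] = field(default_factory=list)


def binary_entropy(p: float) -> float:
    """h(p) = -p log2 p - (1-p) log2 (1-p), with h(0) = h(1) = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def module_entropy(network: WeightedNetwork, members: set[str]) -> float:
    """Average boundary entropy of the members' inside-degree fractions."""
    if not members:
        raise ValueError("members must be non-empty")
    total = 0.0
    for v in members:
        deg = network.weighted_degree(v)
        if deg == 0.0:
            if not network.graph.has_node(v) or network.graph.degree(v) == 0:
                raise ValueError(f"member {v!r} has zero total degree")
            # all incident weights are zero: inside fraction undefined -> 0
            raise ValueError(f"member {v!r} has zero total weighted degree")
        inside = sum(
            network.weight(v, u) for u in network.graph.neighbors(v) if u in members
        )
        total += binary_entropy(inside / deg)
    return total / len(members)


def propagation_scores(network: WeightedNetwork, tol: float = 1e-10,
                       max_iter: int = 10000) -> dict[str, float]:
    """Fixed point of g <- A' g under unit-norm scaling.

    A' = D^{-1/2} W D^{-1/2} is the symmetrically normalized weighted
    adjacency. The iteration is damped (averaged with the identity), which
    leaves the fixed point unchanged but removes the oscillation of
    bipartite spectra; the limit is the principal eigenvector of A'.
    """
    if network.n_nodes == 0 or network.n_edges == 0:
        raise ValueError("network must have at least one edge")
    nodes = sorted(network.nodes)
    W = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, weight="weight", format="csr")
    deg = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    g = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
    for _ in range(max_iter):
        g_new = 0.5 * (dinv * (W @ (dinv * g)) + g)
        nrm = np.linalg.norm(g_new)
        if nrm == 0.0:
            raise RuntimeError("propagation collapsed to the zero vector")
        g_new /= nrm
        residual = float(np.max(np.abs(g_new - g)))
        g = g_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"propagation did not converge in {max_iter} iterations (residual {residual:.3e})"
        )
    return dict(zip(nodes, g.tolist()))


def seed_ranking(network: WeightedNetwork, top_fraction: float = 0.01,
                 tol: float = 1e-10, max_iter: int = 10000,
                 min_component_size: int = 5) -> SeedRanking:
    """Rank genes by propagation z-score and select the top fraction as seeds.

    The seed budget is ``max(1, floor(top_fraction * n_nodes))``, ties in z
    broken by gene id. On a disconnected network every component of at
    least ``min_component_size`` nodes is guaranteed its top-ranked gene as
    a seed (the propagation fixed point orders whole components, so a
    purely global cut would starve all but the dominant component); on a
    connected network this reduces to the plain global top-k rule.
    """
    scores = propagation_scores(network, tol=tol, max_iter=max_iter)
    nodes = sorted(scores)
    g = np.array([scores[v] for v in nodes])
    sd = g.std()
    z = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    zscores = dict(zip(nodes, z.tolist()))

    ranked = sorted(nodes, key=lambda v: (-zscores[v], v))
    budget = max(1, math.floor(top_fraction * len(nodes)))

    components = [c for c in nx.connected_components(network.graph)]
    guaranteed: list[str] = []
    for comp in components:
        if len(comp) >= min_component_size:
            guaranteed.append(min(comp, key=lambda v: (-zscores[v], v)))
    chosen = set(guaranteed)
    for v in ranked:
        if len(chosen) >= max(budget, len(guaranteed)):
            break
        chosen.add(v)
    seeds = sorted(chosen, key=lambda v: (-zscores[v], v))
    return SeedRanking(scores, zscores, seeds)


class _ExpansionState:
    """Incremental bookkeeping for greedy entropy-minimizing expansion.

    Tracks, for each member, its inside weight and total weighted degree,
    plus the running sum of member entropies, so candidate evaluations cost
    O(deg(u)) instead of a from-scratch recomputation.
    """

    def __init__(self, network: WeightedNetwork, members: set[str]):
        self.net = network
        self.members = set(members)
        self.deg = {}
        self.inside = {}
        for v in self.members:
            self.deg[v] = network.weighted_degree(v)
            self.inside[v] = sum(
                network.weight(v, u) for u in network.graph.neighbors(v) if u in self.members
            )
        self.h_sum = sum(binary_entropy(self.inside[v] / self.deg[v]) for v in self.members)
        # candidate -> weight into the current module
        self.cand_in: dict[str, float] = {}
        for v in self.members:
            for u in network.graph.neighbors(v):
                if u not in self.members:
                    self.cand_in[u] = self.cand_in.get(u, 0.0) + network.weight(v, u)

    @property
    def entropy(self) -> float:
        return self.h_sum / len(self.members)

    def delta_h(self, u: str) -> float:
        """Entropy change H(C) - H(C + u) for candidate u."""
        w_u = self.cand_in[u]
        deg_u = self.net.weighted_degree(u)
        new_sum = self.h_sum + binary_entropy(w_u / deg_u)
        for v in self.net.graph.neighbors(u):
            if v in self.members:
                w = self.net.weight(u, v)
                new_sum += binary_entropy((self.inside[v] + w) / self.deg[v]) - binary_entropy(
                    self.inside[v] / self.deg[v]
                )
        return self.entropy - new_sum / (len(self.members) + 1)

    def add(self, u: str) -> None:
        deg_u = self.net.weighted_degree(u)
        self.members.add(u)
        self.deg[u] = deg_u
        self.inside[u] = self.cand_in.pop(u)
        self.h_sum += binary_entropy(self.inside[u] / deg_u)
        for v in self.net.graph.neighbors(u):
            w = self.net.weight(u, v)
            if v in self.members and v != u:
                old = binary_entropy(self.inside[v] / self.deg[v])
                self.inside[v] += w
                self.h_sum += binary_entropy(self.inside[v] / self.deg[v]) - old
            elif v != u:
                self.cand_in[v] = self.cand_in.get(v, 0.0) + w


def expand_module(network: WeightedNetwork, seed: str, max_size: int | None = None,
                  batch_add: bool = False) -> GeneModule:
    """Grow a module from ``seed`` by greedy entropy minimization.

    The module is initialized with the seed's closed neighborhood (the seed
    plus all its network neighbors); then, at each step, the neighbor whose
    addition most decreases the module entropy is added, as long as the
    decrease dH is strictly positive (ties broken by gene id). With
    ``batch_add`` every neighbor with dH > 0 against the current module is
    added at once per round instead, which is the literal reading of the
    procedure but makes the entropy path depend on evaluation order.

    An isolated seed yields the degenerate single-gene module with entropy
    0 (removed later by the size filter).
    """
    if seed not in network.nodes:
        raise ValueError(f"seed {seed!r} not in network")
    neighbors = set(network.graph.neighbors(seed))
    if not neighbors:
        log.warning("isolated seed %s: degenerate single-gene module", seed)
        return GeneModule("", seed, {seed}, 0.0, [])
    if max_size is not None and len(neighbors) + 1 > max_size:
        # truncate the initial neighborhood to the strongest-weight neighbors
        ranked = sorted(neighbors, key=lambda u: (-network.weight(seed, u), u))
        neighbors = set(ranked[: max_size - 1])

    state = _ExpansionState(network, {seed} | neighbors)
    trace: list[tuple[str, float]] = []
    while max_size is None or len(state.members) < max_size:
        candidates = sorted(state.cand_in)
        if not candidates:
            break
        if batch_add:
            adds = [(u, state.delta_h(u)) for u in candidates]
            adds = [(u, dh) for u, dh in adds if dh > 0.0]
            if not adds:
                break
            for u, dh in adds:
                if max_size is not None and len(state.members) >= max_size:
                    break
                if u in state.cand_in:  # may have been absorbed already
                    trace.append((u, dh))
                    state.add(u)
        else:
            best_u, best_dh = None, 0.0
            for u in candidates:
                dh = state.delta_h(u)
                if dh > best_dh + _TIE_TOL:
                    best_u, best_dh = u, dh
            if best_u is None or best_dh <= 0.0:
                break
            trace.append((best_u, best_dh))
            state.add(best_u)
    # final entropy from scratch: exact (no accumulated float drift) and
    # guarantees the module invariant H == module_entropy(members)
    members = set(state.members)
    return GeneModule("", seed, members, module_entropy(network, members), trace)


def jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def refine_modules(network: WeightedNetwork, modules: list[GeneModule],
                   min_size: int = 5, jaccard_threshold: float = 0.5) -> list[GeneModule]:
    """Size-filter and Jaccard-merge candidate modules.

    Modules with fewer than ``min_size`` members are dropped; then the pair
    with the highest Jaccard index >= threshold is merged (union, entropy
    recomputed, seed taken from the canonically earlier module) until no
    pair qualifies. Module ids are reassigned in entropy-ascending order.
    The result is independent of the input module order.
    """
    def canon_key(m: GeneModule):
        return (m.entropy, m.seed, tuple(sorted(m.members)))

    pool = sorted((m for m in modules if len(m.members) >= min_size), key=canon_key)
    while len(pool) > 1:
        best = None  # (neg jaccard, i, j)
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                jac = jaccard(pool[i].members, pool[j].members)
                if jac >= jaccard_threshold:
                    cand = (-jac, i, j)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            break
        _, i, j = best
        earlier, later = pool[i], pool[j]
        union = earlier.members | later.members
        merged = GeneModule(
            "", earlier.seed, union, module_entropy(network, union),
            earlier.trace + later.trace,
        )
        pool = [m for k, m in enumerate(pool) if k not in (i, j)] + [merged]
        pool.sort(key=canon_key)

    pool.sort(key=lambda m: (m.entropy, m.seed, tuple(sorted(m.members))))
    out = []
    for idx, m in enumerate(pool, start=1):
        out.append(GeneModule(f"M{idx}", m.seed, set(m.members), m.entropy, list(m.trace)))
    return out


def search_modules(network: WeightedNetwork, top_fraction: float = 0.01,
                   min_size: int = 5, jaccard_threshold: float = 0.5,
                   max_size: int | None = None, batch_add: bool = False,
                   min_component_size: int = 5) -> tuple[SeedRanking, list[GeneModule]]:
    """Full module search: seed ranking, expansion from every seed, refinement."""
    ranking = seed_ranking(network, top_fraction, min_component_size=min_component_size)
    grown = [expand_module(network, s, max_size=max_size, batch_add=batch_add)
             for s in ranking.seeds]
    return ranking, refine_modules(network, grown, min_size, jaccard_threshold)
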