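"""Permutation significance of discovered modules.

The null model randomizes the DCN (same node set, same edge count, edge
weights reassigned as a random permutation), re-runs the full module search
on each randomized network, and pools the resulting module entropies. A
module's empirical P-value is the pseudocounted probability of a null
module scoring at least as well (entropy at least as small); P-values are
Benjamini-Hochberg adjusted across the observed modules and modules with
adjusted P <= dm_alpha are flagged differential modules (DMs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from . import modules as mod
from . import stats
from .network import WeightedNetwork

log = logging.getLogger(__name__)

NULL_MODELS = ("gnm", "rewire")


@dataclass
class NullDistribution:
    """Pooled null module scores with sizes and per-replicate counts."""

    entropies: np.ndarray
    sizes: np.ndarray
    per_replicate_counts: list[int]

    def __len__(self) -> int:
        return int(self.entropies.size)


@dataclass
class ModuleSignificance:
    module_id: str
    observed: float
    n_null: int
    empirical_p: float
    adjusted_p: float
    is_dm: bool


def randomize_network(network: WeightedNetwork, rng: np.random.Generator,
                      null_model: str = "gnm") -> WeightedNetwork:
    """Randomized network with the same node set, edge count and weight multiset.

    ``gnm`` draws a uniform random simple graph with the matched edge count
    and assigns the observed weights to the new edges as a random
    permutation; ``rewire`` instead degree-preservingly rewires via double
    edge swaps before permuting weights.
    """
    nodes = sorted(network.nodes)
    n, m = len(nodes), network.n_edges
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValueError(f"{m} edges exceed the simple-graph maximum {max_edges}")

    if null_model == "gnm":
        g_int = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g_int, dict(enumerate(nodes)))
        g.add_nodes_from(nodes)
    elif null_model == "rewire":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((u, v) for u, v, _ in network.edges())
        if m >= 2:
            nx.double_edge_swap(
                g, nswap=10 * m, max_tries=1000 * m, seed=int(rng.integers(2**31))
            )
    else:
        raise ValueError(f"unknown null model {null_model!r}; choose from {NULL_MODELS}")

    weights = np.array([w for _, _, w in sorted(network.edges())])
    perm = rng.permutation(weights)
    for k, (u, v) in enumerate(sorted(tuple(sorted(e)) for e in g.edges())):
        g[u][v]["weight"] = float(perm[k])
    return WeightedNetwork(g)


def null_score_distribution(network: WeightedNetwork, n_replicates: int = 100,
                            rng_seed: int | np.random.Generator = 0,
                            null_model: str = "gnm",
                            top_fraction: float = 0.01, min_size: int = 5,
                            jaccard_threshold: float = 0.5,
                            max_size: int | None = None,
                            batch_add: bool = False) -> NullDistribution:
    """Pool module entropies from module search on randomized networks.

    The search parameters should match those used for the observed modules.
    A replicate yielding zero modules simply contributes nothing.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    entropies: list[float] = []
    sizes: list[int] = []
    counts: list[int] = []
    for _ in range(n_replicates):
        rn = randomize_network(network, rng, null_model=null_model)
        try:
            _, found = mod.search_modules(
                rn, top_fraction=top_fraction, min_size=min_size,
                jaccard_threshold=jaccard_threshold, max_size=max_size,
                batch_add=batch_add,
            )
        except ValueError:
            # e.g. a randomization left no edges to propagate on
            found = []
        counts.append(len(found))
        for m in found:
            entropies.append(m.entropy)
            sizes.append(len(m.members))
    log.info("null distribution: %d modules pooled from %d replicates",
             len(entropies), n_replicates)
    return NullDistribution(np.array(entropies), np.array(sizes), counts)


def empirical_pvalues(observed_modules: Sequence[mod.GeneModule],
                      null_scores: NullDistribution | Sequence[float],
                      dm_alpha: float = 0.05, size_matched: bool = False,
                      size_tol: float = 0.2) -> list[ModuleSignificance]:
    """Empirical permutation P-values for observed modules, BH-adjusted.

    Smaller entropy is better; P = (1 + #{null <= observed}) / (1 + #null).
    With ``size_matched`` the null pool for each module is restricted to
    null modules whose size is within ``size_tol`` (relative) of the
    module's size, falling back to the full pool when the stratum is empty.
    """
    if isinstance(null_scores, NullDistribution):
        null_h = null_scores.entropies
        null_sizes = null_scores.sizes
    else:
        null_h = np.asarray(list(null_scores), dtype=float)
        null_sizes = None
    if null_h.size == 0:
        raise ValueError("empty null pool: no null modules were found")

    pvals = []
    for m in observed_modules:
        pool = null_h
        if size_matched and null_sizes is not None:
            size = len(m.members)
            mask = np.abs(null_sizes - size) <= size_tol * size
            if mask.any():
                pool = null_h[mask]
            else:
                log.warning("no size-matched null modules for %s; using full pool", m.module_id)
        p = (1.0 + float((pool <= m.entropy).sum())) / (1.0 + pool.size)
        pvals.append(p)

    adjusted = stats.bh_adjust(pvals)
    return [
        ModuleSignificance(
            module_id=m.module_id, observed=m.entropy, n_null=int(null_h.size),
            empirical_p=p, adjusted_p=ap, is_dm=bool(ap <= dm_alpha),
        )
        for m, p, ap in zip(observed_modules, pvals, adjusted)
    ]
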