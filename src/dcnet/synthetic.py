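"""Synthetic two-condition expression studies with planted modules.

The generator emulates the statistical structure the pipeline assumes:
paired baseline/treated samples, planted gene modules whose members are
strongly co-expressed in the treated condition only (a single latent factor
per module with loading ``lam``), mean differential-expression shifts on
planted genes, i.i.d. Gaussian background noise, and an interactome that
contains the planted modules as dense subgraphs plus random background
edges. Ground truth is returned alongside so every downstream stage is
testable without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import EdgeList, ExpressionStudy, GeneSetCollection

log = logging.getLogger(__name__)

# Sub-stream labels: all randomness flows from one rng_seed, with a fixed
# per-stage offset so stages are independently reproducible.
_STREAM_STUDY = 1
_STREAM_INTERACTOME = 2
_STREAM_GENESETS = 3


@dataclass
class PlantedModule:
    """One planted module: ``size`` genes, factor loading ``lam`` in (0,1)
    and a differential-expression mean shift ``de_shift`` in units of the
    noise SD."""

    size: int
    lam: float = 0.97
    de_shift: float = 2.0


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults are the desk-scale conditions used throughout the test suite:
    800 genes, 10 paired subjects, two planted modules (20 and 15 genes,
    loading 0.97, shift 2 noise SDs), in-module interactome edge
    probability 0.9 and background edge probability 0.01.
    """

    n_genes: int = 800
    n_subjects: int = 10
    planted_modules: tuple[PlantedModule, ...] = (
        PlantedModule(20, 0.97, 2.0),
        PlantedModule(15, 0.97, 2.0),
    )
    background_edge_prob: float = 0.01
    in_module_edge_prob: float = 0.9
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.planted_modules = tuple(
            m if isinstance(m, PlantedModule) else PlantedModule(*m)
            for m in self.planted_modules
        )
        if self.n_genes < 1 or self.n_subjects < 2:
            raise ValueError("need n_genes >= 1 and n_subjects >= 2")
        if sum(m.size for m in self.planted_modules) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        for m in self.planted_modules:
            if not (0 <= m.lam < 1):
                raise ValueError(f"loading must be in [0, 1): {m.lam}")
            if m.size < 1:
                raise ValueError("module size must be >= 1")
        if not (0 <= self.background_edge_prob <= 1 and 0 <= self.in_module_edge_prob <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted-module memberships and shifted genes, plus a config echo."""

    module_memberships: list[set[str]]
    de_genes: set[str]
    gene_ids: list[str]
    config: SyntheticConfig = field(repr=False, default=None)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_study(config: SyntheticConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a paired two-condition study with planted modules.

    Baseline samples are i.i.d. Normal(0, noise_sd^2) for every gene. In
    treated samples, each planted module draws one latent factor value per
    sample and its member genes get ``lam * f + sqrt(1 - lam^2) * eps +
    de_shift * noise_sd`` (unit total variance when noise_sd = 1), so the
    module is co-expressed and mean-shifted in the treated condition only.
    """
    rng = np.random.default_rng([config.rng_seed, _STREAM_STUDY])
    genes = _gene_ids(config.n_genes)
    sd = config.noise_sd

    # disjoint random placement of planted modules
    order = rng.permutation(config.n_genes)
    memberships: list[set[str]] = []
    pos = 0
    for m in config.planted_modules:
        idx = order[pos : pos + m.size]
        memberships.append({genes[i] for i in idx})
        pos += m.size

    S = config.n_subjects
    baseline = rng.normal(0.0, sd, (config.n_genes, S))
    treated = rng.normal(0.0, sd, (config.n_genes, S))
    for m, members in zip(config.planted_modules, memberships):
        rows = sorted(genes.index(g) for g in members)
        f = rng.normal(0.0, 1.0, S)
        eps = rng.normal(0.0, sd, (len(rows), S))
        treated[rows, :] = m.lam * f[None, :] + np.sqrt(1.0 - m.lam**2) * eps + m.de_shift * sd

    subjects = [f"P{j:02d}" for j in range(S)]
    sample_ids = [f"{p}_baseline" for p in subjects] + [f"{p}_treated" for p in subjects]
    condition = {s: ("baseline" if s.endswith("baseline") else "treated") for s in sample_ids}
    subject = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    study = ExpressionStudy(
        gene_ids=genes,
        values=np.hstack([baseline, treated]),
        sample_ids=sample_ids,
        condition=condition,
        subject=subject,
    )
    study.validate_design()
    de_genes = set().union(
        *(mem for m, mem in zip(config.planted_modules, memberships) if m.de_shift != 0),
        set(),
    )
    truth = GroundTruth(memberships, de_genes, genes, config)
    return study, truth


def generate_interactome(config: SyntheticConfig, truth: GroundTruth,
                         max_retries: int = 100) -> EdgeList:
    """Random interactome containing the planted modules as dense subgraphs.

    Each within-module pair is included with probability
    ``in_module_edge_prob`` (redrawn until the module's induced subgraph is
    connected, up to ``max_retries``); every other pair is included with
    probability ``background_edge_prob``.
    """
    rng = np.random.default_rng([config.rng_seed, _STREAM_INTERACTOME])
    genes = truth.gene_ids
    edges = EdgeList()

    module_pairs: set[tuple[str, str]] = set()
    for members in truth.module_memberships:
        mem = sorted(members)
        pairs = [(a, b) for i, a in enumerate(mem) for b in mem[i + 1 :]]
        module_pairs.update(pairs)
        if len(mem) == 1:
            continue
        for attempt in range(max_retries):
            keep = [p for p in pairs if rng.random() < config.in_module_edge_prob]
            g = nx.Graph(keep)
            g.add_nodes_from(mem)
            if nx.is_connected(g):
                break
        else:
            raise RuntimeError(
                f"module of size {len(mem)} not connected after {max_retries} draws; "
                "increase in_module_edge_prob"
            )
        for a, b in keep:
            edges.add(a, b)

    if config.background_edge_prob > 0:
        gi, gj = np.triu_indices(len(genes), k=1)
        draw = rng.random(gi.size) < config.background_edge_prob
        for i, j in zip(gi[draw], gj[draw]):
            pair = (genes[i], genes[j])
            if pair not in module_pairs:
                edges.add(*pair)
    return edges


def generate_gene_sets(truth: GroundTruth, n_decoy_sets: int = 10,
                       decoy_size: int = 15, rng_seed: int = 0) -> GeneSetCollection:
    """One gene set per planted module (exact membership) plus random decoys."""
    rng = np.random.default_rng([rng_seed, _STREAM_GENESETS])
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i, members in enumerate(truth.module_memberships, start=1):
        sets[f"planted_{i}"] = set(members)
        descriptions[f"planted_{i}"] = "planted module"
    genes = np.array(truth.gene_ids)
    for i in range(1, n_decoy_sets + 1):
        pick = rng.choice(len(genes), size=min(decoy_size, len(genes)), replace=False)
        sets[f"decoy_{i}"] = set(genes[pick].tolist())
        descriptions[f"decoy_{i}"] = "random decoy set"
    return GeneSetCollection(sets, descriptions)
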