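"""Self-contained validation experiments on synthetic data.

These drive the whole pipeline on generated studies with known ground
truth and measure what a user cares about: are planted modules recovered,
do they pass the permutation and attract screens, does enrichment point
back at the right gene set, and are the statistics calibrated under the
null? Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import modules as mod
from . import significance as sig
from . import stats as st
from . import synthetic as syn
from .attract import attract_rank
from .enrichment import enrich_modules
from .network import build_dcn, edge_correlations

log = logging.getLogger(__name__)

#: Search-size cap used by the desk-scale experiments. On networks of a few
#: dozen nodes, unbounded entropy-greedy expansion can return the whole
#: (randomized) network as a single boundary-free module, which degrades the
#: permutation null; the cap forbids that degenerate solution. Observed
#: planted modules stop at their component boundaries far below the cap.
DESK_MAX_SIZE = 30

#: Permutation replicates for desk-scale runs (scaled down from the
#: documented default of 100 so a ten-seed experiment stays interactive).
DESK_REPLICATES = 50


@dataclass
class ModuleRecovery:
    """Recovery verdict for one planted module in one run."""

    planted_size: int
    jaccard: float
    adjusted_p: float | None
    is_dm: bool
    is_key: bool
    top_set_matches: bool


@dataclass
class RecoveryOutcome:
    rng_seed: int
    dcn_nodes: int
    dcn_edges: int
    per_module: list[ModuleRecovery]

    @property
    def all_recovered(self) -> bool:
        return all(
            r.jaccard >= 0.7 and r.is_dm and r.is_key and r.top_set_matches
            for r in self.per_module
        )


def run_planted_recovery(rng_seed: int, config: syn.SyntheticConfig | None = None,
                         n_replicates: int = DESK_REPLICATES,
                         max_size: int | None = DESK_MAX_SIZE,
                         top_fraction: float = 0.01) -> RecoveryOutcome:
    """Full pipeline on one synthetic study; verdict per planted module."""
    cfg = config or syn.SyntheticConfig(rng_seed=rng_seed)
    study, truth = syn.generate_study(cfg)
    edges = syn.generate_interactome(cfg, truth)
    gene_sets = syn.generate_gene_sets(truth, rng_seed=cfg.rng_seed)

    de = st.de_pvalues(study)
    corr = edge_correlations(study, edges)
    dcn = build_dcn(corr, de)
    _, found = mod.search_modules(dcn, top_fraction=top_fraction, max_size=max_size)
    null = sig.null_score_distribution(
        dcn, n_replicates=n_replicates,
        rng_seed=np.random.default_rng([cfg.rng_seed, 101]),
        top_fraction=top_fraction, max_size=max_size,
    )
    significance = sig.empirical_pvalues(found, null)
    dm_ids = {s.module_id for s in significance if s.is_dm}
    dms = [m for m in found if m.module_id in dm_ids]
    att = attract_rank(study, dms)
    key_ids = {a.module_id for a in att if a.is_key}
    keys = [m for m in found if m.module_id in key_ids]
    universe = set(study.gene_ids) & edges.genes()
    enr = enrich_modules(keys, gene_sets, universe) if keys else []

    sig_by_id = {s.module_id: s for s in significance}
    per_module: list[ModuleRecovery] = []
    for idx, planted in enumerate(truth.module_memberships, start=1):
        best = max(found, key=lambda m: mod.jaccard(m.members, planted), default=None)
        if best is None:
            per_module.append(ModuleRecovery(len(planted), 0.0, None, False, False, False))
            continue
        s = sig_by_id.get(best.module_id)
        rows = [r for r in enr if r.module_id == best.module_id]
        per_module.append(
            ModuleRecovery(
                planted_size=len(planted),
                jaccard=mod.jaccard(best.members, planted),
                adjusted_p=s.adjusted_p if s else None,
                is_dm=bool(s and s.is_dm),
                is_key=best.module_id in key_ids,
                top_set_matches=bool(rows) and rows[0].set_name == f"planted_{idx}",
            )
        )
    return RecoveryOutcome(cfg.rng_seed, dcn.n_nodes, dcn.n_edges, per_module)


def planted_recovery_experiment(seeds=range(10), **kwargs) -> list[RecoveryOutcome]:
    return [run_planted_recovery(s, **kwargs) for s in seeds]


def paired_t_uniformity(n_genes: int = 2000, rng_seed: int = 0) -> float:
    """KS P-value for uniformity of paired-t P-values under the null config."""
    cfg = syn.SyntheticConfig(n_genes=n_genes, planted_modules=(), rng_seed=rng_seed)
    study, _ = syn.generate_study(cfg)
    p = np.array(list(st.de_pvalues(study).values()))
    return float(sps.kstest(p, "uniform").pvalue)


def null_on_null_calibration(seeds=range(10), n_replicates: int = DESK_REPLICATES,
                             max_size: int | None = DESK_MAX_SIZE) -> tuple[int, int]:
    """Score modules found on a randomized DCN against the permutation null.

    For each study, the DCN is randomized once and module search is run on
    that randomization; the resulting modules are exchangeable with the
    null pool, so their empirical P-values should not concentrate below
    0.05. Returns (number significant at 0.05, total modules).
    """
    n_sig = n_total = 0
    for seed in seeds:
        cfg = syn.SyntheticConfig(rng_seed=seed)
        study, truth = syn.generate_study(cfg)
        edges = syn.generate_interactome(cfg, truth)
        de = st.de_pvalues(study)
        corr = edge_correlations(study, edges)
        dcn = build_dcn(corr, de)
        observed_net = sig.randomize_network(dcn, np.random.default_rng([seed, 7]))
        try:
            _, found = mod.search_modules(observed_net, max_size=max_size)
        except ValueError:
            found = []
        if not found:
            continue
        null = sig.null_score_distribution(
            dcn, n_replicates=n_replicates,
            rng_seed=np.random.default_rng([seed, 8]), max_size=max_size,
        )
        for s in sig.empirical_pvalues(found, null):
            n_total += 1
            n_sig += s.empirical_p <= 0.05
    return n_sig, n_total
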