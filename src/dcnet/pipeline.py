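"""End-to-end orchestration: simulate -> DCN -> modules -> significance ->
attract -> enrichment -> report.

A :class:`PipelineConfig` collects every stage's parameters (defaults:
delta = 0.9, top 1% seeds, minimum module size 5,
Jaccard 0.5, 100 randomizations, DM alpha 0.05, key alpha 0.05, enrichment
FDR < 0.01 with count >= 10). :func:`run` executes the stages in order,
writes the result tables plus a machine-readable manifest, and is
byte-reproducible for a fixed rng_seed and fixed inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import attract as attract_mod
from . import enrichment as enrichment_mod
from . import io as dio
from . import modules as mod
from . import network as net
from . import significance as sig
from . import stats
from . import synthetic as syn
from .containers import EdgeList, ExpressionStudy, GeneSetCollection

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # inputs
    matrix_path: str | None = None
    design_path: str | None = None
    mapping_path: str | None = None
    edges_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "dcnet_results"
    rng_seed: int = 0
    log_level: str = "INFO"
    # dcn
    delta: float = 0.9
    weight_form: str = "sum_of_roots"
    de_method: str = "paired_t"
    # module_search
    top_fraction: float = 0.01
    min_size: int = 5
    jaccard_threshold: float = 0.5
    max_size: int | None = None
    batch_add: bool = False
    # significance
    n_replicates: int = 100
    null_model: str = "gnm"
    dm_alpha: float = 0.05
    size_matched: bool = False
    # attract
    key_alpha: float = 0.05
    background: str = "all_genes"
    # enrichment
    fdr_max: float = 0.01
    min_count: int = 10
    universe: str = "study_and_interactome"
    # synthetic (used by `simulate`)
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)


_SECTIONS = {
    "inputs": ["matrix_path", "design_path", "mapping_path", "edges_path",
               "gmt_path", "out_dir", "rng_seed", "log_level"],
    "dcn": ["delta", "weight_form", "de_method"],
    "module_search": ["top_fraction", "min_size", "jaccard_threshold",
                      "max_size", "batch_add"],
    "significance": ["n_replicates", "null_model", "dm_alpha", "size_matched"],
    "attract": ["key_alpha", "background"],
    "enrichment": ["fdr_max", "min_count", "universe"],
}
_SYNTHETIC_KEYS = [f.name for f in dataclasses.fields(syn.SyntheticConfig)]


def load_config(path) -> PipelineConfig:
    """Load a YAML config with per-stage sections; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")
    cfg = PipelineConfig()
    for section, content in raw.items():
        if section == "synthetic":
            bad = sorted(set(content) - set(_SYNTHETIC_KEYS))
            if bad:
                raise ValueError(
                    f"unknown synthetic keys {bad}; valid keys: {_SYNTHETIC_KEYS}"
                )
            params = dict(content)
            if "planted_modules" in params:
                params["planted_modules"] = tuple(
                    syn.PlantedModule(*m) if isinstance(m, (list, tuple))
                    else syn.PlantedModule(**m)
                    for m in params["planted_modules"]
                )
            cfg.synthetic = syn.SyntheticConfig(**params)
            continue
        if section not in _SECTIONS:
            raise ValueError(
                f"unknown section {section!r}; valid sections: {sorted(_SECTIONS) + ['synthetic']}"
            )
        if content is None:
            continue
        valid = _SECTIONS[section]
        bad = sorted(set(content) - set(valid))
        if bad:
            raise ValueError(f"unknown keys {bad} in section {section!r}; valid keys: {valid}")
        for key, value in content.items():
            setattr(cfg, key, value)
    return cfg


def simulate(config: PipelineConfig, out_dir: str | None = None) -> dict[str, str]:
    """Generate a synthetic study + interactome + gene sets and write them."""
    out = out_dir or config.out_dir
    os.makedirs(out, exist_ok=True)
    study, truth = syn.generate_study(config.synthetic)
    edges = syn.generate_interactome(config.synthetic, truth)
    sets = syn.generate_gene_sets(truth, rng_seed=config.synthetic.rng_seed)

    paths = {
        "matrix": os.path.join(out, "matrix.tsv"),
        "design": os.path.join(out, "design.tsv"),
        "edges": os.path.join(out, "edges.tsv"),
        "gmt": os.path.join(out, "gene_sets.gmt"),
        "truth": os.path.join(out, "truth.json"),
    }
    dio.write_expression(study, paths["matrix"], paths["design"])
    dio.write_edge_list(edges, paths["edges"])
    dio.write_gmt(sets, paths["gmt"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "module_memberships": [sorted(m) for m in truth.module_memberships],
                "de_genes": sorted(truth.de_genes),
                "rng_seed": config.synthetic.rng_seed,
            },
            fh, indent=2,
        )
    log.info("simulated study written to %s", out)
    return paths


@dataclass
class RunSummary:
    """Counts, result paths and in-memory objects from one pipeline run."""

    dcn_nodes: int
    dcn_edges: int
    seed_count: int
    modules_found: int
    dm_count: int
    key_count: int
    enrichment_pass_count: int
    paths: dict[str, str]
    modules: list[mod.GeneModule]
    significance: list[sig.ModuleSignificance]
    attract: list[attract_mod.AttractResult]
    enrichment: list[enrichment_mod.EnrichmentRow]


def run_objects(study: ExpressionStudy, edges: EdgeList,
                gene_sets: GeneSetCollection | None,
                config: PipelineConfig) -> RunSummary:
    """Run all analysis stages on in-memory inputs and write results."""
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
        return _Timer()

    with stage("de"):
        de = stats.de_pvalues(study, method=config.de_method)
    with stage("dcn"):
        corr = net.edge_correlations(study, edges, condition="treated")
        dcn = net.build_dcn(corr, de, delta=config.delta, weight_form=config.weight_form)
    with stage("module_search"):
        ranking, found = mod.search_modules(
            dcn, top_fraction=config.top_fraction, min_size=config.min_size,
            jaccard_threshold=config.jaccard_threshold, max_size=config.max_size,
            batch_add=config.batch_add,
        )
    with stage("significance"):
        null = sig.null_score_distribution(
            dcn, n_replicates=config.n_replicates,
            rng_seed=np.random.default_rng([config.rng_seed, 101]),
            null_model=config.null_model, top_fraction=config.top_fraction,
            min_size=config.min_size, jaccard_threshold=config.jaccard_threshold,
            max_size=config.max_size, batch_add=config.batch_add,
        )
        significance = sig.empirical_pvalues(
            found, null, dm_alpha=config.dm_alpha, size_matched=config.size_matched,
        )
        dm_ids = {s.module_id for s in significance if s.is_dm}
        dms = [m for m in found if m.module_id in dm_ids]
    with stage("attract"):
        att = attract_mod.attract_rank(
            study, dms, key_alpha=config.key_alpha,
            background=config.background, dcn_nodes=dcn.nodes,
        )
        key_ids = {a.module_id for a in att if a.is_key}
        keys = [m for m in found if m.module_id in key_ids]
    with stage("enrichment"):
        if gene_sets is not None and keys:
            if config.universe == "study_and_interactome":
                universe = set(study.gene_ids) & edges.genes()
            elif config.universe == "study":
                universe = set(study.gene_ids)
            else:
                raise ValueError(f"unknown universe {config.universe!r}")
            enr = enrichment_mod.enrich_modules(
                keys, gene_sets, universe, fdr_max=config.fdr_max,
                min_count=config.min_count,
            )
        else:
            enr = []
    with stage("report"):
        paths = dio.write_results(found, significance, att, enr, config.out_dir)
        inter_dir = os.path.join(config.out_dir, "intermediate")
        os.makedirs(inter_dir, exist_ok=True)
        dio.write_edge_list(dcn.to_edge_list(), os.path.join(inter_dir, "dcn_edges.tsv"))
        with open(os.path.join(inter_dir, "seeds.tsv"), "w") as fh:
            fh.write("gene\tscore\tzscore\n")
            for s in ranking.seeds:
                fh.write(f"{s}\t{ranking.scores[s]!r}\t{ranking.zscores[s]!r}\n")
        with open(os.path.join(inter_dir, "null_scores.tsv"), "w") as fh:
            fh.write("entropy\tsize\n")
            for h, n_mem in zip(null.entropies, null.sizes):
                fh.write(f"{h!r}\t{int(n_mem)}\n")

    manifest = {
        "config": _config_echo(config),
        "timings_sec": {k: round(v, 4) for k, v in timings.items()},
        "counts": {
            "dcn_nodes": dcn.n_nodes,
            "dcn_edges": dcn.n_edges,
            "seed_count": len(ranking.seeds),
            "modules_found": len(found),
            "null_modules_pooled": len(null),
            "dm_count": len(dms),
            "key_count": len(keys),
            "enrichment_pass_count": sum(r.passes_filter for r in enr),
        },
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path

    return RunSummary(
        dcn_nodes=dcn.n_nodes, dcn_edges=dcn.n_edges,
        seed_count=len(ranking.seeds), modules_found=len(found),
        dm_count=len(dms), key_count=len(keys),
        enrichment_pass_count=sum(r.passes_filter for r in enr),
        paths=paths, modules=found, significance=significance,
        attract=att, enrichment=enr,
    )


def run(config: PipelineConfig) -> RunSummary:
    """Read the configured inputs and run the full analysis."""
    if config.matrix_path is None or config.design_path is None or config.edges_path is None:
        raise PipelineError("inputs", "matrix_path, design_path and edges_path are required")
    try:
        study = dio.read_expression(config.matrix_path, config.design_path,
                                    config.mapping_path)
        edges = dio.read_edge_list(config.edges_path)
        gene_sets = dio.read_gmt(config.gmt_path) if config.gmt_path else None
    except (OSError, ValueError) as exc:
        raise PipelineError("inputs", str(exc)) from exc
    return run_objects(study, edges, gene_sets, config)


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synthetic"]["planted_modules"] = [
        dataclasses.asdict(m) for m in config.synthetic.planted_modules
    ]
    return d
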