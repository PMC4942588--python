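"""Readers and writers for all external file formats.

Expression matrix and design table (TSV), probe -> symbol mapping,
STRING-style interactome edge lists, GMT gene-set collections, and the
tab-delimited result tables written at the end of a run.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EdgeList, ExpressionStudy, GeneSetCollection, canonical_pair

log = logging.getLogger(__name__)

MEMBERS_FILE = "module_members.tsv"
STATS_FILE = "module_stats.tsv"
ENRICHMENT_FILE = "enrichment.tsv"


def read_expression(matrix_path, design_path, mapping_path=None) -> ExpressionStudy:
    """Read an expression matrix plus design table into an ExpressionStudy.

    The matrix is tab-delimited with a header row of sample ids and a first
    column of gene (or probe) ids. The design table has columns
    ``sample_id``, ``condition`` (baseline/treated) and ``subject``. An
    optional mapping table (columns ``probe_id``, ``symbol``) collapses
    probes to symbols, keeping the probe with maximal row variance; probes
    without a mapping entry are dropped.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.columns.duplicated().any():
        raise ValueError("duplicate sample ids in matrix header")
    if mat.index.duplicated().any() and mapping_path is None:
        raise ValueError("duplicate gene ids in matrix without a mapping table")
    if mat.isna().any().any():
        raise ValueError("missing values in expression matrix are not supported")

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "subject"}
    if not required.issubset(design.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    missing = [s for s in design["sample_id"] if s not in mat.columns]
    if missing:
        raise ValueError(f"design references samples absent from the matrix: {missing}")

    extra = [c for c in mat.columns if c not in set(design["sample_id"])]
    if extra:
        log.warning("dropping %d samples absent from the design: %s", len(extra), extra)
        mat = mat.drop(columns=extra)
    # keep matrix column order for the retained samples
    condition = dict(zip(design["sample_id"], design["condition"].str.strip()))
    subject = dict(zip(design["sample_id"], design["subject"].str.strip()))

    if mapping_path is not None:
        mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
        if not {"probe_id", "symbol"}.issubset(mapping.columns):
            raise ValueError("mapping table must have columns probe_id, symbol")
        probe_to_symbol = dict(
            zip(mapping["probe_id"].str.strip(), mapping["symbol"].str.strip())
        )
        unmapped = [p for p in mat.index if p not in probe_to_symbol]
        if unmapped:
            log.warning("dropping %d probes without a symbol mapping", len(unmapped))
            mat = mat.drop(index=unmapped)
        variances = mat.var(axis=1, ddof=1)
        best: dict[str, str] = {}
        for probe in mat.index:
            sym = probe_to_symbol[probe]
            # max-variance collapse; deterministic tie-break on probe id
            incumbent = best.get(sym)
            if incumbent is None or variances[probe] > variances[incumbent] or (
                variances[probe] == variances[incumbent] and probe < incumbent
            ):
                best[sym] = probe
        symbols = sorted(best)
        mat = mat.loc[[best[s] for s in symbols]]
        mat.index = symbols

    gene_ids = [str(g).strip() for g in mat.index]
    study = ExpressionStudy(
        gene_ids=gene_ids,
        values=mat.to_numpy(dtype=float),
        sample_ids=[str(s) for s in mat.columns],
        condition=condition,
        subject=subject,
    )
    study.validate_design()
    return study


def read_edge_list(path) -> EdgeList:
    """Read a STRING-style two-column edge list with optional score column.

    Pairs are stored order-independently and deduplicated; self-pairs are
    dropped with a logged count. Lines with fewer than two fields raise a
    ValueError naming the line number.
    """
    edges = EdgeList()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 fields, got {len(fields)}")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            score = float(fields[2]) if len(fields) >= 3 else None
            edges.add(a, b, score)
    if n_self:
        log.warning("dropped %d self-pairs", n_self)
    return edges


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-separated)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT lines need >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate gene-set name {name!r}")
            sets[name] = {m.strip() for m in members if m.strip()}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges.pairs):
            score = edges.scores.get((a, b))
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score!r}\n")


def write_expression(study: ExpressionStudy, matrix_path, design_path) -> None:
    frame = pd.DataFrame(study.values, index=study.gene_ids, columns=study.sample_ids)
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep="\t")
    design = pd.DataFrame(
        {
            "sample_id": study.sample_ids,
            "condition": [study.condition[s] for s in study.sample_ids],
            "subject": [study.subject[s] for s in study.sample_ids],
        }
    )
    design.to_csv(design_path, sep="\t", index=False)


def write_results(modules, significance, attract_rows, enrichment_rows, out_dir) -> dict[str, str]:
    """Write the three tab-delimited result tables.

    ``module_members.tsv`` (module_id, seed, gene), ``module_stats.tsv``
    (one row per module with entropy, permutation and attract statistics),
    and ``enrichment.tsv``. Floats are written with shortest round-trip
    representation, so re-reading reproduces values exactly.
    """
    out_dir = str(out_dir)
    if not os.path.isdir(out_dir):
        try:
            os.makedirs(out_dir, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")

    members_rows = [
        {"module_id": m.module_id, "seed": m.seed, "gene": g}
        for m in modules
        for g in sorted(m.members)
    ]
    members = pd.DataFrame(members_rows, columns=["module_id", "seed", "gene"])

    sig_by_id = {s.module_id: s for s in significance}
    att_by_id = {a.module_id: a for a in attract_rows}
    stats_rows = []
    for m in modules:
        s = sig_by_id.get(m.module_id)
        a = att_by_id.get(m.module_id)
        stats_rows.append(
            {
                "module_id": m.module_id,
                "seed": m.seed,
                "size": len(m.members),
                "entropy": m.entropy,
                "empirical_P": s.empirical_p if s else np.nan,
                "adjusted_P": s.adjusted_p if s else np.nan,
                "attract_t": a.t if a else np.nan,
                "attract_adjusted_P": a.adjusted_p if a else np.nan,
                "is_DM": bool(s.is_dm) if s else False,
                "is_key": bool(a.is_key) if a else False,
            }
        )
    stats_cols = [
        "module_id", "seed", "size", "entropy", "empirical_P", "adjusted_P",
        "attract_t", "attract_adjusted_P", "is_DM", "is_key",
    ]
    stats = pd.DataFrame(stats_rows, columns=stats_cols)

    enr_cols = [
        "module_id", "set_name", "overlap", "set_size", "module_size",
        "universe_size", "P", "FDR", "passes_filter",
    ]
    enr = pd.DataFrame(
        [
            {
                "module_id": r.module_id,
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "module_size": r.module_size,
                "universe_size": r.universe_size,
                "P": r.p,
                "FDR": r.fdr,
                "passes_filter": r.passes_filter,
            }
            for r in enrichment_rows
        ],
        columns=enr_cols,
    )

    paths = {
        "members": os.path.join(out_dir, MEMBERS_FILE),
        "stats": os.path.join(out_dir, STATS_FILE),
        "enrichment": os.path.join(out_dir, ENRICHMENT_FILE),
    }
    members.to_csv(paths["members"], sep="\t", index=False)
    stats.to_csv(paths["stats"], sep="\t", index=False)
    enr.to_csv(paths["enrichment"], sep="\t", index=False)
    return paths


def read_results(out_dir) -> dict[str, pd.DataFrame]:
    """Re-read the result tables written by :func:`write_results`."""
    return {
        "members": pd.read_csv(os.path.join(out_dir, MEMBERS_FILE), sep="\t"),
        "stats": pd.read_csv(os.path.join(out_dir, STATS_FILE), sep="\t"),
        "enrichment": pd.read_csv(os.path.join(out_dir, ENRICHMENT_FILE), sep="\t"),
    }
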