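"""GSEA-ANOVA ("attract") ranking of differential modules.

For every gene a one-way ANOVA F-statistic across the study's condition
groups measures its group-discriminating power. A module is informative if
its members' log2 F values are collectively shifted relative to background
genes, assessed by a Welch t-test of member log2 F against non-member
log2 F. P-values are BH-adjusted across modules; modules with adjusted
P <= key_alpha are flagged key modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import stats
from .containers import ExpressionStudy
from .modules import GeneModule

log = logging.getLogger(__name__)

#: F-statistics are floored here before log2 so degenerate genes stay finite.
F_FLOOR = 2.0**-20

BACKGROUNDS = ("all_genes", "dcn_genes")


@dataclass
class AttractResult:
    module_id: str
    t: float
    df: float
    p: float
    adjusted_p: float
    is_key: bool


def attract_rank(study: ExpressionStudy, dms: Sequence[GeneModule],
                 key_alpha: float = 0.05, background: str = "all_genes",
                 dcn_nodes: Iterable[str] | None = None) -> list[AttractResult]:
    """Rank differential modules by the shift of their genes' log2 F values.

    ``background`` selects the comparison pool: all profiled non-member
    genes (``all_genes``, the GSEA-ANOVA contrast) or only non-member DCN
    genes (``dcn_genes``, requires ``dcn_nodes``). Results are sorted by
    adjusted P ascending.
    """
    if background not in BACKGROUNDS:
        raise ValueError(f"unknown background {background!r}; choose from {BACKGROUNDS}")
    if background == "dcn_genes" and dcn_nodes is None:
        raise ValueError("background='dcn_genes' requires dcn_nodes")
    if not dms:
        return []

    fres = stats.anova_f(study)
    logf = {g: math.log2(max(f if math.isfinite(f) else 1.0 / F_FLOOR, F_FLOOR))
            for g, f in fres.f.items()}
    study_genes = set(study.gene_ids)
    pool = study_genes if background == "all_genes" else set(dcn_nodes) & study_genes

    rows: list[tuple[GeneModule, float, float, float]] = []
    for m in dms:
        present = m.members & study_genes
        if not present:
            raise ValueError(f"module {m.module_id or m.seed!r} has no genes in the study")
        if len(present) < len(m.members):
            log.warning("module %s: %d members absent from the study",
                        m.module_id, len(m.members) - len(present))
        if len(present) < 2:
            raise ValueError(f"module {m.module_id!r} has fewer than 2 genes in the study")
        bg = sorted(pool - m.members)
        if len(bg) < 2:
            raise ValueError(f"background for module {m.module_id!r} has fewer than 2 genes")
        member_logf = [logf[g] for g in sorted(present)]
        bg_logf = [logf[g] for g in bg]
        t, df, p = stats.welch_t_test(member_logf, bg_logf)
        rows.append((m, t, df, p))

    adjusted = stats.bh_adjust([p for _, _, _, p in rows])
    results = [
        AttractResult(m.module_id, t, df, p, ap, bool(ap <= key_alpha))
        for (m, t, df, p), ap in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p, r.module_id))
    return results
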