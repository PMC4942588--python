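"""Hypergeometric gene-set enrichment of key-module genes.

Each (module, gene set) pair with a non-empty overlap is tested with the
one-sided hypergeometric test against a configurable gene universe; FDR is
computed by Benjamini-Hochberg within each module (each module is its own
family). A row passes the reporting filter when FDR < fdr_max and the
overlap count is at least min_count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import stats
from .containers import GeneSetCollection
from .modules import GeneModule

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    module_id: str
    set_name: str
    overlap: int
    set_size: int
    module_size: int
    universe_size: int
    p: float
    fdr: float
    passes_filter: bool


def enrich_modules(key_modules: Sequence[GeneModule], gene_sets: GeneSetCollection,
                   universe: Iterable[str], fdr_max: float = 0.01,
                   min_count: int = 10) -> list[EnrichmentRow]:
    """Test every key module against every gene set restricted to the universe.

    Gene sets are intersected with the universe before testing; the
    universe must contain every module gene. Rows are ordered per module by
    (FDR, P, set name), modules in input order.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    restricted = gene_sets.restricted_to(universe)
    N = len(universe)

    out: list[EnrichmentRow] = []
    for m in key_modules:
        missing = m.members - universe
        if missing:
            raise ValueError(
                f"module {m.module_id!r} has genes outside the universe: {sorted(missing)[:5]}"
            )
        members = m.members
        tested: list[tuple[str, int, int, float]] = []
        for name, genes in sorted(restricted.items()):
            overlap = len(members & genes)
            if overlap < 1:
                continue
            p = stats.hypergeom_pvalue(overlap, len(genes), len(members), N)
            tested.append((name, overlap, len(genes), p))
        if not tested:
            continue
        fdrs = stats.bh_adjust([p for _, _, _, p in tested])
        rows = [
            EnrichmentRow(
                module_id=m.module_id, set_name=name, overlap=overlap,
                set_size=set_size, module_size=len(members), universe_size=N,
                p=p, fdr=fdr, passes_filter=bool(fdr < fdr_max and overlap >= min_count),
            )
            for (name, overlap, set_size, p), fdr in zip(tested, fdrs)
        ]
        rows.sort(key=lambda r: (r.fdr, r.p, r.set_name))
        out.extend(rows)
    return out
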