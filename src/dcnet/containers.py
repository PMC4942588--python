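"""Core in-memory containers shared across the pipeline.

An :class:`ExpressionStudy` holds a gene x sample matrix of log-scale
expression values together with the two-condition (baseline/treated),
paired-subject design. :class:`EdgeList` is an undirected interactome and
:class:`GeneSetCollection` a named collection of gene sets (pathways).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

CONDITIONS = ("baseline", "treated")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-independent representation of an undirected gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionStudy:
    """Gene x sample expression matrix with condition and subject labels.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per matrix row.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` holding
        log-scale expression intensities.
    sample_ids
        Unique sample identifiers, one per matrix column.
    condition
        Map sample_id -> condition label (normally ``baseline``/``treated``).
    subject
        Map sample_id -> subject identifier; pairing key across conditions.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    condition: dict[str, str]
    subject: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.condition or s not in self.subject]
        if missing:
            raise ValueError(f"samples missing condition/subject labels: {missing}")
        # A subject may contribute at most one sample per condition.
        seen: set[tuple[str, str]] = set()
        for s in self.sample_ids:
            key = (self.subject[s], self.condition[s])
            if key in seen:
                raise ValueError(f"subject {key[0]} appears twice in condition {key[1]}")
            seen.add(key)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition[s] for s in self.sample_ids))

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition[s] == condition]

    def matrix_for(self, condition: str) -> np.ndarray:
        cols = [self.sample_ids.index(s) for s in self.samples_in(condition)]
        return self.values[:, cols]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def paired_matrices(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Baseline and treated matrices with columns aligned by subject.

        Returns ``(baseline, treated, subjects)`` where column ``j`` of both
        matrices belongs to ``subjects[j]``. Raises if any subject lacks a
        sample in either condition.
        """
        by_cond: dict[str, dict[str, str]] = {c: {} for c in CONDITIONS}
        for s in self.sample_ids:
            c = self.condition[s]
            if c in by_cond:
                by_cond[c][self.subject[s]] = s
        subjects = sorted(set(by_cond["baseline"]) | set(by_cond["treated"]))
        broken = [p for p in subjects if p not in by_cond["baseline"] or p not in by_cond["treated"]]
        if broken:
            raise ValueError(f"subjects without a sample in both conditions: {broken}")
        col = {s: j for j, s in enumerate(self.sample_ids)}
        b = self.values[:, [col[by_cond["baseline"][p]] for p in subjects]]
        t = self.values[:, [col[by_cond["treated"][p]] for p in subjects]]
        return b, t, subjects

    def validate_design(self) -> None:
        """Contract checks applied at the I/O boundary.

        Condition labels must be in ``{baseline, treated}`` and each
        condition must have at least two samples.
        """
        bad = sorted({c for c in self.condition.values() if c not in CONDITIONS})
        if bad:
            raise ValueError(f"condition labels outside {CONDITIONS}: {bad}")
        for c in CONDITIONS:
            if len(self.samples_in(c)) < 2:
                raise ValueError(f"fewer than 2 samples in condition {c!r}")


@dataclass
class EdgeList:
    """Undirected, deduplicated gene-symbol pairs with optional scores."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = {canonical_pair(*p) for p in self.pairs}
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pairs are not allowed")
        self.scores = {canonical_pair(*p): v for p, v in self.scores.items()}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Iterable[str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in p}

    def add(self, a: str, b: str, score: float | None = None) -> None:
        if a == b:
            raise ValueError(f"self-pair {a!r}")
        p = canonical_pair(a, b)
        self.pairs.add(p)
        if score is not None:
            self.scores[p] = float(score)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        kept = {n: s & universe for n, s in self.sets.items() if s & universe}
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})
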