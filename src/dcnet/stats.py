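"""Shared statistical primitives.

Per-gene differential-expression P-values (paired or Welch t-test), the
one-way ANOVA F-statistic used by the GSEA-ANOVA module ranking,
Benjamini-Hochberg step-up FDR adjustment, and the one-sided hypergeometric
overlap test used for gene-set enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .containers import ExpressionStudy

log = logging.getLogger(__name__)

#: Floor applied to P-values before taking logs downstream.
P_FLOOR = 1e-300


@dataclass
class FStatResult:
    """Per-gene one-way ANOVA F-statistics.

    ``infinite`` collects genes whose residual sum of squares is exactly
    zero while the treatment sum of squares is positive (F diverges);
    genes constant across all samples (0/0) are reported as F = 0.
    """

    f: dict[str, float]
    infinite: set[str] = field(default_factory=set)

    def __getitem__(self, gene: str) -> float:
        return self.f[gene]


def de_pvalues(study: ExpressionStudy, method: str = "paired_t") -> dict[str, float]:
    """Two-sided differential-expression P-value per gene.

    ``paired_t`` tests the per-subject treated-baseline differences against
    zero and requires every subject to be present in both conditions;
    ``welch_t`` is the unpaired fallback. Degenerate genes (zero variance of
    the paired differences, or zero variance in both groups) get P = 1.
    """
    if method == "paired_t":
        base, treat, _ = study.paired_matrices()
        diffs = treat - base
        n = diffs.shape[1]
        if n < 2:
            raise ValueError("paired_t requires at least 2 paired subjects")
        sd = diffs.std(axis=1, ddof=1)
        degenerate = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diffs.mean(axis=1) / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    elif method == "welch_t":
        a = study.matrix_for("baseline")
        b = study.matrix_for("treated")
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("welch_t requires >= 2 samples per condition")
        res = sps.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    else:
        raise ValueError(f"unknown DE method {method!r}")

    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    n_deg = int(degenerate.sum())
    if n_deg:
        log.warning("%d genes with degenerate variance set to P = 1", n_deg)
    p = np.clip(p, P_FLOOR, 1.0)
    return dict(zip(study.gene_ids, p.tolist()))


def anova_f(study: ExpressionStudy) -> FStatResult:
    """One-way ANOVA F per gene across the study's condition groups.

    F_m = MSS_m / RSS_m with
    MSS_m = (1/(K-1)) * sum_k r_k (ybar_km - ybar_m)^2 and
    RSS_m = (1/(N-K)) * sum_k sum_n (y_nkm - ybar_km)^2,
    i.e. the standard between/within mean-square ratio.
    """
    groups = study.conditions
    K = len(groups)
    N = study.n_samples
    if K < 2:
        raise ValueError("anova_f requires at least 2 groups")
    if N <= K:
        raise ValueError(f"N = {N} samples with K = {K} groups leaves no residual df")

    mats = [study.matrix_for(c) for c in groups]
    sizes = np.array([m.shape[1] for m in mats])
    group_means = np.column_stack([m.mean(axis=1) for m in mats])  # genes x K
    grand = study.values.mean(axis=1)

    mss = (sizes[None, :] * (group_means - grand[:, None]) ** 2).sum(axis=1) / (K - 1)
    rss = sum(((m - gm[:, None]) ** 2).sum(axis=1)
              for m, gm in zip(mats, group_means.T)) / (N - K)

    f = np.empty(study.n_genes)
    infinite: set[str] = set()
    n_const = 0
    for i, g in enumerate(study.gene_ids):
        if rss[i] == 0.0:
            if mss[i] == 0.0:
                f[i] = 0.0  # constant gene: 0/0 reported as 0
                n_const += 1
            else:
                f[i] = np.inf
                infinite.add(g)
        else:
            f[i] = mss[i] / rss[i]
    if n_const:
        log.warning("%d constant genes assigned F = 0", n_const)
    return FStatResult(dict(zip(study.gene_ids, f.tolist())), infinite)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values, in the input order.

    Sort ascending, multiply by n/rank, enforce monotonicity from the
    largest P down, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("P-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out.tolist()


def hypergeom_pvalue(overlap: int, set_size: int, module_size: int, universe_size: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeometric(N, K, n).

    ``overlap`` successes when drawing ``module_size`` genes from a
    ``universe_size`` universe containing ``set_size`` marked genes.
    """
    k, K, n, N = overlap, set_size, module_size, universe_size
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: overlap={k}, set_size={K}, module_size={n}, universe={N}"
        )
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Returns ``(t, df, two_sided_P)``. If both samples have zero variance
    the statistic is undefined; returns ``(0, n_a + n_b - 2, 1.0)`` with a
    warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires >= 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        log.warning("both samples have zero variance; returning P = 1")
        return 0.0, float(a.size + b.size - 2), 1.0
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df=df))
    return float(t), float(df), min(p, 1.0)
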