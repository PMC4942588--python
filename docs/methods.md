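# Methods

This note documents the statistical model behind `dcnet`, the defaults and
why they are set where they are, the numerical choices that are not forced
by the mathematics, and what the synthetic-data experiments do and do not
demonstrate.

## Input model

The pipeline expects a gene × sample matrix of log-scale expression
intensities with a paired two-condition design: each subject contributes
one baseline and one treated sample. Differential expression is therefore
assessed with a per-gene paired t-test on the treated−baseline differences
(two-sided); an unpaired Welch t-test is available (`de_method: welch_t`)
for designs without pairing. Genes with zero variance of the paired
differences get P = 1 with a warning rather than an error, because a
handful of flat probes should not abort a run.

## DCN construction

Candidate edges are interactome pairs only — the coexpression signal is
evaluated on a biologically constrained graph, not on all gene pairs.
Correlation is computed across the *treated* samples; the baseline
condition enters only through the differential-expression weights. The
edge filter is |Pearson r| ≥ δ with δ = 0.9 by default.

Edge weights combine both endpoints' DE significance:

    w_ij = (sqrt(L_i) + sqrt(L_j)) / (2 sqrt(max_l L_l)),  L_g = -log P_g,

with the maximum taken over the thresholded network's node set. Properties
that motivated this exact form: w ∈ [0, 1] with w = 1 attained exactly when
both endpoints are the network's most significant gene; w is monotone in
either endpoint's significance; and the logarithm base cancels, so natural
log and log10 give identical weights (checked to 1e-12 in the tests). An
alternative reading of the weight — sqrt(L_i + L_j) in the numerator — is
available as `weight_form: root_of_sum`; it caps at 1/sqrt(2) and is not
the default. P-values are floored at 1e-300 before logs.

## Seed prioritization

Gene scores are the fixed point of g ← A′g on the symmetrically normalized
weighted adjacency A′ = D^(−1/2) W D^(−1/2), computed by power iteration
(tolerance 1e-10, at most 10 000 iterations) from a uniform non-negative
start. The iteration is damped — each step averages A′g with g — which
leaves the fixed point unchanged while removing the sign oscillation that
bipartite-ish spectra (an isolated edge, an even cycle) otherwise cause.
The limit is the principal eigenvector of A′ (verified against a dense
eigendecomposition in the tests). Scores are z-scored across the network;
seeds are the top `floor(top_fraction · n)` genes (minimum one), ties
broken by gene id.

One deliberate refinement: on a *disconnected* network the fixed point is
a per-component multiple of the square root of weighted degree, and the
multipliers order whole components — every gene of the dominant component
outranks every gene of the others. A purely global top-k would therefore
never seed smaller components, which at small scale silently discards real
structure. `seed_ranking` consequently guarantees each connected component
of at least `min_component_size` (default 5) nodes its top-z gene as one
seed, expanding the budget if necessary; on a connected network this is
exactly the global top-k rule (2956 nodes → 29 seeds).

## Module entropy and expansion

The module score is the average boundary entropy

    H(C) = (1/|C|) Σ_{v∈C} h(p_v),   p_v = w_in(v) / w_tot(v),

where h is the binary entropy, w_in(v) the weight of v's edges into C and
w_tot(v) its total weighted degree. H = 0 means every member's edge weight
lies entirely inside the module; h(1/2) = 1 bit is the worst case.

Expansion is greedy hill-climbing on −H: starting from the seed's *closed
neighborhood* (the seed plus all its network neighbors), the single
neighbor with the largest entropy decrease ΔH is added while ΔH > 0 (ties
by gene id). The closed-neighborhood start matters: a two-node start
inside a dense module cannot grow at all, because h is concave with its
peak at p = 1/2 — adding the third member of a clique always *raises* the
average boundary entropy, so strict-improvement hill-climbing from a
minimal start is trapped on the wrong side of the entropy hump. Starting
from the closed neighborhood places the search past the hump for any
module denser than its surroundings, after which ΔH > 0 additions complete
the module. This is the standard initialization in entropy-based
seed-expansion clustering. A `batch_add` option adds *every*
ΔH > 0 neighbor per round instead (the procedure's literal reading); it
makes the entropy path depend on evaluation order and is off by default.

Candidate evaluations use incremental bookkeeping (O(deg u) per candidate);
the final entropy is recomputed from scratch, so the stored score is exact
and independent of the expansion path's floating-point history.

Refinement drops modules below `min_size` (default 5) and repeatedly
merges the pair with the highest Jaccard index ≥ 0.5 (the threshold is
inclusive). Merging recomputes entropy on the union and keeps the seed of
the canonically earlier (lower-entropy) parent; the whole refinement is
independent of input order, and module ids M1, M2, … are assigned in
ascending entropy.

## Permutation significance

Null networks share the DCN's node set and edge count; edges are drawn as
a uniform random simple graph (G(n, m)) and the observed weight multiset is
reassigned as a random permutation. A degree-preserving alternative
(`null_model: rewire`, double-edge swaps) is available. The full module
search runs on every replicate (default 100; the desk-scale experiments use
50) and all resulting module entropies are pooled. The empirical P-value
uses a pseudocount, P = (1 + #{null ≤ observed})/(1 + #null), so P is never
0 and BH adjustment across the observed modules is well defined. Smaller
entropy is better, consistent with ΔH > 0 meaning entropy decrease. A
size-stratified option (`size_matched`, ±20% of the module's size, falling
back to the full pool when the stratum is empty) exists because entropy
correlates with module size; it is off by default.

### Small-network degeneracy and the `max_size` guard

On networks of a few dozen nodes, greedy entropy minimization can reach
the *entire* connected graph: a module with no boundary has H = 0
vacuously, and once a module covers more than about half of a dense graph
every addition lowers the average boundary entropy, so the search rolls
downhill to the trivial solution. On randomized desk-scale networks
(~35-40 nodes, density ~0.35) this made nearly every null module the whole
graph with H = 0, destroying the contrast with genuine modules. The
`max_size` knob bounds module growth (and truncates an oversized initial
neighborhood to the strongest-weight neighbors); the desk-scale
experiments set it to 30 — about three-quarters of the DCN — which forbids
the degenerate whole-network solution while leaving real module expansion
untouched (planted modules stop at their component boundaries, sizes
20/15). At realistic scales (thousands of nodes) expansion never
approaches the full graph and the default `max_size: null` is appropriate.

## Attract (GSEA-ANOVA) ranking

Per gene, the one-way ANOVA F-statistic across the condition groups uses
the standard between/within mean-square ratio (the residual sum of squares
is taken around the *group* means; with K = 2 this makes F equal the
squared pooled t-statistic, which the tests verify to 1e-9). Degenerate
genes: constant genes get F = 0 with a warning; zero residual variance
with a real group effect is flagged infinite, and F values are floored at
2^-20 before log2 so the downstream t-test stays finite.

A module is ranked by a Welch t-test of its members' log2 F against the
log2 F of background genes, two-sided, BH-adjusted across modules. The
background defaults to *all* profiled non-member genes — the contrast the
GSEA-ANOVA approach defines. Restricting background to non-member DCN
genes (`background: dcn_genes`) is available but degenerates whenever the
DCN consists mostly of the modules themselves, as it does at desk scale:
the "background" is then just the other module.

## Enrichment

One-sided hypergeometric test per (module, gene set) pair with overlap ≥ 1;
gene sets are intersected with the universe first. The universe defaults to
genes present in both the study and the interactome — the mapped background
a practitioner would use — with `universe: study` as an override. FDR is
computed within each module (each module is its own BH family, matching
per-module pathway reporting); the reported filter is FDR < 0.01 and
overlap ≥ 10.

## Synthetic data: what it emulates, what it does not

`generate_study` draws baseline samples as i.i.d. Normal(0, σ²) for every
gene. In treated samples each planted module has one latent factor value
f_s per sample and member genes take λ f_s + sqrt(1−λ²) ε + dσ with
ε ~ Normal(0, σ²), so members have unit variance (for σ = 1), pairwise
population correlation λ², and a d·σ mean shift in the treated condition
only. Defaults (the desk-scale study conditions used across the tests):
800 genes, 10 paired subjects, modules of 20 and 15 genes with λ = 0.97
and d = 2, noise SD 1. The interactome contains each within-module pair
with probability 0.9 (redrawn, up to 100 times, until the module subgraph
is connected) and every other pair with probability 0.01. One gene set per
planted module (exact membership) plus random decoy sets feeds the
enrichment stage. All randomness streams from a single seed via fixed
per-stage substreams, so each artifact is independently reproducible.

With λ = 0.97 the population within-module correlation is λ² = 0.9409,
just above the δ = 0.9 filter. Because all of a module's pairs share one
factor, the realized sample correlations move jointly with the factor's
sample variance: per-run survival of within-module pairs at δ = 0.9 ranges
from ~0.5 to 1.0 across seeds (mean ≈ 0.85 over ten seeds), which is why
generator tests assert on means over seeds rather than per-run fractions.

Not emulated: probe-level effects, batch structure, heteroskedastic or
heavy-tailed microarray noise, negative correlation, baseline coexpression,
and overlap between modules. Passing recovery tests therefore show that the
algorithmic chain behaves as designed under its own model assumptions —
not that the method is robust to real microarray artifacts.

## Desk-scale experiment sizes

The validation experiments (`dcnet.validation`) run the full pipeline on
ten generator seeds with 50 permutation replicates, `max_size` 30 and the
default top-1% seed rule; the null-calibration experiment scores modules
found on a randomized DCN against nulls from further randomizations of the
same DCN. The whole set completes in seconds. One known failure mode at
this scale, observed at roughly one seed in ten: a chance background edge
that survives the correlation filter can bridge the two planted components
into one, in which case the single-component DCN gets one seed and only
one of the two modules can be discovered.

## Known limitations

- The entropy objective is vacuous for modules that exhaust their
  component; at small scales the `max_size` guard is required (above).
- The G(n, m) null preserves global density but not degree structure; use
  `null_model: rewire` when degree heterogeneity matters.
- The paired t-test assumes approximately normal paired differences;
  with 10 subjects, heavy tails will inflate the DE weights' spread.
- Merging at Jaccard ≥ 0.5 is single-linkage-like: chains of pairwise
  overlaps can coalesce into one large module.
- Expansion from a seed adjacent to a pendant chain can absorb the chain
  (low-degree nodes have near-zero boundary entropy); interior seeds, the
  typical case after propagation ranking, do not show this.
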