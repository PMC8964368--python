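# Methods

This note documents the statistical procedures `cochnet` implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data experiments do and do not demonstrate.

## Study design being modelled

Three mouse models of sensorineural hearing loss — aging, noise
over-exposure and cisplatin ototoxicity — are profiled by bulk cochlear
RNA-seq at a healthy control stage and an early and a late damage stage per
model. The control group (healthy 2-month animals) is a single shared
group: no model has its own baseline, which is what makes eigengene
trajectories comparable across models. The default simulated design is 12
shared controls plus, per model, 3 early- and 2 late-stage replicates — 27
samples. The split within the early/late groups is a package choice (the
generator exposes all counts in `SimConfig`); it is symmetric across models
so that the three models are statistically exchangeable.

## Synthetic expression model

Expression is simulated on the log2 scale as a loading/template factor
model

    x_gs = mu_g + lambda_g * E_m(model(s), stage(s)) + eps_gs

with per-gene baseline `mu_g ~ Normal(3, 1)` (log2 FPKM units; median ~8
FPKM), loading `lambda_g ~ Uniform(0.7, 1.3)` for planted genes and 0 for
background genes, i.i.d. noise `eps ~ Normal(0, 0.4^2)`, and emitted
FPKM `= 2^x − 1` clipped at zero — the exact inverse of the pipeline's
log2(FPKM + 1), so transforms round-trip.

Stage templates come from archetypes: `shared_up` (0, 1, 2 in every model),
`shared_down` (0, −1, −2), `model_specific:<model>` (0, 1, 2 in one model,
flat elsewhere) and `null_flat`. Control values are 0 in every archetype,
so the shared control group is internally consistent. The default bundle
plants six modules (shared up, shared down, one per-model specific, one
null) of sizes 200/200/200/200/200/100 among 2000 genes; loadings in
[0.7, 1.3] make membership heterogeneous but sign-consistent, as a signed
network assumes.

What the generator deliberately does **not** model: library-size or depth
variation, batch effects, count noise (FPKM is treated as a continuous
measurement), gene–gene correlation inside the background, overlapping
module membership, and annotation/PPI databases with realistic topology.
Recovery results on this generator certify the pipeline's statistical
logic, not its behaviour on raw sequencing artifacts.

The annotation generator plants one term per module containing 80% of the
module plus outside fillers (term size = module size), along with 30
uniform decoy terms. The PPI generator designates 3 hub genes per module,
connects each hub to every module member, adds non-hub within-module edges
at density 0.05 and 2000 uniform background edges, and draws integer
confidence scores in [400, 999] (so the default score threshold of 400
keeps everything in synthetic runs while the threshold remains meaningful
for real STRING exports).

## Network construction

Correlation is Pearson over **all samples pooled** — one network for the
whole triad, since the object of interest is co-variation along damage in
general, not within one model. Genes whose profile is constant to within
1e-10 (relative to the row's magnitude) get correlation 0 and a flag rather
than an error: on synthetic or heavily-filtered data, exactly flat rows are
legitimate inputs, and the tolerance matters because a numerically flat row
has ulp-level jitter whose pattern is shared across genes and would
otherwise correlate at ±1.

Adjacency is the standard signed form `((1 + cor)/2)^β`, mapping cor −1 to
0 so anti-correlated genes are disconnected. The default β = 15 is the
pipeline's fixed operating point; `pick_soft_threshold` scans candidate
powers and takes the smallest whose scale-free fit R² (signed log–log
regression of the binned degree distribution, 10 equal-width bins) reaches
0.85, falling back to the argmax with a warning. A perfectly flat degree
histogram returns fit 0 (no power-law signature) and a single-bin
degenerate case returns NaN.

TOM is the classical overlap `(L + a)/(min(k_i, k_j) + 1 − a)` computed by
one matrix product on the diagonal-zeroed adjacency; this equals the
literal triple sum because the u = i, j terms vanish. Tests hold it to the
brute-force O(n³) oracle at 1e-10.

## Module detection

Average-linkage hierarchical clustering runs on `1 − TOM`. The tree is cut
**statically at an absolute height, default 0.95**. A quantile-of-merge-
heights cut (`cut_height=None`, `cut_quantile`) is also available but is
not the default: when a majority of genes are background, the merge-height
distribution is dominated by background merges at dissimilarity ≈ 1, so
any high quantile lands above the cross-module merge heights and fuses all
real modules into one cluster. The absolute default sits in the analytic
gap for this data class: within-module merges occur below ~0.9 (at the
default noise level) and cross-module merges above ~0.96 even in the
noise-free limit. Clusters below `min_module_size = 30` go to the
unassigned label M0. Over-splitting is repaired by the merge step: module
eigengenes are computed and the most-correlated pair above
`merge_cutoff = 0.75` is fused, iteratively. Labels M1, M2, ... are
assigned by decreasing size (ties: earliest member in input order).

Exact replication of any particular real-data module count is out of
scope: it depends on an unstated cut parameterization and on the data
themselves. The recovery criterion used instead is the adjusted Rand index
against planted labels, computed over genes planted in *signal* modules —
null-profile genes carry no correlation signal by construction and are not
a recovery target (in the noise-free limit they are constant and land in
M0, which is the correct behaviour).

The eigengene is the first right singular direction of the module's
row-standardized expression, unit-norm over samples, sign-oriented so that
its correlation with the mean standardized module profile is non-negative.
A one-gene module returns its normalized standardized profile.

## Cross-model trajectories

The eigengene is averaged within each (model, stage) group; the shared
control group is reused as the control point of all three models, so every
trajectory starts from the same value. Correlating 3-point stage means —
rather than pairing individual samples — is the major interpretive choice:
the models have different, unpaired samples, so sample-level correlation is
not defined, while stage means are.

Selection reads "R > 0.85 in any two of the three models" as **at least
one model pair** (default `min_pairs = 1`); a strict all-pairs mode
(`min_pairs = 3`) preserves the other reading. Highlighting requires the
averaged R (over defined pairs) to exceed 0.92. Direction is the sign of
the mean late-minus-control change across models, with an optional
flat tolerance.

A pairwise R is **undefined** when either trajectory is effectively flat.
Exact zero variance is flagged always; at the report level the guard
extends to excursions below `0.5/sqrt(n_samples)` (~0.096 at n = 27) —
half a typical sample value of a unit-norm eigengene. The rationale: a
model-specific module's trajectories in the other two models are eigengene
noise with excursions measured around 0.02, two orders below real signal
(≥ 0.48), yet 3-point Pearson R is scale-free, so without the guard such
noise trajectories occasionally correlate above 0.92 by chance and would be
spuriously highlighted. Undefined correlations are reported as 0 with an
explicit flag, never dropped; the low-level
`pairwise_trajectory_correlation` keeps guard 0 by default, so R remains
invariant to positive affine rescaling at the operation level.

## Enrichment

One-sided (over-representation) Fisher's exact test: for overlap k, module
size n, term size K, universe N, p = P[X ≥ k] under Hypergeom(N, K, n).
The universe is the annotation universe (all genes with any annotation),
matching an all-genes background; genes outside it are excluded and
counted. FDR is Benjamini–Hochberg, computed per module and per collection.
Ranking is by ascending p with ties broken by larger overlap then term id;
the top-5 slice carries a significance flag at FDR ≤ 0.05. The
implementation uses `scipy.stats.hypergeom` and
`statsmodels.multipletests`; tests verify both against exact integer
enumeration and the hand step-up formula.

## PPI hubs

The module gene list induces a subgraph; genes absent from the network are
reported and kept in coverage denominators. Degree is the raw incident-edge
count; closeness is normalised within each connected component,
`(n_c − 1)/Σ d`, with isolated nodes at 0 — well-defined on the
disconnected graphs induction produces. Hubs are the top 15 by degree, with
closeness then gene id breaking ties (the ranking key is a package choice;
both centralities are reported). Gene coverage counts non-hub input genes
adjacent to at least one hub over the full deduplicated input list (hubs
stay in the denominator, not the numerator); edge coverage counts edges
with a hub endpoint over all edges of the induced graph.

## Assay formulas

`2^(−ΔΔCt)` with ΔΔCt = (Ct_target − Ct_ref) under treatment minus the
same under control; replicate Ct values are averaged before the
subtraction (standard practice; per-replicate computation is available by
passing scalars). Relative viability is
`(OD_exp − OD_pos)/(OD_neg − OD_pos) × 100` with the no-cell control as
OD_pos; values outside [0, 100] are reported as-is with a flag. A plain
two-sided t-test helper is included for group comparisons; no
amplification-efficiency correction is attempted.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; sub-streams (annotations, PPI) are derived by
hashing the seed with a label. Pipeline stages communicate only through
files and write manifests with SHA-256 hashes of inputs and outputs;
rerunning a stage with identical inputs is byte-identical.

The test and acceptance experiments run at the study scale (2000 genes, 27
samples, ten seeded replicates for the shared-module experiment) — sizes
chosen because recovery behaviour is already asymptotic there while a full
run takes seconds. Oracle checks use exhaustive or brute-force computation
at small n (TOM n = 20, Fisher N ≤ 60, graphs n ≤ 30).

## Known limitations

- The static-cut/merge detector is deliberately simple; it recovers
  well-separated planted modules exactly but is not a dynamic-tree-cut
  replacement for real dendrograms with nested structure.
- 3-point trajectory correlations carry no significance statement (none is
  computable from 3 points); selection thresholds are descriptive rules.
- The generator's idealisations (no batch effects, independent noise,
  disjoint modules) mean recovery rates here are upper bounds on real-data
  performance.
- Enrichment assumes flat annotation sets; no ontology-graph propagation.
- PPI analysis is unweighted beyond the score threshold; no betweenness or
  weighted shortest paths.
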