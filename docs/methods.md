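# Methods

This note records the models implemented in `pathcarc`, the assumptions
behind them, the tunable parameters with their defaults, and the design
choices made where more than one reasonable construction existed.

## Pathway representation and topological weights

A pathway is a directed graph of gene nodes (`pathways.PathwayNetwork`);
an undirected interaction is stored as two ordered pairs, self-loops are
rejected. The biological picture is receptor-to-transcription signal flow:
*terminus* nodes (out-degree 0) sit at the transcription-triggering end.

Node weights (`node_weights`): with $d_T(v)$ the directed shortest-path
length from $v$ to the nearest terminus and $D$ the largest finite $d_T$,

    w(v) = 1 + λ (1 − d_T(v)/D),   λ > 0, default 1.

Conventions for degenerate graphs: unreachable-to-terminus nodes weigh 1;
a graph with no terminus (e.g. a fully undirected cycle) weighs 1
everywhere; if $D = 0$, termini weigh $1+λ$ and everything else 1. The
linear-in-distance form is this package's choice: it is monotone toward
the terminus, bounded in $[1, 1+λ]$, and safe on every degenerate input.

Gene–gene proximity (`pairwise_distances`) uses *undirected* shortest-path
lengths: metabolic maps are largely undirected and "perturbed genes close
to each other" is a symmetric notion. Disconnected pairs are carried as
`inf`, never as a large sentinel, so the proximity kernel can map
disconnection to exactly zero.

GMT gene sets are accepted as an edge-free fallback: every node is then a
terminus (uniform weights) and all distances are infinite (the proximity
term degenerates to 1), which reduces the statistic to a weighted mean.

## Enrichment statistic and permutation null

Gene-level scores are absolute pooled-variance two-sample *t* statistics
on log2 expression (treated vs control, ≥ 2 animals per group).
Zero-variance genes score 0 when the group means agree and the table
maximum when they do not (a gene that moved identically in every animal is
maximally perturbed, not undefined). Classic quantile normalization
(`quantile_normalize`) is available as preprocessing; ties receive the
mean of the reference values over the tied rank span.

The pathway score is the product of two brackets (README formula): a
weight-normalized mean perturbation and one plus a score-product-weighted
mean of the proximity kernel κ(d) = 1/(1+d). The second bracket is defined
as 1 when fewer than two nodes are measured or all pairwise score products
vanish. Unmeasured pathway nodes are dropped from both terms; a pathway
with no measured node is skipped and its feature imputed as z = 0 (the
null median), which keeps feature columns aligned across species — the
alternative, dropping columns, would break cross-species panels.

The null reassigns the observed score multiset over the measured universe
— equivalently, each draw scores the pathway on a uniformly drawn
without-replacement sample of |V| values from the score multiset. The
gene-set variant draws |gene set| genes uniformly without replacement.
With K draws (default 5×10⁴; the add-one estimator
p = (1 + #{null ≥ observed}) / (K + 1) keeps p in [1/(K+1), 1]. Features
use z = Φ⁻¹(1 − p) with p clamped to 1 − 1/(K+1) so z is always finite.
Two scaling properties hold by construction: the score is homogeneous of
degree 1 in a common positive rescaling of all gene scores (the second
bracket is scale-free), so permutation p-values are rescaling-invariant;
and under score/topology independence the p-values are uniform on their
achievable grid (checked by Kolmogorov–Smirnov in the test suite).

Implementation note: the per-pathway API (`permutation_pvalue`) draws an
independent null for each pathway. The batch builder
(`pathway_feature_matrix`) instead shares one set of K global permutations
of a chemical's gene-score assignment across the whole pathway panel —
each draw is still an exact without-replacement reassignment, but a
216-pathway × 5×10⁴-draw run stays tractable. The cost is a weak
dependence between pathway p-values within one chemical; marginal
calibration is unaffected.

## Poly-3 carcinogenicity target

Animals dying tumor-free at study fraction t contribute weight t³ to the
adjusted group size; tumor-bearing animals and terminal survivors weigh 1
(`poly3_adjusted_counts`; adjusted counts are therefore real-valued). The
statistic is the pooled two-proportion z (README formula); a degenerate
pooled proportion (0 or 1) yields z = 0. The variance uses the *pooled*
proportion — the unpooled alternative is defensible but pooled matches the
null-hypothesis framing of the bioassay trend test. The test is one-sided
(tumor increases only), consistent with the asymmetric outlier cap:
z values above Φ⁻¹(1 − 2×10⁻⁵) ≈ 4.1075 are capped, the lower tail never
is. Binary calls are positive iff the one-sided p ≤ 0.01 (inclusive), so
equivocal bioassay outcomes at p ≈ 0.075–0.084 land negative.

## Prediction model

`PathwayCarcinogenicityModel` fits continuous capped-z targets on the
chemicals × pathways z-feature matrix.

* **Folds** (`make_folds`): chemicals sorted by target, cut into strata of
  5 consecutive chemicals; each stratum deals to distinct folds with a
  seeded random order, and the following stratum uses that order reversed
  (serpentine pairing). Fold sizes differ by ≤ 1 (26 → 6,5,5,5,5) and every
  fold spans the target range.
* **Library**: random forest (500 trees, √N_p features per split), SVR,
  ridge — a compact stand-in for a larger ensemble library; the final-model
  path depends only on the forest. Learners that raise are excluded and
  logged, never silently imputed.
* **Selection**: discrete super learner = argmin cross-validated MSE (ties
  break by library order); continuous super learner = non-negative least
  squares weights on the out-of-fold prediction matrix, normalized to sum
  to 1 (uniform with a warning if all predictions are constant).
* **Honest predictions**: outer 5-fold CV; within each outer training
  complement, an inner 5-fold CV performs the selection, the selection is
  refit on the full complement and predicts the held-out fold. Changing a
  held-out chemical's target cannot change its own prediction (asserted
  exactly in tests).
* **Importance**: permutation importance of the final forest — mean
  increase in training-set MSE over 10 permutations of each column, all
  permuted copies scored in a single batched predict call. Training-set
  (rather than out-of-bag) permutation importance is this package's
  choice; for the ranking use made of it here the two agree in practice.
* All seeds derive deterministically from one master seed.

`predict_panel` refuses any column mismatch (missing, extra, or reordered
pathways) instead of silently realigning — cross-species panels must share
the training panel order exactly.

## Evaluation

AUC is the tie-aware Mann–Whitney probability (ties count ½), computed via
average ranks and cross-checked in tests against O(n²) pair counting.
Operating points: among ROC vertices (thresholds at observed scores, call
positive if score ≥ threshold) whose specificity lies inside a window
(default 0.56–0.75), pick maximal sensitivity, breaking ties toward higher
specificity; the reconstruction rule recovers the published confusion rows
exactly on the table-derived fixtures. Dose-response slopes are OLS of
predicted z on dose (rescalable to per-unit-dose reporting) with a
one-sided upper-tail t test on n − 2 degrees of freedom; a perfectly flat
series gives slope 0 and p = 0.5 exactly.

## Synthetic data generator

`GeneratorConfig` defaults define the study conditions: 26 chemicals (half
carcinogenic, rounded up), 4000 genes, 200 pathways of 10–80 genes with
1–3 termini each (preferential-attachment DAG skeletons), 5 shared causal
pathways, effect size δ = 1.0 log2 units with terminus bias b = 0.5 (the
terminal half of each causal pathway shifts by δ(1+b) — placing signal
where the topological weighting looks), within-group noise σ = 1.0 on a
N(7, 1) baseline, 4 animals per expression group, and a tumor model that
goes through per-animal outcomes: control tumor probability q₀ = 0.2,
treated probability expit(logit(q₀) + γ·m) with γ = 1.5 and m the mean
causal-gene shift, 50 animals per arm, 20% of tumor-free animals dying
uniformly on [0.4, 1] of the study — so the poly-3 weighting path is
exercised end to end, not bypassed.

Extra species reuse the pathway topology with an ε = 0.1 fraction of gene
labels re-drawn (as a cycle among the re-drawn genes, so relabeling stays
bijective and no pathway acquires duplicate nodes). The biology perturbs
the orthologs of the *reference* causal genes, so ε controls how much of
the causal signal the other species' pathway annotation misses — the
mechanism behind graceful cross-species degradation.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, correlated gene noise, litter effects, historical-control
drift, or chemicals with heterogeneous modes of action (all carcinogens
share one causal pathway set). Passing tests therefore demonstrate that
the pipeline recovers planted pathway-level signal under idealized noise,
not that any particular real-data accuracy is attainable.

## Problem sizes and numerical choices

Unit and property tests run on scaled-down studies (hundreds of genes,
tens of pathways, K in the hundreds) chosen to exercise every code path
quickly; the simulation-based checks use the full default conditions (26
chemicals, 200 pathways) with K = 1000 permutation draws over 10 seeds for
signal recovery and 50 seeds for the chance-level floor — sizes at which
the checked statistics are stable. Permutation draws are vectorized
(random-key argpartition for without-replacement sampling; one K × m
matrix product per pathway), which is what makes the default K = 5×10⁴
usable on real panels.

## Known limitations

The enrichment statistic is a network-weighted, proximity-rewarding score
defined, tested and calibrated on its own terms; numerical agreement with
other SEPEA implementations is not claimed. The
poly-3 variance uses pooled proportions; unpooled is a one-line change.
Multiple-testing correction of pathway p-values is deliberately absent:
all z features feed the model, no selection step exists. Real-data AUCs
require the original arrays and are out of scope.
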