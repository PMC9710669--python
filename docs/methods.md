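# Methods

This note documents the models and procedures `biodrift` implements, the
parameters that matter, the synthetic data the tests run on, and the
numerical conventions that make runs reproducible.

## The online ensemble

The unit of processing is one labeled, Z-scored expression profile. The
ensemble holds a knowledge-based classifier `C_KB` over the known biomarker
panel plus one discovered classifier `C_F` per feature-drift event; no
model is ever removed. For each incoming instance, in order:

1. **Predict** with the soft vote (unweighted mean of class distributions)
   of `C_KB` plus the `R` discovered models with highest prequential
   balanced accuracy. Ties in the vote resolve to the lowest class index;
   ties in the model ranking resolve to the more recently spawned model;
   models that have not yet been scored on any instance rank last.
2. **Score** every model against the true label (each on its own
   prediction) — strictly before training, so all accuracies are
   prequential.
3. **Train** every model on the instance.
4. **Buffer** the instance. When the buffer reaches the window size `W`,
   the chunk is ranked with mRMR; selected genes outside the known panel
   and all previous selections constitute a drift event, which spawns a new
   base model trained one pass over the buffered chunk using the *full*
   selection (all `n_select` genes, not only the novel ones). A chunk with
   a single class present skips selection (logged); a trailing partial
   chunk at stream end is ignored.

With an empty known panel (de-novo discovery) no classifier exists until
the first drift event; until then predictions are uniform. The first
spawned model then takes the always-voting `C_KB` seat.

Key parameters: `W` (window, 200 or 500 in the intended regimes), `R`
(voting models, 1–3), `n_select` (10). The final biomarker model is
`known_panel ∪ discovered_union`, panel genes first, discovered genes in
first-selection order — hence its intersection with the initial panel is
always the full panel.

## mRMR ranking

Expression values are discretized per gene into 3 equal-frequency bins
(low/mid/high; ties broken by stable sample order; vectors with fewer
distinct values than bins collapse with a warning). Mutual information is
the plug-in contingency estimate in bits. Greedy forward selection
maximizes `I(f; class)` first, then `I(f; class) − mean_{s∈S} I(f; s)`
(difference scheme, the default; the quotient scheme is available). All
tie-breaks are lowest feature index, so a chunk yields exactly one
selection. Relevance terms are computed once per chunk and redundancy rows
cached; tests assert equality with a naive per-step recomputation.

## Adaptive windowing (ADWIN)

Each detector keeps a bounded signal in an exponential histogram (rows of
at most 5 buckets holding 1, 2, 4, … observations; overfull rows merge
their two oldest buckets into the next row). After every update each
bucket boundary is tested as a cut: with sub-window means `mu0, mu1`,
sizes `n0, n1`, harmonic-mean size `m`, and `delta' = delta / #cuts`, the
old half is dropped when `|mu0 − mu1| >= sqrt(ln(4/delta') / (2m))`.
Defaults: `delta = 0.002`, 5 buckets per row. Memory is O(log W); the
estimate is the exact mean of the retained window (bucket sums are exact).

## Hoeffding trees

Leaves accumulate per-(feature, class) Welford statistics. Every
`grace_period = 100` instances a leaf evaluates 10 candidate thresholds
per feature, placed uniformly over the pooled ±3-sigma range of the
per-class Gaussians, scoring expected information gain with left/right
class masses from the Gaussian CDF. The best split must beat the runner-up
(or the null split) by the Hoeffding bound with `R = log2(K)` and
`delta = 1e-5`, or the bound must be tighter than the tie threshold
`tau = 0.05`. Leaves with >= `nb_threshold = 10` instances predict with a
Gaussian naive-Bayes posterior (Laplace-smoothed priors; variance floor
1e-3 in squared Z-units); younger leaves return normalized counts; empty
trees are uniform.

The adaptive variant attaches an ADWIN to every node, fed the 0/1 error of
the subtree's own prediction on each instance passing through. A detection
starts an alternate subtree trained on the same traffic; every 100
instances routed through the node the alternate's ADWIN error estimate is
compared with the original's and the alternate replaces the subtree when
lower by more than a Hoeffding bound (R = 1, same delta) at the smaller of
the two window sizes — or is abandoned on the symmetric condition. When no
detector fires the adaptive tree is identical to the plain VFDT (tested).

The chunk-trained random-forest base learner (500 trees, sqrt
max-features) fits once on the chunk that spawns it and is static
afterwards; forests cannot learn incrementally, so this variant trades
adaptivity within a model for batch fit quality.

## Prequential evaluation

Balanced accuracy is the macro average of per-class recall, cumulative
from stream start; classes with no true instances yet are excluded from
the mean (otherwise the early trace is undefined). A windowed variant
(centred moving mean of 0/1 correctness, edge-corrected) supports dip
localization; the recorded dip index is the start of the steepest fall of
the smoothed trace. The NoEns baseline is a single adaptive tree over the
known panel (over all genes when the panel is empty) and is exactly
equivalent to driving the tree directly (tested).

## Cohort preparation

Expression matrices are Z-scored per gene within one cohort (n−1
denominator) before concatenation; zero-variance genes are dropped with a
warning; no re-standardization happens at streaming time. Cohorts are
restricted to their shared genes in sorted order. Subtype labels follow
the surrogate intrinsic-subtype rules from ER/PgR/HER2/Ki-67 status:
hormone-receptor positive and HER2− splits Luminal A vs B at the Ki-67
threshold (default 20%, configurable); hormone-positive and HER2+ is
Luminal B; triple-negative is Basal; ER−/PgR−/HER2+ is the HER2 type. Any
combination whose deciding marker is missing is unlabeled and dropped —
except that a high Ki-67 with unknown HER2 still forces Luminal B, since
both HER2 branches agree. Only the four marker-derivable subtypes are
emitted; the class count elsewhere is configurable.

## Survival evaluation

The univariate Cox fit is a damped 1-D Newton maximization of the Breslow
partial likelihood (descending-time prefix sums; convergence at gradient
< 1e-8 or 50 iterations). Monotone likelihoods (perfect separation) are
flagged and the coefficient capped at |beta| = 10. Standard errors come
from the observed information; p-values from the Wald chi-square(1).
Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
the hand-checkable product-limit contract (censored-only times produce no
step) is asserted in tests, and the Cox fit is cross-checked against
lifelines' full fitter. The |beta| > 0.2 and p < 0.01 prognostic filter is
applied raw, with no multiple-testing correction — treat the output as a
screen, not an inference. Median-split ties go to the low-risk group.

## Synthetic study conditions

The generator emulates the structure of concatenated tumour cohorts, not
their biology. Labels are i.i.d. from an imbalanced five-class mix
(0.45, 0.25, 0.15, 0.10, 0.05 by default — chosen so balanced and raw
accuracy disagree, as they do for subtype frequencies). Within a segment,
each informative gene assigns the K classes equispaced means on
[−effect/2, +effect/2] (assignment permuted per gene); everything else is
Normal(0, noise_sd). Default effect size 2 Z-units against unit noise —
strong markers, recoverable from a few hundred instances, comparable to
top subtype markers after Z-scoring. A cohort switch replaces x by
`scale·x + shift` from a chosen index (defaults shift 1.0, scale 1.0; the
real-world magnitude of such batch effects is not calibrated to any
cohort — it is a free parameter). Survival data follow an exponential
proportional-hazards model with standard-normal covariates and
independent exponential censoring whose rate is solved numerically to hit
the requested censored fraction.

What this does *not* model: count noise and library-size effects,
gene–gene correlation (each gene is conditionally independent), label
noise, and gradual drifts (segments switch abruptly). Passing tests
therefore demonstrate the machinery — detection, adaptation, retention,
calibration — under clean planted signal, not performance on real
transcriptomes.

Test and acceptance runs use streams of 1500–2000 instances with 120–200
genes and 10-gene informative blocks; these sizes keep every planted
effect comfortably detectable at W = 200 while the full suite stays quick
to run.

## Known limitations

- mRMR scans all genes per chunk by default; an optional
  highest-variance cap (`chunk_feature_cap`) trades fidelity for speed on
  very wide matrices.
- Discovered models are never pruned or aged; very long streams grow the
  ensemble linearly in the number of drift events.
- The model-ranking accuracy is cumulative since spawn, so an old model's
  early record can mask recent degradation (a windowed variant of the
  trace exists but does not drive ranking).
- The per-node monitored statistic is the 0/1 subtree error; detectors on
  class-conditional feature distributions are not implemented.
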