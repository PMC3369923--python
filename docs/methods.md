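# Methods

`fruitnet` models a panel of recombinant inbred lines (RILs) as a
three-layer linear system at steady state and uses that model to search
for genome redesigns — combinations of gene knockouts and
over-expressions — that improve metabolite- or trait-defined objectives.
This note records the model, the estimation choices, the synthetic data
the package is tested on, and the numerical decisions a user should know
about.

## The model

Three blocks of algebraic equations, one per omics layer, all linear and
all at steady state:

* **Gene layer.** Each gene's (z-scored, log-scale) expression is a sparse
  linear combination of other genes: `g = W g + b_g + e`, with no
  self-loops in `W`. The per-line term `e` captures everything the network
  does not (genetic background of the line); during training it is simply
  the line's residual, and for a wild-type prediction of a training line
  the solved state reproduces that line exactly. Degradation/production
  constants are absorbed into the coefficients by time rescaling; they are
  not separate parameters.
* **Metabolite layer.** `m = V g + b_m`: each metabolite responds to a
  small set of predictor genes.
* **Trait layer.** `a = U m + b_a`: agronomic traits are linear in the
  metabolome.

Each gene is confined to the interval between the minimum and maximum
expression observed across the expression-profiled lines, optionally
shrunk symmetrically by a fraction `delta` (default 0; `delta` trades
extrapolation reach for conservatism). A **knockout** clamps a gene at
its interval minimum, an **over-expression** at its maximum; the free
genes are re-solved self-consistently subject to their own bounds (a
one-pass propagation mode is available as a flag for comparison).

### Solving the bounded steady state

The unclamped steady state is a direct linear solve. A clamped state is
that solve plus a low-rank update (one rank per clamped gene), which makes
scanning hundreds of single and paired perturbations across dozens of
lines cheap. When the updated solution violates a gene's interval, the
solver pivots on the active set: bound-violating genes are fixed at their
bound, the free block is re-solved, and a bound-active gene is released
when its own equation pulls it back inside (the complementarity condition
of `g = clip(W g + b + e)`). This finds the same fixed point as a damped
projected fixed-point iteration — the test-suite checks the two agree to
1e-8 on random stable systems with clamps — but it does not require the
coefficient matrix to be a contraction and is orders of magnitude faster.
The damped iteration (damping 0.5, tolerance 1e-10, cap 10^4 sweeps)
remains as a fallback and as the independent oracle in tests.

### Stability of the fitted gene layer

Least squares does not constrain the spectral radius of `W`, and fits on
realistic panels routinely land at radius ≈ 1, making perturbed steady
states ill-posed. `fit_layer` therefore rescales the fitted gene matrix to
spectral radius 0.95 whenever the fit reaches 0.95 or more (a warning is
emitted and the raw radius is kept in the model metadata). Wild-type
predictions of training lines are unchanged, because the per-line residual
is defined relative to the final coefficients; only the extrapolation to
perturbed genomes — which requires a well-posed operator — is affected.

## Inference

Each layer is inferred target by target in two nested stages.

1. **CLR mutual-information screen.** Mutual information between every
   (target, predictor) pair is estimated by equal-frequency binning with
   `ceil(lines^(1/3))` bins (at 50–160 lines, square-root binning leaves
   more contingency cells than samples and visibly costs detection power).
   Each MI value is standardized against the empirical background of its
   row and of its column and combined as
   `z = sqrt(max(0, z_row)^2 + max(0, z_col)^2)`; predictors with
   `z >= z*` (default `z* = 2`) survive. Self-pairs are excluded for the
   gene layer. The screen typically cuts the predictor space by an order
   of magnitude; being marginal, it cannot see predictors whose effect is
   masked by larger-variance co-predictors, which bounds attainable recall.
2. **LASSO support selection + OLS refit.** On the surviving candidates,
   the LASSO path (LARS) proposes nested supports and the support
   minimizing the extended BIC — `n log(RSS/n) + k log n + 2γ log C(p, k)`
   with `γ = 1` — is kept; ordinary least squares on that support gives the
   final, de-biased coefficients and intercept. EBIC is the
   support-recovery choice: prediction-optimal penalties (cross-validated
   LASSO) keep many spurious, correlated predictors — on planted panels
   they push the positive predictive value of the recovered edge set below
   0.3 however the penalty is tuned — whereas the EBIC support reaches
   PPV ≈ 0.6–0.8 at a false-positive rate below 1% while keeping the mean
   training correlation near 0.85. Cross-validated (`t_lasso="cv"`) and
   fixed-penalty (`t_lasso=<float>`) selection remain available.

The constant calibration term of each layer is the training-mean residual
(zero up to round-off once intercepts are fitted); per-line variation is
carried by the baseline residuals described above.

Reliability is quantified by (a) k-fold cross-validation with screening
and selection redone inside every training fold, reporting held-out
per-target Pearson r; (b) PPV and FPR of the recovered edge set against a
reference (the planted truth in synthetic runs), with significance from
10,000 random predictor lists of matched size drawn with replacement;
(c) in-degree diagnostics including a discrete maximum-likelihood
power-law exponent (zeta-normalized, `x_min = 1`); and (d) a
noise-robustness curve (correlation of fixed predictions against
increasingly noise-corrupted targets).

## Optimization

An objective is a signed, weighted sum of metabolites and/or traits
(weights default to 1/|set| per side — "balanced"), optionally negated
(minimization), anchored to a target value (`-|value - target|`), or
combined with a second objective as `alpha·z1 + (1-alpha)·z2` with both
sub-scores z-scored against the wild-type population across lines
(default `alpha = 0.5`).

The landscape is explored by (i) exhaustive single-gene KO/OE scans,
(ii) pair scans — all four mode combinations per unordered pair,
exhaustive or a seeded random sample under a budget, optionally including
the degenerate (gene, wild-type) rows so the pair landscape provably
contains the single one — and (iii) a greedy multi-perturbation search
that, per sweep, tentatively sets every gene to KO/OE/wild-type given the
current assignment and commits the single best change, stopping when no
change improves the mean score by more than 1e-9 (ties break by gene id).
Greedy scores are means across the supplied line set, so a redesign is
good on the panel, not on one line.

**Efficiency** of a perturbation for a line is
`100·(s_pert − s_wt)/|s_wt|`; when the wild-type score is numerically
zero the wild-type population standard deviation replaces the
denominator (flagged). Note that balanced objectives over z-scored
features have wild-type scores centered near zero by construction, where
percent efficiencies are numerically enormous without being meaningful —
reports in that regime should prefer improvements in population-sd units
(as `scripts/acceptance.py` does). Rankings use either the mean
efficiency across lines or the maximum objective value reached in any
line ("best-line property"); landscape statistics count, per efficiency
threshold, how many perturbations exceed it per line and how consistently
each perturbation is selected across lines.

## Validation by perturbation signatures

For every metabolite, all single-gene perturbations whose mean relative
effect across lines exceeds 1% of the metabolite's wild-type population
sd form the signature sets Ω⁺ (raising) and Ω⁻ (lowering). The predicted
correlation of two metabolites is `S_same − S_opp`, where `S_same` is the
larger normalized overlap of same-sign sets and `S_opp` of cross-sign
sets. Overlap is normalized by the smaller set (so a subset relationship
counts as full overlap); Jaccard normalization is available for a
stricter reading — the choice is a convention, and both are surfaced.
Predicted and empirical correlation matrices are compared by
precision/recall/F at a cutoff `k` (optionally restricted to pairs with
empirical |r| above a floor), by average-linkage dendrograms exported as
Newick, and by a one-sided Mantel permutation test between the two
distance matrices (`p = (1 + #{r_perm ≥ r}) / (n_perm + 1)`). Overlap of
proposed perturbations with direction-consistent differentially-expressed
genes of engineered lines is scored against random same-size selections,
with a Mann-Whitney U when several engineered lines are given.

## Synthetic panels

The generator plants a ground-truth system and simulates a panel from
it, so every stage can be scored against known truth.

* Coefficients are drawn uniform in ±[0.2, 1.0] (zero-avoiding, so
  planted edges are detectable); `W` is rescaled to spectral radius 0.8.
* Cross-line variation enters as independent standard-normal input per
  gene; the steady state is solved exactly per line. Metabolites and
  traits add Gaussian layer noise (default sd 0.3 in z-score units).
* Measurements are emitted in triplicate with replicate noise at 1/3 of
  the line-level sd; expression is present only for a nested subset of
  lines. Gene ranges are recorded from the observed per-line min/max.
* Defaults — 300 genes, 30 metabolites, 5 traits, 60 expression lines
  nested in 160, mean in-degree 5 — are the desk-scale regime in which
  planted edges are statistically recoverable from the available lines.
  Real panels of this type report much denser fitted networks (tens of
  regulators per target), but such densities are not identifiable from
  ~60 lines and would make a planted-recovery benchmark meaningless; the
  in-degree knob is free for users who want the denser, unidentifiable
  regime.
* Engineered lines (introgression-line-style material) are simulated by
  clamping listed genes inside the true system.

What the generator does **not** emulate: linkage and recombination
structure (lines are exchangeable draws, not a genetic map), array
chemistry (no intensity-dependent bias unless injected), non-Gaussian
metabolite distributions, and correlated measurement error. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the stated linear-Gaussian regime — not performance
on any real panel.

## Numerical conventions and edge cases

* Equal-frequency binning uses average ranks, so constant features fall
  in one bin and contribute zero MI.
* Zero-variance features are dropped (with a warning) before z-scoring;
  transformation parameters are stored for exact inverse mapping.
* Replicate CV masking computes sd/|mean| on the measurement (anti-log)
  scale; cells above the cutoff are set missing in all replicates.
* The LOWESS detrend is MA-style per sample against the across-sample
  mean profile (difference vs average, default span 0.3).
* Empty candidate sets or empty LASSO supports yield intercept-only
  models, flagged, never dropped.
* Bootstrap PPV is undefined (reported missing) for an empty inferred
  support; Mantel r is undefined for constant distance matrices (error).
* Ties on the greedy sweep and in rankings resolve by gene id order
  (stable sort).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  panels, folds, scans and permutation tests.

## Problem sizes used by the shipped analyses

The test-suite and `scripts/acceptance.py` run the pipeline end-to-end at
the generator defaults above (solver oracles on 50-gene systems; 8-gene
toys against 3^8 brute force; scans over 20 baseline lines; greedy over 8
lines and 4 sweeps; signatures over 20 lines; Mantel with 999–1999
permutations; bootstrap with 10,000 replicates). These sizes were chosen
so a complete run is interactive on a laptop while every statistic is
still well-resolved.
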