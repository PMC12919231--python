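# Methods

This note documents the models implemented in `hyperfc`, the parameter
conventions, the synthetic study conditions used by the tests and the
acceptance script, and the numerical and design choices that were
genuinely open.

## Hypergraph model

A hypergraph over `N` parcellated brain regions is stored as a binary
incidence matrix `H ∈ {0,1}^{N×M}`, one column per hyperedge. Every
hyperedge is identified by its *centroid* region — the region whose
regression defined it — and columns are ordered by centroid index, which
makes backbones reproducible and comparable across runs. The contract
enforced throughout: entries are exactly 0/1, every hyperedge has at
least three member regions including its own centroid, centroids are
unique, and `M ≤ N`. Weighted (real-valued) incidence matrices are out of
scope; the analysis chain uses binary membership only.

From `H` and a weight vector `w`: node degrees `d(v_n) = Σ_m w_m H(n,m)`,
hyperedge degrees `δ(e_m) = Σ_n H(n,m)`, similarity
`S = H diag(w) D_e⁻¹ Hᵀ`. `D_e⁻¹` is an element-wise reciprocal — degree-0
columns are forbidden upstream, so no pseudo-inverse is involved. `S` is
symmetrised after the product to remove order-of-summation noise at the
1e-16 level; it is exposed as a first-class output but no downstream
stage consumes it.

## Structure inference

Per subject and per centroid `n`, the coefficient vector solves

    min_α 1/(2P) ‖x_n − X_n α‖₂² + λ‖α‖₁ ,  α ⪰ 0,

with the centroid's own column of the design zeroed. The quadratic term
is averaged per timepoint (the scikit-learn `Lasso` convention). An
unaveraged objective is algebraically equivalent with `λ_unavg = P·λ`,
and both values are recorded in the backbone provenance; the averaged
convention is the one on which the default grid `[0.01, 0.30]` (step
0.01) is meaningful for unit-variance data. The solver is coordinate
descent with convergence tolerance 1e-10 and at most 1e5 iterations —
tight, because downstream binarization is sensitive to coefficients near
the percentile threshold. `λ = 0` falls back to non-negative least
squares.

Choices that the problem statement leaves open, fixed here:

* **Percentile population.** The fifth-percentile threshold is computed
  over the *strictly positive* coefficients of each subject's matrix,
  with linear interpolation between order statistics; entries at or above
  the threshold survive. Non-negative LASSO produces mostly exact zeros,
  so a percentile over all `N²` cells would be identically zero and the
  cut vacuous.
* **Cross-validation folds** are contiguous timepoint blocks
  (`fold k = [kP/5, (k+1)P/5)`), not shuffled: BOLD signals are
  autocorrelated and shuffled folds would leak neighbouring timepoints
  across the split. The procedure is therefore deterministic; the seed is
  recorded for provenance only.
* **Majority vote** turns a cell on when at least 50% of the reference
  cohort has it on (a tie at exactly 50% passes). The minimum-cardinality
  filter is applied per subject before voting *and* re-applied to the
  voted matrix, because voting can shrink a membership below three.
* **Centroid self-membership** is forced before filtering and voting: a
  hyperedge always contains the region it predicts.
* **Z-scoring** uses the sample standard deviation (ddof = 1); constant
  series are a hard error, since every downstream quantity builds on
  correlations.

Backbone stability under shorter acquisitions keeps the first `P'`
timepoints, re-z-scores, rebuilds the backbone at the *same* λ (the
penalty is part of the study design, not re-selected per length), and
compares cell-wise on the full `N×N` centroid-by-region layout with
Jaccard and Pearson.

## Hyperedge weighting

**Algebraic connectivity.** For each subject and hyperedge, the member
regions induce a weighted graph whose edges are absolute Pearson
correlations (diagonal forced to 0 — self-correlation is not an edge);
the weight is the second-smallest eigenvalue of `L = D − A`. It is
computed by dense symmetric eigendecomposition, which is exact at
hyperedge sizes (`k ≤ 7` in realistic backbones; supported to `k = 32`).
Iterative trace-minimisation solvers are a performance choice for large
graphs and are unnecessary here. Eigenvalues below 1e-10 in magnitude are
treated as 0, so a disconnected subgraph yields exactly 0.0 — with a
logged warning naming the hyperedge, since a zero carries no comparative
information and callers may prefer to drop such hyperedges. Useful
closed forms: `a(K_k) = k` under unit weights, `a(P₃) = 1`, disconnected
→ 0; the value is monotone in every edge weight, which bounds it in
`[0, k]`.

**Gaussian kernel.** `K[i,j] = exp(−‖x_i − x_j‖² / 2σ²)` with σ the
median of the raw (not squared) pairwise Euclidean distances among the
hyperedge's member series, computed per hyperedge and per subject. The
hyperedge weight is the *mean* kernel value over unordered pairs — the
mean keeps weights comparable across hyperedge cardinalities. All
members identical (σ = 0) gives weight 1.

**Mean correlation** is the signed mean of pairwise Pearson r, so unlike
the other schemes it may be negative.

**LASSO-L2** refits the subject's coefficient matrix at the backbone's λ
(weights must be subject-specific while the structure is shared) and
takes `Σ αᵢ²` over the centroid row restricted to the hyperedge's
non-centroid members.

**Functional networks.** Each of the seven canonical networks (Vis,
SomMot, DorsAttn, SalVentAttn, Limbic, Cont, Default), parsed from
Schaefer-style labels such as `LH Vis 1` or `7Networks_RH_Default_1`, is
treated as one hyperedge weighted by its mean within-network correlation.

All weighting schemes are invariant to member ordering.

## Group statistics

Kruskal–Wallis (tie-corrected, chi-square p) per hyperedge across
groups; all observations identical is a well-defined degenerate case
with H = 0, p = 1. FDR control is Benjamini–Hochberg at α = 0.05, applied
across all hyperedges for the omnibus family and within each group-pair
family for the post-hoc Mann–Whitney stage — the pairwise family mirrors
how per-pair counts are reported. Post-hoc tests run only on omnibus
survivors. Mann–Whitney uses exact enumeration when both samples are
tie-free and ≤ 20, otherwise the tie-corrected normal approximation (the
exact null does not account for ties, so ties force the asymptotic path
at any sample size). Cliff's δ is computed via ranks in
`O((n+m) log(n+m))`; the global effect size is the mean |δ| over group
pairs. The Shapiro–Wilk screen is reported per (hyperedge, group) but
never switches the pipeline to parametric tests. The reference-cohort
bias check (backbone controls vs analysis controls) is the same omnibus
machinery with two groups.

## Classification

Stratified 80/20 hold-out (each class needs ≥ 5 members so both split
and CV remain stratifiable), grid search by mean 5-fold CV accuracy over
a declared random-forest grid — trees {100, 300, 500}, max depth
{3, 5, none}, min samples per split {2, 5, 10} — refit on the training
portion, then hold-out accuracy and class-weighted precision/recall/F1.
Feature importances are impurity-based, normalised to sum 1. Split, CV
shuffling and forest randomness all derive from one seed, so the
protocol is fully deterministic.

## Mediation

Three OLS equations; covariates, when supplied, enter all three, which
makes `c = c′ + a·b` an algebraic identity — the package asserts
`|total − (direct + indirect)| < 1e-10` on every fit. Collinearity (e.g.
a mediator that is an exact multiple of the exposure) is a hard error
checked via design rank. Binary covariates are 0/1 indicators;
continuous covariates are left unscaled (the path coefficients are
invariant to covariate scaling). The bootstrap is nonparametric case
resampling with a percentile [2.5, 97.5] interval and a two-sided
sign-proportion p-value floored at `1/n_boot` (default 1000 repetitions);
BCa intervals were considered and left out as the percentile interval is
the simplest defensible default at these sample sizes. Resamples only
need `a·b`, so they use plain least squares rather than the full
inference fit; rank-deficient resamples are redrawn with a hard cap of
`100·n_boot` draws. The "total" effect is reported as the coefficient of
the exposure-only equation (identical to `c′ + a·b` under shared
covariates). Subjects missing the exposure or an outcome are dropped per
outcome with a logged count.

## Synthetic study conditions

The generator plants hyperedge communities with a latent-factor model:
member region `i` of hyperedge `h` observes
`x_i = ρ f_h + √(1−ρ²) ε_i` with `f_h` standard Gaussian and
`ε_i ~ N(0, σ²)`, everything independent; unassigned regions are pure
noise, and every series is z-scored. The loading ρ directly controls the
within-hyperedge coupling that algebraic connectivity measures, and can
differ per group to plant effects; at ρ = 1 members are exactly the
latent series and the noise scale is irrelevant. Default conditions used
by tests and the acceptance script: N = 20 regions, P = 192 timepoints,
30 reference subjects, ρ = 0.8 (within-member Pearson r ≈ 0.97 at
σ = 0.2 — a strongly synchronised subnetwork), noise σ = 0.2, group
effects as ρ drops to 0.5–0.6 in one group. Mediation triples follow the
generative three-equation form with chosen (a, b, c′) and unit noise.
The full-study fixture additionally couples a tau-like exposure to group
severity and derives outcome scores from it, so the mediation battery
has signal to find.

What this emulates is the *coupling geometry* of parcellated BOLD data —
not its dynamics. There is no temporal autocorrelation, no hemodynamic
response, no scanner drift or motion artifacts, and planted communities
are cleanly disjoint. Passing tests therefore demonstrate correctness of
the algorithms and calibration of the inference under the stated
statistical model; they do not certify recovery rates on real fMRI,
where autocorrelation inflates effective noise and hyperedges overlap.

## Problem sizes and determinism

The test suite and acceptance script scale the Monte-Carlo studies to
desk-size runs: 500 random graphs for the spectral oracle, 200
simulations for null FDR control (25 subjects × 96 hyperedges × 3
groups), 50 simulations at 80 subjects/group for post-hoc power, 200
replicates × 1000 resamples for bootstrap coverage, 20 seeds for the
random-forest top-feature check. All randomness flows through explicit
`numpy.random.default_rng` seeds; fixed inputs and seeds give
bit-identical backbones, weight tables and bootstrap intervals.

## Known limitations

* A disconnected hyperedge subgraph scores 0 regardless of how its
  components are organised; the weight is only informative for connected
  subgraphs (warned and droppable).
* The LASSO-based backbone inherits the usual behaviour of L1 selection
  among correlated predictors; majority voting across subjects is what
  stabilises memberships, so very small reference cohorts yield brittle
  backbones.
* The Gaussian-kernel bandwidth convention (median of raw distances, per
  hyperedge and subject) is one of several defensible readings of the
  median heuristic; it is isolated in one function if another convention
  is needed.
* FDR families (all hyperedges for the omnibus stage; per group pair for
  post-hoc) are a design choice; other family structures change which
  hyperedges survive at the margin.
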