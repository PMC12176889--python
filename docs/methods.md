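# Methods

## Pipeline overview

The package computes two whole-brain network indices per subject from a
parcellated resting-state signal matrix, then feeds them into a
pre/post moderation analysis. The stages are strictly layered: signal
matrix → correlation → top-K binary network → modularity partition →
(windowed) partition sequence → flexibility → cohort-level regression.

## Network construction

Pairwise Pearson correlation over the selected volumes; the K
highest-ranked region pairs become unweighted, undirected links.

* `k_links` (default 400): on 84 nodes this is 400/3486 = 11.47%
  density. Fixing the count rather than a correlation cutoff equates
  density across subjects, which matters because every downstream graph
  measure depends on density.
* `ranking` (default `signed`): "strongest" links are read as strongest
  positive coactivation, the common positive-tail convention in
  resting-state work; `absolute` ranking is available for analyses that
  treat strong anticorrelation as connectivity. The choice is recorded
  in the per-run config.
* Exact ties in the ranking are broken by lexicographic node-pair
  order, making the edge set a pure function of the correlation matrix.
* Zero-variance (constant-signal) regions are kept as nodes; their
  correlations are set to 0 and their labels recorded, so they are
  never selected at realistic K and surface in a warning rather than an
  abort.

## Module detection

Newman's divisive spectral method, authored here: recursive bisection
along the leading eigenvector of the group-restricted modularity matrix,
a split accepted only if it strictly increases Q under the
degree-preserving null model, with Kernighan–Lin single-node refinement
(`fine_tune`, default on) after each bisection. Determinism is part of
the contract: eigenvectors are oriented so their first nonzero
component is positive, refinement ties go to the lowest node index, and
final labels are consecutive integers ordered by each module's smallest
node. Degree-0 nodes become singleton modules outside the division.

Known limitation: recursive bisection cannot represent every optimal
partition. The 8-cycle is a minimal example — its modularity optimum is
a 3-2-3 split reachable only by a three-way division, while bisection
stalls at Q = 0.25 (optimum 0.28125). The exhaustive-enumeration
equivalence tests therefore use small graphs whose optima are reachable
by repeated bisection (6-ring, 7-path, 8-star, bridged triangles,
bridged 4-cliques); on larger empirical networks the method is a
well-behaved heuristic, not a global optimizer.

## Sliding-window dynamics

* Window length 40 volumes, step 1. The window count convention is
  `floor((T − W)/step)`: for T = 216 this yields 176 snapshots,
  dropping the final admissible start; `include_final_window` restores
  the inclusive 177-window convention. The exact boundary convention of
  the original analysis is not recoverable, so the one that reproduces
  the printed count is the default and both are available.
* Each window's network uses the same `k_links` as the full-run
  network. A per-window K is not separately configurable by design —
  one density parameter governs the whole pipeline.
* Relabeling is chain matching between consecutive windows only (the
  statistic is defined on consecutive transitions, not against a global
  reference). The module-overlap contingency table is solved as an
  exact maximum-weight one-to-one assignment, not greedily: greedy
  matching is order-dependent. Tie rules among co-optimal matchings:
  larger current module first, then the module earlier in canonical
  order (ascending smallest member node — identical to "lower label"
  for detector output, which labels modules in that order). Both tie
  criteria, and the row/column ordering of the assignment problem, are
  functions of module content only, which is what makes flexibility
  provably invariant to arbitrary per-window relabelings of the input.
  Unmatched modules receive fresh labels never used before.
* Flexibility: per-region rate = membership changes / (n_windows − 1),
  overall = mean over regions; both lie in [0, 1] by construction.

## Synthetic signals

A shared-factor model: region i in module m at volume t has signal
λ·F_m(t) + σ·ε_i(t) with F, ε i.i.d. standard normal and
λ = σ·sqrt(ρ/(1−ρ)), so the within-module correlation is exactly
ρ = `within_module_corr` (default 0.8) and between-module correlation
is 0. This gives an analytic loading-to-correlation map; an explicit
covariance-Cholesky generator was deliberately not built. Membership
switches take effect at scheduled volumes; several regions may switch
at the same volume.

What it does not emulate: hemodynamic autocorrelation, physiological
noise, motion, drift — volumes are i.i.d. Passing recovery tests
therefore show the graph pipeline is correct, not that it is robust to
fMRI artifacts.

A note on recovery benchmarks: with 4 planted modules of 21 regions
there are 840 within-module pairs, so at the study-scale K = 400 the
retained subgraph keeps fewer than half the within-module links,
selected essentially at random among them — each block is then an
Erdős–Rényi-like subgraph with genuine (spurious) substructure that
modularity maximization legitimately subdivides. Planted-partition
recovery (ARI = 1) is therefore benchmarked at K = 840, matched to the
planted design; this is a property of top-K filtering, not an
implementation defect.

## Synthetic cohorts

52 subjects by default (25 music, 27 control; group coded 0 = control,
1 = music), baseline cognition N(27.60, 2.84²) on the 0–30 MMSE scale.
Follow-up scores follow
γ0 + γ1·baseline + γ2·group + γ3·flex + γ4·group·flex + ε. Defaults:

* `gamma = (11.27, 0.64, −3.76, −5.11, 20.94)` — the fitted
  coefficients of the motivating study, used as the best available
  stand-in for a generating truth (the true effect sizes are unknown).
* `noise_sd = 1.0` — consistent with the high follow-up R² (~0.8) such
  designs show; a free parameter.
* Baseline flexibility ~ N(0.15, 0.05²) truncated (clipped, not
  resampled, for determinism) to [0, 1] — typical magnitude for
  windowed resting-state flexibility; a free parameter.
* Covariates (age, sex, education) are drawn to match the cohort's
  descriptive table approximately; they carry no planted effect.

## Moderation model

OLS via statsmodels on an explicitly constructed design matrix
(intercept, baseline, group, index, group×index, then optional
additive covariates — no covariate interactions). Complete cases only;
rank deficiency is rejected with the offending column named, after
which VIF diagnostics are redundant for that purpose but remain
available pre-fit via `vif_table`. Classical SEs, two-sided t tests,
95% CIs.

Simple effects: EMMs per group at moderator mean − SD / mean / mean +
SD with baseline and covariates at sample means. The contrast
(music − control) at moderator value m is identically
β_group + β_interaction·m; its SE comes from the coefficient
covariance; p-values are unadjusted (one contrast per level). Cohen's
d = contrast / residual RMSE — one reasonable definition among
several, stated here because the convention is not standardized.

Diagnostics: Shapiro–Wilk on residuals, Breusch–Pagan against the model
design, correlation of |residual| with fitted values, per-predictor
VIF.

## Problem sizes used in the test suite

Monte-Carlo properties run at the design n = 52 with 1000 replicates
(type-I error, interaction-estimate bias) or 500 (simple-effects power
comparison, at noise_sd = 4 so neither level saturates at 100% power).
The Breusch–Pagan power simulation uses a 520-subject cohort: the
screen's power at pilot n is intrinsically modest, and the test
verifies the diagnostic, not the pilot design. Dynamics guards run the
full 84-region generator; multi-seed checks subsample windows with
step 16 (11 windows), and one full single-seed run covers the complete
176-window sequence.

## Known limitations

* Bisection suboptimality (above); no Louvain/Leiden, weighted,
  signed, resolution-parameter, or consensus variants.
* No multilayer (temporal-coupling) community model; flexibility here
  is the relabeling-based statistic, which depends on the per-window
  detector's stability at low SNR.
* No preprocessing: inputs must already be parcellated (or supplied as
  a 4D array with an aligned label volume; no resampling or masking).
* Difference-score and ANCOVA change models, mixed-effects and
  Bayesian alternatives, and multiplicity correction across the
  modularity and flexibility models are out of scope.
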