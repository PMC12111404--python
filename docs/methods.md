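# Methods

## Problem

Rapeseed (canola) oil cake is a protein-rich press residue whose use as a
human food ingredient is limited by phenolic antinutrients (sinapine,
tannins). Dephenolization — washing the defatted cake with aqueous ethanol,
optionally under ultrasound — removes them, and the amount of phenolics
recovered in the wash (total phenolic content, TPC, in mg gallic-acid
equivalents per 100 g dry cake) is the quantity to maximize. Three process
factors span the operating window: ethanol concentration (70–90 %),
solid-to-liquid ratio (10–60 mL solvent per g cake; "1:40 w/v" is encoded
as the number 40), and sonication time (5–25 min).

This package implements the surrogate-based optimization of that process:
a small feed-forward neural network fitted to a screening design serves as
the response surface, connection-weight analysis attributes the response to
the factors, and a particle swarm locates the predicted optimum. The
protein-chemistry formulas that surround the process (extraction-yield
accounting, Bradford protein quantitation, Folin–Ciocalteu GAE
quantitation, amino-acid profile scoring, TCA-soluble digestibility gain)
are provided as plain functions.

## Surrogate model

The surrogate is a three-layer perceptron with a hyperbolic-tangent hidden
layer and linear output,

    f(x) = b_o + Σ_k w_ho[k] · tanh(b_h[k] + Σ_i w_ih[k,i] · x_i),

fitted on z-scored inputs and output (sample sd, denominator n−1; scalers
are part of the fitted results, so predictions are always destandardized).
A linear output unit is the standard regression head for least-squares
training; the hidden activation is tanh.

Training minimizes the sum of squared standardized residuals with a
hand-implemented Levenberg–Marquardt iteration (damped Gauss–Newton on the
analytic residual Jacobian): initial damping 1e-3, ×10 on a rejected step,
÷10 on acceptance, at most 200 accepted iterations, stopping when the
gradient ∞-norm falls below 1e-8 or the accepted step below 1e-10 relative.
Only SSE-decreasing steps are accepted, so the recorded SSE path is
monotone by construction. Weights are initialized uniform(−0.5, 0.5) from a
seeded generator; a (master seed, repeat, init) counter scheme makes every
run reproducible and every repeat/init independent.

With 10 hidden neurons the network has 51 free parameters against 33
observations; the fit is deliberately underdetermined (it interpolates a
noiseless table exactly) and R²/MAE are reported on the training rows, on
the original measurement scale. An optional k-fold evaluator
(`kfold_r2`) is provided for honesty checks but plays no role in topology
selection.

Hidden-layer size is chosen by a repeated-run protocol: for each candidate
size, `n_repeats` independent repeats each keep the best training R² over
`n_inits` random initializations; the candidate's score is the mean of the
repeat bests. Selected is the smallest size whose mean R² reaches 0.9 and
whose successor improves by less than 0.005 (a plateau rule; the constant
is a package choice since only "no significant decrease" is specified
upstream). If no size reaches 0.9 the argmax is returned, flagged.

## Factor importance

Input attribution uses the Yoon connection-weight measure: for input i,

    RI_i (%) = 100 · Σ_k w_ih[k,i]·w_ho[k] / Σ_i' |Σ_k w_ih[k,i']·w_ho[k]|.

Biases are excluded; signs are kept (negative RI: increasing the factor
decreases predicted yield); absolute values sum to 100 by construction. RI
is evaluated on the standardized-scale weights, where inputs are comparably
scaled. Ties in |RI| are broken by input declaration order. Alternatives
(Garson, permutation importance, SHAP) are out of scope.

## Swarm optimization

The fitted surrogate is maximized over the process box by minimizing its
negation with a particle swarm: 20 particles, 800 iterations, personal
coefficient c1 = 1.5, global coefficient c2 = 2.0, and a constant inertia
weight, default 0.729 (the Clerc constriction value, chosen for stability
with these c1/c2; the upstream "equalized inertia range" setting does not
pin a number). Initial positions are uniform in the box (an initial-span
setting wider than the box reduces to exactly that), initial velocities
uniform in ±range/2, velocities capped at the per-axis range. Bounds are
absorbing: positions are clamped and the violating velocity component
zeroed — the simplest contract, documented here. Five independently seeded
restarts are run by default; the spread 100·(max−min)/|max| of the
per-restart bests is reported and flagged above 5 %, the stability
criterion used for the original optimization. A 101³-lattice exhaustive
search (`grid_oracle`, ties to the first row-major index) verifies the
swarm in tests.

## Synthetic data generator

Real screening data for this process are not publicly deposited, so the
generator defines the study conditions the package is verified under. The
ground-truth surface is multiplicative —

    y = y0 · exp(−(E−E*)²/2σ_E²) · S/(S+K) · exp(−(t−t*)²/2σ_t²)

— smooth, positive, unimodal in ethanol and time, saturating (monotone) in
S/L, so its box optimum has interior EtOH/time coordinates and S/L at the
upper bound, matching the reported optimum of 84 % EtOH, 1:60, 15 min. The
default parameters are E* = 84 %, σ_E = 15, K = 25 mL/g, t* = 15 min,
σ_t = 20, with y0 = 1887.76·85/60 ≈ 2674.33 mg GAE/100 g solved so the
noiseless maximum equals the reported optimal phenolic yield of 1887.76
mg/100 g. These widths give the factor ordering S/L > EtOH > time in
first-order variance shares, the reported importance ordering. Replicate
noise is additive Gaussian, sd 40 mg GAE/100 g (~2 % of the maximum — no
replicate variance is reported upstream, so this is a package choice),
truncated at zero.

Designs are Latin hypercube by default (n = 33, the reported sample size;
the true design is unpublished) or a full-factorial lattice. Ground-truth
oracles ship with the generator: `true_optimum` (dense grid + L-BFGS-B
polish) and `true_main_effects` (first-order Sobol shares by the
pick-freeze Monte-Carlo estimator, cross-checked in tests against 1-D
quadrature using the surface's separability).

What the generator does not emulate: replicated center points, heteroscedastic
assay error, phenolic speciation (free/esterified/bound), and any kinetic
mechanism — the surface is phenomenological. Passing tests therefore
demonstrate that the pipeline recovers a known smooth ground truth under
realistic noise and sample size, not that the specific published dataset is
reproduced.

## Known limitations and numerical notes

* **Flat-direction identifiability.** The default surface varies by less
  than 0.5 % over ±2.8 min around t* = 15. A 33-point interpolant cannot
  localize the argmax of so flat a direction: across seeds the recovered
  time coordinate scatters by a few minutes even when the recovered *yield*
  is within 1–4 % of the true maximum. Recovery tests therefore hold EtOH
  and S/L to 5 % of their axis ranges but bound time by the flatness-derived
  3 min and additionally require ≤2 % true-yield regret at the recovered
  point.
* **Noise interpolation.** With 51 parameters and 33 noisy points the
  10-hidden network reaches training R² ≈ 1 by fitting the noise; on noisy
  tables the swarm can then chase spurious wiggles. The topology-selection
  plateau rule mitigates this (it picks 3 hidden neurons on the default
  noisy table, mean R² 0.997); optimum-recovery checks are run on
  noiseless tables, where interpolation is exact.
* **Degenerate inputs.** Constant data columns are rejected at scaling;
  an all-cancelling Yoon denominator raises rather than returning NaN;
  a near-constant surface is flagged `degenerate` by the main-effects
  oracle instead of reporting noise-dominated shares.
* **Reporting convention.** Reports store unrounded optima; the display
  layer rounds (EtOH 0.1 %, S/L 1 mL/g, time 0.1 min). Amino-acid ratio
  rows are printed as whole percents (half away from zero), the convention
  of the tabulated source data; sums are compared at ±0.01 g/100 g.
* **Problem sizes.** Default test and acceptance runs use the n = 33 study
  condition, 10×10 repeat/init fits, 15-size topology scans, 5 swarm
  restarts of 20×800 evaluations, and 20 000-sample Monte-Carlo main
  effects — the full protocol, not a reduction.
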