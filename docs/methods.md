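# Methods

## The model

A residue-resolved two-state exchange assigns each residue an equilibrium
constant K and rate constants k (forward) and k′ (backward) with
K = k/k′. All logarithms in the package are base 10: slopes and flatness
are base-invariant, so only intercepts and offsets depend on the base,
and base 10 matches the pH/decade conventions of the data sources. The
REFER plot regresses log k and log k′ on log K by ordinary least squares
with vertical residuals — the convention under which the plotted
least-squares lines are defined, and the one that preserves the exact
identity slope_f − slope_b = 1 (because the forward and backward
ordinates differ by exactly the abscissa). Measurement uncertainties are
carried as error bars but do not weight the regression by default;
weighted fitting would break the slope identity and is deliberately not
the default.

Line styling follows the interpretability reading of the slope as
transition-state similarity: `solid` when the correlation is significant
(two-sided Pearson test, α = 0.05, configurable) and the slope lies in
the closed band [0, 1] (forward) or [−1, 0] (backward); `dashed` when
significant but outside the band; `none` otherwise. Each direction is
classified independently — nothing in the data forces the two directions
to share significance. A minimum of 4 residues is required: below that a
line is near-perfect by arithmetic and classification is meaningless.

## Scatter taxonomy and the confidence ellipse

Because log K = log k − log k′, REFER linearity must be corroborated by
the log k vs log k′ scatter. The ellipse is the sample-covariance
(n−1 denominator) confidence region: semi-axes √(λᵢ·q) with q the
chi-square(2) quantile at the coverage level (q ≈ 5.991 at 0.95). The
chi-square scaling (known covariance shape) is used rather than the
small-sample F/Hotelling scaling; at the ensemble sizes of interest
(~15–70 residues) the two differ by under 10%, and the level is
configurable. Flatness is f = 1 − b/a; it is invariant under
translation, rotation and uniform scaling of the cloud, which the
property suite verifies.

Decision rule (α = 0.05 shared with the regression):

- significant r < 0 → **N**; significant r > 0 → **P** when
  Var(log k′) ≥ Var(log k) (ties toward P), else **P′**;
- insignificant r with f ≥ 0.6 and the long axis within 20° of the
  vertical → **V**, of the horizontal → **H**;
- otherwise **nr**.

The plane is drawn with log k horizontal and log k′ vertical. Under this
orientation a vertically flattened cloud (spread confined to log k′)
yields REFER slopes ρ_f → 0 and ρ_b → −1, and a horizontally flattened
one yields ρ_f → 1 and ρ_b → 0 — the slope signatures the V/H types are
named for; the orientation is configurable
(`classify_kk_type(..., orientation=)`) for users who draw the axes the
other way, and the type labels stay tied to the data (V always means
spread in log k′), not to the drawing. The numeric cutoffs f ≥ 0.6 and
20° are operational choices — the types are defined geometrically, not
by published thresholds — set so that clearly flattened clouds (axis
ratio ≥ 2.5) classify V/H while the uniform-random fake construction
(population flatness ≈ 0.52) classifies nr; both are exposed as
parameters.

## Robust outlier detection

Collective deviations are detected per direction by IRLS with Tukey
bisquare weights, tuning constant 4.685 (95% Gaussian efficiency),
starting from OLS (deterministic). Each iteration recomputes residuals,
divides them by √(1 − hᵢᵢ) (hat-matrix leverage adjustment, toggleable),
sets the scale to median|r|/0.6745, and solves the weighted least-squares
problem; convergence when coefficients change by < 1e−8, cap 100
iterations. When the scale collapses to zero (a majority of points
exactly on a line) the zero-residual points get weight 1 and all others
weight 0, which keeps the exact-line contract (zero residual ⇒ full
weight) while still rejecting gross outliers. The implementation is
cross-checked in the test suite against an independent robust linear
model (statsmodels RLM with the same ψ-function).

A residue is flagged when its weight falls below 0.5 — the midpoint of
the weight range — in **either** direction; both the threshold and the
OR rule are configurable. After flagging, the main lines are refit by
OLS on the retained residues and the outliers' mean signed vertical
residual from each refit line gives the parallel offset (log10 units).
The offset is reported as a multiplicative rate factor 10^offset rather
than an additive s⁻¹ value, since the additive number also depends on
the absolute intercept. With bisquare weights any point beyond ~2.5
robust scales drops below weight 0.5, so in a Gaussian ensemble a few
percent of clean residues can be flagged by chance; the flagged set
should be read together with the weight table the pipeline writes.

## HX kinetics

The two-process scheme NH(closed) ⇌(k_op/k_cl) NH(open) →(k_int)
ND(exchanged) is evaluated under the steady-state (Linderstrøm-Lang)
approximation k_obs = k_op·k_int/(k_op + k_cl + k_int), which
interpolates between EX1 (k_int ≫ k_cl, k_obs → k_op) and EX2
(k_int ≪ k_cl, k_obs → K_op·k_int). The regime label uses a one-decade
threshold (EX1 when k_int ≥ 10·k_cl, EX2 when k_int ≤ k_cl/10) — the
conventional quantitative reading of "≫"/"≪". The approximation is
validated against the exact slow-phase eigenvalue of the 2×2 rate matrix
(`hx_exact_slow_rate`, a test oracle only): in the folded-protein regime
k_op ≤ 0.01·k_cl it agrees within 1% for any k_int.

The intrinsic rate follows single-term base catalysis,
k_int = k_ref·10^(pH − pH_ref), with a per-residue override table for
externally computed sequence-dependent rates; full sequence-dependent
rate prediction is out of scope.

`fit_hx_rates` estimates pH-independent (k_op, k_cl) per residue by
bounded nonlinear least squares on **occupancy** residuals (occupancy is
the measured quantity), parameterized in log10 rates within
[1e−6, 1e8] s⁻¹, from a 3×3 multistart grid to avoid shelf minima. By
default all pulse durations of a residue are pooled into one fit
(`pool_pulses=True`), reproducing the practice of treating the rates as
unchanged across labeling windows; per-window fits are available.
Standard errors come from the Gauss–Newton covariance at the optimum,
delta-method-converted to the rate scale. Identifiability is checked
explicitly: when the Jacobian is numerically rank-deficient (singular
value ratio < 1e−4) or every observation is EX2 at the fitted k_cl, the
result is downgraded to a one-parameter fit of K_op via
k_obs = K_op·k_int/(1 + K_op) and labeled `regime-limited` rather than
returning a silently unconstrained pair. Residues with occupancy ≈ 1
everywhere (≥ 0.98 by default) return `fully-protected` with no
estimate.

## Synthetic data: what it emulates and what it does not

`generate_lfer_ensemble` draws log K uniformly over
[center ± spread] (normal optional), sets
log k = ρ·log K + c + ε with ε ~ N(0, σ²), optionally adds a constant
offset Δ to a contiguous residue block (the collective-motion mimic),
and derives log k′ = log k − log K so the triad identity is exact by
construction — noise enters log k only, mirroring how K, k, k′ are
mutually constrained in real data. Defaults — 40 residues, ρ = 0.4,
intercept 1, log K over ±1 decade, σ = 0.1 — reflect the decade-wide
log K spreads and ~0.1 log-unit uncertainties typical of
residue-resolved NMR/HX datasets.

`simulate_fake_linearity` draws, per repeat, k ~ U(3, 7) and
k′ ~ U(8, 12) on the **raw rate scale** (the ranges are rate values, not
logarithms; a log-uniform variant exists for sensitivity checks), 15
residues, 30 repeats by default. Aggregates report per-residue mean, SD
and SE = SD/√n_reps — both dispersion measures, since published error
bars use either convention; at 30 repeats SD/SE = √30 ≈ 5.48 exactly.
For these ranges the population forward slope and R² are both
Var(log k)/(Var(log k) + Var(log k′)) ≈ 0.81, so a single repeat
typically shows "good" REFER linearity while classifying nr — the
artifact the construction exists to demonstrate.

`generate_hx_dataset` produces occupancies exp(−k_obs·t) with Gaussian
noise truncated to [0, 1] over a pH 6–11 ladder and pulse durations
(0.05 s, 0.5 s) by default; with k_ref = 1 s⁻¹ at pH_ref = 7 and the
reference truth (k_op, k_cl) = (5, 500) s⁻¹ this spans EX2 through EX1
and makes both rates identifiable. EX2-only designs (e.g. pH 6–7) need
correspondingly longer pulses (~10²–10³ s) before any exchange
registers — at millisecond pulses such residues are genuinely fully
protected, and the fitter says so.

What the generators do **not** emulate: NMR observables themselves (peak
intensities, relaxation rates, measurement-bias structure), heavy-tailed
or correlated errors, proline/exchange-incompetent residues,
back-exchange, or three-state exchange. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under the
stated error model, not robustness to every pathology of literature
data.

All generators take an explicit integer seed (numpy `default_rng`) and
are bit-reproducible; no global random state is touched.

## Problem sizes and numerical choices

The validation suite uses 1000-dataset sweeps for the algebraic-identity
and type-N band checks, 300–2000 repeats for the fake-linearity
distribution against a 10⁵-draw brute-force oracle, 10⁵-point clouds
for ellipse coverage (binomial error ~0.07%), and 50 replicates for the
noisy HX recovery study — sizes at which the Monte-Carlo error is well
below every tolerance asserted. Report files round to 6 significant
digits so diffs are meaningful; numeric comparisons in tests allow for
that rounding where files are re-read.

## Known limitations

- The outlier flag threshold (weight < 0.5) is a convention; reproducing
  a specific published outlier count on real data can depend on the
  reference implementation's exact leverage handling.
- The HX fitter assumes uncorrelated occupancy noise; fits to
  strongly correlated replicate data will understate the standard
  errors.
- The F/Hotelling small-sample ellipse correction is not applied (see
  above); at n < 10 residues the chi-square ellipse is anti-conservative.
- K-only tables (no rates) are rejected: the package's diagnostics all
  require the k/k′ decomposition.
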