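# Methods

## The release model

Cumulative release from a single microparticle formulation is modelled as
first-order (saturating exponential) kinetics:

    Cr(t) = a · (1 − e^(−b·t)),    Cr(0) = 0

with `a` the asymptotic cumulative release and `b` the rate constant (1/h).
Time is in hours throughout; unit conversion is the caller's job. `a` is on
the scale of the data being modelled — percent of loaded drug or µg — and is
deliberately *not* capped at 100% on the percent scale: measured release can
exceed the nominal loading slightly through random and systematic
quantification error, and the model reports such values untruncated (with a
logged flag in the percent-conversion helper) rather than normalising them.
The zero initial condition is built into the functional form; no intercept is
fitted, and a t=0 observation, if present, must be 0.

## Fitting

`fit_first_order` minimises the unweighted residual sum of squares with
`scipy.optimize.least_squares` (TRF, bounds `0 < a ≤ 10·max(y)`,
`0 < b ≤ 100 /h`, tolerances 1e-15, ≤500 function evaluations). The start is
derivative-free: `a₀ = 1.05·max(y)`, and `b₀` from the slope of the
log-linearised transform `ln(1 − y/a₀)` against `t` over points below `a₀`,
falling back to `1/median(t)` when that slope is unusable. On exact model
data the generating parameters are recovered to better than 1e-9 relative; a
brute-force 200×200 log-spaced grid search serves as an independent oracle in
the tests and is never beaten by more than round-off. Curves that are all
zero, non-finite, or carry fewer than two distinct nonzero levels are
rejected (`UnfittableInputError`); solver non-convergence is reported through
`FitResult.converged`, never silently.

Goodness of fit is `R² = 1 − RSS/TSS` (TSS about the observed mean) and
`adjR² = 1 − (1 − R²)(n − 1)/(n − 3)` for the p = 2 parameters; constant
observations make R² undefined and raise. Residual weighting is uniform —
no variance model is assumed for the observations.

## Mixture superposition

A blend with mass-percent weights Cₙ (non-negative, Σ = 100) is assumed to
release as the weighted average of its components:

    Cr_mix(t) = Σ Cₙ·aₙ(1 − e^(−bₙ·t)) / Σ Cₙ

i.e. components release independently — no particle–particle interaction,
no co-dissolution effects. The prediction is a convex combination, so it is
bounded by the pointwise min and max of the component curves and is invariant
to component reordering.

The weights are interpreted as percent of total *particle mass* (blends are
made by massing aliquots of each formulation). On the mass scale the same
rule applies to the per-formulation released µg for equal total mass:
component n contributes (Cₙ/100) of its own mass-scale curve. Mass curves
come either from percent-scale parameters plus a drug loading (µg drug per mg
particles, an explicit input because loading bases vary between studies) or
directly as µg-scale parameters when the loading is unknown — the latter is
how reference 72-h release amounts are encoded in the worked example and the
acceptance script. An "equal" three-way blend is treated as exactly 1/3
each, normalised to sum 100.

## Inverse design

Because Cr_mix is linear in the weights, matching a target profile is a
convex problem: minimise `Σ_t (target(t) − B(t)·x)²` over the simplex
`{x ≥ 0, Σx = 1}`, with B the matrix of component basis curves on the
target's time grid. It is solved with SLSQP on the quadratic objective
(analytic gradient, ftol 1e-16) followed by an exact equality-constrained
KKT solve on the active support, accepted only if it stays feasible — this
polish takes the recovered weights to machine precision. Noiseless targets
generated from known weights are recovered to well under 0.1 percentage
points, and the achieved RSS is verified in the tests against an exhaustive
1%-step simplex grid.

Degeneracy: when the Gram matrix of the basis curves has condition number
above 1e10 (near-identical components), the weights are not unique; the
result is flagged `degenerate`, a `DegenerateComponentsWarning` is emitted,
and the problem is re-solved with a small ridge (1e-8) so the returned
vector approximates the minimal-norm solution.

## Quantification

Beer–Lambert inversion gives the vessel molar concentration from a measured
absorbance, `c = A·D/(ε·l)`, where D ≥ 1 is the dilution applied to the
withdrawn supernatant before measurement (2 for a 1:1 dilution), ε the molar
extinction coefficient (dm³·mol⁻¹·cm⁻¹) and l the path length (cm).
Absorbances at or below a configurable blank threshold (default 0) are
clamped to zero with a logged warning. Conversion to mass is
`µg = c·(V/1000)·MW·10⁶`.

Sampling withdraws medium, and with it already-released drug, so cumulative
release needs mass-balance bookkeeping:

    M_k = V_k·c_k + Σ_{i<k} w_i·c_i

with V_k the vessel volume at sampling k and w_i the withdrawn volumes.
Withdrawn medium is assumed *replaced* with fresh medium by default (V stays
at the initial volume) — repeatedly removing 1 mL from a 1.5 mL vessel is
only sustainable with replacement — but a no-replacement mode (V shrinks) is
supported and tested. Withdrawals exceeding the vessel volume are protocol
errors. Encapsulation efficiency is `100·measured/theoretical` µg, reported
untruncated.

## Synthetic data

Generators are pure functions of (inputs, seed), built on
`numpy.random.default_rng`. `generate_release_curve` samples the model and
adds either additive Gaussian noise (σ in curve units) or proportional
Gaussian noise (σ as a signal fraction; default regime 5%, the typical
replicate scatter of UV–vis release assays); values are clamped at ≥0 and a
t=0 point is pinned to 0. `generate_formulation_set` draws parameters
uniformly from ranges whose defaults (a ∈ [60, 110]%, b ∈ [0.02, 0.4] /h)
bracket slow-releasing and fast-releasing regimes so blends show intermediate
profiles. The default sampling schedule {1, 2, 4, 8, 24, 48, 72} h spans the
burst and plateau phases of a 72-h study.

`simulate_sampling_protocol` forward-simulates the dissolution vessel — new
drug release between samplings, Beer–Lambert absorbance of the diluted
supernatant, withdrawal with or without replacement — and returns both the
instrument-level events and the ground-truth dissolved mass, which the
quantification layer must reconstruct exactly (the round trip is verified to
1e-9 relative in both replacement modes).

What the generator does *not* emulate: instrument drift and baseline error,
particle loss during withdrawal, drug degradation in the medium, and
inter-replicate variability in loading. Passing tests therefore demonstrate
the correctness of the arithmetic and estimation machinery, not robustness
to those real-data artefacts.

## Numerical and design notes

- **Identifiability limit.** At 5% proportional noise on a 7-point, 72-h
  schedule, the median relative error of the recovered rate constant is ≈7%
  at b = 0.05 /h and ≈12% at b = 0.02 /h, against ≈4–5% for faster regimes:
  when the asymptote lies beyond the observation window, the data carry
  little information about b, an information limit rather than an optimizer
  defect (the fitted RSS always beats a dense grid search). The recovery
  test therefore uses an identifiable design — a mid-regime formulation
  (a = 90%, b = 0.08 /h) sampled at 11 points across rise and plateau —
  where the median errors are ≈1.6% (a) and ≈3.9% (b). Slow formulations
  fitted over short windows should be interpreted with this caveat.
- **Percent-vs-mass bases.** Blend percent release depends on each
  component's loaded drug mass, which differs between formulations; blend
  *mass* release for equal total particle mass does not. The package keeps
  the loading basis an explicit parameter and uses the mass scale wherever
  reference amounts are compared.
- **Determinism.** Fitting, prediction and design are deterministic for
  fixed inputs; pipeline reruns produce byte-identical JSON (inputs are
  content-hashed into the report provenance). CSV round-trips are
  bit-identical (`%.17g` on write, round-trip float parsing on read).
- **Machine vs human precision.** Machine outputs carry full double
  precision; human-readable summaries round to 4 significant figures.

## Limitations

Only the two-parameter first-order model is provided — no Higuchi,
Korsmeyer–Peppas or Weibull alternatives, and no bootstrap confidence
intervals on the fitted parameters. The superposition rule assumes
independent, non-interacting components. No mechanistic treatment of polymer
hydrolysis, autocatalysis or porosity-dependent diffusion is attempted: the
model is empirical, and extrapolation beyond the fitted time window inherits
the identifiability caveat above.
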