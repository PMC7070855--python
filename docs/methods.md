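# Methods

`eprbind` analyzes host–guest binding of stable nitroxide radicals to
cucurbit[n]uril macrocycles from continuous-wave EPR titrations, with a
parallel ¹H NMR route for the diamagnetic (reduced) guests. This note
documents the models, the conventions that were fixed where the underlying
physics admits several, the synthetic-data conditions, and the numerical
choices.

## Lineshape model

A nitroxide tumbling fast in solution gives three hyperfine lines from the
I = 1 ¹⁴N nucleus. Each magnetic environment (`RadicalSpecies`) is
described by an isotropic g-factor, the nitrogen coupling `a_N` (Gauss),
and the fast-motion linewidth law

    W(mI) = α + β·mI + γ·mI²,   mI ∈ {+1, 0, −1},

with W the **full width at half height of the absorption line** in Gauss.
α, β, γ are treated as phenomenological per-species parameters; deriving
them from g/A tensor anisotropies and rotational correlation times is out
of scope. Conventions fixed here:

* **mI sign**: the low-field line is mI = +1 (standard for a positive
  nitrogen coupling); the line position is `B_res − a_N·mI` with
  `B_res = center_field·(g_ref/g_iso)`, `g_ref = 2.0059`. A "broader
  high-field line" (slower tumbling) therefore means W(−1) > W(0),
  i.e. γ > β.
* **Profile**: Lorentzian first derivative by default;
  `lorentz_fraction < 1` blends in a Gaussian derivative of the same
  half-width (pseudo-Voigt) to absorb residual instrument broadening.
  Field-modulation distortion is not modelled separately.
* **¹³C satellites**: first-order treatment. A `SatelliteSpec` with `n`
  equivalent carbons at natural abundance p diverts a fraction `n·p` of
  each main line into a pair at ±a_C/2 with the parent line's width; at
  most one ¹³C per molecule is assumed (terms of order p² dropped).
* **Normalization**: the returned derivative is scaled so that its double
  integral over the simulated window, by trapezoidal quadrature, equals 1.
  This is the usual EPR quantitation convention (spin count ∝ double
  integral of the recorded window). Lorentzian wings carry ≈0.5% of their
  mass outside a ±60 G window, so an infinite-window analytic
  normalization would make the on-window double integral depend on the
  widths; the on-window convention keeps it exactly concentration-linear.
* **Default grid**: center 3480 G (X-band, ≈9.76 GHz at g = 2.0059), span
  120 G, 4096 points. The titration presets use a lighter 80 G / 1024-point
  grid, which still spans >4·a_N and keeps the 20-seed fitting studies
  fast; the grid is a parameter everywhere.

A magnetically independent dinitroxide (`BiradicalModel`) is the weighted
pointwise sum of its two site spectra — no spin exchange, as appropriate
for bis-TEMPO-bis-ketal whose radicals are too far apart to couple.

## Line metrics

`line_metrics` reconstructs the absorption by cumulative integration,
locates the three largest maxima (≥4 G apart, plateau-tolerant), splits
the field axis at the midpoints, and reports per line:

* the **zero-crossing center** of the derivative (linear interpolation,
  ties toward lower field) — exact for resolved symmetric lines;
* a **first-moment center** for blended lines: the centroid on a symmetric
  window centered on the running centroid (iterated to its fixed point),
  after subtracting a linear baseline anchored at the window edges. The
  window half-width is where the line falls below 2% of its maximum. The
  symmetric window cancels the truncation asymmetry of the line's own
  Lorentzian tails (raw region moments are biased by several tenths of a
  Gauss); the edge-anchored baseline removes the slowly varying tails of
  the neighbouring lines. For an equal-width two-component blend the
  estimator is exact; unequal widths leave a bias of a few mG.
* the peak-to-peak derivative amplitude and the absorption width at half
  height (interpolated).

`apparent_a_N` is half the separation of the outer-line centers. Fewer
than three resolved lines yields a flagged result, not an exception.

## Speciation

Concentrations are mol/L internally (mM at all user interfaces);
association constants are M⁻¹.

* **1:1** — the physical root of the binding quadratic, computed in a
  cancellation-free form (discriminant `(K(G−H))² + 2K(G+H) + 1`, complex
  via `2KGH/(b+√disc)`) plus one Newton polish; mass balances close to
  ~1e−15 relative and the equilibrium quotient reproduces K to well below
  1e−6 across K ∈ [1, 1e8] M⁻¹, totals ∈ [1e−7, 0.1] M.
* **Stepwise two-host** (H+G⇌HG, HG+H⇌H₂G) — Brent root-finding on the
  free-host balance over [0, H_total], Newton-polished. K1 and K2 are
  independent: no statistical-factor constraint is imposed because the
  geometry/cooperativity of a second bound host is not established; the
  model is exploratory and excluded from default fitting.
* **Shuttle 1:1** — speciation identical to 1:1 (one host per dinitroxide
  guest); the shuttle enters only through the spectral model below.

## Global titration fit

All spectra of a series are fitted jointly ("2D": field × concentration).
Slow exchange on the EPR timescale is assumed, so each measured spectrum
is modelled as a population-weighted superposition of shared species
spectra, the weights coming from the speciation at the candidate
constant(s):

    y_i(B) ≈ s_i · Σ_k w_k(K; G, H_i) · S_k(B; θ) + b_i + c_i·(B−B̄)

* Per-spectrum nuisances (scale s_i, baseline offset b_i, slope c_i) are
  solved by linear least squares inside every objective evaluation
  (variable projection), keeping the nonlinear dimension at ~9–15.
* K is fitted as log₁₀K with a multi-start over five log-spaced
  initializations (10²–10⁶ M⁻¹) — the isotherm has local minima. Coarse
  bounded trust-region passes are followed by a tight polish of the best
  start; cost ties (<1e−9 relative) resolve toward the smaller K.
* Species widths are optimized as the three line widths
  (W(+1), W(0), W(−1)) with positive bounds, so every iterate is a valid
  lineshape, and reported back as α, β, γ.
* Satellite couplings are molecular constants: `initial_guess` accepts
  structural templates carrying the satellite set (and Voigt fraction),
  while a_N and the widths are always estimated from the series endpoints.
* **Shuttle model**: the bound population is a 50/50 two-station
  composite. The uncomplexed station keeps the free-species hyperfine
  coupling (nothing binds there) but has its own fitted linewidths — the
  whole complex tumbles more slowly, broadening both stations, and
  recovery tests confirm the uncomplexed station's α roughly doubles. The
  complexed station's a_N and widths are fully fitted. A
  `shuttle_averaged` variant (single averaged bound species) is provided
  for comparison.
* The quoted **regression coefficient** is the plain Pearson correlation
  between the concatenated fitted model (nuisances included) and the data;
  no noise correction is applied.
* Uncertainties are linearized (Jacobian at the solution); a constant at a
  box bound is flagged in the diagnostics.
* A **two-stage** variant (fit unconstrained per-spectrum bound fractions,
  then fit K to those fractions) is exposed as a diagnostic
  (`strategy="two_stage"`); the constrained joint fit is the default and
  the reference.

`compare_models` runs matched fits for several stoichiometries and ranks
them by regression coefficient without automatic selection — with
overlapping isotherms the extra complex of a 2:1 model often buys only a
marginal R improvement, and that judgement is left to the user.

## NMR route

The reduced (hydroxylamine) guests are diamagnetic, so ¹H titrations are
usable. Two estimators, never combined automatically:

* **Fast exchange**: δ_obs = δ_free + f_bound·(δ_bound − δ_free), with
  f_bound from the 1:1 solve. `fit_nmr_1to1` fits (K, δ_bound) by
  bounded least squares (log-scale K, same multi-start ladder), with
  δ_free pinned to the zero-host reference point to break the strong
  K/δ_bound correlation. Flat titrations return an
  unidentifiability-flagged result.
* **Slow exchange**: separate free/complex signals; the bound percentage
  is 100·I_bound/(I_free+I_bound). Reported fractions are rounded to
  whole percent.

The consistency loop ties the two spectroscopies together: the percent
complex predicted by the EPR-fitted constant at the NMR composition
(guest 0.5 mM, 1.1 equivalents of host) agrees with the slow-exchange
integral fraction within ~2 percentage points.

## Synthetic data: what it emulates

The presets encode the study conditions the pipeline is designed for, with
a provenance tag (`paper` = taken from the published study they emulate,
`default` = documented choice for an unprinted quantity) on every number:

| preset | design | key truths |
|---|---|---|
| `TEMPONE_CB7` | 25 spectra, host 0–10 mM (denser below 2 mM), guest 0.1 mM | Ka 4510 M⁻¹; a_N 16.0 → 15.3 G; Wahh 0.8 G |
| `BTBK_CB8` | 36 spectra, host 0–1 mM, guest 0.05 mM | Ka 20 900 M⁻¹; complexed-station Δa_N 0.34 G; α×2 (uncomplexed), α×1.5 and β,γ×5 (complexed) |
| `REDUCED_TEMPONE_NMR` | 10 points, 0–3 equiv, guest 0.5 mM | Ka 3960 M⁻¹ |
| `REDUCED_BTBK_NMR` | 10 points, 0–3 equiv, guest 0.5 mM | Ka 20 900 M⁻¹; Δδ −0.29 ppm |

Unprinted values use documented defaults: the dinitroxide base station
a_N 16.0 G and widths (0.8, −0.05, 0.05) G; TEMPONE satellite coupling
4.4 G (4.0 G bound) over four equivalent carbons; NMR methyl reference
1.20 ppm. Noise is additive white Gaussian — per-spectrum SNR defined as
max derivative amplitude over noise σ for EPR, shift σ in ppm for NMR —
and every generator takes an explicit seed (identical seed ⇒ bit-identical
output). Baseline drift, modulation artifacts, field drift, host
self-aggregation and competitive displacement are **not** emulated, so
passing recovery tests demonstrate estimator correctness under the assumed
noise model, not robustness to instrument systematics.

Under these conditions the recovery studies (median of 20 seeds) land
within ~1–3% of the encoded constants for the EPR fits at SNR 50/30 and
within ~2% for the NMR fit at 0.002 ppm noise; the acceptance script
recomputes these end to end.

## Numerical and degenerate-input choices

* Identifiability: a series needs ≥3 points and ≥2 distinct host totals
  with at least one nonzero; all-zero-host designs raise an error, and a
  missing zero-host point only warns.
* Spectra are resampled to the first spectrum's grid by linear
  interpolation when a loaded series mixes grids.
* A spectrum window narrower than 4·a_N flags the spectrum and warns
  (outer lines clipped); the warning is suppressed for transient optimizer
  iterates inside the fit objective.
* `line_metrics` on fewer than three resolved lines (e.g. a_N → 0) returns
  a flagged, all-None result.
* Degenerate speciation inputs (zero totals or zero constants) return the
  trivial equilibrium rather than erroring; negative inputs raise.
* The spectrum CSV writer emits the field axis at 10 significant digits
  (6 digits would quantize an X-band axis to 0.01 G) and intensities at 6.

## Known limitations

* Fast-motion perturbation regime only: no slow-motion/Freed-regime
  simulation, no anisotropic powder patterns, no J-coupled five-line
  biradical spectra.
* The 2:1 model's constants are reported as fitted, but with overlapping
  component spectra they are weakly identified; treat the comparison table
  as descriptive.
* Linearized uncertainties understate errors near bounds or for strongly
  correlated parameters.
* Provenance-tagged presets emulate one study's conditions; they are not a
  general nitroxide parameter library.
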