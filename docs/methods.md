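# Methods

This note documents the models, numerical choices and limitations behind
`pahbind`. Units are fixed throughout the core: concentrations in mol/L,
energies in kJ/mol, temperatures in K, lengths in nm;
R = 8.31446×10⁻³ kJ/(mol·K). Unit conversion happens only at the I/O
boundary (CSV headers declare the concentration unit, µM by default).

## Single-site binding model

A PAH ligand L binds one of n equivalent, independent cavities (default
n = 2 per tetramer). With total site concentration S_tot = n·[P]_tot, the
free-site concentration solves the mass balance

    S_free² + S_free·(K_d + L_tot − S_tot) − K_d·S_tot = 0,

taken at the positive root with a cancellation-safe quadratic formula
(the conjugate form is used when the linear coefficient is positive).
The observable is fraction bound y = (F − F₀)/(F∞ − F₀) =
S_free/(K_d + S_free) with B_max fixed at 1.

**Abscissa modes.** `free_sites` (default) evaluates S_free
self-consistently at each K_d iterate — correct when ligand and protein
concentrations are comparable, as in a titration. `total_protein` uses
S_tot directly and is adequate only in large protein excess; the two
agree within fit error once [P]/[L] ≳ 50 (tested).

A practical caveat established during development: published K_d values
for this system are reproduced on the *total-RHCC tetramer axis*
(`mode="total_protein"`, `sites_per_tetramer=1`), which is how the
original assay data were plotted; the free-site estimator applied to the
same points gives a substantially larger K_d (≈ 28 vs ≈ 16 µM for the
packaged naphthalene fixture) because depletion of free sites at low
protein reshapes the isotherm. Both conventions are first-class; reports
always state the mode used.

**Objective.** F₀ is pinned to the measured zero-protein point (every
series must contain exactly one). The fit minimizes intensity-scale
residuals F − [F₀ + (F∞ − F₀)·y_model] over (K_d, F∞) by
Levenberg–Marquardt (lmfit), with five log-spaced K_d starts spanning the
nonzero site-concentration range and the lowest-SSR start winning; the
iteration cap is 200 function evaluations per start. A literal
fraction-scale objective, with y_obs depending on the fitted F∞, is
degenerate — inflating (K_d, F∞) jointly drives every residual to zero —
so the intensity-scale form (the same quantity times the constant
amplitude) is used instead. R² is reported on the fraction-bound scale,
the scale of the model equation. Standard errors come from the fit
covariance; the 95% CI is the normal approximation K_d ± 1.96·SE.
Residuals are unweighted. A Pearson |r| < 0.3 between intensity and
protein concentration is rejected before fitting as "no sign-consistent
direction"; quenching data (F∞ < F₀) fit normally, the sign is inferred,
never assumed.

**Gibbs energy and capacity.** ΔG = RT ln K_d with T defaulting to 297 K
(the temperature at which the published table values are reproduced;
configurable — the assay itself ran at 293 K). Sorbent capacity is
occupancy × sites × mass/molar-mass with the tetramer at 23.6 kg/mol;
25 mg at two sites gives 2.12 µmol, i.e. 84.7 nmol per mg. (The
frequently quoted "85 pmol per mg" figure is dimensionally inconsistent
with 2.12 µmol per 25 mg; the nanomole reading is the self-consistent
one and is what this package reports. The CLI report carries a unit
note.)

## Py-value and uptake kinetics

Band intensities are the *maximum* within fixed wavelength windows —
band I in 368–378 nm, band III in 379–390 nm — rather than values at
fixed wavelengths, tolerating ±2 nm calibration shifts. Py = I_I/I_III.
Windows must be disjoint and non-empty; a zero band-III intensity is a
domain error.

The uptake trace is modelled as F(t) = F∞ − (F∞ − F₀)e^(−kt): no rate
law is implied by the data themselves, but with a ~35-fold protein excess
pseudo-first-order kinetics is the simplest model consistent with a
monotone approach to a plateau. Equilibration time is defined as 99% of
amplitude, t_eq = ln(100)/k. The average uptake rate is the transparent
arithmetic (L_tot/P_tot)/t_eq in mol ligand per (h·mol protein) — for
2 µM pyrene, 70 µM protein and t_eq = 80 h this is 3.57×10⁻⁴ mol/(h·mol).
A published figure of 1.59 nmol/(h·mol) for the same experiment cannot be
reproduced under any unit reading we attempted and is not used as a
check. A plateau flag (last three points within 2%) is set on the fit but
does not block it; fewer than 6 points or a directionless trace raise
errors.

## Thermodynamic-integration post-processing

Window uncertainties come from block averaging: the series is split into
n contiguous equal blocks (default 10, remainder truncated) and
σ = sd(block means)/√n. Block lengths must exceed the correlation time
for unbiased errors; for AR(1) noise with lag-1 correlation φ the SE of
the mean inflates by √((1+φ)/(1−φ)), which the tests verify against
Monte-Carlo truth at φ = 0.9.

ΔG legs are trapezoidal quadrature of the window means over λ ∈ [0, 1];
Simpson's rule is available for uniform odd-length grids. Endpoint
windows at λ = 0 and 1 are required — no extrapolation (soft-core
endpoint handling belongs to the MD engine, out of scope). Uncertainty
propagates as √(Σ wᵢ²σᵢ²) with the quadrature weights wᵢ, treating
windows as independent.

## Restraint volume and cycle corrections

The flat-bottom harmonic well is U(r) = 0 inside r₀ and k(r−r₀)² beyond
(defaults k = 1000 kJ mol⁻¹ nm⁻², r₀ = 0.55 nm). Its effective volume is

    V_FBHW = ∫ exp(−U(r)/RT) d³r
           = (4/3)πr₀³ + 4π ∫₀^∞ (r₀+s)² e^(−ks²/RT) ds.

The numeric method substitutes s = u·√(RT/k) so the quadrature is
well-conditioned for arbitrarily stiff springs (adaptive quadrature,
relative tolerance 1e−8; the k → ∞ limit recovers the hard sphere to
0.1%). At the defaults and 300 K it gives 0.883 nm³. A widely reproduced
closed-form expansion,
(4/3)πr₀³ + 4πr₀²(πRT/k)^½ + 2πr₀(πRT/k) + (πRT/k)^{3/2}, evaluates to
1.061 nm³ with the same inputs — its Gaussian-tail terms are missing the
half-Gaussian factors (the correct tail integrals are r₀²·(πRT/k)^½/… with
coefficients ½√π·w, RT/2k and ¼√π·w³ for the three moments). The numeric
integral is authoritative; both values appear in every cycle report so
the inconsistency is never silently absorbed.

ΔG₂ = +RT ln(V_FBHW/V₀) with V₀ = 1.660 nm³ (1 M standard state); it is
analytic and carries no uncertainty. ΔG_symm = −RT ln σ applies only when
orientational restraints confine the ligand's rotation; with a purely
translational FBHW the ligand rotates freely and the term is omitted by
default (`include_symmetry=False`).

The cycle assembles as ΔG⁰ = −ΔG₁ − ΔG₂ + ΔG₃, with
σ = √(σ₁²+σ₃²)/√2 by default. That √2 divisor is undocumented in the
source material but is the unique rule consistent with every published
uncertainty row; plain root-sum-square (`error_rule="rss"`) is provided
as the conventional alternative, and the rule used is recorded in the
result. Cycle arithmetic defaults to 300 K.

## Synthetic generators

All generators are pure functions of (parameters, seed) — one
`numpy.random.default_rng(seed)` per call, no global state — and their
outputs always pass the validators of the types they construct.

- `gen_titration`: forward isotherm with self-consistent free sites;
  2% multiplicative Gaussian noise by default (fluorimeter-like);
  the zero-protein point stays noise-free, as F₀ is measured separately
  in the assay.
- `gen_uptake_timecourse`: single exponential plus noise.
- `gen_ti_profile`: polynomial mean over λ with stationary AR(1) noise
  per window (MD-like correlation, vectorized via a linear filter).
  `sigma_target` is the intended SE of each window mean; with
  `sigma_is_marginal=True` it is the marginal sample SD instead, so the
  correlation's cost in precision is visible.
- `gen_pyrene_spectrum`: two Gaussian bands on a 1 nm grid with
  amplitudes solved from a 2×2 overlap correction so the *peak* ratio
  equals the target Py exactly even at 4 nm band width.

What the generators do **not** emulate: inner-filter effects,
photobleaching, baseline drift, tyrosine emission bleed-through at
275 nm excitation, multi-exponential uptake, λ-dependent MD noise
variance, or soft-core endpoint spikes in dG/dλ. Passing the recovery
tests therefore demonstrates estimator correctness under the stated
noise models, not robustness to every instrumental artifact.

## Problem sizes and defaults used in the test suite

Parameter-recovery checks use 200 seeded titration replicates (11
concentrations spanning 0–4·K_d, 2% noise), 50 uptake replicates at 5%
noise, and 300-seed Monte-Carlo checks of block averaging at n = 4000
samples/window — sizes chosen to give stable medians and coverage
estimates while keeping the whole suite fast enough to run on every
commit.

## Known limitations

- The free-site mass balance assumes independent, equal sites; no
  cooperativity or Hill-type models.
- No inner-filter or photobleaching corrections; single-wavelength
  analysis only.
- TI post-processing only — the package never generates trajectories,
  and no BAR/MBAR estimators are provided.
- The normal-approximation CI for K_d can undercover for strongly
  skewed likelihoods (very sparse or very noisy titrations).
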