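# Methods

## Isotope bookkeeping

All mixing, carrier-removal and blank-correction arithmetic is done in
(amount, atom fraction) space, where ¹⁵N and ¹⁴N contents are each
conserved exactly at any enrichment. δ¹⁵N enters and leaves only at the
interfaces through n = R/(1+R), R = r_std(1 + δ/1000). The linear
δ-mixing approximation, common at natural abundance, is avoided because a
98 at-% tracer is far outside its validity range.

The reference ratio defaults to r_std = 0.0036765 (atmospheric N₂), which
maps δ¹⁵N = 0‰ to 0.3663 atom-% — the natural-abundance value assumed for
ambient NH₄⁺. The tracer atom fraction defaults to 0.98; both are
configurable. Pools carry a concentration (nmol N L⁻¹) and optionally a
volume, in which case amount-based operations (carrier unmixing, blank
subtraction) use conc × volume; without a volume the concentration value
doubles as an amount against a nominal 1 L. Blank corrections warn when
blanks exceed 3% of the measured N and refuse (rather than silently
truncate) blank-dominated samples.

## Rate equations and their relationship

Two algebraically related routes give the bulk (ambient + tracer)
transformation rate from a two-endpoint incubation:

1. the single-endpoint product-enrichment form
   R_bulk = C₀(nₜ − n₀)/(t f¹⁵), and
2. the atom-accumulation chain R₁₅ = (Cₜnₜ − C₀n₀)/t,
   R₁₄ = R₁₅(1 − n)/n, bulk = R₁₅ + R₁₄.

Under the framework's standing assumptions — constant substrate labelling
f¹⁵ over the (short, 3–12 h) incubation, no isotope dilution by
regeneration, no fractionation — route 2 is an exact inversion of the
¹⁵N mass balance: if nitrogen transforms at rate R carrying fraction f¹⁵,
then R₁₅ = R f¹⁵ and R₁₄ = R(1 − f¹⁵) identically. Route 1 agrees with
route 2 exactly when the product pool is constant (Cₜ = C₀) and otherwise
carries a small O(n₀/f¹⁵) low bias (≈0.7% at f¹⁵ ≈ 0.5) because the
product pool starts at natural rather than zero ¹⁵N. Both are exposed;
the estimator-comparison report and the kinetic-series assembly use the
exact chain, and report the single-endpoint value alongside.

The in-situ calibration R_in situ = (R₁₅ + R₁₄)·Ci/(Ci + Ct) linearly
interpolates the bulk rate from the spiked concentration back to ambient.
It is exact only for a strictly first-order response and is therefore
valid when total substrate stays well below Kₛ; when a kinetic fit is
available and Ci + Ct ≥ Kₛ the function warns. Against the
Michaelis–Menten truth the residual error of the linear form is
1 − (Kₛ + Ci)/(Kₛ + Ci + Ct), e.g. ≈1.9% for Ci = Ct = 20 nmol L⁻¹ and
Kₛ = 1000 nmol L⁻¹.

Negative computed rates are retained, not clamped: truncation would bias
replicate averages, and the below-detection flag already marks values
indistinguishable from zero.

## Daily integration

Oxidation: 12 h × light hourly rate + 12 h × dark hourly rate (paired
incubations are required because ammonia oxidizers are photoinhibited, so
neither condition alone represents the diel mean). Uptake: 16 × the light
hourly rate, an empirical day-length factor for photoautotrophic
assimilation; whether a dark contribution should enter is genuinely open,
and the package applies the factor to the light rate only. All three
multipliers are configuration fields.

## Detection limits

The detection limit is per-sample, not global, because the product pool
varies by orders of magnitude over depth. The smallest detectable rate is
the one that raises the product pool's δ¹⁵N by k·σ (default 3 × 0.2‰ =
0.6‰) above its initial value:

    DL = C_product × Δn_min / (t × f¹⁵),

with Δn_min computed by the exact δ→atom-fraction conversion at the pool's
initial δ rather than a linearised sensitivity (negligible difference at
natural abundance, but self-consistent). A 30 µmol L⁻¹ NOₓ pool with
f¹⁵ = 0.9 over 24 h gives ≈0.073 nmol N L⁻¹ d⁻¹.

## Kinetics

R(S) = V_max S/(Kₛ + S) is fitted by unweighted nonlinear least squares
(optional constant-CV relative weighting). The optimiser works in
log(V_max), log(Kₛ) to enforce positivity — important for four-point
designs where an unconstrained step can cross zero — with starting values
V_max⁰ = max observed rate and Kₛ⁰ = median substrate concentration.
Standard errors come from the Gauss–Newton covariance in natural parameter
space; α = V_max/Kₛ gets a delta-method standard error. Convergence is
reported honestly: a failed fit still returns parameters, flagged.

The kinetic abscissa is total substrate (ambient + spike), matching the
experimental design in which each addition level measures a bulk rate at
its own total concentration. The default design is four levels at
{10, 100, 500, 2000} nmol L⁻¹ with duplicates, spanning the documented
10–2000 nmol L⁻¹ range; replicates are fitted jointly rather than
averaged first (equivalent for balanced designs, better-behaved
otherwise).

## Profile feature detection

- **MLD**: shallowest depth where T = T_surface − 0.8 °C, linearly
  interpolated between bottles (snapping to bottle depths would quantise
  the estimate to the sampling grid). Isothermal profiles return a
  distinct no-MLD result.
- **Nitracline**: adjacent-pair finite-difference NO₃⁻ gradients, no
  smoothing. The "steepest range" is the contiguous run of pairs
  containing the maximum whose gradients reach ≥90% of the maximum (the
  delimitation rule is otherwise underdetermined; 90% is the package's
  declared, configurable choice). The nitracline depth is the midpoint of
  that range. A flatness floor (default 0.01 concentration units m⁻¹)
  returns no-nitracline for well-mixed nutrient-replete profiles.
- **Euphotic depth**: k from the least-squares slope of ln(PAR) vs depth;
  depth = ln(1/fraction)/k with fraction defaulting to 0.001 (0.1% sPAR).
- **Extrema**: global maxima of NO₂⁻ (PNM), fluorescence (DCM) and the
  NO₃⁻/SiO₄ ratio (computed only where SiO₄ > 0); ties break shallow and
  endpoint maxima are flagged as boundary extrema.
- **Transition depth**: rate profiles are interpolated onto the union of
  their depth grids; the crossover is the shallowest depth where
  nitrification exceeds uptake and stays greater for ≥2 consecutive
  samples (the persistence rule suppresses transient flips where the two
  processes co-occur at comparable rates), linearly interpolated.
- **Light/dark comparison**: Student's t, paired across depths when the
  groups are depth-matched, two-sample otherwise; degenerate identical
  groups return t = 0, p = 1.

## Synthetic data: what it emulates, and what it does not

The incubation generator holds the transformation rate constant within an
incubation (zeroth-order over 3–12 h: pools are effectively undepleted and
f¹⁵ constant, consistent with the rate equations' own assumptions) and
accumulates product ¹⁵N by exact mass balance. Analytical noise is
multiplicative on concentrations (CV 3.5%, the NH₄⁺ method precision) and
additive on δ¹⁵N (SD 0.2‰, the isotope-ratio accuracy). Light inhibition
(a 0–1 factor, default 0.5) applies to nitrification only. Default truth:
V_max = 22 nmol N L⁻¹ h⁻¹, Kₛ = 300 nmol N L⁻¹, ambient NH₄⁺
20 nmol L⁻¹, a 30 µmol L⁻¹ natural-abundance NOₓ product pool, 20 nmol L⁻¹
spikes for oxidation and four-level kinetic designs as above.

The station generator builds analytic profiles — a mixed layer over an
exponentially saturating thermocline, PAR = sPAR·e^(−kz) with k = 0.06
m⁻¹, a logistic nitracline centred at 70 m, Gaussian DCM (75 m) and PNM
(85 m), patchy NH₄⁺ clipped to 1–74 nmol L⁻¹, and Gaussian uptake
(shallow) and nitrification (deep) rate peaks crossing near 61 m — on a
5 m grid to 200 m, plus seeded measurement noise (temperature SD 0.01 °C;
PAR 2%, NO₃⁻ 1%, NO₂⁻/NH₄⁺ 3.5%, fluorescence 3%, rates 5% CV). Every
true feature depth is known in closed form (the rate crossover by root
finding on the noise-free curves), so recovery studies compare detections
against exact truth.

The kinetic recovery study uses 5% multiplicative rate noise (the
canonical condition for that study); the alternative "analytical" mode
pushes concentration/δ noise through the full incubation chain, which is
harsher at low spike levels because small δ enrichments of a large product
pool carry large relative errors.

What the generators do **not** emulate: substrate depletion and isotope
dilution within an incubation, regeneration/remineralization fluxes, diel
light forcing, multi-species competitive kinetics, density-driven
structure (MLD is temperature-only), and bottle-to-bottle heterogeneity
beyond independent Gaussian noise. Passing recovery tests therefore
demonstrate correctness of the estimators under the framework's own
assumptions, not robustness to processes the assumptions exclude — in
field data, regeneration over long incubations or a Kₛ varying with depth
would add biases that these tests cannot see.

## Numerical choices and degenerate inputs

Tolerances: isotope round trips and mass-balance identities hold to 1e-12
relative; kinetic fits use xtol = ftol = gtol = 1e-14. Carrier unmixing
and blank correction raise on non-physical results (negative amounts,
atom fractions outside (0,1)) instead of clipping. Feature detectors
return typed "absent" results (no-MLD, no-nitracline, no-crossover,
flat-series) distinct from errors, so downstream tables can record the
scientific outcome. CSV outputs are written atomically (temp file +
rename) and inputs are never modified; malformed rows are rejected
individually with line numbers rather than failing the file.

## Problem sizes

The recovery studies run 200 simulated kinetic series and 100 simulated
stations — large enough for stable medians and a resolvable ≥95% recovery
criterion, small enough that the whole suite runs in seconds.

## Known limitations

- The in-situ linear calibration inherits the first-order assumption; for
  designs where Ci + Ct approaches Kₛ only the kinetic approach is
  unbiased, and the package flags rather than corrects such cases.
- Kₛ and V_max standard errors from four-point designs are asymptotic
  (Gauss–Newton) and optimistic at high noise.
- The nitracline midpoint depends on the 90% contiguity rule when the
  NO₃⁻ ramp is nearly linear; the rule is exposed as a parameter.
- MLD uses temperature only; salinity-compensated density structure is out
  of scope.
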