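# Methods

This note records the models implemented in `mesoglass`, the conventions
chosen where the field has no single standard, the numerical tactics, and
what the synthetic-data validation does and does not establish.

## Physical picture

A drug glass ground and melted together with mesoporous silica
partitions into three populations with distinct thermal signatures:
**rigid** drug, immobilized at the silica surface, contributes no
heat-capacity step at the glass transition; **free** drug behaves like
the bulk glass and cold-crystallizes on heating; **intermediate** drug
shows a glass transition but cannot crystallize. Which populations
dominate depends on the mixing ratio and on the pore geometry, and the
package quantifies all three routes to that assignment: calorimetry
(fractions), dielectric spectroscopy (mobility and its distribution) and
isothermal kinetics (crystallization propensity).

## Units

Config files and CSV inputs use practitioner units (°C, J/(g·K), g/cm³,
mL/g, m²/g, nm). All computation that mixes Boltzmann's constant with
specific heats runs in SI internally (`*_si` accessors on the material
specs); fractions are dimensionless internally and percent only at
presentation. This removes the classic double-scaling and off-by-10³
failure modes.

## Loading geometry

The molecular footprint uses the cubic idealization: a molecule of volume
V = M/(ρ N_A) presents a face V^(2/3). ρ is the *glass* density, so the
footprint describes amorphous packing, not any crystal face. Monolayer
capacity is SA/footprint; the critical silica fractions follow from mass
balance (f = 1/(1+r)). `monolayer_occupancy` divides the drug:silica mass
ratio at the measured full-rigid load by the monolayer ratio; it assumes
every rigid molecule is in wall contact, which partially filled pores
violate, so it is exposed as a diagnostic, not a claim about pore
filling.

## DSC feature extraction

Onset/end are tangent constructions: the intersection of the
maximum-slope tangent with linear baselines fitted outside the transition
region (the region where the smoothed derivative exceeds 10% of its
peak, plus a guard margin). ΔC_p is the vertical separation of the two
extrapolated baselines at the midpoint. Traces are smoothed with an
11-point Savitzky–Golay filter (order 3) before differentiation — slope
tangents on raw noisy traces are ill-posed. A step below 0.02 J/(g·K)
(configurable) raises a "no transition" error rather than returning
noise. Peak enthalpies integrate the signal above the straight line
joining the window endpoints; heat-flow traces are converted to a C_p
basis with the declared heating rate, and traces without that metadata
are rejected rather than guessed. Both the linear baseline and the
tangent choice are conventions; instrument software differs, and
absolute onsets can shift by a few tenths of a kelvin between
conventions.

## Fraction decomposition

The rigid/free formulas take the enthalpy ratios at face value: no
temperature correction of the cold-crystallization enthalpy and no
allowance for polymorph-dependent heats — a documented limitation, since
the free fraction inherits any bias in ΔH_cc. Raw triples always sum to
100 exactly; clipping to [0, 100] (with renormalization only when
rigid + free exceeds 100) handles noise-driven negative values, and the
raw values are kept for diagnostics. The full-rigid extrapolation is
unweighted OLS of ΔC_p(mixture) against silica fraction; replicate-based
weights would be better but are rarely available, and the root is
reported with r². Pure-drug reference values (ΔC_p and ΔH_cc per gram of
drug) are explicit inputs — they are instrument- and protocol-specific
and the package refuses to assume them.

## Donth CRR

L = [k_B T_g² Δ(1/c_p) / (ρ δT²)]^(1/3) with Δ(1/c_p) = 1/c_pg − 1/c_pl
(positive) and δT = half the onset-to-end width from the same tangent
construction. The ambient glass density stands in for the density at
T_g; the thermal-expansion correction (~1–2% in ρ, ~0.5% in L) is far
below the sensitivity of L to δT (L ∝ δT^(−2/3)). Equal specific heats
degenerate to L = 0 with a warning, not an error.

## Dielectric relaxation

Fitting is loss-only on log10 ε″ over the measured (log-spaced)
frequencies: the loss spans decades and a linear objective would see only
the peak. ε_∞ is therefore not identified by the default fit (it only
enters ε′) and is estimated from the high-frequency ε′ tail; joint
real+imaginary fitting is available via `fit_real=True`. σ_dc is
initialized from the low-frequency flank when it shows slope −1 and
fitted in log space. Multi-start: five τ-jittered (±0.5 decade)
restarts, best χ² kept. Two-process fits parametrize the second process
by a non-negative log-τ gap from the first, which pins the slow process
to index 0 and removes label-switching. ε_∞ and σ_dc are shared across
processes.

τ_α maps the HN parameters to the loss-peak reciprocal angular
frequency, τ_α = τ_HN [sin(aπ/(2+2b))]^(−1/a) [sin(abπ/(2+2b))]^(1/a);
the identity is property-tested against dense numerical peak location
across random (a, b).

The KWW loss shape is the one-sided sine transform of −dΦ/dt with
Φ = exp(−(t/τ)^β). The raw integrand has an integrable u^(β−1)
singularity at the origin that defeats oscillatory quadrature, so the
implementation integrates by parts — loss(w) = w ∫₀^∞ e^(−u^β) cos(wu) du
— and switches between ordinary adaptive quadrature (few oscillations
inside the decay envelope) and Fourier-weight QAWF (many), by oscillation
count. Validated to ≤5×10⁻¹¹ relative error against 30-digit
reference quadrature over β ∈ [0.3, 1], ωτ ∈ [0.01, 1000]. β is fitted
in the frequency domain to the unit-peak shape on the measured log-f
grid (time-domain fitting of back-transformed data is an alternative
some labs use; frequency-domain shape fitting avoids the inverse
transform). Inputs must be single-peaked with an interior maximum.

VFT fits run on log10 τ. Initialization scans T0 candidates — for fixed
T0 the model is linear in 1/(T−T0) — and a bounded nonlinear polish
follows. Three points are interpolated to machine accuracy; the
Arrhenius limit is representable (T0 floor 0.01 K, with D·T0 then the
activation temperature).

## Crystallization kinetics

Model X(t) = plateau·(1 − exp(−k(t−d)^n)), identically 0 for t ≤ d. In
this form k has units s⁻ⁿ; kinetic tables conventionally print k in
s⁻¹, so reports carry both the fitted k and k^(1/n). By default
plateau = 1 (the uncrystallized remainder is ignored); `fit_plateau=True`
frees it. The double-log linearization only seeds the nonlinear fit.
ε′-based traces are converted with ε′_N first; a missing long-time
plateau is an error, never a silent extrapolation.

**Identifiability.** With the 600-s sampling used for isothermal runs
and 1% conversion noise, (log k, d, n) are strongly correlated: the
Cramér–Rao bound puts the median |error in log10 k| near 0.18 for a
free induction time, versus ~0.06 with d known. Rate-constant recovery
studies in the test suite therefore pin d at its generating value
(`fix_d`); single-trace fits leave d free (bounded at 0) and report the
correlated uncertainty honestly via the residual.

t_1/2 solves X = 0.5 absolutely: d + (−ln(1 − 0.5/plateau)/k)^(1/n),
undefined when the plateau is below 0.5. The empirical t_1/2 is linear
interpolation of the first 0.5 crossing. Terminal conversion averages
the last 20% of points and tests the tail slope against zero (OLS
p > 0.05 ⇒ settled); still-rising traces return the mean flagged
unsettled.

## Synthetic generators

Every generator is seeded (`GeneratorRecipe`) and returns (data, truth);
identical recipes are byte-identical. Noise is multiplicative for loss
spectra (instrument loss noise scales with signal), additive for
conversion traces and thermograms, log-normal for relaxation times —
each configurable. Defaults mirror a celecoxib-like regime: onset T_g
58 °C, ΔC_p 0.45 J/(g·K), transition width 4 K, cold-crystallization
enthalpy 60 J/g, KWW β 0.69 for the bulk glass, VFT (10⁻¹⁴ s, D = 8,
T0 = 270 K), Avrami (k = 1.59×10⁻⁷ s⁻ⁿ, d = 907 s, n = 1.8) sampled at
600-s intervals to 3.6×10⁴ s, dielectric sweeps 10⁻²–10⁷ Hz at 8
points/decade. The thermogram step is a logistic whose tangent
construction has exactly the requested onset-to-end width (scale =
width/4); Gaussian peak areas are exact. The mixture-ladder generator's
default fraction model places the rigid fraction so that the ΔC_p
ladder is exactly linear with a planted full-rigid root at 83.9%
silica — the form the linear extrapolation assumes.

What the generators deliberately do not emulate: thermal lag and
modulation deconvolution of real DSC hardware, electrode polarization
and sub-T_g secondary relaxations in dielectric sweeps, and
polymorph-dependent melting. Passing the recovery suites shows the
estimators are correct and well-conditioned for data of this structure
and noise class; it does not certify accuracy against those instrument
artifacts.

## Problem sizes

Test and acceptance runs use the sizes above (73-point spectra, ~60-point
kinetic traces, 1600-point thermograms, 50-replicate recovery studies);
these match routine experimental sampling and keep the full suite under
a few minutes on one core.

## Known limitations

- Loss-only HN fitting cannot determine ε_∞; the reported value is a
  tail estimate unless `fit_real=True`.
- The free fraction inherits any bias in the pure-drug ΔH_cc reference.
- The Donth length uses the ambient density and a tangent-construction
  width; both conventions shift L by a few percent between labs.
- `monolayer_occupancy` is interpretive (assumes all rigid drug is in
  monolayer wall contact).
- No non-isothermal kinetics (Ozawa/Kissinger), no Gibbs–Thomson melting
  analysis, no polymorph assignment.
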