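# mesoglass

Analysis toolkit for the physical stability of **amorphous (glassy) drugs
confined in mesoporous silica**. Amorphous formulations dissolve better
than crystals but tend to recrystallize; dispersing the drug glass in a
high-surface-area silica slows or stops that. `mesoglass` implements the
standard characterization chain a formulation-physics lab applies to such
systems — calorimetry, dielectric spectroscopy and crystallization
kinetics — as a tested Python library, together with seeded synthetic-data
generators so every stage can be exercised and validated without
instrument data.

## What it computes

**Loading geometry** (`mesoglass.loading`). From a silica grade's surface
area SA and pore volume V_p and the drug's molar mass M and glass density
ρ: the cubic-assumption adsorption footprint (M/(ρN_A))^(2/3), the
monolayer capacity SA/footprint, and two critical silica mass fractions —
for full monolayer coverage, f = 1/(1 + r) with r the monolayer drug:silica
mass ratio, and for complete pore confinement, f = 1/(1 + V_p ρ).

**DSC features** (`mesoglass.dsc`). Tangent-construction glass-transition
onset/end/width and the heat-capacity step ΔC_p; peak enthalpies above a
linear baseline; crystallinity X = 1 − ΔC_p(t)/ΔC_p(0).

**Fraction decomposition** (`mesoglass.fractions`). Splits the drug into
*rigid* (no glass transition: rigid% = 100(1 − ΔC_p/(w·ΔC_p,pure))),
*free* (cold-crystallizing: free% = 100·ΔH_cc/(w·ΔH_cc,pure)) and
*intermediate* (remainder) populations, and extrapolates the ΔC_p-vs-load
line to the silica fraction that silences the glass transition.

**CRR size** (`mesoglass.crr`). Donth's fluctuation relation
L = [k_B T_g² (1/c_pg − 1/c_pl) / (ρ δT²)]^(1/3), with δT half the
transition width — the cooperativity length to compare against pore size.

**Dielectric relaxation** (`mesoglass.bds`). Havriliak–Negami fits
ε*(ω) = ε_∞ + Σ Δε/(1+(iωτ_HN)^a)^b − iσ_dc/(ε_0ω) (one or two processes,
multi-start, loss-only objective on log ε″), the loss-peak relaxation
time τ_α, Vogel–Fulcher–Tammann fits τ = τ_0 exp(DT_0/(T−T_0)), and the
Kohlrausch–Williams–Watts stretching exponent β fitted to normalized loss
peaks through the exact one-sided Fourier transform of exp(−(t/τ)^β).

**Crystallization kinetics** (`mesoglass.kinetics`). Conversion from the
normalized dielectric dispersion ε′_N = (ε′_0−ε′_t)/(ε′_0−ε′_∞) or from
ΔC_p; Avrami–Erofeev fits X(t) = plateau·(1 − e^(−k(t−d)^n)); analytic and
empirical t_1/2; terminal-plateau estimation with a settledness test.

**Synthetic data** (`mesoglass.synthetic`). Seeded generators for every
input class, each returning the generating truth alongside the data.

## Worked example

```bash
python examples/loading_geometry.py
```

prints, for the two shipped Sylysia grades mixed with celecoxib:

```
SYL350  (SA 300.0 m²/g, Vp 1.6 mL/g)
  footprint            0.586 nm²/molecule
  monolayer capacity   5.12e+20 molecules/g
  f(monolayer)         75.5 % silica
  f(pore filling)      30.7 % silica

SYL730  (SA 700.0 m²/g, Vp 0.44 mL/g)
  footprint            0.586 nm²/molecule
  monolayer capacity   1.19e+21 molecules/g
  f(monolayer)         57.0 % silica
  f(pore filling)      61.7 % silica
```

Reading: a celecoxib molecule occupies ≈0.59 nm² of wall; a 25% silica
mixture is *overloaded* for both grades — there is neither enough wall
area for a monolayer nor enough pore volume to confine the whole drug
load. The other examples (`dsc_fractions.py`, `dielectric_relaxation.py`,
`crr_size.py`, `crystallization_kinetics.py`) walk the remaining stages
the same way.

A thin CLI mirrors the library for shell use on instrument CSV exports:

```bash
mesoglass loading --silica SYL350
mesoglass simulate avrami --seed 3 --out-dir out
mesoglass avrami out/trace.csv --out-dir out
mesoglass run --config pipeline.yaml --out-dir out   # all stages + manifest
```

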