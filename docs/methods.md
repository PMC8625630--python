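# Methods

## Model

The resting-state gate of a voltage-gated sodium channel — a hydrophobic
constriction of the four S6 helices at the intracellular end — is treated
as a one-dimensional energy barrier of height `g` (the work required to
open the gate, estimated as gating charge × (half-activation voltage −
resting potential)) spread linearly over the gate length `w`:
`U(x) = g·x/w` on `x ∈ [0, w]`.  For an ion with kinetic energy `KE < g`
the classically forbidden region is `[x1, w]` with `x1 = w·KE/g`, and the
WKB transmission through it integrates in closed form:

```
∫ √(U(x) − KE) dx over [x1, w]  =  (2w/3g)·(g − KE)^(3/2)
T_Q = exp(−√(8m)/ħ · (2w/3g) · (g − KE)^(3/2))
```

The package keeps both routes: the closed form (`tunneling_exponent`) and
an adaptive-quadrature evaluation of the integral
(`exponent_integral_oracle`) that exists purely as an independent check;
the tests require agreement to 10⁻⁶ relative over the whole parameter
box.

Kinetic energies follow the resting-state geometry.  An extracellular ion
falls through the whole membrane voltage before reaching the gate
(`KE = q·Vm + (3/2)k_B·T`; the voltage drop across the short gate itself
is neglected and no partial-voltage option is offered); an intracellular
ion arrives with thermal energy only.  `Vm` is everywhere the *magnitude*
of the inside-negative resting potential — signed values are rejected
rather than silently absolute-valued.

Transmission converts to conductance through the conductance quantum:
`C_Q = (q²/h)·T_Q` per channel, `MC_Q = D·C_Q` (reported in mS/cm²) for a
membrane with areal channel density `D`.

## Parameters and defaults

| parameter | meaning | default / range | rationale |
|---|---|---|---|
| `g` (`G`) | gate barrier energy | 5×10⁻²⁰ J; swept 3–7×10⁻²⁰ | span of gating-charge × half-activation estimates across channel subtypes (cardiac ≈3.3, neuronal ≈6.5×10⁻²⁰ J) |
| `w` (`L`) | gate length | 1×10⁻¹⁰ m; swept 0–2×10⁻¹⁰ | one amino-acid constriction (1.5 Å), reduced by helix tilt, extremes included |
| `Vm` | resting-potential magnitude | 0.087 V | classical GHK solution of the reference bath below |
| `D` | channel density | 10¹¹ /cm²; swept 10⁹–10¹¹ | upper literature bound for sodium-channel density |
| ion masses | Li-7 1.15×10⁻²⁶, Li-6 9.83×10⁻²⁷, K 6.5×10⁻²⁶ kg | registry | isotopes differ by one neutron mass |
| bath | K 4/140, Na 142/14 mmol/L (out/in); MC_K 0.5, MC_Na 0.005 mS/cm² | reference values | textbook mammalian resting state |
| `li_ratio` (R) | [Li]in/[Li]out | 2 (quantum), 1–4 (classical sweeps) | quantum potentials are insensitive over 1–4 because intracellular tunneling is negligible |

Parameters outside these boxes *warn* (`PlausibilityWarning`) but never
error: the model evaluates fine there, it is simply unexercised.

## Constants profiles

All derived coefficients come from `ionqt.constants` in one of two
profiles.  The `paper` profile (default) uses the rounded constants the
published tables were computed with, and additionally pins the printed
intermediates: exponent coefficients 19.2 (Li-7) and 17.8 (Li-6), thermal
energy 0.64×10⁻²⁰ J, GHK slope 37.45 V⁻¹, conductance quantum
3.88×10⁻⁵ S.  This is deliberate: the tables round intermediates, and
re-deriving them in full precision moves 2-significant-figure cells by up
to ~7% (e.g. the L=2 extracellular probability).  The `codata` profile
computes everything from CODATA-2018 values for sensitivity checks; the
two profiles agree to <0.5% on every coefficient.  Consequently, under
the `paper` profile the thermal-energy term is the printed constant
rather than literally (3/2)k_B·T — exact linearity in T holds only in
`codata` mode.

The tunneling exponent is evaluated in the scaled presentation units
(`G = g/10⁻²⁰`, `L = w/10⁻¹⁰`), with the powers of ten absorbed into the
coefficient.  This is algebraically identical to the SI form (the scale
factors are exact binary-representable powers of ten combinations) and
keeps the printed coefficients usable directly.

## GHK solvers

Classical branch: the lithium term is a fixed leak conductance
(`MC_Li ≈ MC_Na`; optionally scaled by the isotope acceleration factor
1.17 or the diffusion factor 1.006 via `li6_scaled_leak`), the balance has
a single exponential and is solved in closed form; an inner sum not
exceeding the outer one returns `Vm = 0` flagged `non-polarized`.  A test
cross-checks the closed form against an independent scalar root-finder to
10⁻⁹ V.

Quantum branch: the extracellular lithium conductance depends on `Vm`
through the kinetic energy, so the residual `LHS(Vm) − RHS(Vm)` is
transcendental.  Over the default bracket [0, 0.2] V the left side is
non-decreasing and the right side strictly decreasing, so the root is
unique; the solver verifies exactly one sign change on a 1 mV grid before
running Brent's method, and raises a diagnostic (naming the bracket
residuals) rather than extrapolating when the bracket misses the root.
The root is refined to 10⁻¹⁰ V so the residual guarantee
(|residual| < 10⁻⁶ of the left-side magnitude) holds with margin; the
documented `SolverSettings.tolerance` (10⁻⁷ V) is the reporting
tolerance.  Sodium and potassium stay classical leak terms in both
branches.

Depolarization degree is `DD = Vm(baseline) − Vm(with lithium)`.  The
reproduction harness computes table `DD` cells the way the printed tables
do — both potentials rounded to 3 decimals (the printed precision) before
subtracting — so borderline rounding matches the published arithmetic.

## Isotope analytics

The Li-6/Li-7 transmission ratio is
`exp(Δc·(L/G)·(G − KE)^(3/2))` with `Δc` *computed* as the difference of
the two exponent coefficients under the active profile (1.4 in `paper`
mode), never hard-coded; an identity test pins the closed form to the
quotient of the two tunneling probabilities at machine precision.  Rates
of change are plain secant slopes between the modelled interval endpoints
(G: 3→7, L: 0→2, Vm: 0→87 mV, the last with a millivolt denominator);
they are definitions, not derivative approximations, so no derivative
mode exists.

## Table-reproduction harness

`_fixtures/tables.yaml` carries every printed cell of the 36 source
tables with per-cell tolerances: relative 5% for probabilities and
conductances (2 s.f. printing with rounded intermediates; empirical drift
≤4%), absolute 0.001 V for potentials and depolarization degrees,
relative 1% for isotope ratios.  One isotope-rate cell is printed to a
single significant figure (−0.1 mV⁻¹; exact −0.099) and carries the
half-ulp absolute tolerance 0.005 of its printed precision instead.
Cells the source prints inconsistently are `flag`ged with a reason and
reported but never pass/fail:

- the extracellular Li-7 probability at Vm = 0.087 V in the
  voltage-sweep table prints 2.97×10⁻⁸ where the governing equation (and
  the companion conductance tables) give 2.97×10⁻⁹;
- the quoted potassium single-channel conductance 2.13×10⁻²⁵ S is ~18%
  above the value implied by the stated mass (1.77×10⁻²⁵ S).

The membrane-conductance tables that share a setting but print slightly
different values (11.5 vs 11.3, 48.2 vs 47.4 mS/cm²) both sit inside the
5% band and carry an explanatory note.  `reproduce_all()` recomputes all
170 assertable cells plus the two flagged ones; the suite requires zero
non-flagged failures and exactly those two flags.

## Numerical choices and degenerate inputs

- `KE ≥ g` and `w = 0` clamp the exponent to 0 (probability 1): the
  forbidden region is empty and transport is unimpeded.  The naive
  formula would go complex there.
- The quadrature oracle drives `scipy.integrate.quad` on relative error
  only (`epsabs=0`): the SI integral is ~10⁻²⁰ and the default absolute
  tolerance would accept it unexamined.
- Hand-style rounding (`round_half_up`, ties away from zero) is used when
  reproducing printed 3-decimal potentials, to mirror how the tables were
  produced.
- Nothing in the package draws random numbers; sweeps and solvers are
  bit-reproducible, and the acceptance script's `--seed` exists for
  interface uniformity only.

## Limitations

- No time dependence: the model gives steady-state potentials and
  conductances only — no kinetics of lithium accumulation, action
  potentials, or pump/exchanger fluxes.
- The linear-ramp barrier is the only gate shape; no general WKB for
  arbitrary profiles.
- Only monovalent cations; the charge enters as a fixed +1e.
- The quantum GHK inherits the convention that concentrations (mmol/L)
  multiply conductances (mS/cm²) with only ratios mattering; no
  dimensional re-derivation is attempted.
- No fitting of `g`, `w` or `D` to electrophysiological recordings; the
  package evaluates the forward model.
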