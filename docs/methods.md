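# Methods

## Physical model

Migration of an oligomer from a PET article into food is modelled as
one-dimensional Fickian diffusion in a slab of thickness L with a uniform
initial concentration C_P,0 (mg/kg polymer), a sealed back face, and a
single face in contact with a finite, well-mixed food phase.  At the
contact face local partition equilibrium holds at all times,
c_P(0, t) = K · c_F(t), with K = K_P/F the ratio of volumetric
concentrations polymer/food.  There is no boundary-layer resistance on the
food side, no swelling, no concentration dependence of D, and each
scenario is isothermal.  These are the standard assumptions of
compliance-oriented migration modeling; they are conservative for rigid
PET below its glass transition.

Two dimensionless groups determine the transferred fraction of the total
migrant mass m_tot = C_P,0 · ρ_P · V_P:

* α = V_F / (K · V_P), the capacity ratio; equilibrium transfer is
  α/(1+α);
* τ = D t / L².

The partition convention deserves emphasis: K relates *volumetric*
concentrations (mg/cm³ per mg/cm³), so α carries no density factor.  With
the mass-fraction convention (mg/kg per mg/kg) every α would be scaled by
ρ_F/ρ_P and the storage-condition sensitivity cells come out near 34 %
instead of the published 26 %; the volumetric convention reproduces the
published values exactly and is the one used throughout.

## Solvers

**Eigenfunction series (primary).**  The classic limited-volume solution
expands over the positive roots q_n of tan q = −α q, with weights
2α(1+α)/(1+α+α²q_n²) that sum to one.  Roots are bracketed in
((2n−1)π/2, nπ) — where they provably lie for α > 0 — and polished with
Brent's method on the pole-free function sin q + α q cos q to ~1e−12
absolute; α = 0 degenerates to q_n = nπ exactly.  The series is truncated
adaptively when the next term falls below 1e−12 of the partial sum (hard
cap 1e5 terms); τ ≥ 50 returns the equilibrium fraction directly.

**Short-time closed form.**  For τ ≤ 0.01 the back face is invisible and
the semi-infinite/limited-bath form
m(t)/m_eq = (1+α)[1 − exp(x²) erfc(x)], x = √τ/α, applies (evaluated via
the scaled complement erfcx for stability).  Below τ = 1e−6 the series
would need ≳ 10⁴–10⁶ terms, so `migrate_series` substitutes this form
automatically (reported as `method="erfc"`); a warning is emitted below
τ = 1e−8 where the result is numerically indistinguishable from zero.  In
this regime the migrated *mass* at fixed contact area and food volume is
thickness-independent, which is why the partition-sensitivity table is
identical for 10 µm and 2 mm films at the storage conditions.

**Finite-volume Crank–Nicolson (oracle).**  An independent check uses a
cell-centred conservative discretisation with a geometrically stretched
mesh (first cell ≈ diffusion length/12) and quadratically graded time
steps resolving the √t ingress.  The bath is coupled through the same
half-cell surface flux that enters the first cell's balance, so total
mass is conserved to roundoff by construction; the solver raises if the
tracked balance ever exceeds 1e−8 relative.  Series and finite-volume
results agree within 0.2 % relative over τ ∈ [1e−4, 10] and
α ∈ [0.01, 1667] at the default resolution (400 cells, 1200 steps).

## Diffusion models

**A_P model.**  D_P = 1e4 · exp(A'_P − τ_c/T − 0.1351 M_W^(2/3) +
0.003 M_W − 10454/T) cm²/s with A'_P = 3.1 (realistic) or 6.4 (upper
limit, exactly e^3.3 ≈ 27× higher at any size and temperature) and
τ_c = 1577 K.  Its effective activation energy is R(10454 + 1577) ≈
100 kJ/mol for every migrant — the model's known weakness at heating
temperatures.  Computed values match the published prediction table for
the cyclic trimer to within one unit in the second printed digit; three
of the six cells differ from exact two-significant-figure rounding by
≤ 1.8 % (e.g. 4.53e−11 vs printed 4.6e−11 at 149 °C), a residual we
attribute to internal constants of the commercial tool that produced the
printed table.  We keep the standard closed form rather than tune
constants to the printed cells.

**Activation-energy (E_A) model.**  Each migrant is an Arrhenius pair
(E_A, ln D_0).  The validated PET parameter set (a = 1.93e−3 1/K,
b = 2.37 cm²/s, c = 11.1 Å³, d = 1.50e−5 1/K) parameterises a published
molecular-volume correlation that this package deliberately does not
reconstruct: no dimensionally sound combination of the four constants
reproduces the known anchor (E_A ≈ 210.4 kJ/mol, ln D_0 ≈ 35.95 at
M_V = 484.64 Å³), so guessing the functional form would silently produce
wrong chemistry.  `dp_welle` therefore requires either a per-substance
override or an explicit correlation callable and raises
`CalibrationRequiredError` otherwise.  One genuine calibration ships: the
first-series cyclic trimer, fitted at import time through the published
176 °C and 115 °C predictions; the 149 °C prediction then falls on the
same Arrhenius line, confirming internal consistency.

For pipeline exercises the synthetic-data module provides
`synthetic_welle_correlation`, a clearly labelled stand-in: E_A linear in
M_V through the real trimer anchor (chosen to give ≈ 110 kJ/mol at the
smallest packaged oligomer, the order reported for small migrants in
PET, floored at 40 kJ/mol) and a compensation line for ln D_0 through the
same anchor.  It exists so the dual-model screen runs end to end; its
outputs characterise the pipeline, not real substances.

## Scenarios, thresholds, screening policy

The twelve default scenarios combine three bottles (500/1000/1500 mL,
contact areas 420/660/880 cm²) with storage conditions (25 °C/365 d,
40 °C/60 d) and two trays (rectangular 566 cm²/500 mL, round
329 cm²/637 mL) with heating conditions (70 °C/30 min, 100 °C/10 min,
100 °C/2 h); all walls are 300 µm, ρ_P = 1.4 g/cm³, ρ_F = 1.0 g/cm³.
TTC food limits follow from exposure limits × 60 kg body weight ÷ 1 kg
daily intake; the Cramer class is assigned structurally (linear → I,
cyclic → III) and the mutagen limit is screened for every substance.

The partition-sensitivity statistic runs the reference setup (1000 mg/kg,
10 µm, 600 cm² against 1000 cm³ food) at a condition's (T, t) for K = 1
and K = 1000 and reports 100·(M₁ − M₁₀₀₀)/M₁ rounded half-up to integer
percent.  The dual-K screening policy adds a K = 1000 run per
(oligomer, condition, model) whenever this deviation exceeds 10 %.  Note
the isothermal model bounds the deviation by
1 − (α₁₀₀₀/(1+α₁₀₀₀))/(α₁/(1+α₁)) ≈ 37.5 % for the reference α values;
published heating-condition figures up to 40 % exceed this bound and
cannot arise from the model implemented here, so the heating columns are
reported but not treated as reference values.

Reverse modeling exploits exact linearity in C_P,0: the maximum
permissible concentration is threshold ÷ conc_food(C_P,0 = 1), computed
at K = 1 (worst case).  Results are classified `plausible` (≤ 1 % w/w,
10⁴ mg/kg — the highest content considered realistic and the validity
limit of dilute-diffusion physics), `unlikely` (≤ 100 % w/w) or
`impossible` (> 10⁶ mg/kg, more than pure oligomer); unreachable
thresholds (no migration at all) return +∞ and classify `impossible`.

## Synthetic data

Real per-oligomer C_P,0 compilations live in scattered appendices and are
not shipped.  The generator reproduces their *structure*: exactly 29 of
the 52 oligomers receive a (min, max) range; minima are log-uniform over
10^−1–10^3.7 mg/kg (concentrations span orders of magnitude in the
literature); maxima extend each minimum by a uniform factor up to 100
(reported ranges per substance rarely exceed two decades); everything is
capped at 1 % w/w so synthetic inputs always classify `plausible`; and the
first-series cyclic trimer — consistently the most abundant oligomer in
PET — always receives data, drawn from the top decade.  Everything is
deterministic under a seed.  Passing tests on synthetic inputs
demonstrates pipeline correctness and determinism, not agreement with any
real material's oligomer content; the desk-reproducible physics
(diffusion cells, sensitivity percentages, threshold conversions) is what
ties the package to published numbers.

## Numerical choices and limitations

* Units: cm / s / K / mg internally; µm, days, °C, mL conversions happen
  once at the CLI boundary.  Rounding only at presentation (2 s.f. for
  D_P, integer % for sensitivities, 2 d.p. for M_W).
* Monomer masses fixed at TPA 166.131, EG 62.068, DEG 106.121, water
  18.015 g/mol; these reproduce all 52 tabulated molecular weights within
  0.013 g/mol.
* Predicted D_P below 1e−30 cm²/s warns rather than truncating to zero;
  exponents are clamped at ±700 to avoid overflow.
* Problem sizes: the oracle sweep uses 6 τ-decades × 3 α values at
  400 cells/1200 steps (~10 s); the full synthetic screen (29 oligomers ×
  12 scenarios × 2 models, dual-K) runs in a few seconds.
* Not modelled: temperature ramps within a scenario, swelling or
  concentration-dependent diffusivity, boundary-layer resistance,
  evaporation, molecular-volume prediction from structure (values are
  shipped data), and partition-coefficient prediction (screened via the
  K = 1 / K = 1000 bracket instead).
* The `hypothetical` flag in the packaged table is an editorial
  annotation (19 of 52 rows); it does not enter any computation.
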