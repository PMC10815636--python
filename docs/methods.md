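# Methods

## Scope and data model

The package operates on six plain-CSV table schemas (swelling, gpc,
solgel, calibration, release, plate) with fixed units — masses mg,
volumes mL, swelling/release time hours, degradation time days,
temperature °C, molar mass g·mol⁻¹, concentration µg/mL, lengths Å — and
never converts units implicitly. Missing values are rejected; an aliquot
that was not taken is an omitted row. All schemas round-trip bit-exactly
through `write_table`/`load_table` (floats are serialised at `repr`
precision).

## Swelling and equilibrium detection

Swelling degree is Q = (m_t − m₀)/m₀ per weighing. Equilibrium detection
uses a plateau criterion: the equilibrium point is the first observation
whose arriving relative change |ΔQ|/Q and all later changes stay below
`plateau_rel_tol` (default 0.01); the first point of a fully settled
series qualifies, and a curve that never settles falls back to its final
point. The anchoring-on-arrival choice matters: anchoring on the point
*before* the settled region systematically reports Q one step short of
the plateau (≈1.1% low for a first-order curve with k = 1.5 h⁻¹ sampled
hourly), while the arrival rule bounds the deficit by
tol·e^(−k)/(1 − e^(−k)) ≈ 0.3% at the default kinetics. No smoothing is
applied before detection, so the estimator inherits the raw blotting
noise — by design, to keep it transparent.

`temperature_profile` tabulates equilibrium Q against temperature per
crosslinker and flags whether Q_eq is non-increasing in temperature
(non-strict, so replicate ties do not break the flag).

## Sol–gel accounting

Two conventions are exposed. `mass_retained` (default) defines
gel% = 100·(W₁/W₀): the crosslinked mass surviving exhaustive washing.
The literal complement convention `as_printed`, gel% = 100·(W₀ − W₁)/W₀,
is retained because some write-ups label that expression "gel fraction"
even though it evaluates the washed-out (sol) share; for the gels this
package targets the reported gel contents (82/77/66%) are only consistent
with `mass_retained`. Numerically the ratio is formed before scaling and
the pair is returned as exact float complements, so gel% + sol% == 100
exactly and the two conventions swap gel and sol bit-for-bit.

## Network structure

The swelling → structure chain is ν₂,ₛ = ρₛ/(Q ρ_p + ρₛ), then the
modified Flory–Rehner relation for M̄c (crosslinked-in-the-dry-state
form, functionality φ kept literal so the elastic denominator is
ν₂,ₛ^⅓ − (2/φ)ν₂,ₛ), then N = 2M̄c/M_r, r₀ = l√(C_n N), ξ = ν₂,ₛ^(−⅓) r₀.
The mixing term uses `log1p` to avoid cancellation at small ν₂,ₛ; the
float64 evaluation agrees with a 50-digit-precision reference to better
than 10 significant digits across the physical parameter box. A
non-positive 1/M̄c is reported as "parameters outside validity" rather
than returning a negative molar mass. `nu1 = 0` is accepted as a
degenerate test hook that reduces the relation to the phantom limit
1/M̄c = 2/M̄n.

Default constants (PSA-*g*-mPEG in water): M̄n 17 500 g·mol⁻¹, χ₁ 0.426
(PEG value — PEG dominates the swelling thermodynamics of the graft
copolymer), V₁ 18.1 mL·mol⁻¹, φ 2 (bifunctional disuccinyl-PEG
crosslinker), C_n 6.1 (Nylon-6,6 proxy for the polyester backbone),
l 1.51 Å, M_r 640 g·mol⁻¹. The dry-polymer and solvent densities were not
available, so ρ_p = 1.2 g·cm⁻³, ρ_s = 1.0 g·cm⁻³ and ν₁ = 1/ρ_p are
assumed defaults; they are the largest single source of systematic
uncertainty in ξ (the CLI provenance log labels density-dependent outputs
accordingly) and every constant is overridable from a YAML/JSON params
file. Mesh sizes are reported at full precision; display rounding
(including the 3-significant-figure convention used in the drivers) is
the caller's choice. `stretched_peg_length` likewise never rounds:
1.5 Å per ethylene-oxide unit, with M/44.05 units for a PEG of molar
mass M.

## Degradation

Retention is 100·Mn(day)/Mn(0), reported unrounded. The optional rate fit
assumes first-order decay, ln Mn(t) = ln Mn(0) − k·t, estimated by
ordinary least squares; this random-scission proxy is a modelling choice
(the underlying chemistry is ester hydrolysis, for which no kinetic law
is established here), and r² is reported so a poor fit is visible.

## Calibration, loading, release, viability

Calibration is an OLS line intensity = slope·conc + intercept (≥3 points,
≥2 distinct concentrations). Back-calculated concentrations below zero —
intensities within blank noise — clamp to zero with a counted warning.
Cumulative release applies the standard dissolution-testing correction
for sampled-and-replaced aliquots, C_corr(t_k) = C_raw(t_k) +
(v/V)·ΣC_raw(t_i<k); the correction restores the mass balance exactly
(corrected concentration × V equals total released mass including the
mass carried away in aliquots), which the noiseless end-to-end test
verifies to 0.1%. release% above 100 is flagged, not errored, because
calibration extrapolation can overshoot. Loading is by depletion of the
soak solution: mass = (c₀ − c_end)·V_load. Viability is
100·(F − F_blank)/(F_negative − F_blank); values above 100 are reported
as-is (metabolic stimulation).

## Synthetic data: what it emulates and what it does not

The generators encode the study conditions every estimator is scored
against: first-order swelling to Q_inf = 3.84/6.73/11.81 (k_swell
1.5 h⁻¹, chosen so the <1%-change plateau is reached by ~4 h; m₀ 10 mg;
hourly sampling over 24 h; 1% multiplicative blotting noise);
exponential Mn decay from 11 000 (PSA) and 16 000 (PSA-*g*-mPEG) g·mol⁻¹
at k = 0.01005 and 0.00362 day⁻¹ — rates fixed by the measured day-84
retentions of 43.0% and 73.8% — sampled at days 0/28/84 with 2% GPC
noise; a calibration line of slope 2000 a.u./(µg/mL), intercept 50 a.u.,
1%-of-signal noise on an 8-point grid; and biexponential release
F(t) = f_b(1 − e^(−k_b t)) + (1 − f_b)(1 − e^(−k_s t)) with f_b = 0.40,
k_b = 1.0 h⁻¹, k_s = 0.012 h⁻¹ (≈42% released at 4 h), a 10 µg dose in
10 mL with 0.5 mL aliquots. The release medium is simulated forward
through the sampling protocol, so each aliquot physically removes mass —
the generated intensities contain exactly the artefact the correction
removes. All draws derive from `SeedSequence(seed, stream)` with one
stream per assay, so datasets are reproducible and mutually independent.

The first-order swelling law and the biexponential release law are
simulation assumptions, not claims about the gels: real swelling may show
relaxation-limited (non-Fickian) kinetics, real release couples to
swelling, degradation and solute–network interactions, and real GPC/
plate-reader noise is not purely multiplicative i.i.d. Passing the
recovery suite therefore demonstrates that the estimators are correct and
unbiased under the stated statistical model — not that the model captures
every feature of the laboratory system.

## Problem sizes and statistical checks

Recovery tests run 20 simulation seeds at default noise and assert that
the mean recovered parameter across seeds is within the stated band
(equilibrium swelling 3%, hydrolysis rate 10%, calibration slope 2%,
end-to-end release fraction 5%). The mean-across-seeds formulation is
deliberate: for the slowly degrading polymer (k = 0.00362 day⁻¹) a
three-point GPC fit at 2% noise has a per-fit standard error near 9% of
k, so a per-seed 10% bound would fail by construction about a quarter of
the time regardless of implementation correctness; the fast-decaying
series, which carries enough signal, is additionally held to 10% on every
individual seed. Property-based tests (hypothesis, derandomised) cover
scale invariance of Q and retention, exact gel/sol complementarity, and
monotonicity of ν₂,ₛ (decreasing) and ξ (increasing) in Q over
Q ∈ [0.5, 20].

## Known limitations

- Densities default to assumed values; ξ shifts by roughly its reported
  5% agreement band for ±0.1 g·cm⁻³ changes in ρ_p.
- No mechanistic release or swelling-kinetics model fitting
  (Korsmeyer–Peppas, Higuchi, relaxation exponents) — out of scope.
- Replicate aggregation is left to the caller: each gravimetric series
  yields one Q_eq; no error bars are synthesised.
- Instrument exports (GPC chromatograms, plate-reader files) are not
  parsed; inputs are pre-tabulated CSVs.
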