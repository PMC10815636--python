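# gelphys

Analysis toolkit for PEG-crosslinked polyester hydrogels: gravimetric
swelling, sol–gel accounting, network structural parameters from
equilibrium-swelling theory, hydrolytic degradation tracking by GPC, and
fluorescence-based solute loading/release quantification. It is written
for experimentalists characterising poly(sorbitol adipate)-*graft*-mPEG
(PSA-*g*-mPEG) hydrogels — or any chemically crosslinked gel analysed the
same way — who want the desk calculations behind their wet-lab numbers to
be reproducible, unit-explicit and tested.

## The model at the core

A gel of dry mass m₀ weighed wet at time t has swelling degree
Q = (m_t − m₀)/m₀. From the equilibrium value Q the package estimates the
network's structural parameters:

- polymer volume fraction in the swollen state
  ν₂,ₛ = ρₛ / (Q ρ_p + ρₛ);
- number-average molar mass between crosslinks M̄c by the modified
  Flory–Rehner relation

  1/M̄c = 2/M̄n − (ν₁/V₁) · [ln(1 − ν₂,ₛ) + ν₂,ₛ + χ₁ ν₂,ₛ²] / [ν₂,ₛ^⅓ − (2/φ) ν₂,ₛ];

- mesh size (correlation length) following Canal–Peppas:
  N = 2 M̄c/M_r, (r̄₀²)^½ = l (C_n N)^½, ξ = ν₂,ₛ^(−⅓) (r̄₀²)^½.

Around this sit gel/sol fraction accounting (gel% = 100·W₁/W₀ by default;
the literal complement convention is also exposed), molar-mass retention
and a first-order hydrolysis-rate fit for GPC time series, ordinary
least-squares fluorescence calibration, loading-by-depletion, cumulative
release with the standard aliquot-replacement correction

  C_corr(t_k) = C_raw(t_k) + (v/V) Σ_{i<k} C_raw(t_i),

and resazurin viability normalisation. A synthetic-data module generates
every input with known ground truth (first-order swelling kinetics,
exponential molar-mass decay, linear calibration, biexponential
burst+sustained release simulated through the physical sampling protocol),
so every estimator in the chain can be scored end to end.

## Worked example

```pycon
>>> from gelphys import NetworkParams, characterize_network
>>> r = characterize_network(3.84, NetworkParams())
>>> round(r.v2s, 4), round(r.mc), round(r.xi, 1)
(0.1783, 1521, 14.4)
```

A gel whose equilibrium swelling degree is 3.84 (a PEG-400-crosslinked
PSA-*g*-mPEG formulation at 22 °C) is 17.8 vol-% polymer when swollen; the
network strand between crosslinks averages ≈1520 g·mol⁻¹, giving a mesh
size of ≈14.4 Å — about the 13.5 Å stretched length of the PEG-400 spacer
itself, as expected when the crosslinker dominates the mesh. The default
constants (M̄n = 17 500 g·mol⁻¹, χ₁ = 0.426, V₁ = 18.1 mL·mol⁻¹, φ = 2,
C_n = 6.1, l = 1.51 Å, M_r = 640 g·mol⁻¹) describe PSA-*g*-mPEG in water;
the densities ρ_p = 1.2, ρ_s = 1.0 g·cm⁻³ are documented assumptions and
every value is overridable via `NetworkParams` or a YAML params file.

The same computation from the shell:

```sh
$ gelphys structure --q 3.84
Q = 3.84: v2s = 0.178, Mc = 1.52e+03 g/mol, N = 4.75, r0 = 8.13 A, xi = 14.4 A
```

The numbered scripts under `analysis/` run the full study pipeline
(simulate → swelling → sol-gel → structure → degradation → release →
viability) and write their tables under `results/`; e.g.
`python analysis/04_network_structure.py` prints

```
PEG-400: Q = 3.84, v2s = 0.1783, Mc = 1521 g/mol, xi = 14.4 A (stretched spacer 13.5 A)
PEG-1000: Q = 6.73, v2s = 0.1102, Mc = 3485 g/mol, xi = 25.7 A (stretched spacer 34.5 A)
PEG-2000: Q = 11.81, v2s = 0.0659, Mc = 5822 g/mol, xi = 39.4 A (stretched spacer 67.5 A)
```

— mesh size grows with crosslinker chain length, and `gelphys all --seed 7
--out run/` exercises every stage on simulated data with a full parameter
provenance log.

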