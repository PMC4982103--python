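# chelapower

Quantifying the catalytic power of **magnesium chelatase**, the
three-subunit AAA⁺ enzyme (ChlI/ChlD/ChlH) that couples ATP hydrolysis to
insertion of Mg²⁺ into a porphyrin — the first committed step of
chlorophyll biosynthesis. The package is aimed at enzymologists and
modellers who want to reproduce, probe, or extend the kinetic and
thermodynamic analysis of ATP-driven metalation assays.

Chelation of Mg²⁺ by deuteroporphyrin IX (D_IX) is intrinsically
unfavorable, with association constant K_eq = [MgD]/([Mg²⁺][D]) ≈ 10⁻⁶ M⁻¹,
and the metalloporphyrin spontaneously dechelates with first-order rate
constant k_dechel. The package implements four linked analyses:

1. **Dechelation kinetics** — through-origin regression of initial rates
   vs. [MgD_IX] gives k_dechel; microscopic reversibility then gives the
   *second-order uncatalyzed* chelation constant
   k_uncat = K_eq · k_dechel, and the pseudo-first-order half-life
   ln 2/(k_uncat·[Mg²⁺]) at a reference Mg²⁺ concentration.
2. **Progress-curve ODE model** — a separable saturation rate law
   v = k_cat·E₀·(D/(K_m+D))·(Mg^h/(K₀.₅^h+Mg^h))·(ATP/(K₀.₅,ATP+ATP))
   balanced against uncatalyzed loss k_dechel·[MgD], with ATP depletion,
   an uncoupled basal ATPase, and a PEP/pyruvate-kinase regeneration
   system modelled as an ATP clamp debiting a finite PEP pool. This
   reproduces the characteristic rise → steady state (d[P]/dt ≈ 0) →
   fall of chelatase assays, and solves the algebraic steady state by
   bracketed root finding.
3. **Catalytic power** — rate enhancement k_cat/k_uncat (M), catalytic
   proficiency (k_cat/(K_m^DIX·K₀.₅^Mg))/k_uncat (M⁻¹), transition-state
   dissociation constant K_TX = proficiency⁻¹ (M), standard free energy
   −RT ln K_eq, and the displacement of the driven steady state from
   equilibrium, RT ln(ratio/K_eq).
4. **Probabilistic ATP coupling** — the observed ATP:metalloporphyrin
   stoichiometry n_ATP is read as a per-cycle success probability
   p = 1/n_ATP; ATP spent per product is geometric, simulated and
   checked against closed-form moments.

A seeded synthetic-data module emulates the plate-reader assays
(fluorescence of MgD_IX, λex 420 nm / λem 580 nm) so every stage is
testable without instrument data.

## Worked example

```sh
python examples/catalytic_power_report.py
```

prints (default Synechocystis constants: k_cat = 1/75 s⁻¹,
k_dechel = 3.17×10⁻⁵ s⁻¹, K_eq = 10⁻⁶ M⁻¹, K_m·K₀.₅ = 1.4×10⁻⁸ M²):

```
chelatase:
  k_uncat          = 3e-11 1/(M s)
  rate enhancement = 4e+08 M
  proficiency      = 3e+16 1/M
  K_TX             = 3e-17 M (attomolar)
  t1/2 (1 mM Mg2+) = 7e+05 years
  dG standard      = +35.3 kJ/mol (unfavorable)
  displacement     = 1.3e+09 x equilibrium (53.5 kJ/mol)
```

Read: without the enzyme, inserting Mg²⁺ at 1 mM free Mg²⁺ would take
~0.7 million years per half-reaction; the chelatase accelerates the
bimolecular reaction by a factor of ~4×10⁸ M, binds its transition state
with attomolar affinity, and — paying ~15 ATP per metalloporphyrin —
holds the product:substrate ratio about nine orders of magnitude above
the chelation equilibrium. The other examples
(`dechelation_fit.py`, `progress_curves.py`, `stochastic_coupling.py`)
walk through the fitting, simulation, and coupling stages individually.

The same operations are available from a thin CLI, e.g.

```sh
chelapower synth --preset fig4 --seed 42 --out-dir data/
chelapower fit-dechel data/initial_rates.csv
chelapower steady-state --preset fig3b-low
chelapower run --out-dir results/ --seed 42
```

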