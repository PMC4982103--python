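"""The full catalytic-power report, with and without Gun4.

Assembles rate enhancement, catalytic proficiency, transition-state
affinity, the uncatalyzed half-life, and the thermodynamic displacement
of the low-porphyrin steady state from the default kinetic constants.
"""

from chelapower import (
    DEFAULT_PARAMS,
    GUN4_PARAMS,
    AssayConditions,
    ThermoContext,
    power_report,
)

thermo = ThermoContext(K_eq=1e-6, T=307.15)
cond = AssayConditions(D_total=2.5e-6, ATP_0=5e-3)  # low-porphyrin assay

for label, params in [("chelatase", DEFAULT_PARAMS), ("+ Gun4", GUN4_PARAMS)]:
    report = power_report(params, thermo, mg_ref=1e-3, conditions=cond)
    r = report.rendered()  # "circa" style: 1 significant figure
    print(f"{label}:")
    print(f"  k_uncat          = {r['k_uncat_per_M_s']:.0e} 1/(M s)")
    print(f"  rate enhancement = {r['rate_enhancement_M']:.0e} M")
    print(f"  proficiency      = {r['proficiency_per_M']:.0e} 1/M")
    print(f"  K_TX             = {r['K_TX_M']:.0e} M (attomolar)")
    print(f"  t1/2 (1 mM Mg2+) = {r['halflife_years']:.0e} years")
    print(f"  dG standard      = +{report.dG_standard:.1f} kJ/mol (unfavorable)")
    print(f"  displacement     = {report.displacement:.1e} x equilibrium "
          f"({report.dG_displacement:.1f} kJ/mol)")
print("-> the enzyme both accelerates an impossibly slow reaction and,")
print("   paying with ATP, holds its product far above equilibrium.")
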