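"""Simulate chelatase progress curves: rise, steady state, and fall.

Runs two scenarios of the standard assay (8 uM deuteroporphyrin IX,
10 mM Mg2+): with an ATP-regeneration system (1 mM ATP + 2 mM PEP) the
product plateau is held for hours; without it the 0.5 mM ATP pool
depletes and MgD_IX decays back toward equilibrium at the uncatalyzed
dechelation rate.
"""

import numpy as np

from chelapower import (
    find_steady_state,
    get_preset,
    simulate_progress,
    steady_state_maintenance_time,
)

for name in ("fig2b", "fig2a-noregen"):
    preset = get_preset(name)
    curve = simulate_progress(preset.params, preset.conditions,
                              preset.t_end, preset.n_out)
    imax = int(curve.MgD.argmax())
    print(f"{name}: MgD peaks at {curve.MgD[imax] * 1e6:.2f} uM "
          f"({curve.times[imax] / 3600:.1f} h), "
          f"ends at {curve.MgD[-1] * 1e6:.2f} uM after "
          f"{curve.times[-1] / 3600:.0f} h")
    if preset.conditions.regeneration_on:
        ss = find_steady_state(preset.params, preset.conditions)
        held = steady_state_maintenance_time(curve, 0.10, plateau=ss.MgD_ss)
        print(f"  algebraic steady state {ss.MgD_ss * 1e6:.2f} uM; held within "
              f"10% for {held.duration_s / 3600:.1f} h")
    else:
        tail = curve.times > curve.times[-1] - 7200
        slope = np.polyfit(curve.times[tail], np.log(curve.MgD[tail]), 1)[0]
        print(f"  tail decay rate {-slope:.2e} 1/s "
              f"(uncatalyzed k_dechel = {preset.params.k_dechel:.2e})")
print("-> the plateau is a driven steady state, not an equilibrium: it")
print("   survives exactly as long as ATP turnover pays for it.")
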