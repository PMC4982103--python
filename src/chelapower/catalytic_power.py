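"""Headline catalytic-power quantities for magnesium chelatase.

Two complementary measures of what ATP hydrolysis buys the enzyme:

* **Rate acceleration.**  Comparing the catalyzed turnover with the
  uncatalyzed bimolecular insertion gives the rate enhancement
  ``k_cat/k_uncat`` (units M, since the two constants differ by one
  order in concentration) and the catalytic proficiency
  ``(k_cat/(K_m^DIX K_0.5^Mg))/k_uncat`` (1/M), whose reciprocal is the
  transition-state dissociation constant K_TX — attomolar here.

* **Thermodynamic displacement.**  Chelation is unfavorable
  (K_eq ~ 1e-6 1/M, dG°' = -RT ln K_eq > 0); the ATP-driven steady
  state holds [MgD]/([D][Mg2+]) orders of magnitude above K_eq, a free
  energy displacement RT ln(ratio/K_eq).

Values are stored at full precision; a render layer rounds to a chosen
number of significant figures ("circa" style: 1 by default) without
touching the stored numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dechelation import (
    chelation_second_order_constant,
    pseudo_first_order_halflife,
    seconds_to_years,
)

__all__ = [
    "GAS_CONSTANT",
    "ThermoContext",
    "DerivedPower",
    "rate_enhancement",
    "catalytic_proficiency",
    "transition_state_kd",
    "standard_free_energy",
    "displacement_free_energy",
    "power_report",
    "round_sig",
]

GAS_CONSTANT = 8.314  # J/(mol K)


@dataclass(frozen=True)
class ThermoContext:
    """Equilibrium context for Mg2+ + D_IX <-> MgD_IX.

    K_eq carries units 1/M ([MgD]/([Mg][D]) with molar concentrations);
    the standard state c0 = 1 M makes dG°' well-defined.
    """

    K_eq: float = 1.0e-6
    T: float = 307.15  # K
    R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if not self.K_eq > 0:
            raise ValueError("K_eq must be > 0")
        if not self.T > 0:
            raise ValueError("T must be > 0")


def round_sig(x: float, sig_figs: int = 1) -> float:
    """Round to a number of significant figures (render helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + sig_figs - 1)


@dataclass
class DerivedPower:
    """Full-precision catalytic-power report.

    ``K_TX * proficiency == 1`` and ``rate_enhancement = k_cat/k_uncat``
    by construction.  ``dG_displacement`` is populated only when a
    steady-state ratio is available.
    """

    k_uncat: float  # 1/(M s)
    rate_enhancement: float  # M
    proficiency: float  # 1/M
    K_TX: float  # M
    halflife_s: float  # uncatalyzed pseudo-first-order t1/2 at mg_ref
    halflife_years: float
    mg_ref: float  # M, reference free Mg2+ for the half-life
    dG_standard: float  # kJ/mol
    dG_displacement: float | None = None  # kJ/mol
    displacement: float | None = None  # dimensionless factor
    sig_figs: int = 1

    def rendered(self) -> dict[str, float]:
        """Rounded view (does not alter the stored values)."""
        out = {
            "k_uncat_per_M_s": round_sig(self.k_uncat, self.sig_figs),
            "rate_enhancement_M": round_sig(self.rate_enhancement, self.sig_figs),
            "proficiency_per_M": round_sig(self.proficiency, self.sig_figs),
            "K_TX_M": round_sig(self.K_TX, self.sig_figs),
            "halflife_years": round_sig(self.halflife_years, self.sig_figs),
            "dG_standard_kJ_per_mol": round_sig(self.dG_standard, self.sig_figs),
        }
        if self.dG_displacement is not None:
            out["dG_displacement_kJ_per_mol"] = round_sig(
                self.dG_displacement, self.sig_figs
            )
        if self.displacement is not None:
            out["displacement_factor"] = round_sig(self.displacement, self.sig_figs)
        return out


def rate_enhancement(k_cat: float, k_uncat: float) -> float:
    """k_cat / k_uncat (units M): first-order turnover over the
    second-order uncatalyzed insertion constant."""
    if not k_uncat > 0:
        raise ValueError("k_uncat must be > 0")
    if k_cat < 0:
        raise ValueError("k_cat must be >= 0")
    return k_cat / k_uncat


def catalytic_proficiency(
    k_cat: float, K_m_DIX: float, K_05_Mg: float, k_uncat: float
) -> float:
    """(k_cat/(K_m^DIX * K_0.5^Mg)) / k_uncat, in 1/M.

    For a multi-substrate cooperative enzyme, k_cat/(K_m K_0.5) is the
    parameter comparable to the uncatalyzed bimolecular constant; their
    ratio measures transition-state stabilization.
    """
    if min(k_cat, K_m_DIX, K_05_Mg, k_uncat) <= 0:
        raise ValueError("all inputs must be > 0")
    return (k_cat / (K_m_DIX * K_05_Mg)) / k_uncat


def transition_state_kd(proficiency: float) -> float:
    """Transition-state dissociation constant K_TX = 1/proficiency (M)."""
    if not proficiency > 0:
        raise ValueError("proficiency must be > 0")
    return 1.0 / proficiency


def standard_free_energy(thermo: ThermoContext) -> float:
    """dG°' = -RT ln(K_eq c0) in kJ/mol (positive: unfavorable)."""
    return -thermo.R * thermo.T * math.log(thermo.K_eq * 1.0) / 1000.0


def displacement_free_energy(ratio_over_Mg: float, thermo: ThermoContext) -> float:
    """RT ln(ratio/K_eq) in kJ/mol: how far from equilibrium the
    ATP-driven steady state is held."""
    if not ratio_over_Mg > 0:
        raise ValueError("ratio_over_Mg must be > 0")
    return thermo.R * thermo.T * math.log(ratio_over_Mg / thermo.K_eq) / 1000.0


def power_report(
    params,
    thermo: ThermoContext,
    mg_ref: float = 1.0e-3,
    sig_figs: int = 1,
    conditions=None,
) -> DerivedPower:
    """Assemble the full catalytic-power report from a parameter set.

    ``params`` is a ``KineticParameterSet``; ``mg_ref`` is the free-Mg2+
    reference for the uncatalyzed half-life (default 1 mM).  When
    ``conditions`` (an ``AssayConditions``) is given, the algebraic
    steady state is solved and the displacement factor and free energy
    are included.
    """
    k_uncat = chelation_second_order_constant(thermo.K_eq, params.k_dechel)
    prof = catalytic_proficiency(
        params.k_cat, params.K_m_DIX, params.K_05_Mg, k_uncat
    )
    t_half = pseudo_first_order_halflife(k_uncat, mg_ref)
    dG_disp = None
    disp = None
    if conditions is not None:
        from .chelatase_model import displacement_factor, find_steady_state

        ss = find_steady_state(params, conditions)
        disp = displacement_factor(ss, thermo)
        dG_disp = displacement_free_energy(ss.ratio_over_Mg, thermo)
    return DerivedPower(
        k_uncat=k_uncat,
        rate_enhancement=rate_enhancement(params.k_cat, k_uncat),
        proficiency=prof,
        K_TX=transition_state_kd(prof),
        halflife_s=t_half,
        halflife_years=seconds_to_years(t_half),
        mg_ref=mg_ref,
        dG_standard=standard_free_energy(thermo),
        dG_displacement=dG_disp,
        displacement=disp,
        sig_figs=sig_figs,
    )
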