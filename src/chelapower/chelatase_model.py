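"""Deterministic kinetic model of ATP-coupled magnesium chelation.

Magnesium chelatase (ChlI/ChlD/ChlH) couples ATP hydrolysis to insertion
of Mg2+ into a porphyrin.  Because the metalloporphyrin spontaneously
dechelates (first-order, rate constant ``k_dechel``), a chelatase assay
shows a characteristic rise of product to a steady state where the
enzymatic formation flux balances the uncatalyzed loss flux
(d[P]/dt ~ 0), followed by a fall back toward equilibrium once the
nucleotide driving force is exhausted.  An ATP-regeneration system
(phosphoenolpyruvate + pyruvate kinase) clamps [ATP] at its initial value
while a finite PEP pool lasts, extending the steady state for hours.

The catalyzed rate law is a product of independent saturating factors:

    v = k_cat * E0 * D/(K_m + D) * Mg^h/(K_0.5^h + Mg^h)
                 * ATP/(K_0.5,ATP + ATP) * 1/(1 + MgD/K_i)

with E0 = min([ChlI], [ChlD], [ChlH]) (the active complex cannot exceed
the scarcest subunit).  This separable form is the simplest one in which
K_m^DIX and K_0.5^Mg enter the catalytic-proficiency expression
k_cat/(K_m K_0.5 k_uncat) as independent factors; all constants are
configuration, not code.

ATP is consumed at ``n_ATP`` per chelation (stoichiometric coupling) plus
an uncoupled basal ATPase term carried by ChlI.  Free Mg2+ is clamped
(10 mM >> µM porphyrin turnover).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "KineticParameterSet",
    "AssayConditions",
    "ModelState",
    "ProgressCurve",
    "SteadyStateResult",
    "MaintenanceResult",
    "DEFAULT_PARAMS",
    "GUN4_PARAMS",
    "chelation_velocity",
    "atp_flux",
    "simulate_progress",
    "find_steady_state",
    "displacement_factor",
    "steady_state_maintenance_time",
]


@dataclass(frozen=True)
class KineticParameterSet:
    """Enzyme-side rate constants (SI units: M, s).

    Defaults are the Synechocystis chelatase set: k_cat = 1/75 1/s and
    k_dechel = 3.17e-5 1/s are measured values; K_m_DIX = 2.0 µM and
    K_05_Mg = 7.0 mM are a labeled split of the constrained product
    K_m*K_0.5 = 1.4e-8 M^2 (only the product is pinned by the catalytic
    proficiency); hill_Mg = 2 reflects the reported Mg2+ cooperativity;
    K_05_ATP = 0.1 mM places ATP saturation near 150 µM; n_ATP = 15 ATP
    per metalloporphyrin; k_basal_ATPase = 0.7 1/s per ChlI is a
    calibration chosen so a 0.5 mM ATP pool depletes on the few-hour
    assay timescale and a 2 mM PEP pool sustains the steady state for
    about 8 h.  Product inhibition is off by default (K_i = inf).
    """

    k_cat: float = 1.0 / 75.0
    K_m_DIX: float = 2.0e-6
    K_05_Mg: float = 7.0e-3
    hill_Mg: float = 2.0
    K_05_ATP: float = 1.0e-4
    n_ATP: float = 15.0
    k_basal_ATPase: float = 0.7
    K_i_product: float = math.inf  # inf = no product inhibition
    k_dechel: float = 3.17e-5

    def __post_init__(self) -> None:
        for name in (
            "k_cat", "K_m_DIX", "K_05_Mg", "K_05_ATP",
            "k_basal_ATPase", "K_i_product", "k_dechel",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_ATP < 1:
            raise ValueError("n_ATP must be >= 1")
        if self.hill_Mg < 1:
            raise ValueError("hill_Mg must be >= 1")


#: Synechocystis defaults.
DEFAULT_PARAMS = KineticParameterSet()

#: Gun4-activated parameter set.  k_cat is back-computed from the
#: Gun4 rate enhancement of 550e6 M (k_cat = 550e6 * k_uncat); K_m_DIX is
#: back-computed so that catalytic proficiency is exactly 10x the default
#: (K_m*K_0.5 = 1.8312e-9 M^2).  Both are labeled fits, not measurements.
GUN4_PARAMS = KineticParameterSet(k_cat=1.744e-2, K_m_DIX=2.6160e-7)


@dataclass(frozen=True)
class AssayConditions:
    """Assay composition (SI units).  Defaults follow the standard
    chelatase assay: 0.1 µM ChlI and ChlD, 0.4 µM ChlH, 8 µM
    deuteroporphyrin IX, 10 mM free Mg2+, 34 °C."""

    conc_ChlI: float = 1.0e-7
    conc_ChlD: float = 1.0e-7
    conc_ChlH: float = 4.0e-7
    D_total: float = 8.0e-6
    Mg_free: float = 1.0e-2  # clamped
    ATP_0: float = 5.0e-3
    PEP_0: float = 0.0  # phosphoenolpyruvate pool for regeneration
    regeneration_on: bool = False
    temperature: float = 307.15  # K (34 C)

    def __post_init__(self) -> None:
        for name in (
            "conc_ChlI", "conc_ChlD", "conc_ChlH", "D_total",
            "Mg_free", "ATP_0", "PEP_0",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def E0(self) -> float:
        """Active-complex concentration: the scarcest subunit."""
        return min(self.conc_ChlI, self.conc_ChlD, self.conc_ChlH)


@dataclass(frozen=True)
class ModelState:
    """Species concentrations at one instant (M)."""

    D: float
    MgD: float
    ATP: float
    PEP: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.D, self.MgD, self.ATP, self.PEP) < 0:
            raise ValueError("species concentrations must be >= 0")


@dataclass
class ProgressCurve:
    """Simulated (or synthetic) time course of all species."""

    times: np.ndarray  # strictly increasing (s)
    D: np.ndarray
    MgD: np.ndarray
    ATP: np.ndarray
    PEP: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("D", "MgD", "ATP", "PEP"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in shape")
            setattr(self, name, arr)

    def state_at(self, i: int) -> ModelState:
        return ModelState(
            D=max(self.D[i], 0.0), MgD=max(self.MgD[i], 0.0),
            ATP=max(self.ATP[i], 0.0), PEP=max(self.PEP[i], 0.0),
            t=self.times[i],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "D_M": self.D,
                "MgD_M": self.MgD,
                "ATP_M": self.ATP,
                "PEP_M": self.PEP,
            }
        )


@dataclass(frozen=True)
class SteadyStateResult:
    """Algebraic steady state where formation balances dechelation."""

    D_ss: float
    MgD_ss: float
    ratio_ss: float  # MgD/D (inf if D_ss == 0)
    ratio_over_Mg: float  # MgD/(D * Mg_free), 1/M
    velocity_ss: float  # flux through the cycle at steady state (M/s)


@dataclass(frozen=True)
class MaintenanceResult:
    """How long a progress curve holds its plateau."""

    duration_s: float
    plateau: float
    censored: bool  # plateau still held (or still rising) at t_end
    no_plateau: bool  # curve never rose (pure decay)


def _saturation_factors(
    state: ModelState, params: KineticParameterSet, cond: AssayConditions
) -> tuple[float, float, float, float]:
    D = max(state.D, 0.0)
    ATP = max(state.ATP, 0.0)
    f_D = D / (params.K_m_DIX + D) if D > 0 else 0.0
    mg_h = cond.Mg_free ** params.hill_Mg
    f_Mg = mg_h / (params.K_05_Mg ** params.hill_Mg + mg_h)
    f_ATP = ATP / (params.K_05_ATP + ATP) if ATP > 0 else 0.0
    if math.isinf(params.K_i_product):
        f_inh = 1.0
    else:
        f_inh = 1.0 / (1.0 + max(state.MgD, 0.0) / params.K_i_product)
    return f_D, f_Mg, f_ATP, f_inh


def chelation_velocity(
    state: ModelState, params: KineticParameterSet, cond: AssayConditions
) -> float:
    """Catalyzed Mg-insertion flux v (M/s) under the separable rate law."""
    f_D, f_Mg, f_ATP, f_inh = _saturation_factors(state, params, cond)
    return params.k_cat * cond.E0 * f_D * f_Mg * f_ATP * f_inh


def atp_flux(
    state: ModelState, params: KineticParameterSet, cond: AssayConditions
) -> float:
    """Total ATP consumption flux (M/s): coupled + basal.

    Coupled hydrolysis is n_ATP per chelation; the basal (uncoupled)
    ATPase is carried by ChlI with the same ATP saturation.  With
    regeneration active this flux is paid from the PEP pool instead of
    the ATP pool (1 PEP rephosphorylates 1 ADP).
    """
    ATP = max(state.ATP, 0.0)
    f_ATP = ATP / (params.K_05_ATP + ATP) if ATP > 0 else 0.0
    basal = params.k_basal_ATPase * cond.conc_ChlI * f_ATP
    return params.n_ATP * chelation_velocity(state, params, cond) + basal


def _rhs(regen_active: bool, params: KineticParameterSet, cond: AssayConditions):
    def rhs(t: float, y: np.ndarray) -> list[float]:
        state = ModelState(
            D=max(y[0], 0.0), MgD=max(y[1], 0.0),
            ATP=max(y[2], 0.0), PEP=max(y[3], 0.0), t=t,
        )
        v = chelation_velocity(state, params, cond)
        loss = params.k_dechel * state.MgD
        flux = atp_flux(state, params, cond)
        dD = -v + loss
        dMgD = v - loss
        if regen_active:
            return [dD, dMgD, 0.0, -flux]
        return [dD, dMgD, -flux, 0.0]

    return rhs


def simulate_progress(
    params: KineticParameterSet,
    cond: AssayConditions,
    t_end: float,
    n_out: int = 601,
    MgD_0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ProgressCurve:
    """Integrate the progress-curve ODE on a fixed output grid.

    State is (D, MgD, ATP, PEP) with D + MgD = D_total conserved.  With
    regeneration on, ATP is clamped while PEP > 0 and PEP is debited at
    the ATP flux; the integration is split at PEP exhaustion (solver
    event) and continued with the clamp released.  Stiff-capable LSODA
    with rtol 1e-8 / atol 1e-12 by default; the output grid is
    independent of solver steps.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if MgD_0 < 0 or MgD_0 > cond.D_total:
        raise ValueError("MgD_0 must lie in [0, D_total]")

    grid = np.linspace(0.0, t_end, n_out)
    y0 = [cond.D_total - MgD_0, MgD_0, cond.ATP_0, cond.PEP_0]
    regen = cond.regeneration_on and cond.PEP_0 > 0

    times_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    t0 = 0.0
    segments = 0
    while t0 < t_end:
        segments += 1
        if segments > 4:  # regen can switch off at most once
            raise RuntimeError("integration segmentation did not terminate")
        events = None
        if regen:
            def pep_exhausted(t, y):
                return y[3]
            pep_exhausted.terminal = True
            pep_exhausted.direction = -1
            events = [pep_exhausted]
        sol = solve_ivp(
            _rhs(regen, params, cond),
            (t0, t_end),
            y0,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
            events=events,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed at t={sol.t[-1]:.3g}s "
                f"(state={sol.y[:, -1]}): {sol.message}"
            )
        seg_end = sol.t[-1]
        seg_mask = (grid >= t0) & (grid <= seg_end)
        if seg_mask.any():
            times_out.append(grid[seg_mask])
            ys_out.append(sol.sol(grid[seg_mask]))
        if regen and sol.status == 1:  # PEP pool exhausted: release clamp
            y0 = list(sol.y[:, -1])
            y0[3] = 0.0
            t0 = seg_end
            regen = False
        else:
            break

    t_arr = np.concatenate(times_out)
    y_arr = np.concatenate(ys_out, axis=1)
    # the segment boundary can duplicate a grid point
    t_arr, idx = np.unique(t_arr, return_index=True)
    y_arr = y_arr[:, idx]
    y_arr = np.clip(y_arr, 0.0, None)
    return ProgressCurve(
        times=t_arr,
        D=y_arr[0],
        MgD=y_arr[1],
        ATP=y_arr[2],
        PEP=y_arr[3],
        metadata={"params": params, "conditions": cond, "MgD_0": MgD_0},
    )


def find_steady_state(
    params: KineticParameterSet,
    cond: AssayConditions,
    rtol: float = 1e-12,
) -> SteadyStateResult:
    """Solve v(D) = k_dechel * (D_total - D) with ATP clamped at ATP_0.

    The left side is increasing in D and the right side decreasing, so
    the root in (0, D_total] is unique; it is bracketed and found with
    Brent's method.  Degenerate cases (no enzyme, no nucleotide, no loss
    path) are handled analytically at the boundary.
    """
    Dt = cond.D_total

    def balance(D: float) -> float:
        state = ModelState(D=D, MgD=Dt - D, ATP=cond.ATP_0, PEP=cond.PEP_0)
        return chelation_velocity(state, params, cond) - params.k_dechel * (Dt - D)

    if Dt == 0:
        return SteadyStateResult(0.0, 0.0, math.nan, math.nan, 0.0)
    probe = ModelState(D=Dt, MgD=0.0, ATP=cond.ATP_0, PEP=cond.PEP_0)
    v_max = chelation_velocity(probe, params, cond)
    if v_max == 0.0:
        # no formation path: all porphyrin free
        return SteadyStateResult(Dt, 0.0, 0.0, 0.0, 0.0)
    if params.k_dechel == 0.0:
        # no loss path: complete conversion
        return SteadyStateResult(
            0.0, Dt, math.inf, math.inf, 0.0
        )
    D_ss = brentq(balance, 0.0, Dt, rtol=rtol, xtol=1e-30)
    MgD_ss = Dt - D_ss
    ratio = MgD_ss / D_ss if D_ss > 0 else math.inf
    ratio_over_mg = ratio / cond.Mg_free if cond.Mg_free > 0 else math.inf
    return SteadyStateResult(
        D_ss=D_ss,
        MgD_ss=MgD_ss,
        ratio_ss=ratio,
        ratio_over_Mg=ratio_over_mg,
        velocity_ss=params.k_dechel * MgD_ss,
    )


def displacement_factor(ss: SteadyStateResult, thermo) -> float:
    """Factor by which the driven steady state exceeds equilibrium.

    ratio_over_Mg / K_eq: how far ATP hydrolysis holds
    [MgD]/([D][Mg2+]) above the chelation equilibrium constant.
    """
    if not ss.ratio_over_Mg > 0:
        raise ValueError("ratio_over_Mg must be > 0")
    if not thermo.K_eq > 0:
        raise ValueError("K_eq must be > 0")
    return ss.ratio_over_Mg / thermo.K_eq


def steady_state_maintenance_time(
    curve: ProgressCurve,
    tolerance_fraction: float = 0.10,
    plateau: float | None = None,
) -> MaintenanceResult:
    """Length of the longest interval with MgD within tolerance of plateau.

    The plateau is the supplied algebraic steady state when given,
    otherwise the curve's maximum MgD (the last point before decline).
    A curve that never rises gets duration 0 with ``no_plateau`` set; a
    curve still inside the band (or still rising) at t_end is flagged
    ``censored``.
    """
    mgd = curve.MgD
    t = curve.times
    if plateau is None:
        rises = np.any(np.diff(mgd) > 0)
        if not rises and np.any(np.diff(mgd) < 0):
            return MaintenanceResult(0.0, float(mgd[0]), False, True)
        plateau = float(mgd.max())
    if plateau <= 0:
        return MaintenanceResult(0.0, float(plateau), False, True)
    within = np.abs(mgd - plateau) <= tolerance_fraction * plateau
    if not within.any():
        return MaintenanceResult(0.0, float(plateau), False, False)
    # longest contiguous run of in-band points
    best = (0, 0)
    i = 0
    n = within.size
    while i < n:
        if within[i]:
            j = i
            while j + 1 < n and within[j + 1]:
                j += 1
            if t[j] - t[i] > t[best[1]] - t[best[0]]:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    i0, i1 = best
    censored = bool(within[-1]) or mgd.argmax() == n - 1
    return MaintenanceResult(
        duration_s=float(t[i1] - t[i0]),
        plateau=float(plateau),
        censored=censored,
        no_plateau=False,
    )
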