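"""Uncatalyzed dechelation kinetics of magnesium deuteroporphyrin.

Magnesium porphyrins spontaneously lose their metal ion; for
Mg-deuteroporphyrin IX the loss is first-order in the metalloporphyrin
([MgD] decays exponentially).  This module estimates the first-order
dechelation rate constant ``k_dechel`` from initial-rate data (rate vs.
concentration through the origin), and combines it with the chelation
equilibrium constant to obtain the *second-order* rate constant of the
uncatalyzed forward reaction

    Mg2+ + D_IX  <->  MgD_IX,      K_eq = k_on / k_off,

so ``k_uncat = K_eq * k_dechel``.  At a fixed free-Mg2+ concentration the
uncatalyzed insertion is pseudo-first-order, with half-life
``ln 2 / (k_uncat * [Mg2+])`` — geological timescales at millimolar Mg2+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InitialRateMeasurement",
    "FirstOrderFit",
    "initial_rate",
    "fit_first_order_constant",
    "chelation_second_order_constant",
    "pseudo_first_order_halflife",
    "seconds_to_years",
    "SECONDS_PER_YEAR",
]

#: Julian year, so printed round numbers are reproducible.
SECONDS_PER_YEAR = 3.15576e7


@dataclass(frozen=True)
class InitialRateMeasurement:
    """One initial-rate point: dechelation rate at a starting [MgD].

    Rates are stored as positive magnitudes; the decay sign is handled at
    the time-course level.
    """

    conc: float  # starting MgD concentration (M)
    rate: float  # initial dechelation rate (M/s), >= 0
    rate_se: float | None = None  # standard error of the rate (M/s)

    def __post_init__(self) -> None:
        if not self.conc > 0:
            raise ValueError(f"conc must be > 0, got {self.conc}")
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.rate_se is not None and self.rate_se < 0:
            raise ValueError("rate_se must be >= 0")


@dataclass
class FirstOrderFit:
    """Through-origin fit of initial rate vs. concentration."""

    k_dechel: float  # first-order rate constant (1/s)
    k_se: float  # standard error (1/s); 0 for a single point
    n_points: int
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.k_dechel < 0 or self.k_se < 0 or self.n_points < 1:
            raise ValueError("invalid FirstOrderFit fields")


def initial_rate(
    times: np.ndarray,
    conc: np.ndarray,
    window_seconds: float = 300.0,
) -> tuple[float, float]:
    """Initial rate (magnitude) from a concentration time course.

    Fits an ordinary least-squares line to concentration vs. time over
    ``[0, window_seconds]`` and returns ``(|slope|, slope standard error)``.
    The default 300 s window mirrors a 5-min plate-reader time course; for
    a decay with k ~ 3e-5 1/s the curvature bias over that window is
    ~k*t/2 ~ 0.5%.

    Raises ``ValueError`` for fewer than 3 points in the window or a
    non-monotone time grid.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and conc must be 1-D arrays of equal length")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    mask = (t >= 0) & (t <= window_seconds)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"need >=3 points inside the {window_seconds} s window, got {n}"
        )
    tw, cw = t[mask], c[mask]
    # OLS slope with intercept; SE from residual variance (n-2 dof).
    tbar = tw.mean()
    sxx = float(((tw - tbar) ** 2).sum())
    slope = float(((tw - tbar) * (cw - cw.mean())).sum() / sxx)
    resid = cw - (cw.mean() + slope * (tw - tbar))
    se = float(np.sqrt((resid**2).sum() / ((n - 2) * sxx))) if n > 2 else 0.0
    return abs(slope), se


def fit_first_order_constant(
    data: list[InitialRateMeasurement],
) -> FirstOrderFit:
    """Fit rate = k * conc through the origin by least squares.

    Zero rate at zero concentration is chemically forced, so the fit has
    no intercept:  k = sum(c_i r_i) / sum(c_i^2), with

        SE = sqrt( sum((r_i - k c_i)^2) / ((n - 1) sum(c_i^2)) )

    for n >= 2, and SE = 0 for a single measurement.
    """
    if not data:
        raise ValueError("no measurements supplied")
    c = np.array([m.conc for m in data], dtype=float)
    r = np.array([m.rate for m in data], dtype=float)
    if np.any(c <= 0):
        raise ValueError("all concentrations must be > 0")
    scc = float((c * c).sum())
    k = float((c * r).sum() / scc)
    resid = r - k * c
    n = c.size
    se = float(np.sqrt((resid**2).sum() / ((n - 1) * scc))) if n > 1 else 0.0
    return FirstOrderFit(k_dechel=k, k_se=se, n_points=n, residuals=resid)


def chelation_second_order_constant(K_eq: float, k_dechel: float) -> float:
    """Second-order uncatalyzed chelation constant k_uncat = K_eq * k_dechel.

    Microscopic reversibility: K_eq = k_on/k_off for
    Mg2+ + D <-> MgD, so the forward bimolecular constant is the
    association constant times the measured off-rate.
    """
    if K_eq < 0 or k_dechel < 0:
        raise ValueError("K_eq and k_dechel must be >= 0")
    return K_eq * k_dechel


def pseudo_first_order_halflife(k_uncat: float, mg_conc: float) -> float:
    """Half-life (s) of uncatalyzed insertion at fixed free [Mg2+].

    t_1/2 = ln 2 / (k_uncat * [Mg2+]).
    """
    if k_uncat <= 0 or mg_conc <= 0:
        raise ValueError("k_uncat and mg_conc must be > 0")
    return float(np.log(2) / (k_uncat * mg_conc))


def seconds_to_years(seconds: float) -> float:
    """Convert seconds to Julian years (3.15576e7 s/yr)."""
    return seconds / SECONDS_PER_YEAR
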