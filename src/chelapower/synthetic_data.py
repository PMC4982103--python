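"""Seeded synthetic datasets emulating the plate-reader assays.

Two experiment families are generated, each with the statistical
structure the analysis assumes and each alongside its noise-free truth
(the oracle channel — never written into the noisy output):

* **Dechelation time courses**: exponential decay of MgD_IX at several
  starting concentrations, sampled over a 5-min window at 10-s
  intervals, with multiplicative measurement noise; initial rates are
  extracted from the noisy curves exactly as they would be from real
  traces.

* **Chelatase assay progress curves**: the ODE model's MgD_IX course
  mapped to a fluorescence signal (lambda_ex 420 nm / lambda_em 580 nm;
  signal = gain * [MgD] + baseline, the product being the only emitter
  by default) with noise applied to the signal.

Default noise is multiplicative with 3% CV — plate-reader-like; the
magnitude is a labeled assumption.  All generators are pure functions of
(arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chelatase_model import (
    DEFAULT_PARAMS,
    GUN4_PARAMS,
    AssayConditions,
    KineticParameterSet,
    ProgressCurve,
    simulate_progress,
)
from .dechelation import InitialRateMeasurement

__all__ = [
    "NoiseModel",
    "FluorescenceTrace",
    "DecayTrace",
    "DechelationExperiment",
    "Preset",
    "DechelationPreset",
    "PRESETS",
    "get_preset",
    "generate_dechelation_experiment",
    "generate_chelatase_assay",
    "fluorescence_to_conc",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``multiplicative_cv``: signal * (1 + magnitude * N(0,1)) — constant
    coefficient of variation.  ``additive_sd``: signal + magnitude *
    N(0,1) in the signal's own units.
    """

    kind: str = "multiplicative_cv"
    magnitude: float = 0.03
    seed: int = 42

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_cv", "additive_sd"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(np.shape(values))
        if self.kind == "multiplicative_cv":
            return values * (1.0 + self.magnitude * eps)
        return values + self.magnitude * eps


@dataclass
class FluorescenceTrace:
    """Raw fluorescence readout of a chelatase assay."""

    times: np.ndarray  # s
    signal: np.ndarray  # a.u.
    gain: float  # a.u. per M
    baseline: float = 0.0  # a.u.
    excitation_nm: float = 420.0
    emission_nm: float = 580.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class DecayTrace:
    """One dechelation time course (noisy) plus its clean truth."""

    conc0: float  # starting MgD (M)
    times: np.ndarray  # s
    conc: np.ndarray  # noisy concentration readout (M)
    conc_true: np.ndarray  # noise-free exponential (oracle channel)


@dataclass
class DechelationExperiment:
    """Synthetic initial-rate experiment across concentrations."""

    curves: list[DecayTrace]
    measurements: list[InitialRateMeasurement]  # rates fit from noisy curves
    true_rates: dict[float, float]  # conc -> k_true * conc (oracle)
    k_true: float
    seed: int


@dataclass(frozen=True)
class Preset:
    """A named chelatase-assay scenario (parameters + conditions)."""

    name: str
    params: KineticParameterSet
    conditions: AssayConditions
    noise: NoiseModel
    t_end: float  # s
    n_out: int
    gain: float = 1.0e8  # a.u. per M
    baseline: float = 0.0
    description: str = ""


@dataclass(frozen=True)
class DechelationPreset:
    """A named dechelation initial-rate scenario."""

    name: str
    k_true: float
    concs: tuple[float, ...]
    duration: float
    n_points: int
    noise: NoiseModel
    description: str = ""


def _fig2_conditions(atp: float, regen: bool) -> AssayConditions:
    return AssayConditions(
        ATP_0=atp,
        PEP_0=2.0e-3 if regen else 0.0,
        regeneration_on=regen,
    )


_FIG2_DESC = (
    "standard chelatase assay: 0.1 uM ChlI/ChlD, 0.4 uM ChlH, "
    "8 uM deuteroporphyrin IX, 10 mM Mg2+, 34 C"
)

PRESETS: dict[str, Preset | DechelationPreset] = {}


def _register(preset: Preset | DechelationPreset) -> None:
    if preset.name in PRESETS:
        raise ValueError(f"duplicate preset name {preset.name!r}")
    PRESETS[preset.name] = preset


for _name, _atp, _regen in [
    ("fig2a", 0.5e-3, True),
    ("fig2a-noregen", 0.5e-3, False),
    ("fig2b", 1.0e-3, True),
    ("fig2b-noregen", 1.0e-3, False),
    ("fig2c", 5.0e-3, True),
    ("fig2c-noregen", 5.0e-3, False),
]:
    _hours = 12.0 if _regen else 10.0
    _register(
        Preset(
            name=_name,
            params=DEFAULT_PARAMS,
            conditions=_fig2_conditions(_atp, _regen),
            noise=NoiseModel(),
            t_end=_hours * 3600.0,
            n_out=int(_hours * 120) + 1,  # 30-s grid
            description=(
                f"{_FIG2_DESC}; {_atp * 1e3:g} mM MgATP2-, regeneration "
                f"{'on (2 mM PEP)' if _regen else 'off'}"
            ),
        )
    )

_register(
    Preset(
        name="fig3b-low",
        params=DEFAULT_PARAMS,
        conditions=AssayConditions(
            D_total=2.5e-6, ATP_0=5.0e-3, PEP_0=2.0e-3, regeneration_on=True
        ),
        noise=NoiseModel(),
        t_end=12.0 * 3600.0,
        n_out=1441,
        description="low-porphyrin assay: 2.5 uM D_IX, 5 mM MgATP2-, regeneration on",
    )
)

for _base in ("fig2b", "fig3b-low"):
    _p = PRESETS[_base]
    _register(
        replace(
            _p,
            name=_base + "-gun4",
            params=GUN4_PARAMS,
            description=_p.description + "; + 0.4 uM Gun4 (activated parameter set)",
        )
    )

_register(
    DechelationPreset(
        name="fig4",
        k_true=3.17e-5,
        concs=tuple(c * 1e-6 for c in (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)),
        duration=300.0,
        n_points=31,
        noise=NoiseModel(),
        description=(
            "uncatalyzed dechelation initial rates; the 1-6 uM concentration "
            "range and single replicate per point are assumptions of this "
            "preset, not measured design"
        ),
    )
)


def get_preset(name: str) -> Preset | DechelationPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def generate_dechelation_experiment(
    k_true: float,
    concs: list[float] | tuple[float, ...],
    duration: float,
    n_points: int,
    noise: NoiseModel,
    seed: int | None = None,
    k_photolysis: float = 0.0,
) -> DechelationExperiment:
    """Synthetic exponential-decay experiment with an initial-rate table.

    For each starting concentration a decay exp(-(k_true+k_photolysis)t)
    is sampled on a uniform grid with noise applied (the raw-trace
    channel), and an initial-rate *measurement* is drawn by applying the
    same noise model to the true rate k_eff * c0 (the rate channel, with
    the noise CV as its standard error).  The rate channel is separate
    because a 5-min window resolves only ~1% of the decay: refitting
    rates from the noisy traces would be dominated by point noise rather
    than by the chemistry.  The photolysis term defaults to 0 (controls
    found it insignificant).  ``seed`` overrides ``noise.seed``.
    """
    if not k_true > 0:
        raise ValueError("k_true must be > 0")
    if len(concs) == 0:
        raise ValueError("concs must be non-empty")
    if duration <= 0 or n_points < 3:
        raise ValueError("need duration > 0 and n_points >= 3")
    if k_photolysis < 0:
        raise ValueError("k_photolysis must be >= 0")
    use_seed = noise.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    k_eff = k_true + k_photolysis
    times = np.linspace(0.0, duration, n_points)
    curves: list[DecayTrace] = []
    measurements: list[InitialRateMeasurement] = []
    for c0 in concs:
        clean = c0 * np.exp(-k_eff * times)
        noisy = noise.apply(clean, rng)
        curves.append(DecayTrace(conc0=c0, times=times, conc=noisy, conc_true=clean))
        true_rate = k_eff * c0
        rate = float(np.clip(noise.apply(np.array(true_rate), rng), 0.0, None))
        se = (
            noise.magnitude * true_rate
            if noise.kind == "multiplicative_cv"
            else noise.magnitude
        )
        measurements.append(
            InitialRateMeasurement(conc=c0, rate=rate, rate_se=se)
        )
    return DechelationExperiment(
        curves=curves,
        measurements=measurements,
        true_rates={c0: k_eff * c0 for c0 in concs},
        k_true=k_eff,
        seed=use_seed,
    )


def generate_chelatase_assay(
    preset: Preset, seed: int | None = None
) -> tuple[FluorescenceTrace, ProgressCurve]:
    """Simulate a preset and read it out as noisy fluorescence.

    Returns the noisy trace and the clean underlying progress curve
    (oracle channel).  ``seed`` overrides the preset noise seed.
    """
    curve = simulate_progress(
        preset.params, preset.conditions, preset.t_end, preset.n_out
    )
    rng = np.random.default_rng(preset.noise.seed if seed is None else seed)
    clean_signal = preset.gain * curve.MgD + preset.baseline
    trace = FluorescenceTrace(
        times=curve.times,
        signal=preset.noise.apply(clean_signal, rng),
        gain=preset.gain,
        baseline=preset.baseline,
        metadata={"preset": preset.name, "seed": preset.noise.seed if seed is None else seed},
    )
    return trace, curve


def fluorescence_to_conc(trace: FluorescenceTrace) -> tuple[np.ndarray, int]:
    """Invert the calibration: conc = (signal - baseline)/gain, clipped
    at 0.  Returns (concentrations, number of clipped points)."""
    if not trace.gain > 0:
        raise ValueError("gain must be > 0")
    conc = (trace.signal - trace.baseline) / trace.gain
    n_clipped = int((conc < 0).sum())
    return np.clip(conc, 0.0, None), n_clipped


# ---------------------------------------------------------------------------
# CSV emission (used by the CLI `synth` subcommand)

def dechelation_to_frames(
    exp: DechelationExperiment,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Noisy per-concentration curve tables plus the rates table."""
    curves = {
        f"dechel_curve_{i + 1}": pd.DataFrame(
            {"time_s": tr.times, "conc_M": tr.conc}
        )
        for i, tr in enumerate(exp.curves)
    }
    rates = pd.DataFrame(
        {
            "conc_M": [m.conc for m in exp.measurements],
            "rate_M_per_s": [m.rate for m in exp.measurements],
            "rate_se_M_per_s": [m.rate_se for m in exp.measurements],
        }
    )
    return curves, rates
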