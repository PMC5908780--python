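"""Synthetic bench simulator: oscillator, circuit gas mixing, and a well-mixed
rigid test lung with continuous CO2 insufflation.

The simulator works at per-cycle resolution.  Each oscillation cycle
exchanges an alveolar volume of lung gas against inspired gas whose CO2
content is set by dilution of the previous exhalate with the per-cycle
effective bias-flow volume.  The lung CO2 fraction then evolves as a linear
per-cycle map whose fixed point is available in closed form, so every run
carries its own analytic ground truth.

The alveolar exchange volume ``V_alv = c1*max(aSV - VD, 0) + c2*aSV**p`` is a
declared stand-in (no mechanistic transport model is available for this
bench); its default coefficients are chosen only so that downstream estimates
land in a plausible few-to-20 L/min band at 8 Hz and are visible in
:class:`TransportParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .circuit_core import (
    GasConditions,
    LungModelSpec,
    MixingParams,
    OscillatorSettings,
)

__all__ = [
    "AttenuationParams",
    "TransportParams",
    "NoiseParams",
    "SimConfig",
    "FlowTrace",
    "PCO2Trace",
    "TruthRecord",
    "Condition",
    "BenchRun",
    "attenuate_sv",
    "make_flow_trace",
    "resolve_actual_sv",
    "cycle_bias_volume",
    "alveolar_exchange_volume",
    "step_cycle",
    "steady_state_fraction",
    "mass_balance_residual",
    "simulate_run",
    "grid_conditions",
    "simulate_grid",
    "simulate_calibration",
    "replicate_seed",
    "write_trace",
    "read_trace",
    "grid_truth_table",
]


@dataclass(frozen=True)
class AttenuationParams:
    """Linear map from panel stroke volume to delivered stroke volume.

    aSV = (slope_base - slope_bf_penalty*BF) * sSV + intercept, floored at 0.
    Defaults are invented placeholders (calibratable), not device inference.
    """

    slope_base: float = 0.75
    slope_bf_penalty: float = 0.002  # per L/min of bias flow
    intercept: float = 0.0


@dataclass(frozen=True)
class TransportParams:
    """Per-cycle alveolar exchange volume coefficients (declared stand-in)."""

    conv_coeff: float = 0.2  # c1, dead-space-excess convection
    disp_coeff: float = 0.00165  # c2, dispersive term amplitude
    disp_power: float = 2.0  # p

    def __post_init__(self) -> None:
        if self.conv_coeff < 0 or self.disp_coeff < 0:
            raise ValueError("transport coefficients must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    flow_sd: float = 5.0  # mL/s
    pco2_sd: float = 0.2  # mmHg

    def __post_init__(self) -> None:
        if self.flow_sd < 0 or self.pco2_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulated bench condition."""

    settings: OscillatorSettings = field(default_factory=OscillatorSettings)
    lung: LungModelSpec = field(default_factory=LungModelSpec)
    mixing: MixingParams = field(default_factory=MixingParams)
    gas: GasConditions = field(default_factory=GasConditions)
    attenuation: AttenuationParams = field(default_factory=AttenuationParams)
    transport: TransportParams = field(default_factory=TransportParams)
    flow_sample_rate: float = 200.0  # Hz
    capno_sample_rate: float = 10.0  # Hz
    capno_time_constant: float = 2.0  # s
    noise: NoiseParams = field(default_factory=NoiseParams)
    duration: float = 240.0  # s
    seed: int = 0
    #: when set, the delivered stroke volume is forced to this value and the
    #: attenuation map is bypassed (study-2 style conditions)
    target_asv: float | None = None

    def __post_init__(self) -> None:
        if self.flow_sample_rate <= 0 or self.capno_sample_rate <= 0:
            raise ValueError("sample rates must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.capno_time_constant < 0:
            raise ValueError("capno_time_constant must be >= 0")


@dataclass
class FlowTrace:
    """Uniformly sampled airway flow, mL/s, inspiratory positive."""

    samples: np.ndarray
    rate: float  # Hz
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("flow samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class PCO2Trace:
    """Uniformly sampled capnometer CO2 partial pressure, mmHg."""

    samples: np.ndarray
    rate: float  # Hz
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("PCO2 samples must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class TruthRecord:
    """Analytic latent values behind one simulated run."""

    actual_sv: float  # mL
    pco2_ss: float  # mmHg
    lung_co2_fraction_ss: float
    va_asymptote: float  # L/min, bias-flow -> infinity limit of the estimator


@dataclass(frozen=True)
class Condition:
    """Grid cell label attached to runs produced by :func:`simulate_grid`."""

    study: int
    sv_value: float  # setting SV (study 1) or targeted actual SV (study 2)
    bias_flow: float
    replicate: int
    seed: int


@dataclass
class BenchRun:
    flow_trace: FlowTrace
    pco2_trace: PCO2Trace
    truth: TruthRecord
    config_echo: SimConfig
    converged: bool = True
    condition: Condition | None = None


def attenuate_sv(
    setting_sv: float, bias_flow: float, attenuation: AttenuationParams
) -> float:
    """Map panel stroke volume to delivered stroke volume, mL."""
    if setting_sv < 0:
        raise ValueError(f"setting_sv must be >= 0, got {setting_sv}")
    slope = attenuation.slope_base - attenuation.slope_bf_penalty * bias_flow
    if slope <= 0:
        raise ValueError(
            f"attenuation slope {slope:.4g} is not positive at bias flow "
            f"{bias_flow} L/min; check slope_base/slope_bf_penalty"
        )
    return max(0.0, slope * setting_sv + attenuation.intercept)


def make_flow_trace(
    actual_sv: float,
    frequency: float,
    rate: float = 200.0,
    duration: float = 60.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FlowTrace:
    """Sinusoidal oscillatory flow whose half-cycle volume equals ``actual_sv``.

    q(t) = q0*sin(2*pi*f*t) with q0 = actual_sv*pi*f, so the integral of each
    half cycle is exactly ``actual_sv`` mL.  Additive zero-mean Gaussian noise
    with sd ``noise_sd``; deterministic for a fixed seed.
    """
    if actual_sv < 0:
        raise ValueError(f"actual_sv must be >= 0, got {actual_sv}")
    if frequency <= 0 or rate <= 0:
        raise ValueError("frequency and rate must be > 0")
    if duration < 1.0 / frequency:
        raise ValueError(
            f"duration {duration} s is shorter than one cycle ({1.0 / frequency} s)"
        )
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    q0 = actual_sv * math.pi * frequency
    samples = q0 * np.sin(2.0 * math.pi * frequency * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    return FlowTrace(samples=samples, rate=rate)


def resolve_actual_sv(config: SimConfig) -> float:
    """Delivered stroke volume for a config: forced target or attenuated setting."""
    if config.target_asv is not None:
        if config.target_asv < 0:
            raise ValueError("target_asv must be >= 0")
        return float(config.target_asv)
    return attenuate_sv(
        config.settings.setting_sv, config.settings.bias_flow, config.attenuation
    )


def cycle_bias_volume(config: SimConfig) -> float:
    """Effective bias-flow volume delivered per oscillation cycle, mL."""
    f = config.settings.frequency
    return (
        config.mixing.effective_bf_fraction
        * config.settings.bias_flow
        * 1000.0
        / (60.0 * f)
    )


def alveolar_exchange_volume(actual_sv: float, config: SimConfig) -> float:
    """Per-cycle alveolar exchange volume V_alv, mL (declared stand-in model)."""
    tr = config.transport
    return tr.conv_coeff * max(actual_sv - config.lung.dead_space, 0.0) + (
        tr.disp_coeff * actual_sv**tr.disp_power
    )


def step_cycle(
    lung_co2_fraction: float, config: SimConfig
) -> tuple[float, float]:
    """Advance the lung CO2 fraction by one oscillation cycle.

    Returns ``(next_fraction, inspired_fraction)``.  The inspired fraction is
    the lung fraction diluted by the per-cycle effective bias volume:
    C_insp = C_lung * aSV/(aSV + V_bf).  The lung balance over one cycle is

        dC = [VCO2/(60f) - V_alv*(C_lung - C_insp) - q_cap*C_lung] / V_container

    with q_cap the capnometer withdrawal per cycle.
    """
    if not 0.0 <= lung_co2_fraction < 1.0:
        raise ValueError(
            f"lung_co2_fraction must be in [0, 1), got {lung_co2_fraction}"
        )
    asv = resolve_actual_sv(config)
    f = config.settings.frequency
    v_bf = cycle_bias_volume(config)
    v_alv = alveolar_exchange_volume(asv, config)
    vco2_per_cycle = config.lung.vco2_insufflation / (60.0 * f)
    if v_alv == 0.0 and vco2_per_cycle > 0.0:
        raise ValueError(
            "alveolar exchange volume is zero while CO2 is insufflated: "
            "no steady state exists"
        )
    q_cap = config.lung.capno_sample_flow / (60.0 * f)
    if asv + v_bf > 0:
        inspired = lung_co2_fraction * asv / (asv + v_bf)
    else:
        inspired = 0.0
    v_container_ml = config.lung.container_volume * 1000.0
    delta = (
        vco2_per_cycle
        - v_alv * (lung_co2_fraction - inspired)
        - q_cap * lung_co2_fraction
    ) / v_container_ml
    return lung_co2_fraction + delta, inspired


def _steady_state_parts(config: SimConfig) -> tuple[float, float, float, float]:
    asv = resolve_actual_sv(config)
    f = config.settings.frequency
    v_bf = cycle_bias_volume(config)
    v_alv = alveolar_exchange_volume(asv, config)
    q_cap = config.lung.capno_sample_flow / (60.0 * f)
    return asv, v_bf, v_alv, q_cap


def steady_state_fraction(config: SimConfig) -> float:
    """Closed-form fixed point of the per-cycle CO2 balance.

    Solving dC = 0 gives C_ss = (VCO2/(60f)) / (V_alv*V_bf/(aSV+V_bf) + q_cap).
    """
    asv, v_bf, v_alv, q_cap = _steady_state_parts(config)
    f = config.settings.frequency
    vco2_per_cycle = config.lung.vco2_insufflation / (60.0 * f)
    denom = v_alv * v_bf / (asv + v_bf) + q_cap if asv + v_bf > 0 else q_cap
    if vco2_per_cycle == 0.0:
        return 0.0
    if denom <= 0.0:
        raise ValueError("no steady state: no CO2 removal path in configuration")
    c_ss = vco2_per_cycle / denom
    if c_ss >= 1.0:
        raise ValueError(
            f"steady-state CO2 fraction {c_ss:.3f} >= 1; configuration removes "
            "too little CO2 for a physical steady state"
        )
    return c_ss


def mass_balance_residual(config: SimConfig, lung_co2_fraction: float) -> float:
    """Relative CO2 mass-balance residual at a given lung fraction.

    Zero at steady state: inflow equals removal through the effective bias
    flow (alveolar exchange against the diluted inspirate) plus capnometer
    withdrawal.
    """
    asv, v_bf, v_alv, q_cap = _steady_state_parts(config)
    f = config.settings.frequency
    vco2_per_cycle = config.lung.vco2_insufflation / (60.0 * f)
    if vco2_per_cycle == 0.0:
        raise ValueError("mass-balance residual undefined with zero CO2 inflow")
    inspired = (
        lung_co2_fraction * asv / (asv + v_bf) if asv + v_bf > 0 else 0.0
    )
    removed = v_alv * (lung_co2_fraction - inspired) + q_cap * lung_co2_fraction
    return (vco2_per_cycle - removed) / vco2_per_cycle


def _va_asymptote(config: SimConfig) -> float:
    """Literal-scale alveolar-ventilation estimate in the BF -> infinity limit."""
    asv, _v_bf, v_alv, q_cap = _steady_state_parts(config)
    f = config.settings.frequency
    vco2 = config.lung.vco2_insufflation
    if vco2 == 0.0:
        return 0.0
    c_inf = (vco2 / (60.0 * f)) / (v_alv + q_cap)
    return vco2 / (c_inf * config.gas.barometric_pressure)


def simulate_run(
    config: SimConfig, initial_fraction: float | None = None
) -> BenchRun:
    """Simulate one bench condition end to end.

    ``initial_fraction`` of ``None`` starts the lung at the analytic steady
    state (the experimental protocol records only the stabilized value, so
    this is the default); pass an explicit value (e.g. 0.0) to simulate the
    washin transient.  The capnometer output is the per-cycle lung PCO2 passed
    through a first-order lag plus Gaussian noise.  The container-volume
    change due to mean airway pressure (~2.5% at 25 cmH2O) is ignored in the
    balance.
    """
    asv = resolve_actual_sv(config)
    f = config.settings.frequency
    c_ss = steady_state_fraction(config)
    if initial_fraction is None:
        initial_fraction = c_ss

    n_cycles = int(math.ceil(config.duration * f))
    fractions = np.empty(n_cycles + 1)
    fractions[0] = initial_fraction
    c = initial_fraction
    for i in range(n_cycles):
        c, _ = step_cycle(c, config)
        fractions[i + 1] = c

    # convergence: relative drift over the final 10% of cycles
    tail = max(2, n_cycles // 10)
    ref = abs(fractions[-1]) if fractions[-1] != 0 else 1.0
    drift = abs(fractions[-1] - fractions[-tail]) / ref
    converged = drift < 1e-3

    rng = np.random.default_rng(config.seed)
    flow_seed = int(rng.integers(0, 2**31 - 1))
    flow = make_flow_trace(
        asv,
        f,
        rate=config.flow_sample_rate,
        duration=config.duration,
        noise_sd=config.noise.flow_sd,
        seed=flow_seed,
    )

    pb = config.gas.barometric_pressure
    n_capno = int(round(config.duration * config.capno_sample_rate))
    t_capno = np.arange(n_capno) / config.capno_sample_rate
    cycle_idx = np.minimum((t_capno * f).astype(int), n_cycles)
    lung_pco2 = fractions[cycle_idx] * pb
    if config.capno_time_constant > 0:
        alpha = 1.0 - math.exp(
            -1.0 / (config.capno_sample_rate * config.capno_time_constant)
        )
        smoothed = np.empty_like(lung_pco2)
        y = lung_pco2[0]
        for i, u in enumerate(lung_pco2):
            y += alpha * (u - y)
            smoothed[i] = y
    else:
        smoothed = lung_pco2
    if config.noise.pco2_sd > 0:
        smoothed = smoothed + rng.normal(0.0, config.noise.pco2_sd, size=n_capno)
    pco2 = PCO2Trace(samples=np.clip(smoothed, 0.0, None), rate=config.capno_sample_rate)

    truth = TruthRecord(
        actual_sv=asv,
        pco2_ss=c_ss * pb,
        lung_co2_fraction_ss=c_ss,
        va_asymptote=_va_asymptote(config),
    )
    return BenchRun(
        flow_trace=flow,
        pco2_trace=pco2,
        truth=truth,
        config_echo=config,
        converged=converged,
    )


def replicate_seed(master_seed: int, index: int) -> int:
    """Deterministic per-cell seed derived from a master seed and cell index."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def grid_conditions(
    base: SimConfig,
    sv_values: Sequence[float],
    bf_values: Sequence[float],
    replicates: int,
    seed: int,
    study: int = 1,
) -> Iterator[tuple[Condition, SimConfig]]:
    """Yield (label, config) pairs for a study grid in deterministic order.

    Study 1 sweeps setting SV through the attenuation map; study 2 targets
    actual SV directly and bypasses attenuation.
    """
    if not sv_values or not bf_values:
        raise ValueError("sv_values and bf_values must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if study not in (1, 2):
        raise ValueError(f"study must be 1 or 2, got {study}")
    index = 0
    for sv in sv_values:
        for bf in bf_values:
            for rep in range(1, replicates + 1):
                cell_seed = replicate_seed(seed, index)
                index += 1
                settings = replace(
                    base.settings,
                    bias_flow=float(bf),
                    setting_sv=float(sv) if study == 1 else base.settings.setting_sv,
                )
                config = replace(
                    base,
                    settings=settings,
                    seed=cell_seed,
                    target_asv=float(sv) if study == 2 else None,
                )
                yield Condition(
                    study=study,
                    sv_value=float(sv),
                    bias_flow=float(bf),
                    replicate=rep,
                    seed=cell_seed,
                ), config


def simulate_grid(
    base: SimConfig,
    sv_values: Sequence[float],
    bf_values: Sequence[float],
    replicates: int = 5,
    seed: int = 0,
    study: int = 1,
) -> list[BenchRun]:
    """Simulate a full study grid; one run per (sv, bf, replicate) cell."""
    runs: list[BenchRun] = []
    for condition, config in grid_conditions(
        base, sv_values, bf_values, replicates, seed, study=study
    ):
        run = simulate_run(config)
        run.condition = condition
        runs.append(run)
    return runs


def simulate_calibration(
    vco2: float,
    o2_flow: float,
    gas: GasConditions,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> float:
    """Capnometer reading, mmHg, of the CO2 source diluted into an O2 flow.

    PCO2 = PB * VCO2 / (VCO2 + o2_flow*1000), plus optional Gaussian noise.
    """
    if vco2 < 0:
        raise ValueError(f"vco2 must be >= 0, got {vco2}")
    if o2_flow <= 0:
        raise ValueError(f"o2_flow must be > 0, got {o2_flow}")
    value = gas.barometric_pressure * vco2 / (vco2 + o2_flow * 1000.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        value += rng.normal(0.0, noise_sd)
    return value


# ---------------------------------------------------------------------------
# trace file format: two-column delimited time series with a '#' header block

_TRACE_UNITS = {"flow": "mL/s", "pco2": "mmHg"}


def write_trace(trace: FlowTrace | PCO2Trace, path: str | Path) -> None:
    """Write a trace as a tab-delimited (time, value) file with a header block."""
    kind = "flow" if isinstance(trace, FlowTrace) else "pco2"
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# hfovbench-trace v1\n")
        fh.write(f"# kind: {kind}\n")
        fh.write(f"# units: {_TRACE_UNITS[kind]}\n")
        fh.write(f"# rate_hz: {trace.rate!r}\n")
        fh.write(f"# t0_s: {trace.t0!r}\n")
        fh.write("time_s\tvalue\n")
        for t, v in zip(trace.times, trace.samples):
            fh.write(f"{t:.6f}\t{float(v)!r}\n")


def read_trace(path: str | Path) -> FlowTrace | PCO2Trace:
    """Read a trace file written by :func:`write_trace`."""
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("time_s"):
                continue
            _, _, val = line.partition("\t")
            values.append(float(val))
    kind = meta.get("kind")
    if kind not in _TRACE_UNITS:
        raise ValueError(f"{path}: unrecognized trace kind {kind!r}")
    rate = float(meta["rate_hz"])
    t0 = float(meta.get("t0_s", "0.0"))
    cls = FlowTrace if kind == "flow" else PCO2Trace
    return cls(samples=np.array(values), rate=rate, t0=t0)


def grid_truth_table(runs: Sequence[BenchRun]):
    """Tidy per-run ground-truth table (one row per grid cell)."""
    import pandas as pd

    rows = []
    for run in runs:
        cond = run.condition
        rows.append(
            {
                "study": cond.study if cond else 0,
                "sv_value": cond.sv_value if cond else float("nan"),
                "bias_flow": cond.bias_flow
                if cond
                else run.config_echo.settings.bias_flow,
                "replicate": cond.replicate if cond else 1,
                "seed": cond.seed if cond else run.config_echo.seed,
                "actual_sv_true": run.truth.actual_sv,
                "pco2_ss_true": run.truth.pco2_ss,
                "va_asymptote": run.truth.va_asymptote,
                "converged": run.converged,
            }
        )
    return pd.DataFrame(rows)
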