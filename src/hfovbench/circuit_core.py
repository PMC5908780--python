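"""Closed-form circuit and gas-transport computations for the oscillator bench.

All operations are pure functions of their arguments.  Quantities follow the
conventions used throughout the package: stroke volumes in mL, flows in L/min
(except CO2 insufflation and capnometer sampling, which are mL/min), partial
pressures in mmHg, compliances in mL/cmH2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_BAROMETRIC_MMHG",
    "BTPS_FACTOR",
    "OscillatorSettings",
    "LungModelSpec",
    "GasConditions",
    "MixingParams",
    "VentilationResult",
    "minute_ventilation",
    "va_paper_estimator",
    "va_physiological",
    "rebreathing_pco2",
    "ve_bf_ratio",
    "required_bias_flow",
    "gas_compression_compliance",
    "efficiency_index",
]

DEFAULT_BAROMETRIC_MMHG = 760.0
#: dry-gas to BTPS conversion constant used by the physiological estimator
BTPS_FACTOR = 0.863


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class OscillatorSettings:
    """Ventilator panel state for one experimental condition."""

    frequency: float = 8.0  # Hz
    setting_sv: float = 100.0  # mL
    map_pressure: float = 25.0  # cmH2O
    bias_flow: float = 10.0  # L/min
    fio2: float = 0.21
    insp_fraction: float = 0.5

    def __post_init__(self) -> None:
        _require(self.frequency > 0, f"frequency must be > 0, got {self.frequency}")
        _require(self.setting_sv >= 0, f"setting_sv must be >= 0, got {self.setting_sv}")
        _require(self.bias_flow > 0, f"bias_flow must be > 0, got {self.bias_flow}")
        _require(
            0 < self.insp_fraction < 1,
            f"insp_fraction must be in (0, 1), got {self.insp_fraction}",
        )
        _require(
            0.21 <= self.fio2 <= 1.0, f"fio2 must be in [0.21, 1.0], got {self.fio2}"
        )


@dataclass(frozen=True)
class LungModelSpec:
    """Geometry and gas-exchange constants of the bench test lung."""

    container_volume: float = 20.0  # L
    dead_space: float = 110.0  # mL
    airway_resistance: float = 2.0  # cmH2O/L/s, metadata only
    vco2_insufflation: float = 200.0  # mL/min
    capno_sample_flow: float = 200.0  # mL/min
    well_mixed: bool = True

    def __post_init__(self) -> None:
        _require(
            self.container_volume > 0,
            f"container_volume must be > 0, got {self.container_volume}",
        )
        _require(self.dead_space >= 0, f"dead_space must be >= 0, got {self.dead_space}")
        _require(
            self.vco2_insufflation >= 0,
            f"vco2_insufflation must be >= 0, got {self.vco2_insufflation}",
        )
        _require(
            self.capno_sample_flow >= 0,
            f"capno_sample_flow must be >= 0, got {self.capno_sample_flow}",
        )


@dataclass(frozen=True)
class GasConditions:
    """Ambient gas conditions; the bench operates at room temperature, dry."""

    barometric_pressure: float = DEFAULT_BAROMETRIC_MMHG  # mmHg
    temperature_note: str = "ATPD"
    btps_factor: float = BTPS_FACTOR

    def __post_init__(self) -> None:
        _require(
            self.barometric_pressure > 0,
            f"barometric_pressure must be > 0, got {self.barometric_pressure}",
        )


@dataclass(frozen=True)
class MixingParams:
    """Fraction of bias flow that fully mixes with exhaled gas."""

    effective_bf_fraction: float = 1.0

    def __post_init__(self) -> None:
        _require(
            0 < self.effective_bf_fraction <= 1.0,
            "effective_bf_fraction must be in (0, 1], "
            f"got {self.effective_bf_fraction}",
        )


@dataclass(frozen=True)
class VentilationResult:
    """Derived quantities for one experimental condition."""

    actual_sv: float  # mL
    minute_ventilation: float  # L/min
    pco2_ss: float  # mmHg
    alveolar_ventilation: float  # L/min
    efficiency: float  # dimensionless
    ve_bf_ratio: float  # dimensionless
    settings: OscillatorSettings = field(default_factory=OscillatorSettings)


def minute_ventilation(actual_sv: float, frequency: float) -> float:
    """Minute ventilation in L/min from stroke volume (mL) and frequency (Hz)."""
    _require(actual_sv >= 0, f"actual_sv must be >= 0, got {actual_sv}")
    _require(frequency > 0, f"frequency must be > 0, got {frequency}")
    return actual_sv / 1000.0 * frequency * 60.0


def va_paper_estimator(vco2: float, pco2: float) -> float:
    """Alveolar ventilation as the literal ratio VCO2 (mL/min) / PCO2 (mmHg).

    The returned value is reported on the study's literal scale (L/min); the
    units do not cancel but this is the convention the source results use.
    See :func:`va_physiological` for a dimensionally explicit variant.
    """
    _require(vco2 >= 0, f"vco2 must be >= 0, got {vco2}")
    _require(pco2 > 0, f"pco2 must be > 0, got {pco2}")
    return vco2 / pco2


def va_physiological(
    vco2: float, pco2: float, gas: GasConditions, btps: bool = False
) -> float:
    """Pressure-explicit alveolar-ventilation estimate, L/min.

    Dry-gas form: (VCO2/1000) * PB / PCO2.  With ``btps=True`` the classical
    0.863 conversion constant is applied instead of the explicit barometric
    pressure.
    """
    _require(vco2 >= 0, f"vco2 must be >= 0, got {vco2}")
    _require(pco2 > 0, f"pco2 must be > 0, got {pco2}")
    if btps:
        return gas.btps_factor * vco2 / pco2
    return (vco2 / 1000.0) * gas.barometric_pressure / pco2


def rebreathing_pco2(vco2: float, bias_flow: float, gas: GasConditions) -> float:
    """Mean rebreathed CO2 partial pressure, mmHg, if all bias flow is effective.

    At steady state the mean CO2 concentration exhausted from the expiratory
    circuit equals VCO2/BF; under complete mixing the rebreathed gas has the
    same mean concentration, giving (VCO2 / (BF*1000)) * PB.
    """
    _require(vco2 >= 0, f"vco2 must be >= 0, got {vco2}")
    _require(bias_flow > 0, f"bias_flow must be > 0, got {bias_flow}")
    return vco2 / (bias_flow * 1000.0) * gas.barometric_pressure


def ve_bf_ratio(minute_ventilation: float, bias_flow: float) -> float:
    """Ratio of actual minute ventilation to bias flow (both L/min)."""
    _require(
        minute_ventilation >= 0,
        f"minute_ventilation must be >= 0, got {minute_ventilation}",
    )
    _require(bias_flow > 0, f"bias_flow must be > 0, got {bias_flow}")
    return minute_ventilation / bias_flow


def required_bias_flow(target_ratio: float, minute_ventilation: float) -> float:
    """Bias flow (L/min) needed to hold a given minute-ventilation/BF ratio."""
    _require(target_ratio > 0, f"target_ratio must be > 0, got {target_ratio}")
    _require(
        minute_ventilation >= 0,
        f"minute_ventilation must be >= 0, got {minute_ventilation}",
    )
    return minute_ventilation / target_ratio


def gas_compression_compliance(
    volume: float,
    pressure_abs: float,
    mode: str = "isothermal",
    gamma: float = 1.4,
) -> float:
    """Compliance (mL/cmH2O) of a rigid gas volume due to gas compression.

    ``volume`` in L, ``pressure_abs`` the absolute pressure in cmH2O.
    Isothermal: 1000*V/P.  Adiabatic: 1000*V/(gamma*P).  The bench container's
    printed value matches the isothermal formula, so that is the default mode.
    """
    _require(volume > 0, f"volume must be > 0, got {volume}")
    _require(pressure_abs > 0, f"pressure_abs must be > 0, got {pressure_abs}")
    _require(gamma >= 1, f"gamma must be >= 1, got {gamma}")
    if mode == "isothermal":
        return 1000.0 * volume / pressure_abs
    if mode == "adiabatic":
        return 1000.0 * volume / (gamma * pressure_abs)
    raise ValueError(f"mode must be 'isothermal' or 'adiabatic', got {mode!r}")


def efficiency_index(alveolar_ventilation: float, minute_ventilation: float) -> float:
    """Ventilation efficiency: alveolar / minute ventilation (fraction)."""
    _require(
        alveolar_ventilation >= 0,
        f"alveolar_ventilation must be >= 0, got {alveolar_ventilation}",
    )
    _require(
        minute_ventilation > 0,
        f"minute_ventilation must be > 0, got {minute_ventilation}",
    )
    return alveolar_ventilation / minute_ventilation
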