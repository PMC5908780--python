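"""Stroke-volume measurement from sampled airway flow.

Reimplements the prototype measurement chain: the 200-Hz flow signal is
DC-corrected, the expiratory (negative) lobe is digitally integrated over
each one-second window, and the per-second values are averaged over one
minute.  Values are reported per cycle (window total divided by the number of
cycles in the window) so that measured aSV is directly comparable to the
panel setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_bench import FlowTrace

__all__ = ["SvSeries", "remove_dc_offset", "expiratory_sv_per_second", "mean_sv", "measure_actual_sv"]


@dataclass
class SvSeries:
    """Per-second expiratory stroke volumes, mL per cycle."""

    per_second_sv: np.ndarray
    mean_sv: float
    n_seconds: int

    def __post_init__(self) -> None:
        self.per_second_sv = np.asarray(self.per_second_sv, dtype=float)
        if np.any(self.per_second_sv < 0):
            raise ValueError("per-second stroke volumes must be >= 0")


def remove_dc_offset(trace: FlowTrace) -> FlowTrace:
    """Subtract the whole-trace mean so the oscillatory signal is zero-mean."""
    if trace.samples.size == 0:
        raise ValueError("empty flow trace")
    return FlowTrace(
        samples=trace.samples - trace.samples.mean(), rate=trace.rate, t0=trace.t0
    )


def expiratory_sv_per_second(trace: FlowTrace, frequency: float = 8.0) -> SvSeries:
    """Integrate the expiratory lobe per one-second window.

    Negative samples are integrated by the trapezoidal rule within each full
    second; the magnitude divided by the number of cycles per second gives mL
    per cycle.  Partial trailing seconds are discarded.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    per_second = trace.rate
    n_per_window = int(round(per_second))
    if abs(per_second - n_per_window) > 1e-9:
        raise ValueError(
            f"sample rate {trace.rate} Hz does not give an integer number of "
            "samples per second"
        )
    n_windows = trace.samples.size // n_per_window
    if n_windows < 1:
        raise ValueError("flow trace shorter than one second")
    clipped = np.minimum(trace.samples[: n_windows * n_per_window], 0.0)
    windows = clipped.reshape(n_windows, n_per_window)
    integrals = np.trapezoid(windows, dx=1.0 / trace.rate, axis=1)
    values = np.abs(integrals) / frequency
    return SvSeries(per_second_sv=values, mean_sv=float(values.mean()), n_seconds=n_windows)


def mean_sv(series: SvSeries, n: int = 60) -> float:
    """Arithmetic mean of the first ``n`` per-second stroke volumes, mL."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if series.per_second_sv.size < n:
        raise ValueError(
            f"series has {series.per_second_sv.size} values, need {n}"
        )
    return float(series.per_second_sv[:n].mean())


def measure_actual_sv(
    trace: FlowTrace, frequency: float = 8.0, n: int = 60, dc_correct: bool = True
) -> float:
    """Convenience chain: DC removal -> per-second integration -> n-second mean."""
    if dc_correct:
        trace = remove_dc_offset(trace)
    series = expiratory_sv_per_second(trace, frequency=frequency)
    return mean_sv(series, n=min(n, series.per_second_sv.size))
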