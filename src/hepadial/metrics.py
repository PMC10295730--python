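"""Removal-efficiency summaries and the A-vs-B comparison report.

The efficiency of the module at time t is η(t) = 1 − C_out(t)/C_TB0: the
fraction of the incoming toxin stream that does not leave with the blood.
Windowed time averages of η are the headline numbers used to compare the
two configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import RunConfig
from .results import SimulationResult

__all__ = [
    "EfficiencyReport",
    "removal_efficiency_series",
    "windowed_mean_efficiency",
    "compare_configurations",
    "fill_time",
]


@dataclass(frozen=True)
class EfficiencyReport:
    """Efficiency summary of one simulated run."""

    label: str
    times: np.ndarray  # min
    efficiency: np.ndarray  # η(t), dimensionless
    windowed_means: dict[tuple[float, float], float]


def removal_efficiency_series(result: SimulationResult,
                              inlet_conc: float | None = None) -> np.ndarray:
    """Pointwise removal efficiency η(t) = 1 − C_out(t)/C_TB0.

    ``inlet_conc`` defaults to the run's own inlet concentration; passing
    it explicitly (in the same units as the outlet series) makes the
    series unit-invariant by construction.
    """
    ctb0 = result.config.operating.inlet_toxin_conc if inlet_conc is None else inlet_conc
    if ctb0 <= 0:
        raise ValueError("inlet concentration must be > 0")
    return 1.0 - result.outlet_series / ctb0


def windowed_mean_efficiency(times, efficiency, t_start: float, t_end: float) -> float:
    """Trapezoid time-average of η over [t_start, t_end].

    Window edges need not coincide with grid points; η is linearly
    interpolated there.  Raises on an empty or out-of-horizon window.
    """
    times = np.asarray(times, dtype=float)
    efficiency = np.asarray(efficiency, dtype=float)
    if not t_start < t_end:
        raise ValueError("need t_start < t_end")
    if t_start < times[0] or t_end > times[-1]:
        raise ValueError("window must lie within the simulated horizon")
    inside = (times > t_start) & (times < t_end)
    ts = np.concatenate(([t_start], times[inside], [t_end]))
    es = np.concatenate(
        ([np.interp(t_start, times, efficiency)],
         efficiency[inside],
         [np.interp(t_end, times, efficiency)])
    )
    return float(np.trapezoid(es, ts) / (t_end - t_start))


def fill_time(config: RunConfig) -> float:
    """Time to fill the (initially empty) fiber lumens: lumen volume / QB,
    in min.  Relevant to configuration A only; configuration B starts full."""
    return config.geometry.fiber_lumen_volume / config.operating.blood_flow


def _report(label: str, result: SimulationResult, ctb0: float,
            windows) -> EfficiencyReport:
    eta = removal_efficiency_series(result, ctb0)
    means = {
        (float(a), float(b)): windowed_mean_efficiency(result.times, eta, a, b)
        for a, b in windows
    }
    return EfficiencyReport(label=label, times=result.times,
                            efficiency=eta, windowed_means=means)


def compare_configurations(result_a: SimulationResult, result_b: SimulationResult,
                           windows=((0.0, 100.0),)) -> tuple[EfficiencyReport, EfficiencyReport, bool]:
    """Efficiency reports for both configurations plus the superiority
    verdict: True iff configuration A's full-horizon mean efficiency
    strictly exceeds configuration B's.

    Both runs must share the inlet concentration and horizon.
    """
    c0a = result_a.config.operating.inlet_toxin_conc
    c0b = result_b.config.operating.inlet_toxin_conc
    if not np.isclose(c0a, c0b):
        raise ValueError("runs must share the inlet toxin concentration")
    if not np.isclose(result_a.times[-1], result_b.times[-1]):
        raise ValueError("runs must share the simulated horizon")
    horizon = (0.0, float(result_a.times[-1]))
    all_windows = tuple(windows) + (horizon,)
    rep_a = _report("config A", result_a, c0a, all_windows)
    rep_b = _report("config B", result_b, c0b, all_windows)
    verdict = rep_a.windowed_means[horizon] > rep_b.windowed_means[horizon]
    return rep_a, rep_b, verdict
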