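"""Synthetic outlet-concentration datasets emulating the in-vitro runs.

The bench experiment pumps artificial blood (albumin + bilirubin) through
the module for 12 h and assays outlet bilirubin at regular intervals.  The
generator runs the matching forward model, samples its outlet series on a
schedule (default: every 30 min over 720 min, 25 points), and applies a
configurable measurement-noise model — by default 5 % relative Gaussian,
a typical spectrophotometric repeatability.  Negative draws are clipped
to zero (concentrations are non-negative; the small bias this introduces
at near-zero signal is accepted for simplicity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import ObservedSeries
from .model_a import simulate_config_a
from .model_b import simulate_config_b
from .parameters import NumericsConfig, RunConfig, ValidationError

__all__ = ["NoiseModel", "default_schedule", "generate_dataset", "generate_mass_sweep"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``kind`` is one of ``"relative-gaussian"`` (scale = relative sd),
    ``"absolute-gaussian"`` (scale in µmol/L) or ``"none"``.  Seeded
    generation is reproducible bit-for-bit.
    """

    kind: str = "relative-gaussian"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("relative-gaussian", "absolute-gaussian", "none"):
            raise ValidationError(
                f"noise kind '{self.kind}' unknown; use relative-gaussian, "
                "absolute-gaussian or none"
            )
        if self.scale < 0:
            raise ValidationError("noise scale must be >= 0")

    def apply(self, truth: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.kind == "none":
            return truth.copy()
        if self.kind == "relative-gaussian":
            noisy = truth * (1.0 + self.scale * rng.standard_normal(truth.shape))
        else:
            noisy = truth + self.scale * rng.standard_normal(truth.shape)
        return np.clip(noisy, 0.0, None)


def default_schedule(duration: float = 720.0, interval: float = 30.0) -> np.ndarray:
    """Sampling times 0, interval, …, duration (min)."""
    return np.arange(0.0, duration + 0.5 * interval, interval)


def _simulate(config: RunConfig, schedule: np.ndarray):
    # sample the solver exactly at the schedule times so that fitting
    # (which also evaluates the model there) sees no interpolation error
    num = NumericsConfig(
        n_axial_cells=config.numerics.n_axial_cells,
        time_solver_rel_tol=config.numerics.time_solver_rel_tol,
        time_solver_abs_tol=config.numerics.time_solver_abs_tol,
        output_times=tuple(float(t) for t in schedule),
    )
    sim = simulate_config_a if config.configuration == "a" else simulate_config_b
    return sim(config, num)


def generate_dataset(config: RunConfig, schedule=None,
                     noise: NoiseModel | None = None) -> ObservedSeries:
    """Forward-simulate ``config``, sample the outlet on ``schedule`` and
    apply ``noise``; returns an :class:`ObservedSeries` ready for fitting.

    The schedule must lie within [0, duration].  ``noise=None`` means the
    default 5 % relative-Gaussian model; pass ``NoiseModel("none")`` for
    exact model output.
    """
    schedule = default_schedule(config.operating.duration) if schedule is None \
        else np.asarray(schedule, dtype=float)
    if schedule.min() < 0 or schedule.max() > config.operating.duration:
        raise ValidationError("schedule must lie within [0, duration]")
    noise = NoiseModel() if noise is None else noise

    result = _simulate(config, schedule)
    truth = result.outlet_at(schedule)
    observed = noise.apply(truth)
    sd = None
    if noise.kind == "relative-gaussian":
        sd = noise.scale * truth
    elif noise.kind == "absolute-gaussian":
        sd = np.full_like(truth, noise.scale)
    return ObservedSeries(times=schedule, outlet_conc=observed, noise_sd=sd)


def generate_mass_sweep(config: RunConfig, masses, schedule=None,
                        noise: NoiseModel | None = None) -> list[ObservedSeries]:
    """One dataset per adsorbent mass (g), in the given order — the
    configuration-A experiment repeated at different adsorbent inventories
    (e.g. 0, 30 and 700 mg).  Each dataset gets an independent seed offset
    so replicates are not correlated."""
    if config.configuration != "a":
        raise ValidationError("mass sweeps are a configuration-A experiment")
    datasets = []
    for i, mass in enumerate(masses):
        if mass < 0:
            raise ValidationError("adsorbent mass must be >= 0")
        cfg_m = config.with_updates(operating={"adsorbent_mass": float(mass)})
        noise_i = noise
        if noise is not None and noise.kind != "none":
            noise_i = NoiseModel(noise.kind, noise.scale, noise.seed + i)
        datasets.append(generate_dataset(cfg_m, schedule, noise_i))
    return datasets
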