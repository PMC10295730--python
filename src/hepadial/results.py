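"""Simulation output container shared by both module configurations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import RunConfig

__all__ = ["SimulationResult", "SolverError", "NumericalStabilityError"]


class SolverError(RuntimeError):
    """Time integration failed; carries the time reached."""

    def __init__(self, message: str, time_reached: float):
        super().__init__(f"{message} (integration reached t = {time_reached:g} min)")
        self.time_reached = time_reached


class NumericalStabilityError(RuntimeError):
    """A state variable went negative beyond tolerance; refine the grid or
    tighten solver tolerances."""


@dataclass
class SimulationResult:
    """Space-time fields of one forward simulation.

    ``blood_field`` has shape (n_times, n_axial_cells) on the cell-centered
    ``axial_grid``; ``outlet_series`` is its last column.  For configuration
    A ``dialysate_series`` and the scalar solid phase are populated; for
    configuration B the solid phase is a (n_times, n_axial_cells) field and
    ``dialysate_series`` is None.  ``solid_loading_series`` is the adsorbed
    loading n_T = m′·C_TP in µmol/g.  ``cumulative_inflow``/``_outflow``
    (nmol) are integrated by the ODE solver itself for exact bookkeeping.
    """

    config: RunConfig
    times: np.ndarray  # min
    axial_grid: np.ndarray  # cm, cell centers
    blood_field: np.ndarray  # µmol/L
    solid_conc: np.ndarray  # C_TP, µmol/L; (nt,) for A, (nt, nz) for B
    dialysate_series: np.ndarray | None  # µmol/L, config A only
    cumulative_inflow: np.ndarray = field(repr=False, default=None)  # nmol
    cumulative_outflow: np.ndarray = field(repr=False, default=None)  # nmol

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.diff(self.axial_grid) > 0):
            raise ValueError("axial_grid must be strictly increasing")

    @property
    def outlet_series(self) -> np.ndarray:
        """Blood concentration at the fiber outlet, CTB(z=L, t) in µmol/L."""
        return self.blood_field[:, -1]

    @property
    def solid_loading_series(self) -> np.ndarray:
        """Adsorbed loading n_T = m′·C_TP in µmol/g (same shape as
        ``solid_conc``)."""
        return self.config.equilibrium.isotherm_slope * self.solid_conc

    def outlet_at(self, t) -> np.ndarray:
        """Linear interpolation of the outlet series at times ``t`` (min)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.outlet_series)

    def to_frame(self) -> pd.DataFrame:
        """Tidy blood field: columns time_min, z_cm, C_blood_umol_L."""
        nt, nz = self.blood_field.shape
        return pd.DataFrame(
            {
                "time_min": np.repeat(self.times, nz),
                "z_cm": np.tile(self.axial_grid, nt),
                "C_blood_umol_L": self.blood_field.ravel(),
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per-time summary: outlet, dialysate (if any) and mean loading."""
        data = {"time_min": self.times, "C_outlet_umol_L": self.outlet_series}
        if self.dialysate_series is not None:
            data["C_dialysate_umol_L"] = self.dialysate_series
        loading = self.solid_loading_series
        data["n_T_umol_g"] = loading if loading.ndim == 1 else loading.mean(axis=1)
        return pd.DataFrame(data)
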