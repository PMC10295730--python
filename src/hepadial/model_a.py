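"""Forward model of configuration A: fibers immersed in stirred dialysate
with suspended adsorbent microspheres.

Semi-discrete (method-of-lines) system on ``n`` cell-centered axial nodes,
first-order upwind in z:

    dC_i/dt   = -v (C_i - C_{i-1})/dz - (2/Rf) PΣ (αB C_i - αD CTD)
    dCTD/dt   =  (nf π Rf² / VD) Σ_i e_i dz  -  (k A_TOT / VD)(αD CTD - αP CTP)
    ρP dn_T/dt = (k A_TOT / VD)(ε/(1-ε))(αD CTD - αP CTP),  n_T = m' CTP

with v = QB/(nf π Rf²), inlet Dirichlet C_0 = CTB0, and everything
initially toxin-free (fibers empty, fresh dialysate, clean adsorbent).
The dialysate source term uses the same cell sum as the blood sink
(midpoint quadrature of the axial integral), which makes the semi-discrete
system conserve mass exactly; the ε/(1-ε) factor makes the printed
dialysate/solid pair conservative as well, since ε/(1-ε) = VD/VS.

The solid balance is expressed in the liquid-equivalent concentration
C_TP via the linear isotherm; the unit factor 1000 converts the m' slope
(L/g) into the internal mL-based system.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import (
    free_fraction_exact,
    free_fraction_simplified,
    total_particle_surface,
    void_fraction,
)
from .parameters import RunConfig
from .results import NumericalStabilityError, SimulationResult, SolverError

__all__ = ["simulate_config_a", "mass_balance_residual"]

_L_PER_ML = 1e-3  # m' [L/g] -> internal mL system: 1 L = 1000 mL


def _alphas(config: RunConfig):
    """Per-compartment free-fraction evaluators.

    In ``simplified`` mode the α's are the constants 1/(1 + kB·CALB_i);
    in ``exact`` mode blood and dialysate α's are state-dependent via the
    full mass-action quadratic (the solid compartment keeps the simplified
    constant — its liquid-equivalent concentration is an isotherm construct,
    not a real solution volume).
    """
    eq = config.equilibrium
    kb = eq.binding_constant
    a_b = free_fraction_simplified(eq.albumin_conc_blood, kb)
    a_d = free_fraction_simplified(eq.albumin_conc_dialysate, kb)
    a_p = free_fraction_simplified(eq.albumin_conc_solid, kb)
    if config.alpha_mode == "simplified":
        return (lambda c: a_b), (lambda c: a_d), a_p
    return (
        lambda c: free_fraction_exact(c, eq.albumin_conc_blood, kb),
        lambda c: free_fraction_exact(c, eq.albumin_conc_dialysate, kb),
        a_p,
    )


def simulate_config_a(config: RunConfig, numerics=None) -> SimulationResult:
    """Integrate the configuration-A balances and return the space-time
    solution at the requested output times.

    Parameters
    ----------
    config :
        Validated configuration-A parameter set.
    numerics :
        Optional :class:`~hepadial.parameters.NumericsConfig` overriding
        ``config.numerics``.

    Raises
    ------
    SolverError
        If adaptive time integration fails before ``duration``.
    NumericalStabilityError
        If any concentration undershoots below -1e3·abs_tol.
    """
    if config.configuration != "a":
        raise ValueError("simulate_config_a requires a configuration-'a' RunConfig")
    num = numerics if numerics is not None else config.numerics
    geo, op, tr, eq = config.geometry, config.operating, config.transport, config.equilibrium

    n = num.n_axial_cells
    dz = geo.module_length / n
    area = geo.fiber_count * np.pi * geo.fiber_inner_radius**2  # total lumen cross-section, cm²
    v = op.blood_flow / area  # cm/min
    ctb0 = op.inlet_toxin_conc
    p_sigma = tr.global_exchange_coeff
    two_over_rf = 2.0 / geo.fiber_inner_radius
    vd = op.dialysate_volume
    mp = op.adsorbent_mass

    alpha_b, alpha_d, alpha_p = _alphas(config)

    has_solid = mp > 0
    if has_solid:
        atot = total_particle_surface(mp, op.particle_density, op.particle_radius)
        eps = void_fraction(vd, mp, op.particle_density)
        # dCTP/dt = s·(ε/(1-ε)) / (ρP·m′), s = (k·A_TOT/VD)·Δ, m′ in mL/g
        solid_rate = tr.solid_exchange_coeff * atot / vd
        ctp_coeff = (eps / (1.0 - eps)) / (
            op.particle_density * eq.isotherm_slope / _L_PER_ML
        )
    else:
        solid_rate = 0.0
        ctp_coeff = 0.0

    # state: [C_1..C_n, CTD, CTP, M_out] (M_out in nmol for bookkeeping)
    def rhs(t, y):
        c = y[:n]
        ctd = y[n]
        ctp = y[n + 1]
        exch = two_over_rf * p_sigma * (alpha_b(c) * c - alpha_d(ctd) * ctd)
        dc = np.empty(n)
        dc[0] = -v * (c[0] - ctb0) / dz - exch[0]
        dc[1:] = -v * (c[1:] - c[:-1]) / dz - exch[1:]
        gain = area * dz * np.sum(exch) / vd  # exactly what the blood cells lose
        s = solid_rate * (alpha_d(ctd) * ctd - alpha_p * ctp)
        return np.concatenate((dc, [gain - s, ctp_coeff * s, op.blood_flow * c[-1]]))

    t_end = op.duration
    if num.output_times is not None:
        t_eval = np.asarray(num.output_times, dtype=float)
    else:
        t_eval = np.linspace(0.0, t_end, 721)
    if t_eval[0] > 0.0:
        t_eval = np.concatenate(([0.0], t_eval))

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.zeros(n + 3),
        method="LSODA",
        t_eval=t_eval,
        rtol=num.time_solver_rel_tol,
        atol=num.time_solver_abs_tol,
    )
    if not sol.success:
        raise SolverError(f"config-A integration failed: {sol.message}",
                          time_reached=float(sol.t[-1]) if sol.t.size else 0.0)
    if sol.y[:n + 2].min() < -1e3 * num.time_solver_abs_tol:
        raise NumericalStabilityError(
            "negative concentration excursion beyond tolerance; "
            "increase n_axial_cells or tighten solver tolerances"
        )

    z = (np.arange(n) + 0.5) * dz
    return SimulationResult(
        config=config,
        times=sol.t,
        axial_grid=z,
        blood_field=np.clip(sol.y[:n].T, 0.0, None),
        solid_conc=np.clip(sol.y[n + 1], 0.0, None),
        dialysate_series=np.clip(sol.y[n], 0.0, None),
        cumulative_inflow=op.blood_flow * ctb0 * sol.t,
        cumulative_outflow=sol.y[n + 2],
    )


def mass_balance_residual(result: SimulationResult) -> float:
    """Relative toxin bookkeeping error over the full horizon.

    |inflow − outflow − accumulated| / inflow, where "accumulated" sums the
    lumen, dialysate and adsorbed inventories at the final time (all in
    nmol; concentrations are µmol/L = nmol/mL).  The outflow integral is
    carried by the ODE solver itself, so a converged run closes the balance
    to solver tolerance.
    """
    cfg = result.config
    geo, op, eq = cfg.geometry, cfg.operating, cfg.equilibrium
    n = result.blood_field.shape[1]
    dz = geo.module_length / n
    cell_vol = geo.fiber_count * np.pi * geo.fiber_inner_radius**2 * dz  # mL

    lumen = cell_vol * float(np.sum(result.blood_field[-1]))
    dialysate = op.dialysate_volume * float(result.dialysate_series[-1])
    # adsorbed moles: MP [g] · n_T [µmol/g] -> nmol
    loading = eq.isotherm_slope * float(result.solid_conc[-1])  # µmol/g
    solid = op.adsorbent_mass * loading * 1e3

    inflow = float(result.cumulative_inflow[-1])
    outflow = float(result.cumulative_outflow[-1])
    return abs(inflow - outflow - lumen - dialysate - solid) / inflow
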