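"""Albumin-binding equilibria and adsorbent geometry.

Only the *free* (unbound) fraction of a protein-bound toxin can cross the
fiber membrane or adsorb on a microsphere.  With 1:1 mass-action binding
of toxin T to albumin A,

    T + A <-> TA,      kB = [TA] / ([T][A]),

the free fraction α = CT/Ctox in a compartment holding total toxin Ctox
and total albumin CALB solves a quadratic; when albumin is in large excess
(CALB >> Ctox) it reduces to the constant α = 1/(1 + kB·CALB).

Adsorption on the albumin-functionalized silica is described by a linear
isotherm n_T = m′·C_TP (a linearized Langmuir regime), and the dialysate
void fraction and total microsphere surface follow from the adsorbent
inventory assuming monodisperse spheres.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "free_fraction_exact",
    "free_fraction_simplified",
    "isotherm_loading",
    "isotherm_inverse",
    "void_fraction",
    "total_particle_surface",
]


def free_fraction_simplified(albumin_conc, binding_constant):
    """Free fraction α = 1/(1 + kB·CALB), the albumin-excess limit.

    Parameters
    ----------
    albumin_conc : array_like
        Total albumin concentration CALB in µmol/L.
    binding_constant : float
        Association constant kB in L/µmol.

    Returns
    -------
    float or ndarray in (0, 1].
    """
    calb = np.asarray(albumin_conc, dtype=float)
    if np.any(calb < 0):
        raise ValueError("albumin_conc must be >= 0")
    if binding_constant < 0:
        raise ValueError("binding_constant must be >= 0")
    out = 1.0 / (1.0 + binding_constant * calb)
    return out if out.ndim else float(out)


def free_fraction_exact(total_toxin_conc, albumin_conc, binding_constant):
    """Free fraction from the full 1:1 mass-action equilibrium.

    Solves kB·CT² + (1 + kB·(CALB − Ctox))·CT − Ctox = 0 for the free
    toxin concentration CT and returns α = CT/Ctox, using the numerically
    stable quadratic branch.  At Ctox = 0 the continuity limit
    1/(1 + kB·CALB) is returned; with kB = 0 or CALB = 0, α = 1.

    Parameters are in µmol/L (concentrations) and L/µmol (kB); inputs
    broadcast like numpy ufuncs.
    """
    ctox = np.asarray(total_toxin_conc, dtype=float)
    calb = np.asarray(albumin_conc, dtype=float)
    if np.any(ctox < 0):
        raise ValueError("total_toxin_conc must be >= 0")
    if np.any(calb < 0):
        raise ValueError("albumin_conc must be >= 0")
    if binding_constant < 0:
        raise ValueError("binding_constant must be >= 0")
    kb = float(binding_constant)
    if kb == 0.0:
        alpha = np.ones(np.broadcast_shapes(ctox.shape, calb.shape))
        return alpha if alpha.ndim else 1.0

    ctox_b, calb_b = np.broadcast_arrays(ctox, calb)
    b = 1.0 + kb * (calb_b - ctox_b)
    # CT = (-b + sqrt(b^2 + 4 kB Ctox)) / (2 kB); rationalized to avoid
    # cancellation when b > 0:
    disc = np.sqrt(b * b + 4.0 * kb * ctox_b)
    ct = 2.0 * ctox_b / (b + disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(ctox_b > 0, ct / np.where(ctox_b > 0, ctox_b, 1.0),
                         1.0 / (1.0 + kb * calb_b))
    return alpha if alpha.ndim else float(alpha)


def isotherm_loading(solid_liquid_conc, isotherm_slope):
    """Linear isotherm n_T = m′·C_TP.

    ``solid_liquid_conc`` C_TP in µmol/L, ``isotherm_slope`` m′ in L/g;
    returns the adsorbed loading n_T in µmol per g of solid.
    """
    if isotherm_slope <= 0:
        raise ValueError("isotherm_slope must be > 0")
    ctp = np.asarray(solid_liquid_conc, dtype=float)
    if np.any(ctp < 0):
        raise ValueError("solid_liquid_conc must be >= 0")
    out = isotherm_slope * ctp
    return out if out.ndim else float(out)


def isotherm_inverse(loading, isotherm_slope):
    """Invert the linear isotherm: C_TP = n_T / m′ (µmol/L from µmol/g)."""
    if isotherm_slope <= 0:
        raise ValueError("isotherm_slope must be > 0")
    nt = np.asarray(loading, dtype=float)
    if np.any(nt < 0):
        raise ValueError("loading must be >= 0")
    out = nt / isotherm_slope
    return out if out.ndim else float(out)


def void_fraction(dialysate_volume: float, adsorbent_mass: float,
                  particle_density: float) -> float:
    """Liquid volume fraction ε = VD / (MP/ρP + VD) of the dialysate
    compartment (VD in mL, MP in g, ρP in g/mL)."""
    if dialysate_volume <= 0:
        raise ValueError("dialysate_volume must be > 0")
    if adsorbent_mass < 0:
        raise ValueError("adsorbent_mass must be >= 0")
    if particle_density <= 0:
        raise ValueError("particle_density must be > 0")
    return dialysate_volume / (adsorbent_mass / particle_density + dialysate_volume)


def total_particle_surface(adsorbent_mass: float, particle_density: float,
                           particle_radius: float) -> float:
    """Total microsphere surface A_TOT = 3·MP/(ρP·rP) in cm².

    Monodisperse spheres of radius rP: surface/volume = 3/rP, solid
    volume = MP/ρP.  MP = 0 gives A_TOT = 0.
    """
    if adsorbent_mass < 0:
        raise ValueError("adsorbent_mass must be >= 0")
    if particle_density <= 0:
        raise ValueError("particle_density must be > 0")
    if particle_radius <= 0:
        raise ValueError("particle_radius must be > 0")
    return 3.0 * adsorbent_mass / (particle_density * particle_radius)
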