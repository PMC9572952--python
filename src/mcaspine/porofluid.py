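"""Interstitial-fluid state and Biot coupling on the element network.

Each element carries a pore fluid described by its current density ``rho``
(the conserved quantity is the fluid mass ``rho * phi * V``), linked to the
pore pressure by a linear equation of state

    rho(P) = rho0 * (1 + (P - P0) / K_fl).

Fluid moves between bonded elements down the density (pressure) gradient by
Darcy filtration on the element-centre network, with a two-point flux and
the harmonic-mean interface permeability; there is no transfer out of an
element whose density is at or below the equilibrium value ``rho0``.

Skeleton strain couples in two ways: a volumetric strain increment changes
the pore volume and recompresses the resident fluid (raising ``P_pore``),
and the pore-pressure increment reduces the effective stress carried by the
solid through the Biot ratio ``a`` (see :mod:`mcaspine.core`).

The coupled time stepping lives in :mod:`mcaspine._kernels`; the functions
here are the module's reference forms, also used directly on small fixtures.
"""

from __future__ import annotations

import numpy as np

from .errors import NotAvailableError, PhysicalLimitError, StabilityError
from .materials import FluidSpec, Material

__all__ = [
    "eos_density",
    "eos_pressure",
    "couple_pore_pressure",
    "update_porosity_permeability",
    "fluid_solid_strain_source",
    "filtration_step",
    "undrained_pressure_rise",
    "consolidation_coefficient",
    "terzaghi_profile",
]


def eos_density(P_pore, fluid: FluidSpec):
    """rho(P) = rho0 (1 + (P - P0)/K_fl)."""
    return fluid.rho0 * (1.0 + (np.asarray(P_pore, dtype=float) - fluid.P0) / fluid.K_fl)


def eos_pressure(rho, fluid: FluidSpec):
    """Invert the linear EOS: P = P0 + K_fl (rho/rho0 - 1)."""
    return fluid.P0 + fluid.K_fl * (np.asarray(rho, dtype=float) / fluid.rho0 - 1.0)


def couple_pore_pressure(mat: Material, dP_pore: float) -> float:
    """Normal-force increment correction (per unit interaction area) from a
    pore-pressure change of the element: -a * dP_pore.

    A uniform normal bond stress homogenizes 1:1 into the element mean
    stress, so this weight places exactly the Biot effective-stress
    reduction -a dP_pore on the diagonal of the total stress.  The
    constitutive volumetric feedback acts on the effective (skeleton)
    stress, which excludes this term.  Vanishes in the
    incompressible-skeleton limit a = 0; tangential forces are unaffected.
    """
    return -mat.a * dP_pore


def update_porosity_permeability(mat: Material, evol):
    """Porosity and permeability at volumetric strain ``evol``.

    Solid-volume conservation gives phi = 1 - (1 - phi0)/(1 + evol); the
    permeability follows the channel law k = phi * d_ch**2.
    """
    evol = np.asarray(evol, dtype=float)
    if np.any(mat.phi0 + evol <= 0.0):
        raise PhysicalLimitError(
            f"pore space exhausted: volumetric strain {np.min(evol):g} collapses "
            f"porosity {mat.phi0}"
        )
    phi = 1.0 - (1.0 - mat.phi0) / (1.0 + evol)
    if np.any(phi <= 0.0):
        raise PhysicalLimitError("porosity would become non-positive")
    k = phi * mat.d_ch**2
    return phi, k


def fluid_solid_strain_source(mat: Material, rho, evol_old, evol_new):
    """Recompression of the resident fluid by a pore-volume change.

    V_pore is proportional to (phi0 + evol); with the fluid mass held fixed,
    rho_new = rho_old * V_pore_old / V_pore_new.  Exactly reversible.
    """
    if mat.phi0 + np.min(np.asarray(evol_new)) <= 0.0:
        raise PhysicalLimitError("pore space exhausted")
    return np.asarray(rho, dtype=float) * (mat.phi0 + evol_old) / (mat.phi0 + evol_new)


def undrained_pressure_rise(mat: Material, fluid: FluidSpec, evol: float) -> float:
    """Closed-form pore-pressure rise of a single closed element subjected to
    an instantaneous volumetric strain (one-element undrained response)."""
    rho = fluid_solid_strain_source(mat, fluid.rho0, 0.0, evol)
    return float(eos_pressure(rho, fluid)) - fluid.P0


def filtration_step(rho, k, phi, r_ij, S_ij, pairs, fluid: FluidSpec, dt, V):
    """One explicit finite-volume filtration update on a pair network.

    ``pairs`` is an (M, 2) int array; fluxes are antisymmetric by
    construction so total fluid mass is conserved exactly.  Raises if ``dt``
    exceeds the explicit diffusion limit.  Returns the updated density array.
    """
    rho = np.asarray(rho, dtype=float).copy()
    k = np.asarray(k, dtype=float)
    phi = np.asarray(phi, dtype=float)
    pairs = np.asarray(pairs)
    r_ij = np.broadcast_to(np.asarray(r_ij, dtype=float), (len(pairs),))
    S_ij = np.broadcast_to(np.asarray(S_ij, dtype=float), (len(pairs),))

    dt_lim = 0.25 * r_ij.min() ** 2 * phi.min() * fluid.eta / (fluid.K_fl * max(k.max(), 1e-300))
    if dt > dt_lim and k.max() > 0:
        raise StabilityError(
            f"filtration dt = {dt:g} s exceeds the explicit limit {dt_lim:g} s; "
            f"sub-cycle by a factor of at least {int(np.ceil(dt / dt_lim))}"
        )
    mass = rho * phi * V
    for (i, j), r, S in zip(pairs, r_ij, S_ij):
        donor = i if rho[i] > rho[j] else j
        if rho[donor] <= fluid.rho0:
            continue
        if k[i] + k[j] == 0:
            continue
        kh = 2.0 * k[i] * k[j] / (k[i] + k[j])
        dm = fluid.K_fl * (kh / fluid.eta) * S / r * (rho[j] - rho[i]) * dt
        mass[i] += dm
        mass[j] -= dm
        rho[i] = mass[i] / (phi[i] * V)
        rho[j] = mass[j] / (phi[j] * V)
    return rho


def consolidation_coefficient(mat: Material, fluid: FluidSpec,
                              geometry: str = "column") -> float:
    """Effective consolidation (pressure-diffusion) coefficient of the model.

    The storage per unit pressure combines fluid compressibility with the
    skeleton's effective-stress compliance under constant total stress:
    c_v = k0 / (eta * S).  The compliance term depends on the element
    coordination, because the energy-consistent pore force scales with
    1/nb: for the 1 x 1 x n verification column (two bonds per element,
    pore-force weight three times the bulk value) force balance at zero
    total stress gives ev = 9 a P / (2G), hence S = phi0/K_fl + 9a/(2G);
    for a full-coordination bulk S = phi0/K_fl + a/K.
    """
    if geometry == "column":
        compliance = 9.0 * mat.a / (2.0 * mat.G)
    elif geometry == "bulk":
        compliance = mat.a / mat.K
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    storage = mat.phi0 / fluid.K_fl + compliance
    return mat.k0 / (fluid.eta * storage)


def terzaghi_profile(z_over_H, T, n_terms: int = 200):
    """Normalized one-dimensional consolidation solution p/p0(z, T).

    Drained boundary at z = 0, impermeable at z = H; T = c_v t / H^2.
    Classic Fourier series solution of the consolidation equation.
    """
    z = np.asarray(z_over_H, dtype=float)
    out = np.zeros_like(z)
    for m in range(n_terms):
        M = 0.5 * np.pi * (2 * m + 1)
        out += (2.0 / M) * np.sin(M * z) * np.exp(-(M**2) * T)
    return out


def require_fluid(fluid: FluidSpec | None) -> FluidSpec:
    if fluid is None:
        raise NotAvailableError("fluid fields requested but the fluid phase is disabled")
    return fluid
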