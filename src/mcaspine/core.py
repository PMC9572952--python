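"""Solid movable-cellular-automata kernel: pair network, forces, integration.

The material is an ensemble of equal-size bonded elements on a lattice.
Each bonded pair carries a normal force, a tangential force vector and a
rotational-resistance torque, updated incrementally (hypoelastic small-strain
form).  Pair strain increments are partitioned between dissimilar materials
by a 2x2 solve that enforces Newton's third law exactly; per-element stress
tensors are recovered by moment homogenization over the bonds, and their
mean feeds back into the volumetric part of the bond law so that the
emergent continuum response reproduces the input bulk and shear moduli.

Time integration is explicit velocity Verlet, with the step bounded by the
sound-transit time across one element.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .errors import (
    InvalidMaterialError,
    NumericalBlowupError,
    StabilityError,
)
from .geometry import Packing, REGION_NAMES
from .materials import FluidSpec, Material

__all__ = [
    "Numerics",
    "Ensemble",
    "compute_normal_strain",
    "partition_pair_increment",
    "compute_volume_force",
    "homogenize_stress",
    "compute_torque",
    "stable_timestep",
    "volume_coefficient",
]

_BOND_CUTOFF = 1.3  # bonds = initial contacts within this multiple of d


def volume_coefficient(K: float, G: float) -> float:
    """Coefficient A of the volume-dependent (many-body) force.

    The pair-local mean-stress coefficient is D = 1 - 2G/K; requiring the
    affine lattice response to reproduce the macroscopic bulk modulus fixes
    D + A = 1 - 2G/(3K), hence A = 4G/(3K).
    """
    return 4.0 * G / (3.0 * K)


def compute_normal_strain(q_ij: float, d_i: float) -> float:
    """Normal strain of element i in a pair: xi = (q - d/2) / (d/2)."""
    if d_i <= 0:
        raise InvalidMaterialError("element size must be positive")
    return (q_ij - d_i / 2.0) / (d_i / 2.0)


def partition_pair_increment(
    dr: float,
    dl_shear,
    mat_i: Material,
    mat_j: Material,
    dP_i: float = 0.0,
    dP_j: float = 0.0,
    d: float = 1.0,
    S: float = 1.0,
    dPpore_i: float = 0.0,
    dPpore_j: float = 0.0,
):
    """Split a pair displacement increment between two (possibly different)
    materials and return ``(dxi_ij, dxi_ji, dF_n, dF_tau)``.

    ``dP_i/dP_j`` are the mean-stress increments of the two elements
    (tension-positive); ``dPpore_*`` are pore-pressure increments entering
    through the Biot ratio.  For identical materials and zero volumetric
    terms the strain splits evenly: dxi_ij = dxi_ji = dr / d.
    """
    Gi, Gj = mat_i.G, mat_j.G
    if Gi <= 0 and Gj <= 0:
        raise InvalidMaterialError("pair with two zero-shear-modulus materials is singular")
    Di = 1.0 - 2.0 * Gi / mat_i.K
    Dj = 1.0 - 2.0 * Gj / mat_j.K
    Ai = volume_coefficient(mat_i.K, Gi)
    Aj = volume_coefficient(mat_j.K, Gj)
    pore = 0.5 * (mat_i.a * dPpore_i + mat_j.a * dPpore_j)
    hi = Di * dP_i + Ai * dP_j - pore
    hj = Dj * dP_j + Aj * dP_i - pore
    dxi_i = (4.0 * Gj * dr / d + hj - hi) / (2.0 * (Gi + Gj))
    dxi_j = 2.0 * dr / d - dxi_i
    dF_n = S * (2.0 * Gi * dxi_i + hi)
    dl = np.asarray(dl_shear, dtype=float)
    dF_tau = (4.0 * S / d) * (Gi * Gj / (Gi + Gj)) * dl
    return dxi_i, dxi_j, dF_n, dF_tau


def compute_volume_force(P_j, S_ij, n_ij, A: float) -> np.ndarray:
    """Many-body volume-dependent force F = -A * sum_j P_j S_ij n_ij.

    ``P_j`` are the neighbours' hydrostatic pressures (compression-positive).
    In the coupled solver this term is folded into the pair partition; the
    standalone form is kept as the module's reference implementation.
    """
    P = np.atleast_1d(np.asarray(P_j, dtype=float))
    S = np.broadcast_to(np.asarray(S_ij, dtype=float), P.shape)
    n = np.atleast_2d(np.asarray(n_ij, dtype=float))
    return -A * np.sum((P * S)[:, None] * n, axis=0)


def homogenize_stress(q_ij, n_ij, F_ij, V: float):
    """Average stress tensor of one element from its pair forces.

    sigma_ab = (1/V) sum_j q_ij sym(n_a F_b); returns (sigma, P) with P the
    compression-positive mean pressure -tr(sigma)/3.
    """
    q = np.atleast_1d(np.asarray(q_ij, dtype=float))
    n = np.atleast_2d(np.asarray(n_ij, dtype=float))
    F = np.atleast_2d(np.asarray(F_ij, dtype=float))
    outer = np.einsum("p,pa,pb->ab", q, n, F)
    sigma = (outer + outer.T) / 2.0 / V
    P = -np.trace(sigma) / 3.0
    return sigma, P


def compute_torque(q_ij: float, n_ij, F_pair, K_ij=(0.0, 0.0, 0.0)):
    """Total pair torques (M_ij on i, M_ji on j).

    Moment-arm term q (n x F) on both elements (force couple) plus the
    rotational-resistance torque K_ij (+K on i, -K on j), so the pair's net
    angular momentum input vanishes.
    """
    n = np.asarray(n_ij, dtype=float)
    F = np.asarray(F_pair, dtype=float)
    K = np.asarray(K_ij, dtype=float)
    arm = q_ij * np.cross(n, F)
    return arm + K, arm - K


def stable_timestep(
    materials,
    d: float,
    safety: float = 0.2,
    fluid: FluidSpec | None = None,
) -> float:
    """dt = safety * min over materials of d / c_p.

    c_p = sqrt((K + 4G/3) / rho_eff); with fluid on, the undrained bulk
    modulus K + a*K_fl/phi0 governs (the pore fluid stiffens the element)
    and the saturated density includes the fluid mass.
    """
    if isinstance(materials, Material):
        materials = [materials]
    elif isinstance(materials, Mapping):
        materials = list(materials.values())
    dt = np.inf
    for m in materials:
        K = m.K
        rho = m.rho_matrix
        if fluid is not None:
            K = K + m.a * fluid.K_fl / m.phi0
            rho = rho + m.phi0 * fluid.rho0
        cp = np.sqrt((K + 4.0 * m.G / 3.0) / rho)
        dt = min(dt, d / cp)
    return safety * dt


@dataclass
class Numerics:
    """Numerical controls for the explicit solver.

    safety        : fraction of the sound-transit stability limit used for dt
    damping       : non-viscous local damping coefficient (0 = off)
    vol_relax     : under-relaxation of the mean-stress increments feeding
                    the volumetric bond terms (stabilizes high-contrast
                    material interfaces; the accumulated force telescopes
                    to the same converged value)
    sample_every  : record the reaction force every this many steps
    smooth_window : rolling-mean window (in samples) for the stop condition
    mass_scaling  : quasi-static mass scaling: inflate the inertia of the
                    materials with the smallest stable time step until all
                    materials share the most permissive one (equilibrium
                    response unchanged; transients non-physical)
    clamp_lateral : pin the lateral velocity of boundary-layer particles
    """

    safety: float = 0.2
    damping: float = 0.1
    vol_relax: float = 1.0
    mass_scaling: bool = False
    sample_every: int = 50
    smooth_window: int = 100
    clamp_lateral: bool = True
    max_steps: int = 2_000_000


class Ensemble:
    """Mutable solver state for one packing + material assignment."""

    def __init__(
        self,
        packing: Packing,
        materials: Material | Mapping[str, Material],
        fluid: FluidSpec | None = None,
        numerics: Numerics | None = None,
    ):
        self.packing = packing
        self.fluid = fluid
        self.numerics = numerics or Numerics()
        n = len(packing)
        pos = packing.positions
        d = packing.d

        if isinstance(materials, Material):
            self.materials = {REGION_NAMES[m]: materials for m in np.unique(packing.material_id)}
        else:
            self.materials = dict(materials)
        region_names = [REGION_NAMES[m] for m in packing.material_id]
        mats = [self.materials[r] for r in region_names]

        def arr(attr):
            return np.array([getattr(m, attr) for m in mats], dtype=np.float64)

        self.G = arr("G")
        self.K = arr("K")
        self.biot = arr("a")
        self.phi0 = arr("phi0")
        self.dch2 = arr("d_ch") ** 2
        self.D = 1.0 - 2.0 * self.G / self.K
        self.A = 4.0 * self.G / (3.0 * self.K)
        rho_eff = arr("rho_matrix")
        if fluid is not None:
            rho_eff = rho_eff + self.phi0 * fluid.rho0

        self.d = d
        self.q = d / 2.0
        self.Vsite = packing.site_volume
        nb_bulk = 12 if packing.lattice == "fcc" else 6
        self.S = 3.0 * self.Vsite / (nb_bulk * self.q)

        self.pos = pos.copy()
        self.vel = np.zeros((n, 3))
        self.omg = np.zeros((n, 3))
        self.frc = np.zeros((n, 3))
        self.trq = np.zeros((n, 3))
        self.fext = np.zeros((n, 3))
        self.mass = rho_eff * self.Vsite
        self.inert = 0.4 * self.mass * (d / 2.0) ** 2
        self.bc = packing.boundary_id.astype(np.int8).copy()

        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=_BOND_CUTOFF * d, output_type="ndarray").reshape(-1, 2)
        self.pi = np.ascontiguousarray(pairs[:, 0], dtype=np.int64)
        self.pj = np.ascontiguousarray(pairs[:, 1], dtype=np.int64)
        dvec = pos[self.pj] - pos[self.pi]
        self.rprev = np.sqrt(np.sum(dvec**2, axis=1))
        m = len(self.pi)
        self.fn = np.zeros(m)
        self.ft = np.zeros((m, 3))
        self.ktq = np.zeros((m, 3))
        self.xi_i = np.zeros(m)
        self.xi_j = np.zeros(m)
        self.xg_i = np.zeros(m)
        self.xg_j = np.zeros(m)
        self.sxi = np.zeros(n)
        self.nvec = np.zeros((m, 3))
        self.nb = np.bincount(
            np.concatenate([self.pi, self.pj]), minlength=n
        ).astype(np.float64)
        self.nb[self.nb == 0] = 1.0

        self.sig = np.zeros((n, 6))
        self.sigm = np.zeros(n)
        self.dsigm = np.zeros(n)

        # fluid state (allocated regardless so the kernel signature is stable)
        self.drained = np.zeros(n, dtype=np.bool_)
        self.evol = np.zeros(n)
        self.phi = self.phi0.copy()
        self.kperm = self.phi0 * self.dch2
        if fluid is not None:
            self.rho_f = np.full(n, fluid.rho0)
            self.Pp = np.full(n, fluid.P0)
            self.mfl = fluid.rho0 * self.phi0 * self.Vsite
        else:
            self.rho_f = np.zeros(n)
            self.Pp = np.zeros(n)
            self.mfl = np.zeros(n)
        self.dPp = np.zeros(n)

        self.clock = np.zeros(2)  # [t, u]
        if self.numerics.mass_scaling and len(self.materials) > 1:
            limits = {
                name: stable_timestep(mat, d, 1.0, fluid) * self._material_margin(mat, fluid)
                for name, mat in self.materials.items()
            }
            target = max(limits.values())
            for name, mat in self.materials.items():
                fac = (target / limits[name]) ** 2
                if fac > 1.0:
                    sel = np.array([rn == name for rn in region_names])
                    self.mass[sel] *= fac
                    self.inert[sel] *= fac
            self.dt = self.numerics.safety * target
        else:
            self.dt = stable_timestep(self.materials, d, self.numerics.safety, fluid) \
                * self._stability_margin(fluid)
        self.n_sub = self._filtration_subcycles()

    # ------------------------------------------------------------------
    def _stability_margin(self, fluid) -> float:
        """Extra time-step margin below the acoustic limit.

        The lagged mean-stress feedback of the volumetric bond terms (gain
        D + A -> 1 as nu -> 0.5) tightens the stable step by roughly
        (2G/(3K))^(1/2) per material; the very stiff in-step pore response
        costs another factor ~2 and steepens the exponent to 3/4 when the
        fluid is on.  Calibrated on homogeneous saturated/dry lattices of
        all tissue presets.
        """
        return min(self._material_margin(m, fluid) for m in self.materials.values())

    @staticmethod
    def _material_margin(mat, fluid) -> float:
        expo = 0.75 if fluid is not None else 0.5
        fac = (2.0 * mat.G / (3.0 * mat.K)) ** expo
        return float(min(fac, 1.0)) * (0.5 if fluid is not None else 1.0)

    def _filtration_subcycles(self) -> int:
        """Explicit-diffusion subcycling factor for the filtration step."""
        if self.fluid is None:
            return 1
        kmax = float(np.max(self.kperm))
        if kmax <= 0:
            return 1
        phimin = float(np.min(self.phi0))
        # explicit-diffusion limit for the bare density diffusivity K_fl*k/(phi*eta)
        dtf = 0.25 * self.rprev.min() ** 2 * phimin * self.fluid.eta / (self.fluid.K_fl * kmax)
        return max(1, int(np.ceil(self.dt / dtf)))

    @property
    def n_particles(self) -> int:
        return len(self.pos)

    @property
    def n_pairs(self) -> int:
        return len(self.pi)

    @property
    def t(self) -> float:
        return float(self.clock[0])

    @property
    def u(self) -> float:
        return float(self.clock[1])

    def fluid_mass_total(self) -> float:
        return float(np.sum(self.mfl))

    def set_drained(self, mask) -> None:
        self.drained[:] = False
        self.drained[mask] = True

    def set_pore_pressure(self, P) -> None:
        """Initialize pore pressure (and the consistent fluid density/mass)."""
        if self.fluid is None:
            raise InvalidMaterialError("fluid is disabled for this ensemble")
        fl = self.fluid
        P = np.broadcast_to(np.asarray(P, dtype=float), self.Pp.shape)
        self.Pp[:] = P
        self.rho_f[:] = fl.rho0 * (1.0 + (P - fl.P0) / fl.K_fl)
        self.mfl[:] = self.rho_f * (self.phi0 + self.evol) * self.Vsite
        self.dPp[:] = 0.0

    # ------------------------------------------------------------------
    def run_until(
        self,
        target_force: float,
        v_target: float = 0.0,
        ramp_time: float = 0.0,
        max_steps: int | None = None,
        max_samples: int | None = None,
        stop_on_bottom: bool = True,
    ):
        """Drive the top layer and integrate until the smoothed reaction force
        reaches ``target_force``; returns (status, samples dict)."""
        num = self.numerics
        max_steps = max_steps if max_steps is not None else num.max_steps
        if max_samples is None:
            max_samples = max_steps // num.sample_every + 2
        out_t = np.empty(max_samples)
        out_u = np.empty(max_samples)
        out_ftop = np.empty(max_samples)
        out_fbot = np.empty(max_samples)
        fl = self.fluid
        status, nsteps, nsamp = _kernels.run_until(
            self.pos, self.vel, self.omg, self.frc, self.trq, self.fext,
            self.mass, self.inert, self.bc,
            self.pi, self.pj, self.rprev, self.fn, self.ft, self.ktq,
            self.xi_i, self.xi_j, self.xg_i, self.xg_j, self.sxi, self.nvec,
            self.G, self.D, self.A, self.biot,
            self.sig, self.sigm, self.dsigm,
            fl is not None, self.drained, self.nb, self.mfl, self.rho_f, self.Pp,
            self.dPp, self.evol, self.phi, self.kperm, self.phi0, self.dch2,
            fl.K_fl if fl else 0.0, fl.rho0 if fl else 1.0,
            fl.P0 if fl else 0.0, fl.eta if fl else 1.0, self.n_sub,
            self.d, self.S, self.q, self.Vsite, self.dt,
            num.damping, num.vol_relax, num.clamp_lateral,
            v_target, ramp_time, target_force, max_steps,
            self.clock,
            num.sample_every, num.smooth_window, stop_on_bottom,
            out_t, out_u, out_ftop, out_fbot,
        )
        if status == _kernels.STATUS_NAN:
            bad = np.where(~np.isfinite(self.vel).all(axis=1) | ~np.isfinite(self.pos).all(axis=1))[0]
            first = int(bad[0]) if len(bad) else -1
            raise NumericalBlowupError(
                f"non-finite state during integration; first offending particle: {first}"
            )
        samples = {
            "t": out_t[:nsamp].copy(),
            "u": out_u[:nsamp].copy(),
            "F_top": out_ftop[:nsamp].copy(),
            "F_bot": out_fbot[:nsamp].copy(),
        }
        return status, samples

    def step(self, n: int = 1) -> None:
        """Advance n plain steps (no drive, no stop condition)."""
        self.run_until(target_force=np.inf, v_target=0.0, max_steps=n)

    # ------------------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> Path:
        """Exact-round-trip HDF5 state checkpoint."""
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            for name in ("pos", "vel", "omg", "frc", "trq", "rprev", "fn", "ft",
                         "ktq", "xi_i", "xi_j", "xg_i", "xg_j", "sig", "sigm",
                         "dsigm", "mfl", "rho_f", "Pp", "dPp", "evol", "clock"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["t"] = self.t
        return path

    def load_checkpoint(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "r") as f:
            for name in ("pos", "vel", "omg", "frc", "trq", "rprev", "fn", "ft",
                         "ktq", "xi_i", "xi_j", "xg_i", "xg_j", "sig", "sigm",
                         "dsigm", "mfl", "rho_f", "Pp", "dPp", "evol", "clock"):
                getattr(self, name)[...] = f[name][...]
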