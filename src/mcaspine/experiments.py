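"""Experiment drivers: ramped-velocity compression, stiffness extraction,
discretization convergence, loading-rate sensitivity and disc-degeneration
scenarios.

Loading emulates a quasi-static compression test: the top particle layer is
driven downward at a velocity ramped from zero to ``v_target`` and held
constant; the bottom layer is fixed; the run stops when the smoothed
reaction force on the driven layer reaches ``stop_force``.  Stiffness is the
least-squares slope of the force-displacement curve over its final portion,
reported in N/mm.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .core import Ensemble, Numerics, stable_timestep
from .errors import InsufficientDataError, McaSpineError
from .geometry import MM, Packing, SegmentRecipe, build_segment
from .materials import (
    DegenerationMode,
    DegenerationStage,
    FluidSpec,
    Material,
    load_presets,
)
from .postprocess import (
    FieldSnapshot,
    dorsal_shift_metric,
    intradiscal_pressure_stats,
    locate_pore_pressure_maximum,
)

__all__ = [
    "LoadingProtocol",
    "RunResult",
    "run_compression",
    "extract_stiffness",
    "convergence_study",
    "rate_study",
    "degeneration_study",
    "measure_uniaxial_modulus",
    "terzaghi_column",
]


@dataclass(frozen=True)
class LoadingProtocol:
    """Ramped-velocity boundary drive with a target-force stop condition.

    v_target   : constant axial speed after the ramp, m/s
    stop_force : reaction-force level that ends the run, N
    ramp_time  : linear ramp duration, s; None selects ten fast-wave transit
                 times of the model height
    snapshot_forces : reaction-force levels at which field snapshots are taken
    """

    v_target: float = 0.1
    stop_force: float = 500.0
    ramp_time: float | None = None
    snapshot_forces: tuple[float, ...] = ()
    max_steps: int = 2_000_000
    measure: str = "bottom"  # force channel for stop/stiffness: the
    # transmitted (fixed-plate) force is free of the driven plate's
    # inertial overburden; "top" selects the driven-layer sum
    average_window_s: float = 0.0  # if > 0, append a final snapshot whose
    # stress/pore fields are averaged over this much additional loading
    # time (suppresses elastic ringing in centroid-type metrics)

    def __post_init__(self):
        if self.v_target <= 0:
            raise McaSpineError("loading speed must be positive")
        if self.stop_force < 0:
            raise McaSpineError("stop force must be non-negative")


@dataclass
class RunResult:
    """Sampled force-displacement curve plus snapshots and metrics."""

    t: np.ndarray
    u: np.ndarray          # m
    F: np.ndarray          # N, driven (top) layer
    F_bot: np.ndarray      # N, fixed (bottom) layer
    snapshots: list[FieldSnapshot] = field(default_factory=list)
    status: int = 0
    metrics: dict = field(default_factory=dict)

    @property
    def reached_target(self) -> bool:
        return self.status == _kernels.STATUS_TARGET


def _auto_ramp(ensemble: Ensemble) -> float:
    """Ten transit times of the fastest elastic wave across the model height."""
    z = ensemble.pos[:, 2]
    height = float(z.max() - z.min())
    cp_max = ensemble.d * ensemble.numerics.safety / ensemble.dt
    return 10.0 * height / cp_max


def run_compression(
    packing: Packing,
    materials: Material | dict[str, Material],
    protocol: LoadingProtocol,
    fluid: FluidSpec | None = None,
    numerics: Numerics | None = None,
) -> RunResult:
    """Compress a tagged packing until the stop force is reached."""
    if not np.any(packing.boundary_id == 2) or not np.any(packing.boundary_id == 1):
        raise McaSpineError("packing must have tagged driven and fixed boundary layers")
    wall0 = time.perf_counter()
    ens = Ensemble(packing, materials, fluid=fluid, numerics=numerics)
    ramp = protocol.ramp_time if protocol.ramp_time is not None else _auto_ramp(ens)

    targets = sorted(set(f for f in protocol.snapshot_forces if f < protocol.stop_force))
    targets.append(protocol.stop_force)

    chunks: list[dict] = []
    status = _kernels.STATUS_TARGET
    snapshots: list[FieldSnapshot] = []
    steps_left = protocol.max_steps
    t_prev = 0.0
    for tgt in targets:
        status, samples = ens.run_until(
            target_force=tgt,
            v_target=protocol.v_target,
            ramp_time=ramp,
            max_steps=steps_left,
            stop_on_bottom=(protocol.measure == "bottom"),
        )
        chunks.append(samples)
        steps_left = max(steps_left - int(round((ens.t - t_prev) / ens.dt)), 0)
        t_prev = ens.t
        key = "F_bot" if protocol.measure == "bottom" else "F_top"
        F_now = samples[key][-1] if len(samples[key]) else 0.0
        snapshots.append(FieldSnapshot.from_ensemble(ens, F=F_now))
        if status != _kernels.STATUS_TARGET or steps_left == 0:
            break

    if status == _kernels.STATUS_TARGET and protocol.average_window_s > 0:
        n_sub = 8
        sub_steps = max(int(protocol.average_window_s / ens.dt / n_sub), 1)
        sig_acc = np.zeros_like(ens.sig)
        pp_acc = np.zeros_like(ens.Pp)
        for _ in range(n_sub):
            ens.run_until(target_force=np.inf, v_target=protocol.v_target,
                          ramp_time=ramp, max_steps=sub_steps)
            sig_acc += ens.sig
            pp_acc += ens.Pp
        snap = FieldSnapshot.from_ensemble(ens, F=snapshots[-1].F)
        snap.sigma = sig_acc / n_sub
        if fluid is not None:
            snap.P_pore = pp_acc / n_sub
        snap.extra["averaged"] = True
        snapshots.append(snap)

    result = RunResult(
        t=np.concatenate([c["t"] for c in chunks]),
        u=np.concatenate([c["u"] for c in chunks]),
        F=np.concatenate([c["F_top"] for c in chunks]),
        F_bot=np.concatenate([c["F_bot"] for c in chunks]),
        snapshots=snapshots,
        status=status,
    )
    if status == _kernels.STATUS_PORE_COLLAPSE:
        raise McaSpineError("pore collapse: porosity exhausted during loading")
    result.metrics = {
        "stop_force_N": protocol.stop_force,
        "v_target_m_per_s": protocol.v_target,
        "ramp_time_s": ramp,
        "reached_target": bool(result.reached_target),
        "n_particles": ens.n_particles,
        "n_pairs": ens.n_pairs,
        "dt_s": ens.dt,
        "final_force_N": float((result.F_bot if protocol.measure == "bottom" else result.F)[-1]) if len(result.F) else 0.0,
        "final_displacement_mm": float(result.u[-1] / MM) if len(result.u) else 0.0,
        "wall_time_s": time.perf_counter() - wall0,
    }
    try:
        Fm = result.F_bot if protocol.measure == "bottom" else result.F
        result.metrics["stiffness_N_per_mm"] = extract_stiffness((result.u, Fm))
        result.metrics["secant_N_per_mm"] = (
            float(Fm[-1] / (result.u[-1] / MM)) if result.u[-1] > 0 else float("nan")
        )
    except InsufficientDataError:
        pass
    return result


def extract_stiffness(curve, window: float = 0.2, min_samples: int = 10) -> float:
    """Least-squares slope of the final ``window`` fraction of the
    force-displacement curve, N/mm.

    ``curve`` is a RunResult or a (u_m, F_N) pair of arrays.
    """
    if isinstance(curve, RunResult):
        u, F = curve.u, curve.F
    else:
        u, F = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    if len(u) < min_samples:
        raise InsufficientDataError(f"need at least {min_samples} samples, got {len(u)}")
    u_mm = u / MM
    span = u_mm[-1] - u_mm[0]
    sel = u_mm >= u_mm[-1] - window * span
    if np.sum(sel) < min_samples:
        sel = np.zeros(len(u_mm), dtype=bool)
        sel[-min_samples:] = True
    slope = np.polyfit(u_mm[sel], F[sel], 1)[0]
    return float(slope)


def convergence_study(
    recipe: SegmentRecipe,
    sizes_mm,
    protocol: LoadingProtocol,
    materials: dict[str, Material] | None = None,
    fluid: FluidSpec | None = None,
    numerics: Numerics | None = None,
) -> dict:
    """Stiffness versus automaton size at fixed recipe and protocol.

    Returns {"sizes_mm", "stiffness_N_per_mm", "scatter"} with
    scatter = (max - min) / mean over the size ladder.
    """
    if materials is None:
        materials, _ = load_presets("healthy", "healthy")
    sizes = sorted(float(s) for s in sizes_mm)
    stiff = []
    for d in sizes:
        packing = build_segment(replace(recipe, automaton_size=d))
        res = run_compression(packing, materials, protocol, fluid=fluid, numerics=numerics)
        stiff.append(extract_stiffness(res))
    stiff = np.array(stiff)
    return {
        "sizes_mm": sizes,
        "stiffness_N_per_mm": stiff.tolist(),
        "scatter": float((stiff.max() - stiff.min()) / stiff.mean()) if len(stiff) else 0.0,
    }


def rate_study(
    packing_or_recipe,
    speeds=(0.1, 0.2, 1.0),
    protocol: LoadingProtocol | None = None,
    materials: dict[str, Material] | Material | None = None,
    fluid: FluidSpec | None = FluidSpec(),
    numerics: Numerics | None = None,
) -> dict:
    """Stiffness versus loading speed (saturated by default).

    Returns {"speeds_m_per_s", "stiffness_N_per_mm"} ordered by speed.
    """
    if protocol is None:
        protocol = LoadingProtocol()
    if isinstance(packing_or_recipe, SegmentRecipe):
        packing = build_segment(packing_or_recipe)
    else:
        packing = packing_or_recipe
    if materials is None:
        materials, _ = load_presets("healthy", "healthy")
    out = {"speeds_m_per_s": [], "stiffness_N_per_mm": []}
    for v in sorted(speeds):
        res = run_compression(
            packing, materials, replace(protocol, v_target=float(v)),
            fluid=fluid, numerics=numerics,
        )
        out["speeds_m_per_s"].append(float(v))
        out["stiffness_N_per_mm"].append(extract_stiffness(res))
    return out


def degeneration_study(
    mode: DegenerationMode | str,
    stages=(DegenerationStage.healthy, DegenerationStage.stage1, DegenerationStage.stage2),
    protocol: LoadingProtocol | None = None,
    recipe: SegmentRecipe | None = None,
    fluid: FluidSpec | None = FluidSpec(),
    numerics: Numerics | None = None,
    shift_quantiles=(0.8, 0.9, 0.95),
) -> dict:
    """Run the stage matrix for one degeneration mode and collect metrics.

    For every stage: intradiscal pressure statistics, the dorsal-shift
    metric at several quantiles, and the region hosting the pore-pressure
    maximum, all evaluated at the final (stop-force) snapshot.
    """
    mode = DegenerationMode(mode)
    if protocol is None:
        protocol = LoadingProtocol(stop_force=500.0)
    if recipe is None:
        recipe = SegmentRecipe()
    results = {}
    for stage in stages:
        stage = DegenerationStage(stage)
        materials, height_mm = load_presets(stage, mode)
        packing = build_segment(recipe.with_stage_height(height_mm))
        res = run_compression(packing, materials, protocol, fluid=fluid, numerics=numerics)
        snap = res.snapshots[-1]
        entry = {
            "disc_height_mm": height_mm,
            "stiffness_N_per_mm": res.metrics.get("stiffness_N_per_mm"),
            "intradiscal_pressure_MPa": intradiscal_pressure_stats(snap),
            "dorsal_shift_mm": {
                f"q{int(q * 100)}": dorsal_shift_metric(snap, q) for q in shift_quantiles
            },
        }
        if fluid is not None:
            region, coords = locate_pore_pressure_maximum(snap)
            entry["pore_pressure_max_region"] = region
            entry["pore_pressure_max_xyz_mm"] = (coords / MM).tolist()
        entry["run"] = res
        results[stage.value] = entry
    return {"mode": mode.value, "stages": results}


def measure_uniaxial_modulus(
    material: Material,
    L_mm: float = 10.0,
    d_mm: float = 1.0,
    strain: float = 0.006,
    fluid: FluidSpec | None = None,
    lattice: str = "fcc",
    damping: float = 0.3,
) -> dict:
    """Drained/saturated uniaxial-stress modulus of a homogeneous cube.

    Compresses an L x L x L cube between axially-driven plates (lateral
    motion free) at a slow speed, measures the axial strain between two
    interior marker planes (quarter and three-quarter height, which removes
    platen end effects) and the transmitted force on the fixed plate, and
    returns the secant modulus.  The quasi-static quality is reported as
    the top/bottom force ratio.
    """
    from .geometry import pack_box, tag_boundaries

    L = L_mm * MM
    d = d_mm * MM
    packing = pack_box((L, L, L), d, lattice)
    packing = tag_boundaries(packing, 0.3 * d)
    num = Numerics(damping=damping, clamp_lateral=False,
                   sample_every=50, smooth_window=5)
    ens = Ensemble(packing, material, fluid=fluid, numerics=num)

    z0 = packing.positions[:, 2]
    zmin, zmax = z0.min(), z0.max()
    lo = np.abs(z0 - (zmin + 0.25 * (zmax - zmin))) < 0.4 * d
    hi = np.abs(z0 - (zmin + 0.75 * (zmax - zmin))) < 0.4 * d
    gauge0 = z0[hi].mean() - z0[lo].mean()
    midz = z0[np.argmin(np.abs(z0 - (zmin + zmax) / 2))]
    area = np.sum(np.abs(z0 - midz) < 1e-12) * d**2

    # drive slowly relative to the fast wave; ramp over 1000 steps
    cp = ens.d * 1.0 / stable_timestep(ens.materials, ens.d, 1.0, fluid)
    v = 5e-5 * cp
    n_steps = int(strain * (zmax - zmin) / (v * ens.dt))
    status, s = ens.run_until(target_force=np.inf, v_target=v,
                              ramp_time=1000 * ens.dt, max_steps=n_steps)
    gauge1 = ens.pos[hi, 2].mean() - ens.pos[lo, 2].mean()
    eps = (gauge0 - gauge1) / gauge0
    sigma = s["F_bot"][-1] / area
    return {
        "E_eff": float(sigma / eps),
        "strain": float(eps),
        "force_balance": float(s["F_bot"][-1] / s["F_top"][-1]),
        "n_particles": ens.n_particles,
    }


def terzaghi_column(
    material: Material,
    fluid: FluidSpec | None = None,
    n: int = 20,
    d_mm: float = 0.5,
    p0: float = 1.0e5,
    fourier_times=(0.1, 0.5, 1.0),
) -> dict:
    """One-dimensional consolidation of a saturated 1 x 1 x n column.

    The column starts with a uniform excess pore pressure ``p0``, the top
    element is drained (density pinned at the equilibrium value) and the
    bottom element is mechanically fixed; the pore pressure then decays by
    Darcy filtration toward the drained end.  Returns the numerical
    normalized profiles and their RMS error against the classic
    consolidation series at each Fourier time T = c_v t / H^2, with the
    model's own consolidation coefficient c_v = k0 / (eta (phi0/K_fl + a/K)).
    """
    from .geometry import Packing
    from .porofluid import consolidation_coefficient, terzaghi_profile

    fluid = fluid or FluidSpec()
    d = d_mm * MM
    pos = np.zeros((n, 3))
    pos[:, 2] = (np.arange(n) + 0.5) * d
    packing = Packing(pos, d, np.zeros(n, np.int8), np.zeros(n, np.int8), "sc")
    packing.boundary_id[0] = 1  # fixed bottom; free (but drained) top
    num = Numerics(damping=0.5, clamp_lateral=True, sample_every=10**6, smooth_window=5)
    ens = Ensemble(packing, material, fluid=fluid, numerics=num)
    ens.set_pore_pressure(p0)
    ens.set_drained(np.array([n - 1]))

    cv = consolidation_coefficient(material, fluid)
    H = (n - 0.5) * d  # drained cell centre to the no-flux face below cell 0
    zeta = (pos[n - 1, 2] - pos[: n - 1, 2]) / H

    out = {"c_v": cv, "H": H, "times": {}}
    t_prev = 0.0
    for T in fourier_times:
        t_target = T * H**2 / cv
        ens.run_until(np.inf, v_target=0.0,
                      max_steps=int(round((t_target - t_prev) / ens.dt)))
        t_prev = t_target
        p_num = ens.Pp[: n - 1] / p0
        p_ana = terzaghi_profile(zeta, T)
        out["times"][T] = {
            "profile": p_num.copy(),
            "analytic": p_ana,
            "rms": float(np.sqrt(np.mean((p_num - p_ana) ** 2))),
        }
    return out
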