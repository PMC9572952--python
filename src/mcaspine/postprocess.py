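"""Field extraction, disc metrics and standard-format writers.

Metrics are pure functions of :class:`FieldSnapshot` objects, so anything
reported in the JSON metrics can be recomputed from saved snapshots.
Pressure fields follow the compression-positive convention and are reported
in MPa; the dorsal (posterior) direction is -Y.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyRegionError, NotAvailableError
from .geometry import DISC_REGION_IDS, REGION_IDS, REGION_NAMES

MPA = 1e6

__all__ = [
    "FieldSnapshot",
    "hydrostatic_pressure",
    "von_mises",
    "intradiscal_pressure_stats",
    "dorsal_shift_metric",
    "locate_pore_pressure_maximum",
    "write_vtu",
    "read_vtu",
    "write_outputs",
]


def hydrostatic_pressure(sigma) -> np.ndarray:
    """Compression-positive mean pressure, MPa: P = -(sxx+syy+szz)/3.

    ``sigma`` is (N, 6) Voigt [xx, yy, zz, xy, xz, yz] in Pa (or a single
    3x3 tensor).
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 2 and sigma.shape == (3, 3):
        tr = np.trace(sigma)
        return -tr / 3.0 / MPA
    sigma = np.atleast_2d(sigma)
    return -(sigma[:, 0] + sigma[:, 1] + sigma[:, 2]) / 3.0 / MPA


def von_mises(sigma) -> np.ndarray:
    """Von Mises equivalent stress, MPa, from (N, 6) Voigt components."""
    s = np.atleast_2d(np.asarray(sigma, dtype=float))
    sxx, syy, szz, sxy, sxz, syz = (s[:, i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + sxz**2 + syz**2)
    ) / MPA


@dataclass
class FieldSnapshot:
    """Per-particle fields at one instant of a run."""

    t: float
    positions: np.ndarray          # (N, 3) m
    region_id: np.ndarray          # int8, REGION_IDS
    sigma: np.ndarray              # (N, 6) Pa, Voigt
    P_pore: np.ndarray | None = None   # Pa
    rho: np.ndarray | None = None      # kg/m^3
    phi: np.ndarray | None = None
    u: float = 0.0                 # driven-layer displacement, m
    F: float = 0.0                 # reaction force, N
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.positions)
        for name in ("region_id", "sigma"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"snapshot field {name} length mismatch")

    @property
    def pressure(self) -> np.ndarray:
        """Hydrostatic (compression-positive) pressure, MPa."""
        return hydrostatic_pressure(self.sigma)

    @property
    def von_mises(self) -> np.ndarray:
        return von_mises(self.sigma)

    def disc_mask(self) -> np.ndarray:
        return np.isin(self.region_id, list(DISC_REGION_IDS))

    @classmethod
    def from_ensemble(cls, ens, t=None, u=None, F=0.0) -> "FieldSnapshot":
        fluid_on = ens.fluid is not None
        return cls(
            t=ens.t if t is None else t,
            positions=ens.pos.copy(),
            region_id=ens.packing.material_id.copy(),
            sigma=ens.sig.copy(),
            P_pore=ens.Pp.copy() if fluid_on else None,
            rho=ens.rho_f.copy() if fluid_on else None,
            phi=ens.phi.copy() if fluid_on else None,
            u=ens.u if u is None else u,
            F=F,
        )


def intradiscal_pressure_stats(snapshot: FieldSnapshot) -> dict[str, float]:
    """(min, max, p95) of hydrostatic pressure over disc-tagged elements, MPa."""
    mask = snapshot.disc_mask()
    if not np.any(mask):
        raise EmptyRegionError("snapshot contains no disc-tagged elements")
    p = snapshot.pressure[mask]
    return {
        "min": float(np.min(p)),
        "max": float(np.max(p)),
        "p95": float(np.quantile(p, 0.95)),
    }


def dorsal_shift_metric(snapshot: FieldSnapshot, q: float = 0.9) -> float:
    """Posterior shift of the high-pressure region of the disc, mm.

    Y-centroid of disc elements whose hydrostatic pressure exceeds the
    q-quantile minus the Y-centroid of all disc elements; negative values
    mean the stress maxima sit dorsally (toward -Y) of the disc centre.
    """
    if not 0.0 < q < 1.0:
        raise ConfigError(f"quantile must be in (0, 1), got {q}")
    mask = snapshot.disc_mask()
    if not np.any(mask):
        raise EmptyRegionError("snapshot contains no disc-tagged elements")
    p = snapshot.pressure[mask]
    y = snapshot.positions[mask, 1]
    thresh = np.quantile(p, q)
    hot = p >= thresh
    return float((y[hot].mean() - y.mean()) / 1e-3)


_REGION_PRIORITY = (REGION_IDS["CEP"], REGION_IDS["NP"], REGION_IDS["AF"])


def locate_pore_pressure_maximum(snapshot: FieldSnapshot) -> tuple[str, np.ndarray]:
    """Region tag (CEP/NP/AF) hosting the maximum pore pressure in the disc.

    Ties are broken by region priority CEP > NP > AF, then by lowest element
    index.  Returns (region name, coordinates of the element).
    """
    if snapshot.P_pore is None:
        raise NotAvailableError("pore-pressure field not present (fluid disabled)")
    mask = snapshot.disc_mask()
    if not np.any(mask):
        raise EmptyRegionError("snapshot contains no disc-tagged elements")
    idx = np.where(mask)[0]
    p = snapshot.P_pore[idx]
    pmax = np.max(p)
    at_max = idx[p == pmax]
    for rid in _REGION_PRIORITY:
        cand = at_max[snapshot.region_id[at_max] == rid]
        if len(cand):
            winner = int(cand.min())
            return REGION_NAMES[rid], snapshot.positions[winner].copy()
    winner = int(at_max.min())
    return REGION_NAMES[int(snapshot.region_id[winner])], snapshot.positions[winner].copy()


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _snapshot_point_data(snap: FieldSnapshot) -> dict[str, np.ndarray]:
    data = {
        "region": snap.region_id.astype(np.int32),
        "pressure_MPa": snap.pressure,
        "von_mises_MPa": snap.von_mises,
        "sigma": snap.sigma,
    }
    if snap.P_pore is not None:
        data["P_pore_MPa"] = snap.P_pore / MPA
        data["rho_fluid"] = snap.rho
        data["phi"] = snap.phi
    return data


def write_vtu(path: str | Path, points: np.ndarray, point_data: dict) -> Path:
    """Minimal ASCII VTK-XML unstructured grid of vertex cells."""
    path = Path(path)
    n = len(points)

    def fmt(arr):
        arr = np.asarray(arr)
        flat = arr.reshape(n, -1)
        return "\n".join(" ".join(f"{v:.9g}" for v in row) for row in flat), flat.shape[1]

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{n}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        fmt(points)[0],
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(str(i) for i in range(n)),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(i + 1) for i in range(n)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("1" for _ in range(n)),
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        body, ncomp = fmt(arr)
        dtype = "Int32" if np.issubdtype(np.asarray(arr).dtype, np.integer) else "Float64"
        lines.append(
            f'<DataArray type="{dtype}" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">'
        )
        lines.append(body)
        lines.append("</DataArray>")
    lines += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


def read_vtu(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_vtu`."""
    root = ET.parse(path).getroot()
    piece = root.find("UnstructuredGrid/Piece")
    n = int(piece.get("NumberOfPoints"))

    def parse(elem):
        vals = np.fromstring(elem.text.replace("\n", " "), sep=" ")
        ncomp = int(elem.get("NumberOfComponents", "1"))
        arr = vals.reshape(n, ncomp) if ncomp > 1 else vals
        if elem.get("type", "").startswith("Int"):
            arr = arr.astype(np.int64)
        return arr

    points = parse(piece.find("Points/DataArray"))
    data = {e.get("Name"): parse(e) for e in piece.find("PointData")}
    return points, data


def write_outputs(results, out_dir: str | Path, config: dict | None = None, seed: int = 0) -> dict:
    """Write the standard output bundle for a run.

    ``results`` is a RunResult (see :mod:`mcaspine.experiments`).  Produces
    a CSV force-displacement curve, JSON metrics, a .vtu series with a .pvd
    index, and a run log.  Returns the metric dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    curve = pd.DataFrame({
        "t_s": results.t,
        "u_mm": results.u / 1e-3,
        "F_N": results.F,
        "F_bottom_N": results.F_bot,
    })
    curve.to_csv(out_dir / "force_displacement.csv", index=False)

    metrics = dict(results.metrics)
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))

    if results.snapshots:
        pvd = ['<?xml version="1.0"?>',
               '<VTKFile type="Collection" version="0.1"><Collection>']
        for i, snap in enumerate(results.snapshots):
            name = f"snapshot_{i:04d}.vtu"
            write_vtu(out_dir / name, snap.positions, _snapshot_point_data(snap))
            pvd.append(f'<DataSet timestep="{snap.t:.9g}" file="{name}"/>')
        pvd += ["</Collection></VTKFile>"]
        (out_dir / "snapshots.pvd").write_text("\n".join(pvd))

    log = {
        "seed": seed,
        "config": config or {},
        "wall_time_s": results.metrics.get("wall_time_s"),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return metrics
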