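"""Particle packings: primitive boxes and the parametric L4-L5 segment.

All automata share a single size ``d`` (the method uses equal-size discrete
elements).  Two lattices are supported:

* ``sc``  - simple cubic, spacing ``d`` (analytically countable, used in
  verification fixtures);
* ``fcc`` - face-centred cubic, nearest-neighbour distance ``d`` (the
  default: densest packing of equal spheres, 12 bonded neighbours in the
  bulk, per-site volume ``d**3/sqrt(2)``).

Coordinate convention: X lateral, Y anterior(+)/posterior(-), Z axial
(loading axis).  "Dorsal" is -Y.  The segment generator stacks, bottom to
top: lower vertebral body, CEP, disc core (NP ellipse inside an AF ring),
CEP, upper vertebral body.  Vertebral bodies are elliptic cylinders with a
mild waist, split into a cortical shell and a cancellous core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateGeometryError, ResolutionError

__all__ = ["Packing", "SegmentRecipe", "pack_box", "build_segment", "tag_boundaries"]

MM = 1e-3

REGION_IDS = {"cortical": 0, "cancellous": 1, "CEP": 2, "AF": 3, "NP": 4}
REGION_NAMES = {v: k for k, v in REGION_IDS.items()}
DISC_REGION_IDS = frozenset(REGION_IDS[n] for n in ("CEP", "AF", "NP"))
BOUNDARY_IDS = {"interior": 0, "bottom_fixed": 1, "top_driven": 2}
BOUNDARY_NAMES = {v: k for k, v in BOUNDARY_IDS.items()}


@dataclass
class Packing:
    """A packing of equal-size automata with region and boundary labels.

    positions : (N, 3) float64, metres
    d         : automaton size (nearest-neighbour spacing), metres
    material_id, boundary_id : int8 arrays over REGION_IDS / BOUNDARY_IDS
    lattice   : "fcc" or "sc"
    """

    positions: np.ndarray
    d: float
    material_id: np.ndarray
    boundary_id: np.ndarray
    lattice: str = "fcc"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.material_id = np.asarray(self.material_id, dtype=np.int8)
        self.boundary_id = np.asarray(self.boundary_id, dtype=np.int8)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise DegenerateGeometryError("positions must be (N, 3)")
        if len(self.material_id) != len(self.positions) or len(self.boundary_id) != len(self.positions):
            raise DegenerateGeometryError("label arrays must match positions in length")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def site_volume(self) -> float:
        """Space-filling volume per lattice site."""
        return self.d**3 / np.sqrt(2.0) if self.lattice == "fcc" else self.d**3

    def region_mask(self, *names: str) -> np.ndarray:
        ids = [REGION_IDS[n] for n in names]
        return np.isin(self.material_id, ids)

    def region_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.material_id == rid)) for name, rid in REGION_IDS.items()}

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "d": self.d,
                "material_tag": [REGION_NAMES[m] for m in self.material_id],
                "boundary_tag": [BOUNDARY_NAMES[b] for b in self.boundary_id],
            }
        )
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, lattice: str = "fcc") -> "Packing":
        df = pd.read_csv(path)
        return cls(
            positions=df[["x", "y", "z"]].to_numpy(),
            d=float(df["d"].iloc[0]),
            material_id=np.array([REGION_IDS[m] for m in df["material_tag"]], dtype=np.int8),
            boundary_id=np.array([BOUNDARY_IDS[b] for b in df["boundary_tag"]], dtype=np.int8),
            lattice=lattice,
        )


def _sc_sites(extents: np.ndarray, d: float) -> np.ndarray:
    counts = np.floor(extents / d + 1e-9).astype(int)
    axes = [d / 2.0 + d * np.arange(c) for c in counts]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def _fcc_sites(extents: np.ndarray, d: float) -> np.ndarray:
    # fcc as the even-parity sublattice of a cubic grid of spacing h = d/sqrt(2)
    h = d / np.sqrt(2.0)
    counts = np.floor((extents - h) / h + 1e-9).astype(int) + 1
    counts = np.maximum(counts, 1)
    idx = [np.arange(c) for c in counts]
    I, J, K = np.meshgrid(*idx, indexing="ij")
    parity = (I + J + K) % 2 == 0
    pts = np.column_stack([I[parity], J[parity], K[parity]]) * h + h / 2.0
    # centre the block inside the box
    span = (counts - 1) * h
    pts += (extents - span - h) / 2.0
    return pts


def pack_box(extents, d: float, lattice: str = "fcc") -> Packing:
    """Fill an axis-aligned box with lattice sites; deterministic for fixed inputs."""
    extents = np.asarray(extents, dtype=float)
    if np.any(extents < 2 * d):
        raise DegenerateGeometryError(
            f"box extents {extents} must each be at least 2*d = {2 * d:g}"
        )
    if lattice == "sc":
        pts = _sc_sites(extents, d)
    elif lattice == "fcc":
        pts = _fcc_sites(extents, d)
    else:
        raise ConfigError(f"unknown lattice {lattice!r}")
    n = len(pts)
    return Packing(pts, d, np.zeros(n, np.int8), np.zeros(n, np.int8), lattice)


@dataclass(frozen=True)
class SegmentRecipe:
    """Parametric description of the two-vertebra + disc model sample.

    Lengths in millimetres.  ``disc_height`` is the total disc thickness
    including both cartilaginous endplates and takes the values 10 / 8 / 5
    for the healthy and first/second-degree degenerated geometries.
    ``np_fraction`` is the fraction of disc cross-sectional area occupied
    by the nucleus; its centroid sits ``np_center_offset`` mm posterior of
    the disc centroid.
    """

    vb_width: float = 48.0
    vb_depth: float = 35.0
    vb_height: float = 28.0
    cortical_thickness: float = 1.0
    cep_thickness: float = 1.0
    disc_height: float = 10.0
    np_fraction: float = 0.4
    np_center_offset: float = 2.0
    automaton_size: float = 0.5
    waist: float = 0.05
    lattice: str = "fcc"

    def __post_init__(self) -> None:
        if not (0.25 <= self.automaton_size <= 2.0):
            raise ConfigError(
                f"automaton_size {self.automaton_size} mm outside the supported 0.25-2.0 mm range"
            )
        if self.disc_height <= 2 * self.cep_thickness:
            raise ConfigError("disc_height must exceed twice the endplate thickness")
        if not (0.0 <= self.np_fraction < 1.0):
            raise ConfigError("np_fraction must be in [0, 1)")

    def with_stage_height(self, disc_height_mm: float) -> "SegmentRecipe":
        return replace(self, disc_height=disc_height_mm)

    @property
    def total_height(self) -> float:
        return 2 * self.vb_height + self.disc_height

    def analytic_volumes_mm3(self) -> dict[str, float]:
        """Volumes of the recipe solids (no waisting), mm^3."""
        a, b = self.vb_width / 2, self.vb_depth / 2
        area = np.pi * a * b
        t = self.cortical_thickness
        inner = np.pi * (a - t) * (b - t)
        core_h = self.disc_height - 2 * self.cep_thickness
        vb_shell = (area - inner) * self.vb_height + 2 * inner * min(t, self.vb_height / 2)
        vb_inner_h = max(self.vb_height - 2 * t, 0.0)
        return {
            "cortical": 2 * ((area - inner) * self.vb_height + inner * (self.vb_height - vb_inner_h)),
            "cancellous": 2 * inner * vb_inner_h,
            "CEP": 2 * area * self.cep_thickness,
            "NP": area * self.np_fraction * core_h,
            "AF": area * (1 - self.np_fraction) * core_h,
        }


def build_segment(recipe: SegmentRecipe) -> Packing:
    """Generate the tagged particle packing of the spinal motion segment."""
    d = recipe.automaton_size
    for feature, thickness in (
        ("cortical_thickness", recipe.cortical_thickness),
        ("cep_thickness", recipe.cep_thickness),
    ):
        # one lattice plane per feature is the minimum meaningful resolution
        if thickness < 0.99 * d * (0.5 if recipe.lattice == "fcc" else 1.0):
            raise ResolutionError(
                f"automaton size {d} mm cannot resolve {feature} = {thickness} mm"
            )

    H = recipe.total_height
    extents = np.array([recipe.vb_width, recipe.vb_depth, H]) * MM
    box = pack_box(extents, d * MM, recipe.lattice)
    xyz = box.positions / MM  # work in mm
    x = xyz[:, 0] - recipe.vb_width / 2
    y = xyz[:, 1] - recipe.vb_depth / 2
    z = xyz[:, 2]

    a, b = recipe.vb_width / 2, recipe.vb_depth / 2
    z_vb1 = recipe.vb_height
    z_cep1 = z_vb1 + recipe.cep_thickness
    z_core = z_vb1 + recipe.disc_height - recipe.cep_thickness
    z_cep2 = z_vb1 + recipe.disc_height
    z_top = H

    in_vb1 = z < z_vb1
    in_vb2 = z >= z_cep2
    in_cep = (~in_vb1) & (~in_vb2) & ((z < z_cep1) | (z >= z_core))
    in_core = (~in_vb1) & (~in_vb2) & ~in_cep

    # waisted elliptic cross-section inside the vertebral bodies
    scale = np.ones_like(z)
    for lo, hi in ((0.0, z_vb1), (z_cep2, z_top)):
        m = (z >= lo) & (z < hi) if hi < z_top else (z >= lo) & (z <= hi)
        scale[m] = 1.0 - recipe.waist * np.sin(np.pi * (z[m] - lo) / (hi - lo))
    r2 = (x / (a * scale)) ** 2 + (y / (b * scale)) ** 2
    inside = r2 <= 1.0

    keep = inside
    xyzk, xk, yk, zk = xyz[keep], x[keep], y[keep], z[keep]
    r2k = r2[keep]
    scalek = scale[keep]
    in_vb = (zk < z_vb1) | (zk >= z_cep2)
    in_cepk = in_cep[keep]
    in_corek = in_core[keep]

    material = np.full(len(xyzk), -1, dtype=np.int8)

    # vertebral bodies: cortical shell (lateral surface band + axial end bands)
    t = recipe.cortical_thickness
    # lateral distance to the ellipse boundary, approximated along the radial
    # ray: a point at normalized radius rho lies about (1 - rho) * r_local from
    # the surface, r_local being the ellipse radius along that ray
    rho = np.sqrt(np.maximum(r2k, 1e-16))
    r_local = np.hypot(xk, yk) / np.maximum(rho, 1e-12)
    lateral_depth = (1.0 - rho) * np.maximum(r_local, min(a, b) * scalek)

    axial_depth = np.minimum.reduce([
        zk, np.abs(zk - z_vb1), np.abs(zk - z_cep2), z_top - zk
    ])
    shell = in_vb & ((lateral_depth < t) | (axial_depth < t))
    material[in_vb & shell] = REGION_IDS["cortical"]
    material[in_vb & ~shell] = REGION_IDS["cancellous"]
    material[in_cepk] = REGION_IDS["CEP"]

    # disc core: NP ellipse (area fraction np_fraction, posterior offset) in AF ring
    s = np.sqrt(recipe.np_fraction)
    a_np, b_np = a * s, b * s
    y0 = -recipe.np_center_offset
    in_np = in_corek & (((xk / a_np) ** 2 + ((yk - y0) / b_np) ** 2) <= 1.0) if s > 0 else np.zeros(len(xyzk), bool)
    material[in_corek & ~in_np] = REGION_IDS["AF"]
    material[in_corek & in_np] = REGION_IDS["NP"]

    packing = Packing(
        positions=xyzk * MM,
        d=d * MM,
        material_id=material,
        boundary_id=np.zeros(len(xyzk), np.int8),
        lattice=recipe.lattice,
        meta={"recipe": recipe, "height_mm": H},
    )

    counts = packing.region_counts()
    empty = [name for name in ("cortical", "cancellous", "CEP", "AF") if counts[name] == 0]
    if recipe.np_fraction > 0 and counts["NP"] == 0:
        empty.append("NP")
    if empty:
        raise ResolutionError(
            f"automaton size {d} mm leaves region(s) {empty} empty; "
            "refine the packing or thicken the feature"
        )
    return tag_boundaries(packing, layer_thickness=d * MM)


def tag_boundaries(packing: Packing, layer_thickness: float) -> Packing:
    """Tag the top layer as velocity-driven and the bottom layer as fixed."""
    if len(packing) == 0:
        raise DegenerateGeometryError("cannot tag an empty packing")
    z = packing.positions[:, 2]
    zmin, zmax = z.min(), z.max()
    eps = 1e-12 + 1e-9 * packing.d
    if layer_thickness <= eps:
        # degenerate request: only the particles exactly on the extreme planes
        bottom = z <= zmin + eps
        top = z >= zmax - eps
    else:
        # half-open band [zmin, zmin + layer) so that layer = d on a simple
        # cubic lattice selects exactly one plane of particles
        bottom = z < zmin + layer_thickness - eps
        top = z > zmax - layer_thickness + eps
    if np.any(bottom & top):
        raise DegenerateGeometryError(
            "top and bottom boundary layers overlap; the model is too short"
        )
    boundary = np.zeros(len(packing), np.int8)
    boundary[bottom] = BOUNDARY_IDS["bottom_fixed"]
    boundary[top] = BOUNDARY_IDS["top_driven"]
    packing.boundary_id = boundary
    return packing
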