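"""Shared fixtures: tissue presets, small packings, quick simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

import mcaspine as mca
from mcaspine.core import Ensemble, Numerics
from mcaspine.geometry import Packing, SegmentRecipe, pack_box, tag_boundaries


@pytest.fixture(scope="session")
def tissues():
    return mca.tissue_presets()


@pytest.fixture(scope="session")
def fluid():
    return mca.FluidSpec()


@pytest.fixture(scope="session")
def mini_recipe():
    """Small segment recipe used for fast directional studies."""
    return SegmentRecipe(
        vb_width=24, vb_depth=18, vb_height=6,
        cortical_thickness=2.0, cep_thickness=1.5,
        disc_height=10.0, automaton_size=2.0,
    )


@pytest.fixture()
def small_cube():
    """6 mm fcc cube, d = 0.75 mm, tagged plates."""
    d = 0.75e-3
    p = pack_box((6e-3, 6e-3, 6e-3), d, "fcc")
    return tag_boundaries(p, 0.3 * d)


def make_column(n: int, d: float = 0.5e-3, fix_bottom: bool = True) -> Packing:
    pos = np.zeros((n, 3))
    pos[:, 2] = (np.arange(n) + 0.5) * d
    packing = Packing(pos, d, np.zeros(n, np.int8), np.zeros(n, np.int8), "sc")
    if fix_bottom:
        packing.boundary_id[0] = 1
    return packing


def quick_numerics(**kw) -> Numerics:
    base = dict(damping=0.3, clamp_lateral=False, sample_every=20, smooth_window=5)
    base.update(kw)
    return Numerics(**base)


def free_ensemble(packing, material, fluid=None, **num_kw) -> Ensemble:
    """Ensemble with no boundary constraints (all particles interior)."""
    packing.boundary_id[:] = 0
    return Ensemble(packing, material, fluid=fluid, numerics=quick_numerics(**num_kw))
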