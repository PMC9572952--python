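"""Solid kernel: pair mechanics, homogenization, integration, stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mcaspine as mca
from mcaspine.core import (
    Ensemble,
    Numerics,
    compute_normal_strain,
    compute_torque,
    compute_volume_force,
    homogenize_stress,
    partition_pair_increment,
    stable_timestep,
    volume_coefficient,
)
from mcaspine.errors import NumericalBlowupError
from mcaspine.geometry import pack_box, tag_boundaries
from conftest import free_ensemble, quick_numerics


@pytest.fixture(scope="module")
def cortical(tissues=None):
    return mca.tissue_presets()["cortical"]


@pytest.fixture(scope="module")
def soft():
    return mca.Material(name="soft", rho_matrix=1060, E=1.5e6, nu=0.3,
                        Ks=5e9, phi0=0.8, k0=3e-19)


class TestNormalStrain:
    @pytest.mark.parametrize(
        "q, d, xi",
        [(1.0, 2.0, 0.0), (1.05e-3, 2e-3, 0.05), (0.95e-3, 2e-3, -0.05)],
    )
    def test_values(self, q, d, xi):
        assert compute_normal_strain(q, d) == pytest.approx(xi)


class TestPairPartition:
    def test_identical_materials_split_evenly(self, soft):
        dxi_i, dxi_j, dF, _ = partition_pair_increment(
            1e-6, (0, 0, 0), soft, soft, d=2e-3, S=1e-6)
        assert dxi_i == pytest.approx(1e-6 / 2e-3)
        assert dxi_j == pytest.approx(dxi_i)
        assert dF == pytest.approx(1e-6 * 2 * soft.G * dxi_i)

    def test_softer_element_takes_double_strain(self, soft):
        stiff = soft.replace(name="stiff", E=2 * soft.E)
        # G_i = 2 G_j: element i strains 1/3, j strains 2/3 of 2 dr/d
        dxi_i, dxi_j, dF_i, _ = partition_pair_increment(
            1e-6, (0, 0, 0), stiff, soft, d=2e-3, S=1.0)
        assert dxi_i == pytest.approx(1e-6 / (3 * 1e-3))
        assert dxi_j == pytest.approx(2 * dxi_i)
        # Newton's third law: force computed from either side is identical
        dxi_j2, dxi_i2, dF_j, _ = partition_pair_increment(
            1e-6, (0, 0, 0), soft, stiff, d=2e-3, S=1.0)
        assert dF_j == pytest.approx(dF_i, rel=1e-12)
        assert (dxi_i2, dxi_j2) == pytest.approx((dxi_i, dxi_j))

    def test_against_direct_linear_solve(self, soft):
        """Brute-force 2x2 solve oracle for dissimilar materials with
        volumetric source terms."""
        stiff = soft.replace(name="stiff", E=10 * soft.E, nu=0.2)
        dr, d, S = 2.3e-7, 2e-3, 1e-6
        dP_i, dP_j = 150.0, -80.0
        Di = 1 - 2 * stiff.G / stiff.K
        Dj = 1 - 2 * soft.G / soft.K
        hi = Di * dP_i + volume_coefficient(stiff.K, stiff.G) * dP_j
        hj = Dj * dP_j + volume_coefficient(soft.K, soft.G) * dP_i
        # unknowns [dxi_i, dxi_j]:  2Gi x1 - 2Gj x2 = hj - hi ;  x1 + x2 = 2 dr/d
        A = np.array([[2 * stiff.G, -2 * soft.G], [1.0, 1.0]])
        b = np.array([hj - hi, 2 * dr / d])
        x = np.linalg.solve(A, b)
        dxi_i, dxi_j, dF, _ = partition_pair_increment(
            dr, (0, 0, 0), stiff, soft, dP_i=dP_i, dP_j=dP_j, d=d, S=S)
        assert dxi_i == pytest.approx(x[0], rel=1e-12)
        assert dxi_j == pytest.approx(x[1], rel=1e-12)
        assert dF == pytest.approx(S * (2 * stiff.G * x[0] + hi), rel=1e-12)

    def test_zero_increment_gives_zero(self, soft):
        out = partition_pair_increment(0.0, (0.0, 0.0, 0.0), soft, soft)
        assert out[0] == out[1] == out[2] == 0.0
        assert np.allclose(out[3], 0.0)

    @given(dr=st.floats(-1e-6, 1e-6), ratio=st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=30)
    def test_constraint_and_force_equality_hold(self, soft, dr, ratio):
        other = soft.replace(name="o", E=soft.E * ratio)
        d = 2e-3
        dxi_i, dxi_j, dF_i, _ = partition_pair_increment(dr, (0, 0, 0), soft, other, d=d)
        assert dxi_i * d / 2 + dxi_j * d / 2 == pytest.approx(dr, abs=1e-18)
        assert 2 * soft.G * dxi_i == pytest.approx(2 * other.G * dxi_j, rel=1e-9, abs=1e-12)


class TestVolumeForce:
    def test_zero_pressures(self):
        n = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert np.allclose(compute_volume_force([0.0, 0.0], 1e-6, n, A=0.5), 0.0)

    def test_isotropic_shell_cancels(self):
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        F = compute_volume_force(np.full(6, 2.0e5), 1e-6, dirs, A=0.7)
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_opposing_pressures(self):
        n = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        F = compute_volume_force([1e5, -1e5], 2e-6, n, A=0.5)
        # force magnitude 2 A p S, pushed away from the high-pressure side
        assert F == pytest.approx([0, 0, -2 * 0.5 * 1e5 * 2e-6])


class TestHomogenization:
    def test_no_neighbours(self):
        sigma, P = homogenize_stress([], np.zeros((0, 3)), np.zeros((0, 3)), V=1.0)
        assert np.allclose(sigma, 0.0) and P == 0.0

    def test_single_axial_pair(self):
        d, V, F = 2e-3, 8e-9, 3.0
        sigma, P = homogenize_stress([d / 2], [[0, 0, 1.0]], [[0, 0, F]], V=V)
        assert sigma[2, 2] == pytest.approx(d / 2 * F / V)
        assert sigma[0, 0] == sigma[1, 1] == 0.0
        assert P == pytest.approx(-sigma[2, 2] / 3)

    def test_interior_element_under_hydrostatic_load_is_isotropic(self, cortical):
        """Uniform all-round compression of a lattice: the stress tensor of a
        central element is diagonal and isotropic."""
        d = 1e-3
        p = pack_box((6e-3,) * 3, d, "fcc")
        p.boundary_id[:] = 0
        ens = free_ensemble(p, cortical, damping=0.5)
        # squeeze all surface particles inward, componentwise
        centre = ens.pos.mean(axis=0)
        r = ens.pos - centre
        surface = np.abs(r) > np.abs(r).max(axis=0) - 0.6 * d
        ens.fext[:] = -5.0 * np.sign(r) * surface
        ens.run_until(np.inf, v_target=0.0, max_steps=4000)
        i = int(np.argmin(np.sum(r**2, axis=1)))
        sig = ens.sig[i]
        diag = sig[:3]
        assert np.all(diag < 0)  # compressed
        assert np.max(np.abs(diag - diag.mean())) < 0.02 * abs(diag.mean())
        assert np.max(np.abs(sig[3:])) < 0.05 * abs(diag.mean())


class TestTorque:
    def test_central_force_no_torque(self):
        n = [0, 0, 1.0]
        Mi, Mj = compute_torque(1e-3, n, [0, 0, 5.0])
        assert np.allclose(Mi, 0) and np.allclose(Mj, 0)

    def test_tangential_force_moment_arm(self):
        q, Ft = 1e-3, 4.0
        Mi, Mj = compute_torque(q, [0, 0, 1.0], [Ft, 0, 0])
        assert np.linalg.norm(Mi) == pytest.approx(q * Ft)
        assert np.allclose(Mi, Mj)  # force couple: equal torque on both

    def test_rotational_resistance_antisymmetric(self):
        K = np.array([0.0, 0.0, 1e-6])
        Mi, Mj = compute_torque(1e-3, [0, 0, 1.0], [0, 0, 0], K_ij=K)
        assert np.allclose(Mi, K) and np.allclose(Mj, -K)


class TestStableTimestep:
    def test_cortical_example(self, cortical):
        # c_p = sqrt((K + 4G/3)/rho) ~ 2.69 km/s at d = 2 mm
        dt = stable_timestep(cortical, 2e-3, safety=1.0)
        assert dt == pytest.approx(7.41e-7, rel=0.01)

    def test_halving_size_halves_dt(self, cortical):
        assert stable_timestep(cortical, 1e-3) == pytest.approx(
            0.5 * stable_timestep(cortical, 2e-3))

    def test_stiffest_material_governs(self, cortical, soft):
        both = {"a": soft, "b": cortical}
        assert stable_timestep(both, 2e-3) == stable_timestep(cortical, 2e-3)
        assert stable_timestep(both, 2e-3) < stable_timestep(soft, 2e-3)

    def test_fluid_stiffens(self, soft, fluid):
        assert stable_timestep(soft, 2e-3, fluid=fluid) < stable_timestep(soft, 2e-3)


class TestIntegration:
    def test_zero_state_stays_zero(self, cortical):
        p = pack_box((4e-3,) * 3, 1e-3, "fcc")
        ens = free_ensemble(p, cortical)
        ens.run_until(np.inf, v_target=0.0, max_steps=200)
        assert np.max(np.abs(ens.frc)) < 1e-9 * cortical.G * ens.d**2
        assert np.max(np.abs(ens.vel)) == 0.0

    def test_free_particle_constant_force(self, cortical):
        """u(t) = F t^2 / (2 m) for a single unbonded particle."""
        from mcaspine.geometry import Packing

        p = Packing(np.zeros((2, 3)), 1e-3,
                    np.zeros(2, np.int8), np.zeros(2, np.int8), "sc")
        p.positions[1] = [0, 0, 10.0]  # far away: unbonded
        ens = free_ensemble(p, cortical, damping=0.0)
        F = 2e-4
        ens.fext[0, 2] = F
        n = 500
        ens.run_until(np.inf, v_target=0.0, max_steps=n)
        t = n * ens.dt
        expected = 0.5 * F / ens.mass[0] * t**2
        assert ens.pos[0, 2] == pytest.approx(expected, rel=1e-3)

    def test_rigid_translation_generates_no_forces(self, cortical):
        p = pack_box((5e-3,) * 3, 1e-3, "fcc")
        ens = free_ensemble(p, cortical, damping=0.0)
        ens.vel[:] = [0.1, -0.05, 0.2]
        ens.run_until(np.inf, v_target=0.0, max_steps=300)
        assert np.max(np.abs(ens.fn)) < 1e-9 * cortical.G * ens.d**2
        assert np.max(np.abs(ens.ft)) < 1e-9 * cortical.G * ens.d**2

    def test_small_rigid_rotation_forces_below_tolerance(self, cortical):
        p = pack_box((5e-3,) * 3, 1e-3, "fcc")
        ens = free_ensemble(p, cortical, damping=0.0)
        w = 5.0  # rad/s
        centre = ens.pos.mean(axis=0)
        ens.omg[:] = [0, 0, w]
        ens.vel[:] = np.cross([0, 0, w], ens.pos - centre)
        ens.run_until(np.inf, v_target=0.0, max_steps=300)
        # residual forces are O((w dt)^2) per step: tiny vs elastic scale
        assert np.max(np.abs(ens.fn)) < 1e-6 * cortical.G * ens.d**2

    def test_nan_detection_names_particle(self, cortical):
        p = pack_box((4e-3,) * 3, 1e-3, "fcc")
        ens = free_ensemble(p, cortical)
        ens.vel[3, 0] = np.nan
        with pytest.raises(NumericalBlowupError):
            ens.run_until(np.inf, v_target=0.0, max_steps=100)

    def test_newtons_third_law_total_force_balance(self, cortical, soft, fluid):
        """With equal-and-opposite pair forces the internal force sum of an
        unconstrained body vanishes to rounding."""
        p = pack_box((5e-3,) * 3, 1e-3, "fcc")
        z = p.positions[:, 2]
        p.material_id[z > z.mean()] = 4  # NP region
        ens = free_ensemble(p, {"cortical": cortical, "NP": soft}, fluid=fluid, damping=0.0)
        rng = np.random.default_rng(7)
        ens.vel[:] = 1e-3 * rng.standard_normal(ens.vel.shape)
        ens.run_until(np.inf, v_target=0.0, max_steps=200)
        scale = np.abs(ens.frc).max() + 1e-30
        assert np.abs(ens.frc.sum(axis=0)).max() < 1e-9 * max(scale, 1e-6)

    def test_wave_speed_in_long_bar(self, soft):
        """A pulse travels a simple-cubic bar at sqrt(E/rho) within 10%."""
        from conftest import make_column

        n, d = 120, 0.5e-3
        p = make_column(n, d, fix_bottom=False)
        ens = free_ensemble(p, soft, damping=0.0)
        ens.vel[0, 2] = 0.01  # axial tap at one end
        c_expected = np.sqrt(soft.E / soft.rho_matrix)
        z_probe = p.positions[-1, 2] - p.positions[0, 2]
        t, arrived = 0.0, False
        for _ in range(200):
            ens.run_until(np.inf, v_target=0.0, max_steps=100)
            if abs(ens.vel[-1, 2]) > 1e-4:
                arrived = True
                break
        assert arrived
        c_measured = z_probe / ens.t
        assert c_measured == pytest.approx(c_expected, rel=0.10)


class TestCheckpoint:
    def test_exact_roundtrip(self, tmp_path, cortical, fluid):
        p = pack_box((4e-3,) * 3, 1e-3, "fcc")
        p = tag_boundaries(p, 0.3e-3)
        ens = Ensemble(p, cortical, fluid=fluid, numerics=quick_numerics())
        ens.run_until(np.inf, v_target=0.05, ramp_time=0.0, max_steps=200)
        path = ens.save_checkpoint(tmp_path / "state.h5")
        ens2 = Ensemble(p, cortical, fluid=fluid, numerics=quick_numerics())
        ens2.load_checkpoint(path)
        for name in ("pos", "vel", "fn", "ft", "sig", "mfl", "Pp"):
            assert np.array_equal(getattr(ens, name), getattr(ens2, name))
        # identical continuation
        ens.run_until(np.inf, v_target=0.05, max_steps=100)
        ens2.run_until(np.inf, v_target=0.05, max_steps=100)
        assert np.array_equal(ens.pos, ens2.pos)
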