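"""Fluid equation of state, Biot coupling, filtration and consolidation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mcaspine as mca
from mcaspine.core import Ensemble
from mcaspine.errors import PhysicalLimitError, StabilityError
from mcaspine.geometry import pack_box
from mcaspine import porofluid as pf
from conftest import free_ensemble, make_column, quick_numerics


@pytest.fixture(scope="module")
def np_tissue():
    return mca.tissue_presets()["NP"]


class TestEquationOfState:
    def test_equilibrium(self, fluid):
        assert pf.eos_pressure(fluid.rho0, fluid) == fluid.P0

    def test_direct_value(self, fluid):
        # rho = 1010 kg/m^3 at K_fl = 2.4 GPa -> 24 MPa
        assert pf.eos_pressure(1010.0, fluid) == pytest.approx(24e6)

    @given(P=st.floats(-1e7, 5e7))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_exact(self, P):
        fluid = mca.FluidSpec()
        rho = pf.eos_density(P, fluid)
        assert pf.eos_pressure(rho, fluid) == pytest.approx(P, abs=1e-6)


class TestPorosityPermeability:
    def test_zero_strain_identity(self, np_tissue):
        phi, k = pf.update_porosity_permeability(np_tissue, 0.0)
        assert phi == pytest.approx(np_tissue.phi0)
        assert k == pytest.approx(np_tissue.k0, rel=1e-12)

    def test_compression_value(self):
        mat = mca.Material(name="m", rho_matrix=1000, E=1e6, nu=0.3,
                           Ks=1e9, phi0=0.8, k0=3e-19)
        phi, k = pf.update_porosity_permeability(mat, -0.05)
        assert phi == pytest.approx(1 - 0.2 / 0.95)
        assert k == pytest.approx(phi * mat.d_ch**2)

    def test_pore_collapse_guarded(self, np_tissue):
        with pytest.raises(PhysicalLimitError):
            pf.update_porosity_permeability(np_tissue, -0.85)


class TestStrainSource:
    def test_zero_strain_no_change(self, np_tissue, fluid):
        assert pf.fluid_solid_strain_source(np_tissue, fluid.rho0, 0.0, 0.0) == fluid.rho0

    def test_compress_then_expand_reversible(self, np_tissue, fluid):
        rho1 = pf.fluid_solid_strain_source(np_tissue, fluid.rho0, 0.0, -0.02)
        rho2 = pf.fluid_solid_strain_source(np_tissue, rho1, -0.02, 0.0)
        assert rho2 == pytest.approx(fluid.rho0, rel=1e-14)

    def test_undrained_closed_form(self, fluid):
        """1% volumetric compression of a closed element at phi0 = 0.8:
        P = K_fl (phi0/(phi0 + ev) - 1)."""
        mat = mca.Material(name="m", rho_matrix=1000, E=1e6, nu=0.3,
                           Ks=1e9, phi0=0.8, k0=3e-19)
        rise = pf.undrained_pressure_rise(mat, fluid, -0.01)
        expected = fluid.K_fl * (0.8 / 0.79 - 1.0)
        assert rise == pytest.approx(expected, rel=1e-12)
        # approximately K_fl * |ev| / phi0 at small strain
        assert rise == pytest.approx(fluid.K_fl * 0.01 / 0.8, rel=0.02)


class TestBiotCoupling:
    def test_zero_biot_ratio_decouples(self, fluid):
        mat = mca.Material(name="m", rho_matrix=1000, E=3e9, nu=0.25,
                           Ks=2e9, phi0=0.5, k0=1e-16)
        assert mat.a == 0.0
        assert pf.couple_pore_pressure(mat, 1e6) == 0.0

    def test_correction_scales_with_biot_ratio(self, np_tissue):
        assert pf.couple_pore_pressure(np_tissue, 1e6) == pytest.approx(-np_tissue.a * 1e6)

    def test_dry_and_zero_pressure_trajectories_match(self, np_tissue, fluid):
        """With no pore-pressure change the saturated solver follows the dry
        elastic trajectory (inertia aside, the coupling adds nothing)."""
        d = 0.75e-3
        p1 = pack_box((3e-3,) * 3, d, "fcc")
        dry = free_ensemble(p1, np_tissue, fluid=None, damping=0.0)
        p2 = pack_box((3e-3,) * 3, d, "fcc")
        wet = free_ensemble(p2, np_tissue, fluid=fluid, damping=0.0)
        # no motion, no strain -> no pressure change -> same (null) forces
        dry.run_until(np.inf, max_steps=100)
        wet.run_until(np.inf, max_steps=100)
        tol = 1e-9 * np_tissue.G * dry.d**2
        assert np.max(np.abs(dry.fn)) < tol
        assert np.max(np.abs(wet.fn)) < tol
        assert np.max(np.abs(wet.Pp)) < 1.0  # rounding-level pascals

    def test_undrained_coupled_column_matches_closed_form(self, fluid):
        """Quasi-static compression of a closed saturated column: the pore
        pressure tracks K_fl (phi0/(phi0+ev) - 1) with ev the column's own
        volumetric strain measure."""
        mat = mca.Material(name="m", rho_matrix=1500, E=1e9, nu=0.3,
                           Ks=10e9, phi0=0.5, k0=1e-19)
        n, d = 10, 0.5e-3
        packing = make_column(n, d)
        packing.boundary_id[-1] = 2  # driven top
        ens = Ensemble(packing, mat, fluid=fluid,
                       numerics=quick_numerics(damping=0.5, clamp_lateral=True))
        strain = 0.004
        L = packing.positions[-1, 2] - packing.positions[0, 2]
        v = 0.02
        n_steps = int(strain * L / v / ens.dt)
        ens.run_until(np.inf, v_target=v, ramp_time=200 * ens.dt, max_steps=n_steps)
        # let it settle
        ens.run_until(np.inf, v_target=0.0, max_steps=n_steps // 2)
        mid = n // 2
        # the element's pressure obeys the one-element undrained closed form
        # at its own volumetric strain ...
        expected_local = fluid.K_fl * (mat.phi0 / (mat.phi0 + ens.evol[mid]) - 1.0)
        assert ens.Pp[mid] == pytest.approx(expected_local, rel=0.02)
        assert ens.Pp[mid] > 0
        # ... and the strain bookkeeping is consistent with the measured
        # column geometry (end elements carry slightly less)
        L_now = ens.pos[-1, 2] - ens.pos[0, 2]
        col_strain = 1.0 - L_now / L
        assert col_strain > 0.5 * strain
        assert np.mean(ens.evol) == pytest.approx(-3 * col_strain, rel=0.05)
        expected_global = fluid.K_fl * (mat.phi0 / (mat.phi0 - 3 * col_strain) - 1.0)
        assert ens.Pp[mid] == pytest.approx(expected_global, rel=0.10)


class TestFiltration:
    def test_uniform_density_no_flux(self, fluid):
        rho = np.full(5, 1005.0)
        pairs = [(i, i + 1) for i in range(4)]
        out = pf.filtration_step(rho, np.full(5, 1e-13), np.full(5, 0.5),
                                 5e-4, 2.5e-7, pairs, fluid, 1e-9, 1.25e-10)
        assert np.allclose(out, rho)

    def test_two_cell_relaxation_conserves_mass(self, fluid):
        """Unequal densities relax monotonically toward equilibrium; total
        fluid mass is conserved exactly (two-cell ODE oracle)."""
        phi = np.array([0.5, 0.5])
        k = np.full(2, 1e-13)
        V = 1.25e-10
        rho = np.array([1004.0, 1001.0])
        mass0 = np.sum(rho * phi * V)
        pairs = [(0, 1)]
        gap = [rho[0] - rho[1]]
        for _ in range(400):
            rho = pf.filtration_step(rho, k, phi, 5e-4, 2.5e-7, pairs, fluid, 2e-8, V)
            gap.append(rho[0] - rho[1])
        gap = np.array(gap)
        assert np.all(np.diff(gap) <= 1e-15)          # monotone decay
        assert gap[-1] < 0.05 * gap[0]                # approaches equilibrium
        assert np.sum(rho * phi * V) == pytest.approx(mass0, rel=1e-14)

    def test_donor_limiter_blocks_subequilibrium_transfer(self, fluid):
        rho = np.array([fluid.rho0, fluid.rho0 - 5.0])
        out = pf.filtration_step(rho, np.full(2, 1e-13), np.full(2, 0.5),
                                 5e-4, 2.5e-7, [(0, 1)], fluid, 5e-12, 1.25e-10)
        assert np.array_equal(out, rho)

    def test_stability_limit_enforced(self, fluid):
        rho = np.array([1004.0, 1001.0])
        with pytest.raises(StabilityError):
            pf.filtration_step(rho, np.full(2, 1e-10), np.full(2, 0.5),
                               5e-4, 2.5e-7, [(0, 1)], fluid, 1e-3, 1.25e-10)

    def test_closed_system_mass_conserved_in_coupled_run(self, np_tissue, fluid):
        """~100-element saturated fixture, driven compression, no drainage:
        total fluid mass constant to 1e-10 relative per run."""
        from mcaspine.geometry import tag_boundaries

        p = pack_box((4.5e-3,) * 3, 0.9e-3, "fcc")
        p = tag_boundaries(p, 0.3e-3)
        ens = Ensemble(p, np_tissue, fluid=fluid, numerics=quick_numerics())
        m0 = ens.fluid_mass_total()
        ens.run_until(np.inf, v_target=0.05, ramp_time=100 * ens.dt, max_steps=2000)
        assert ens.fluid_mass_total() == pytest.approx(m0, rel=1e-10)


class TestConsolidation:
    def test_terzaghi_column_matches_series(self):
        """RMS error < 5% against the analytic consolidation series at
        T = 0.1, 0.5, 1.0."""
        from mcaspine.experiments import terzaghi_column

        mat = mca.Material(name="permeable-test", rho_matrix=1500, E=1e9,
                           nu=0.3, Ks=10e9, phi0=0.5, k0=1e-13)
        out = terzaghi_column(mat, n=20)
        for T, entry in out["times"].items():
            assert entry["rms"] < 0.05, f"T={T}: rms={entry['rms']}"

    def test_drainage_is_monotone(self):
        """Every element's pore pressure decays monotonically once drainage
        begins."""
        from mcaspine.experiments import terzaghi_column

        mat = mca.Material(name="permeable-test", rho_matrix=1500, E=1e9,
                           nu=0.3, Ks=10e9, phi0=0.5, k0=1e-13)
        out = terzaghi_column(mat, n=12, fourier_times=(0.05, 0.2, 0.5, 1.0))
        profiles = [out["times"][T]["profile"] for T in (0.05, 0.2, 0.5, 1.0)]
        for earlier, later in zip(profiles, profiles[1:]):
            assert np.all(later <= earlier + 1e-9)
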