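import numpy as np
import pytest

from qmmm_embed.benchmark_suite import BoxSpec, generate_water_box
from qmmm_embed.cutoff_switching import (SwitchingSpec, partition_charges,
                                         split_charges)
from qmmm_embed.embedding_models import (build_embedding_operator,
                                         density_embedding_energy, hybrid_energy,
                                         mechanical_energy, mmlc_correction,
                                         multipolar_energy, polarization_energy)
from qmmm_embed.multipole_rep import (LocalField, MultipoleSet, build_esp_grid,
                                      fit_esp_multipoles, local_field,
                                      mulliken_multipoles)
from qmmm_embed.qm_adapter import EmbeddingOperatorSpec, SurrogateBackend
from qmmm_embed.system_io import (BOHR_IN_ANGSTROM, HARTREE_IN_KCALMOL,
                                  MMCharges, QMRegion)


class TestMechanical:
    def test_unit_pair_at_one_bohr(self):
        qm = QMRegion(elements=["H"], coords=[[0, 0, 0]], ff_charges=[1.0],
                      net_charge=1)
        mm = MMCharges([[BOHR_IN_ANGSTROM, 0, 0]], [-1.0], [0])
        assert mechanical_energy(qm, mm) == pytest.approx(-HARTREE_IN_KCALMOL, rel=1e-12)

    def test_unit_pair_at_one_angstrom(self):
        qm = QMRegion(elements=["H"], coords=[[0, 0, 0]], ff_charges=[1.0],
                      net_charge=1)
        mm = MMCharges([[1.0, 0, 0]], [-1.0], [0])
        expected = -627.509474 * 0.529177210903
        assert mechanical_energy(qm, mm) == pytest.approx(expected, rel=1e-10)

    def test_empty_mm_zero(self, hydroxide):
        assert mechanical_energy(hydroxide, MMCharges.empty()) == 0.0

    def test_requires_ff_charges(self):
        qm = QMRegion(elements=["H"], coords=[[0, 0, 0]], net_charge=1)
        with pytest.raises(ValueError, match="ff_charges"):
            mechanical_energy(qm, MMCharges([[2, 0, 0]], [0.1], [0]))


class TestMultipolarEnergy:
    def test_zero_moments(self, hydroxide):
        M = MultipoleSet(hydroxide.coords, np.zeros((2, 4)), 1, "surrogate")
        F = LocalField(np.ones(2), np.ones((2, 3)))
        assert multipolar_energy(M, F) == 0.0

    def test_single_site_charge_term(self):
        M = MultipoleSet([[0, 0, 0]], [[-1.0]], 0, "surrogate")
        F = LocalField(np.array([0.5]), np.zeros((1, 3)))
        assert multipolar_energy(M, F) == pytest.approx(-0.5 * HARTREE_IN_KCALMOL)

    def test_perpendicular_dipole_contributes_nothing(self):
        M = MultipoleSet([[0, 0, 0]], [[0.0, 0.3, 0.0, 0.0]], 1, "surrogate")
        F = LocalField(np.array([0.0]), np.array([[0.0, 0.2, 0.7]]))
        assert multipolar_energy(M, F) == 0.0

    def test_site_count_mismatch(self, hydroxide):
        M = MultipoleSet(hydroxide.coords, np.zeros((2, 4)), 1, "surrogate")
        F = LocalField(np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="site count"):
            multipolar_energy(M, F)


class TestDensityEmbedding:
    def test_empty_mm(self, anion_cloud_surrogate, hydroxide):
        den = anion_cloud_surrogate.density()
        assert density_embedding_energy(den, hydroxide, MMCharges.empty()) == 0.0

    def test_multipole_surrogate_equals_multipolar_energy(self, hydroxide, rng):
        M = MultipoleSet(hydroxide.coords, [[-0.6, 0.2, 0, 0.1], [-0.4, 0, 0, 0]],
                         1, "surrogate")
        be = SurrogateBackend(hydroxide, multipoles=M)
        mm = MMCharges(rng.normal(size=(5, 3)) * 2 + 9, rng.normal(size=5),
                       np.arange(5))
        e = density_embedding_energy(be.density(), hydroxide, mm)
        F = local_field(mm, hydroxide.coords, 1)
        assert e == pytest.approx(multipolar_energy(M, F), rel=1e-12)

    def test_monopole_limit(self, hydroxide, hydroxide_gas):
        """A probe perpendicular to the molecular axis (no dipole projection)
        sees (net charge)/r at long range."""
        density, _, _ = hydroxide_gas
        r_bohr = 100.0
        mm = MMCharges([[r_bohr * BOHR_IN_ANGSTROM, 0, 0]], [1.0], [0])
        e = density_embedding_energy(density, hydroxide, mm)
        expected = -1.0 / r_bohr * HARTREE_IN_KCALMOL
        assert e == pytest.approx(expected, rel=1e-4)


class TestMMLC:
    def test_empty_far_field(self, hydroxide):
        assert mmlc_correction(hydroxide, MMCharges.empty()) == 0.0

    def test_monopole_limit(self, hydroxide):
        # hydroxide ff charges sum to -1
        mm = MMCharges([[50.0, 0, 0]], [0.6], [0])
        e = mmlc_correction(hydroxide, mm)
        expected = -1.0 * 0.6 / (50.0 / BOHR_IN_ANGSTROM) * HARTREE_IN_KCALMOL
        assert e == pytest.approx(expected, rel=1e-3)


@pytest.fixture(scope="module")
def box(hydroxide):
    return generate_water_box(
        BoxSpec(box_length=18.0, n_waters=40, orientation_bias="anion", seed=5),
        hydroxide)


class TestHybrid:

    def test_large_cutoff_step_equals_reference(self, anion_cloud_surrogate,
                                                hydroxide, box):
        den = anion_cloud_surrogate.density()
        ref = hybrid_energy(den, hydroxide, box, "reference",
                            SwitchingSpec("step", 1.0))
        rep = hybrid_energy(den, hydroxide, box, "espcd",
                            SwitchingSpec("step", 100.0), mode="group")
        assert rep.total == pytest.approx(ref.total, abs=1e-9)
        assert rep.components["long_range"] == 0.0

    def test_zero_cutoff_is_pure_multipolar(self, anion_cloud_surrogate,
                                            hydroxide, box):
        den = anion_cloud_surrogate.density()
        rep = hybrid_energy(den, hydroxide, box, "mulcd",
                            SwitchingSpec("lrec", 0.0))
        M = mulliken_multipoles(den, hydroxide, 1)
        F = local_field(box, hydroxide.coords, 1)
        assert rep.components["short_range"] == 0.0
        assert rep.total == pytest.approx(multipolar_energy(M, F), rel=1e-12)

    def test_truncation_drops_long_range(self, anion_cloud_surrogate, hydroxide, box):
        den = anion_cloud_surrogate.density()
        rep = hybrid_energy(den, hydroxide, box, "truncation",
                            SwitchingSpec("lrec", 6.0))
        assert rep.components["long_range"] == 0.0
        assert rep.components["mmlc"] == 0.0

    def test_mmlc_component_appears(self, anion_cloud_surrogate, hydroxide, box):
        den = anion_cloud_surrogate.density()
        rep = hybrid_energy(den, hydroxide, box, "truncation_mmlc",
                            SwitchingSpec("lrec", 6.0))
        assert rep.components["mmlc"] != 0.0
        assert rep.total == pytest.approx(
            rep.components["short_range"] + rep.components["mmlc"], abs=1e-10)

    @pytest.mark.parametrize("model", ["truncation", "truncation_mmlc",
                                       "mulc", "mulcd", "espc", "espcd"])
    def test_component_additivity(self, anion_cloud_surrogate, hydroxide, box, model):
        den = anion_cloud_surrogate.density()
        rep = hybrid_energy(den, hydroxide, box, model, SwitchingSpec("switch", 8.0))
        c = rep.components
        assert c["total"] == pytest.approx(
            c["short_range"] + c["long_range"] + c["mmlc"], abs=1e-10)

    def test_mechanical_model_rejected(self, anion_cloud_surrogate, hydroxide, box):
        with pytest.raises(ValueError):
            hybrid_energy(anion_cloud_surrogate.density(), hydroxide, box,
                          "mechanical", SwitchingSpec("lrec", 8.0))

    def test_smooth_scheme_continuity_across_cutoff(self, anion_cloud_surrogate,
                                                    hydroxide):
        """The deviation from the all-charge reference varies smoothly as a
        charge crosses r_off under LREC but jumps under Step (second
        difference as the discontinuity detector)."""
        den = anion_cloud_surrogate.density()
        base = generate_water_box(
            BoxSpec(box_length=16.0, n_waters=20, seed=9), hydroxide)
        grid = build_esp_grid(hydroxide)
        grid.phi_s = anion_cloud_surrogate.esp_on_points(den, hydroxide, grid.points)

        def deviations(scheme):
            out = []
            for dr in np.arange(-0.02, 0.02, 1e-3):
                coords = base.coords.copy()
                coords[0] = [8.0 + dr, 0.0, 0.0]
                mm = MMCharges(coords, base.q, base.group_id)
                spec = SwitchingSpec(scheme, 8.0)
                rep = hybrid_energy(den, hydroxide, mm, "espcd", spec, grid=grid)
                ref = hybrid_energy(den, hydroxide, mm, "reference", spec)
                out.append(rep.total - ref.total)
            return np.array(out)

        assert np.max(np.abs(np.diff(deviations("lrec"), 2))) < 1e-6
        assert np.max(np.abs(np.diff(deviations("step"), 2))) > 1e-3


class TestOperator:
    def test_truncation_operator_contains_only_scaled_near(self, hydroxide):
        mm = MMCharges([[5.0, 0, 0], [30.0, 0, 0]], [-0.5, 0.7], [0, 1])
        op = build_embedding_operator("truncation", hydroxide, mm,
                                      SwitchingSpec("lrec", 10.0))
        assert op.n_charges == 1
        s = 1.0 - (2 * 0.5**3 - 3 * 0.5**2 + 1) ** 2  # LREC at r/roff ~ 0.5
        # distance to nearest QM atom is min over O and H sites
        assert abs(op.charge_values[0]) < 0.5  # scaled down
        assert op.one_electron_matrix is None

    def test_reference_operator_is_all_charges(self, hydroxide):
        mm = MMCharges([[5.0, 0, 0], [30.0, 0, 0]], [-0.5, 0.7], [0, 1])
        op = build_embedding_operator("reference", hydroxide, mm,
                                      SwitchingSpec("step", 10.0))
        assert op.n_charges == 2
        np.testing.assert_array_equal(op.charge_values, mm.q)

    def test_espcd_scf_grid_route_matches_posthoc_fit(self, rhf, hydroxide):
        """Converge the SCF with projected grid charges, then check the
        long-range energy two ways on the converged density: grid charges
        directly vs the fitted-moment expression (the projection identity
        at the SCF solution)."""
        mm = generate_water_box(BoxSpec(box_length=16.0, n_waters=25, seed=21),
                                hydroxide)
        spec = SwitchingSpec("lrec", 6.0)
        grid = build_esp_grid(hydroxide)
        op = build_embedding_operator("espcd", hydroxide, mm, spec, grid=grid)
        density, _, _ = rhf.converged_scf(hydroxide, op)

        n_grid = grid.n_points
        grid_charges = MMCharges(op.charge_coords[-n_grid:],
                                 op.charge_values[-n_grid:],
                                 np.zeros(n_grid, dtype=int))
        e_grid = density_embedding_energy(density, hydroxide, grid_charges)

        part = partition_charges(mm, hydroxide, spec)
        split = split_charges(part, mm, spec)
        lr_coords = np.vstack([mm.coords[part.near_idx], mm.coords[part.far_idx]])
        lr_q = np.concatenate([split.q_II, mm.q[part.far_idx]])
        lr = MMCharges(lr_coords, lr_q, np.zeros(len(lr_q), dtype=int))
        fit_grid = build_esp_grid(hydroxide)
        fit_grid.phi_s = rhf.esp_on_points(density, hydroxide, fit_grid.points)
        M = fit_esp_multipoles(fit_grid, hydroxide, 1)
        F = local_field(lr, hydroxide.coords, 1)
        e_fit = multipolar_energy(M, F)
        assert e_grid == pytest.approx(e_fit, abs=1e-8)

    def test_mulcd_matrix_linear_in_density(self, rhf, hydroxide, hydroxide_gas, rng):
        """Tr(P h_LR) + shift reproduces the Mulliken charge+dipole energy
        for arbitrary symmetric matrices P (linearity), evaluated through the
        independent population-analysis route."""
        density, _, _ = hydroxide_gas
        mm = MMCharges([[14.0, 2.0, 1.0], [16.0, -3.0, 2.0]], [0.4, -0.3], [0, 1])
        op = build_embedding_operator("mulcd", hydroxide, mm,
                                      SwitchingSpec("lrec", 0.0), density=density)
        F = local_field(mm, hydroxide.coords, 1)
        for _ in range(3):
            P = rng.normal(size=density.density_matrix.shape)
            P = P + P.T

            class FakeDensity:
                density_matrix = P
                overlap = density.overlap
                moment_integrals = density.moment_integrals
                basis_atom_indices = density.basis_atom_indices

            M = mulliken_multipoles(FakeDensity(), hydroxide, 1)
            e_pop = float(M.charges @ F.phi + np.sum(M.dipoles * F.field))
            e_mat = float(np.einsum("mn,mn->", P, op.one_electron_matrix)) \
                + op.nuclear_energy_shift
            assert e_mat == pytest.approx(e_pop, abs=1e-10)

    def test_esp_grid_required_error_path(self, hydroxide):
        # grid is constructed on demand, so the espcd operator works without
        # a prepared grid; a mulliken operator without a density is an error
        mm = MMCharges([[20.0, 0, 0]], [0.5], [0])
        with pytest.raises(ValueError, match="density"):
            build_embedding_operator("mulcd", hydroxide, mm,
                                     SwitchingSpec("lrec", 5.0))


class TestPolarization:
    def test_gas_phase_from_own_density_is_zero(self, rhf, hydroxide, hydroxide_gas):
        density, _, _ = hydroxide_gas
        pol = polarization_energy(rhf, hydroxide, EmbeddingOperatorSpec.vacuum(),
                                  density)
        assert abs(pol) < 1e-6

    def test_variational_bound(self, rhf, hydroxide, hydroxide_gas):
        density, _, _ = hydroxide_gas
        op = EmbeddingOperatorSpec([[3.0, 0.5, 0.0]], [0.8])
        pol = polarization_energy(rhf, hydroxide, op, density)
        assert pol <= 1e-10
        assert pol < -1e-4  # a nearby charge genuinely distorts the orbitals

    def test_matches_reverse_rotation_definition(self, rhf, hydroxide, hydroxide_gas):
        """The truncation-at-zero polarization equals the energy of rotating
        the embedded orbitals back to gas phase, recomputed independently
        from total energies."""
        density_gas, _, e_gas = hydroxide_gas
        op = EmbeddingOperatorSpec([[3.5, 0.0, 0.5]], [-0.6])
        dens_emb, _, _ = rhf.converged_scf(hydroxide, op)
        # evaluate the vacuum Hamiltonian on the embedded density: first SCF
        # cycle of a vacuum run started from the embedded orbitals
        _, e_first, e_conv = rhf.converged_scf(hydroxide, None, initial=dens_emb)
        pol = polarization_energy(rhf, hydroxide, EmbeddingOperatorSpec.vacuum(),
                                  dens_emb)
        assert pol == pytest.approx((e_conv - e_first) * HARTREE_IN_KCALMOL,
                                    abs=1e-9)
        assert e_conv == pytest.approx(e_gas, abs=1e-8)
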