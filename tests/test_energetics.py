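import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endstate import energetics as en
from endstate.constants import COULOMB_CONSTANT

from conftest import make_system


def brute_force_vdw(system, frame, ia, ib):
    total = 0.0
    for i in ia:
        for j in ib:
            r = np.linalg.norm(system.coords[frame, i] - system.coords[frame, j])
            rmin = system.rmin_half[i] + system.rmin_half[j]
            eps = np.sqrt(system.epsilon[i] * system.epsilon[j])
            total += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    return total


def brute_force_coulomb(system, frame, ia, ib):
    total = 0.0
    for i in ia:
        for j in ib:
            r = np.linalg.norm(system.coords[frame, i] - system.coords[frame, j])
            total += COULOMB_CONSTANT * system.charges[i] * system.charges[j] / r
    return total


class TestPairVdw:
    def test_minimum_identity(self):
        # separation exactly rmin_i + rmin_j -> energy -sqrt(eps_i eps_j)
        system = make_system(
            [[0, 0, 0], [3.4, 0, 0]], epsilon=[0.2, 0.3], rmin_half=[1.5, 1.9]
        )
        e = en.pair_vdw(system, 0, [0], [1])
        assert e == pytest.approx(-np.sqrt(0.2 * 0.3), abs=1e-12)

    def test_zero_epsilon_gives_zero(self):
        system = make_system(
            [[0, 0, 0], [2.0, 0, 0], [0, 3, 0]], epsilon=[0.0, 0.2, 0.3]
        )
        assert en.pair_vdw(system, 0, [0], [1, 2]) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 8, size=(5, 3))
        system = make_system(
            coords,
            epsilon=rng.uniform(0.05, 0.3, 5),
            rmin_half=rng.uniform(1.2, 2.0, 5),
        )
        got = en.pair_vdw(system, 0, [0, 1], [2, 3, 4])
        want = brute_force_vdw(system, 0, [0, 1], [2, 3, 4])
        assert got == pytest.approx(want, abs=1e-10)

    def test_coincident_atoms_error(self):
        system = make_system([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="singular"):
            en.pair_vdw(system, 0, [0], [1])

    def test_overlapping_masks_error(self):
        system = make_system([[0, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="disjoint"):
            en.pair_vdw(system, 0, [0, 1], [1])


class TestPairCoulomb:
    def test_closed_form(self):
        system = make_system(
            [[0, 0, 0], [3.320637, 0, 0]], charges=[1.0, -1.0]
        )
        assert en.pair_coulomb(system, 0, [0], [1]) == pytest.approx(-100.0, abs=0.01)

    def test_neutral_mask_zero(self):
        system = make_system([[0, 0, 0], [2, 0, 0], [0, 2, 0]], charges=[0, 0, 1.0])
        assert en.pair_coulomb(system, 0, [0, 1], [2]) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 8, size=(6, 3))
        system = make_system(coords, charges=rng.uniform(-1, 1, 6))
        got = en.pair_coulomb(system, 0, [0, 1, 2], [3, 4, 5])
        want = brute_force_coulomb(system, 0, [0, 1, 2], [3, 4, 5])
        assert got == pytest.approx(want, abs=1e-10)


class TestGbEnergy:
    def test_born_ion_closed_form(self):
        system = make_system([[0, 0, 0]], charges=[1.0], born=[2.0])
        # -1/2 * 332.0637 * (1 - 1/80) / 2
        assert en.gb_energy(system, 0, eps_solvent=80.0) == pytest.approx(
            -81.97, abs=0.05
        )

    def test_eps_one_is_exactly_zero(self):
        system = make_system([[0, 0, 0], [3, 0, 0]], charges=[1.0, -1.0])
        assert en.gb_energy(system, 0, eps_solvent=1.0) == 0.0

    def test_far_pair_approaches_born_sum(self):
        far = make_system(
            [[0, 0, 0], [500.0, 0, 0]], charges=[1.0, -1.0], born=[2.0, 1.5]
        )
        got = en.gb_energy(far, 0)
        lone = sum(
            en.gb_energy(
                make_system([[0, 0, 0]], charges=[q], born=[b]), 0
            )
            for q, b in [(1.0, 2.0), (-1.0, 1.5)]
        )
        # cross term ~ -(k/2)(1-1/eps) q1 q2 / r remains; compare self-term part
        cross = -0.5 * COULOMB_CONSTANT * (1 - 1 / 80.0) * (1.0 * -1.0) / 500.0
        assert got - cross == pytest.approx(lone, rel=1e-3)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 6, size=(5, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -5.0, 3.0])
        a = make_system(coords, charges=rng.uniform(-1, 1, 5))
        b = make_system(moved, charges=a.charges)
        assert en.gb_energy(a, 0) == pytest.approx(en.gb_energy(b, 0), abs=1e-8)

    def test_per_atom_decomposition_sums_to_total(self):
        rng = np.random.default_rng(3)
        system = make_system(
            rng.uniform(0, 6, size=(6, 3)), charges=rng.uniform(-1, 1, 6)
        )
        _, contrib = en.gb_energy_per_atom(system, 0)
        assert contrib.sum() == pytest.approx(en.gb_energy(system, 0), abs=1e-10)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        system = make_system([[0, 0, 0]], rmin_half=[1.5])
        area = en.sasa(system, 0, probe=1.4, n_points=960)
        assert area == pytest.approx(4 * np.pi * 2.9**2, rel=0.005)

    def test_buried_atom_zero(self):
        # a giant engulfing neighbor swallows the central atom's surface
        system = make_system([[0, 0, 0], [0.5, 0, 0]], rmin_half=[1.5, 10.0])
        _, areas = en.sasa_per_atom(system, 0, n_points=240)
        assert areas[0] == 0.0

    def test_overlapping_spheres_match_dense_grid(self):
        system = make_system([[0, 0, 0], [2.0, 0, 0]], rmin_half=[1.5, 1.5])
        coarse = en.sasa(system, 0, n_points=960)
        dense = en.sasa(system, 0, n_points=9600)
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_matches_biotite_reference(self):
        import biotite.structure as struc

        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 5, size=(6, 3))
        radii = rng.uniform(1.2, 2.0, 6)
        system = make_system(coords, rmin_half=radii)
        arr = struc.AtomArray(6)
        arr.coord = coords
        arr.chain_id = np.array(["A"] * 6)
        arr.res_id = np.arange(1, 7)
        arr.res_name = np.array(["RES"] * 6)
        arr.atom_name = np.array([f"X{i}" for i in range(6)])
        arr.element = np.array(["C"] * 6)
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=2000)
        got = en.sasa(system, 0, n_points=2000)
        assert got == pytest.approx(float(ref.sum()), rel=0.01)

    def test_too_few_points_rejected(self):
        system = make_system([[0, 0, 0]])
        with pytest.raises(ValueError):
            en.sasa(system, 0, n_points=11)

    def test_monotone_decrease_on_approach(self):
        prev = np.inf
        for d in [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]:
            system = make_system([[0, 0, 0], [d, 0, 0]], rmin_half=[1.5, 1.5])
            area = en.sasa(system, 0, n_points=960)
            assert area <= prev + 1e-9
            prev = area


class TestNonpolar:
    def test_zero_area_gives_beta(self):
        assert en.nonpolar_energy(0.0, gamma=0.005, beta=0.7) == 0.7

    def test_direct_product(self):
        assert en.nonpolar_energy(105.68, gamma=0.005, beta=0.0) == pytest.approx(
            0.5284
        )

    def test_zero_gamma_gives_beta(self):
        assert en.nonpolar_energy(123.0, gamma=0.0, beta=0.25) == 0.25


class TestGasPhaseInteraction:
    def test_inert_ligand_zero(self):
        system = make_system(
            [[0, 0, 0], [4, 0, 0]],
            charges=[0.5, 0.0],
            epsilon=[0.2, 0.0],
            groups=["receptor", "ligand"],
        )
        assert en.gas_phase_interaction(system, 0) == 0.0

    def test_equals_component_sum(self, toy_complex):
        a = toy_complex.receptor_mask
        b = toy_complex.ligand_mask
        expected = en.pair_vdw(toy_complex, 0, a, b) + en.pair_coulomb(
            toy_complex, 0, a, b
        )
        assert en.gas_phase_interaction(toy_complex, 0) == pytest.approx(
            expected, abs=1e-12
        )


class TestFrameEnergies:
    def test_per_residue_sums_to_totals(self, toy_complex):
        fe = en.frame_energies(toy_complex, 0, sasa_points=120)
        assert fe.per_residue["vdw"].sum() == pytest.approx(fe.e_vdw, abs=1e-6)
        assert fe.per_residue["ele"].sum() == pytest.approx(fe.e_ele, abs=1e-6)
        assert fe.per_residue["gb"].sum() == pytest.approx(fe.g_gb, abs=1e-6)

    def test_np_nonnegative_with_default_coeffs(self, toy_complex):
        fe = en.frame_energies(toy_complex, 0, sasa_points=120)
        assert fe.g_np >= 0.0
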