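import numpy as np
import pytest

from saxstool.forward import (
    ForwardModelError,
    ProfileEvaluator,
    coarse_grain,
    compute_profile,
    debye_intensity,
    effective_form_factor,
    hydration_surface_weights,
)
from saxstool.formfactors import default_table
from saxstool.geometry import rotation_about_axis
from saxstool.molecule import Molecule


def _point_molecule(coords, element="C"):
    coords = np.atleast_2d(coords)
    n = coords.shape[0]
    return Molecule(
        element=np.array([element] * n, dtype=object),
        resid=np.arange(1, n + 1),
        resname=np.array(["ALA"] * n, dtype=object),
        atom_name=np.array(["CA"] * n, dtype=object),
        coords=coords,
    )


class TestFormFactors:
    @pytest.mark.parametrize("element,z", [("H", 1), ("C", 6), ("N", 7), ("O", 8), ("S", 16), ("P", 15)])
    def test_vacuum_factor_at_zero_matches_electron_count(self, element, z):
        table = default_table()
        assert table.vacuum_factor(element, np.array([0.0]))[0] == pytest.approx(z, rel=0.01)

    @pytest.mark.parametrize("element", ["C", "N", "O", "S"])
    def test_vacuum_factor_monotone_nonincreasing(self, element):
        table = default_table()
        q = np.linspace(0.0, 0.5, 200)
        f = table.vacuum_factor(element, q)
        assert np.all(np.diff(f) <= 1e-12)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            default_table().vacuum_factor("Xx", np.array([0.1]))


class TestEffectiveFormFactor:
    def test_neutral_scaling_at_c1_equal_one(self):
        table = default_table()
        q = np.linspace(0.0, 0.4, 30)
        f = effective_form_factor("C", q, c1=1.0, table=table)
        expected = table.vacuum_factor("C", q) - table.dummy_factor("C", q)
        np.testing.assert_allclose(f, expected, rtol=1e-12)

    def test_zero_contrast_when_dummy_cancels_vacuum(self):
        # at q=0 the radius correction reduces to c1^3, so the cancelling c1 is analytic
        table = default_table()
        f_vac0 = table.vacuum_factor("C", np.array([0.0]))[0]
        f_dum0 = table.dummy_factor("C", np.array([0.0]))[0]
        c1 = (f_vac0 / f_dum0) ** (1.0 / 3.0)
        f = effective_form_factor("C", np.array([0.0]), c1=c1, table=table)
        assert abs(f[0]) < 1e-10

    @pytest.mark.parametrize("element", ["C", "N", "O", "S"])
    def test_monotone_in_c1_at_small_q(self, element):
        q = np.array([0.05])
        c1s = np.linspace(0.95, 1.05, 21)
        f = np.array([effective_form_factor(element, q, c1)[0] for c1 in c1s])
        assert np.all(np.diff(f) < 0)  # larger c1 -> more excluded volume -> less contrast


class TestHydrationWeights:
    def test_isolated_atom_fully_exposed(self):
        assert hydration_surface_weights(_point_molecule([[0.0, 0.0, 0.0]]))[0] == 1.0

    def test_two_distant_atoms_fully_exposed(self):
        w = hydration_surface_weights(_point_molecule([[0, 0, 0], [50, 0, 0]]))
        np.testing.assert_allclose(w, 1.0)

    def test_buried_atom_against_numeric_oracle(self, rng):
        # central atom inside a dense 100-atom shell; oracle = independent
        # Monte Carlo accessibility estimate with random (not lattice) points
        shell = []
        while len(shell) < 100:
            p = rng.normal(size=3)
            p *= rng.uniform(3.0, 6.5) / np.linalg.norm(p)
            shell.append(p)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        mol = _point_molecule(coords)
        w = hydration_surface_weights(mol)
        assert w[0] < 0.05
        probe, radii = 1.8, mol.vdw_radii() + 1.8
        pts = rng.normal(size=(4000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        sphere = radii[0] * pts
        d2 = ((sphere[:, None, :] - coords[None, 1:, :]) ** 2).sum(axis=2)
        oracle = 1.0 - np.any(d2 < radii[1:] ** 2, axis=1).mean()
        assert w[0] == pytest.approx(oracle, abs=0.03)


class TestDebyeSum:
    def test_single_scatterer_is_f_squared(self):
        q = np.linspace(0.0, 0.4, 20)
        mol = _point_molecule([[1.0, 2.0, 3.0]], element="BEAD")
        out = compute_profile(mol, q)
        f = default_table().vacuum_factor("BEAD", q) - default_table().dummy_factor("BEAD", q)
        np.testing.assert_allclose(out.intensity, f ** 2, rtol=1e-12)

    def test_two_scatterers_closed_form(self):
        d = 7.3
        q = np.linspace(0.01, 0.4, 50)
        mol = _point_molecule([[0, 0, 0], [d, 0, 0]], element="BEAD")
        out = compute_profile(mol, q)
        table = default_table()
        f = table.vacuum_factor("BEAD", q) - table.dummy_factor("BEAD", q)
        expected = 2 * f ** 2 * (1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(out.intensity, expected, rtol=1e-12)

    def test_matches_brute_force_double_loop(self, rng, q_grid):
        from saxstool.forward import atom_amplitudes

        coords = rng.uniform(-10, 10, size=(30, 3))
        mol = _point_molecule(coords)
        F = atom_amplitudes(mol, q_grid)
        expected = np.zeros_like(q_grid)
        for i in range(30):
            for j in range(30):
                d = np.linalg.norm(coords[i] - coords[j])
                expected = expected + F[i] * F[j] * np.sinc(q_grid * d / np.pi)
        got = compute_profile(mol, q_grid).intensity
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_rigid_motion_invariance(self, rng, q_grid):
        coords = rng.uniform(-8, 8, size=(25, 3))
        mol = _point_molecule(coords)
        base = compute_profile(mol, q_grid).intensity
        R = rotation_about_axis(np.array([1.0, -2.0, 0.5]), 1.1)
        moved = _point_molecule(coords @ R.T + np.array([30.0, -12.0, 4.0]))
        np.testing.assert_allclose(compute_profile(moved, q_grid).intensity, base, rtol=1e-10)

    def test_intensity_at_zero_is_total_amplitude_squared(self, two_domain):
        from saxstool.forward import atom_amplitudes

        q0 = np.array([0.0])
        F0 = atom_amplitudes(two_domain, q0)
        out = compute_profile(two_domain, q0)
        assert out.intensity[0] == pytest.approx(float(F0.sum()) ** 2, rel=1e-12)

    def test_component_decomposition_sums_to_total(self, atom_cluster, q_grid):
        out = compute_profile(atom_cluster, q_grid, c1=1.02, c2=1.0, return_components=True)
        total = sum(out.components.values())
        np.testing.assert_allclose(total, out.intensity, rtol=1e-10)
        # c2=0 removes the hydration component entirely
        out0 = compute_profile(atom_cluster, q_grid, c1=1.02, c2=0.0, return_components=True)
        np.testing.assert_allclose(out0.components["hydration"], 0.0, atol=1e-10)

    def test_empty_molecule_rejected(self, q_grid):
        empty = Molecule(
            element=np.array([], dtype=object),
            resid=np.array([], dtype=int),
            resname=np.array([], dtype=object),
            atom_name=np.array([], dtype=object),
            coords=np.zeros((0, 3)),
        )
        with pytest.raises(ForwardModelError):
            compute_profile(empty, q_grid)

    def test_explicit_hydrogens_dropped_with_warning(self, q_grid):
        mol = Molecule(
            element=np.array(["C", "H"], dtype=object),
            resid=np.array([1, 1]),
            resname=np.array(["ALA", "ALA"], dtype=object),
            atom_name=np.array(["CA", "HA"], dtype=object),
            coords=np.array([[0.0, 0, 0], [1.1, 0, 0]]),
        )
        with pytest.warns(UserWarning, match="hydrogens"):
            out = compute_profile(mol, q_grid)
        only_c = compute_profile(_point_molecule([[0.0, 0, 0]]), q_grid)
        np.testing.assert_allclose(out.intensity, only_c.intensity)


def test_profile_evaluator_matches_compute_profile(atom_cluster, q_grid):
    ev = ProfileEvaluator(atom_cluster, q_grid)
    for c1, c2 in [(1.0, 0.0), (0.97, -0.5), (1.04, 2.0)]:
        direct = compute_profile(atom_cluster, q_grid, c1, c2, surface_weights=ev.surface_weights())
        np.testing.assert_allclose(ev.intensity(c1, c2), direct.intensity, rtol=1e-10)


def test_coarse_grain_one_bead_per_residue(two_domain):
    cg = coarse_grain(two_domain)
    assert len(cg) == len(np.unique(two_domain.resid))
    assert all(e == "BEAD" for e in cg.element)
    out = compute_profile(cg, np.array([0.01, 0.1]))
    assert out.coarse
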