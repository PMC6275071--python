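"""Coulomb/LJ cross terms, generalized Born machinery, LCPO surface areas,
and the per-residue decomposition's conservation identities."""

import numpy as np
import pytest

import unbindkit as uk
from unbindkit import synthetic as syn
from unbindkit.energy import (
    _descreen_integral, _gb_pair_matrix, _subset_topology, lcpo_sasa,
)
from unbindkit.units import COULOMB_CONSTANT

from oracles import numeric_descreen_integral, shrake_rupley_sasa


def _two_atom_topology(charges, lj_radius=(1.7, 1.7), lj_epsilon=(0.1, 0.1),
                       gb_radius=(1.5, 1.5)):
    return uk.Topology(
        atom_names=["X1", "X2"], elements=["C", "C"], res_ids=[1, 1],
        res_names=["AAA", "BBB"], chain_ids=["A", "B"],
        masses=[12.011, 12.011], charges=list(charges),
        lj_radius=list(lj_radius), lj_epsilon=list(lj_epsilon),
        gb_radius=list(gb_radius))


class TestCoulombLJ:
    def test_opposite_unit_charges_hand_value(self):
        top = _two_atom_topology((1.0, -1.0), lj_epsilon=(0.0, 0.0))
        coords = np.array([[0.0, 0.0, 0.0], [3.32, 0.0, 0.0]])
        e_ele, e_vdw, _ = uk.pairwise_coulomb_lj(
            coords, top, top.select(chain="A"), top.select(chain="B"))
        assert np.isclose(e_ele, -COULOMB_CONSTANT / 3.32)
        assert round(e_ele, 2) == -100.02
        assert e_vdw == 0.0

    def test_zero_charges_zero_electrostatics(self):
        top = _two_atom_topology((0.0, 0.0))
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        e_ele, _, _ = uk.pairwise_coulomb_lj(
            coords, top, top.select(chain="A"), top.select(chain="B"))
        assert e_ele == 0.0

    def test_lj_zero_crossing_at_sigma(self):
        top = _two_atom_topology((0.0, 0.0))
        rmin = 1.7 + 1.7
        sigma = rmin / 2 ** (1 / 6)
        coords = np.array([[0.0, 0.0, 0.0], [sigma, 0.0, 0.0]])
        _, e_vdw, _ = uk.pairwise_coulomb_lj(
            coords, top, top.select(chain="A"), top.select(chain="B"))
        assert abs(e_vdw) < 1e-12
        # and the minimum sits at rmin with depth -eps
        coords[1, 0] = rmin
        _, e_min, _ = uk.pairwise_coulomb_lj(
            coords, top, top.select(chain="A"), top.select(chain="B"))
        assert np.isclose(e_min, -0.1)

    def test_overlapping_atoms_rejected(self):
        top = _two_atom_topology((1.0, 1.0))
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="overlap"):
            uk.pairwise_coulomb_lj(coords, top, top.select(chain="A"),
                                   top.select(chain="B"))


class TestBornRadii:
    def test_isolated_atom_offset_corrected(self, single_ion_topology):
        top = single_ion_topology(gb_radius=1.5)
        radii = uk.born_radii(np.zeros((1, 3)), top, uk.GBModel())
        assert np.isclose(radii[0], 1.5 - 0.09)

    def test_distant_atoms_approach_isolated_limit(self):
        top = _two_atom_topology((1.0, -1.0))
        coords = np.array([[0.0, 0.0, 0.0], [500.0, 0.0, 0.0]])
        radii = uk.born_radii(coords, top, uk.GBModel())
        assert np.allclose(radii, 1.5 - 0.09, atol=1e-6)

    @pytest.mark.parametrize("d", [2.2, 3.0, 4.5])
    def test_descreening_matches_numerical_quadrature(self, d):
        """The pairwise descreening integral agrees with direct shell
        quadrature within 2%."""
        rho, s = 1.41, 1.2
        analytic = float(_descreen_integral(np.array(d), np.array(rho),
                                            np.array(s)))
        numeric = numeric_descreen_integral(d, rho, s)
        assert abs(analytic - numeric) / numeric < 0.02

    def test_two_atom_radii_against_integral_oracle(self):
        """Effective radii from the package match radii rebuilt from the
        independent quadrature oracle within 2%."""
        model = uk.GBModel()
        top = _two_atom_topology((1.0, -1.0), gb_radius=(1.5, 1.6))
        coords = np.array([[0.0, 0.0, 0.0], [2.8, 0.0, 0.0]])
        radii = uk.born_radii(coords, top, model)
        scale = model.screening["C"]
        for i, j in ((0, 1), (1, 0)):
            rho_i = top.gb_radius[i] - model.offset
            s_j = scale * (top.gb_radius[j] - model.offset)
            integral = numeric_descreen_integral(2.8, rho_i, s_j)
            psi = integral * rho_i
            inv = 1.0 / rho_i - np.tanh(
                model.alpha * psi - model.beta * psi ** 2
                + model.gamma * psi ** 3) / top.gb_radius[i]
            assert abs(radii[i] - 1.0 / inv) / (1.0 / inv) < 0.02


class TestGBPolar:
    def test_born_ion_closed_form(self, single_ion_topology):
        """Single-ion polar energy equals the Born equation to 1e-8."""
        model = uk.GBModel()
        for q, rho in ((1.0, 1.5), (-2.0, 2.1)):
            top = single_ion_topology(charge=q, gb_radius=rho)
            radius = uk.born_radii(np.zeros((1, 3)), top, model)
            energy = _gb_pair_matrix(np.zeros((1, 3)), np.array([q]),
                                     radius, model.prefactor).sum()
            born = (-0.5 * (1 / model.interior_dielectric
                            - 1 / model.exterior_dielectric)
                    * COULOMB_CONSTANT * q * q / radius[0])
            assert abs(energy - born) / abs(born) < 1e-8

    def test_polar_energy_vanishes_at_matched_dielectrics(self):
        top = _two_atom_topology((0.5, -0.5))
        coords = np.array([[0.0, 0.0, 0.0], [3.5, 0.0, 0.0]])
        a, b = top.select(chain="A"), top.select(chain="B")
        values = []
        for eps_out in (78.5, 10.0, 1.001, 1.0000001):
            model = uk.GBModel(exterior_dielectric=eps_out)
            total, _ = uk.gb_polar_energy(coords, top, model, a, b)
            values.append(abs(total))
        assert values[-1] < 1e-5 * values[0]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_zero_charges_zero_polar(self):
        top = _two_atom_topology((0.0, 0.0))
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        total, table = uk.gb_polar_energy(coords, top, uk.GBModel(),
                                          top.select(chain="A"),
                                          top.select(chain="B"))
        assert total == 0.0
        assert np.all(table["G_pol"] == 0.0)

    def test_mirror_symmetric_dimer_splits_equally(self):
        n = 3
        rng = np.random.default_rng(12)
        half = rng.uniform(0, 3, size=(n, 3))
        half[:, 0] = -np.abs(half[:, 0]) - 1.0
        mirror = half.copy()
        mirror[:, 0] *= -1.0
        coords = np.vstack([half, mirror])
        q = rng.uniform(-0.5, 0.5, size=n)
        top = uk.Topology(
            atom_names=[f"X{i + 1}" for i in range(2 * n)],
            elements=["C"] * 2 * n,
            res_ids=list(range(1, n + 1)) * 2,
            res_names=["MON"] * 2 * n,
            chain_ids=["A"] * n + ["B"] * n,
            masses=[12.0] * 2 * n, charges=np.tile(q, 2),
            lj_radius=[1.7] * 2 * n, lj_epsilon=[0.1] * 2 * n,
            gb_radius=[1.5] * 2 * n)
        total, table = uk.gb_polar_energy(coords, top, uk.GBModel(),
                                          top.select(chain="A"),
                                          top.select(chain="B"))
        a_sum = table[table["chain"] == "A"]["G_pol"].sum()
        b_sum = table[table["chain"] == "B"]["G_pol"].sum()
        assert np.isclose(a_sum, b_sum, rtol=1e-10)
        assert np.isclose(a_sum + b_sum, total)


class TestLCPO:
    def test_isolated_atom_exact(self, sphere_topology):
        top = sphere_topology([1.6], lcpo=(0.75, 0.0, 0.0, 0.0))
        sasa = lcpo_sasa(np.zeros((1, 3)), top)
        assert np.isclose(sasa[0], 0.75 * 4 * np.pi * (1.6 + 1.4) ** 2)

    def test_separated_atoms_additive(self, sphere_topology):
        top = sphere_topology([1.5, 1.8])
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        sasa = lcpo_sasa(coords, top)
        iso = [4 * np.pi * (r + 1.4) ** 2 for r in (1.5, 1.8)]
        assert np.allclose(sasa, iso)

    def test_five_atom_cluster_vs_shrake_rupley(self, sphere_topology):
        radii, coords = syn.generate_sphere_cluster(5, seed=42)
        top = sphere_topology(radii)
        lcpo = lcpo_sasa(coords, top)
        oracle = shrake_rupley_sasa(radii, coords, n_points=10_000)
        assert abs(lcpo.sum() - oracle.sum()) / oracle.sum() < 0.05

    def test_missing_coefficients_named(self, sphere_topology):
        top = sphere_topology([1.5, 1.5])
        top.lcpo_params[1] = np.nan
        with pytest.raises(ValueError, match="X2"):
            lcpo_sasa(np.array([[0.0, 0.0, 0.0], [9.0, 0.0, 0.0]]), top)


class TestDecomposition:
    def _system(self, seed):
        top, coords = syn.generate_random_complex(5, 5, seed=seed)
        traj = uk.Trajectory(top, coords[None])
        return top, coords, traj

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_row_sums_equal_interface_totals(self, seed):
        """Σ_residues of each term equals the whole-interface value."""
        top, coords, traj = self._system(seed)
        a, b = top.select(chain="A"), top.select(chain="B")
        table = uk.decompose_interface(traj, a, b, n_snapshots=1)
        totals = table.totals()
        e_ele, e_vdw, _ = uk.pairwise_coulomb_lj(coords, top, a, b)
        g_pol, _ = uk.gb_polar_energy(coords, top, uk.GBModel(), a, b)
        gamma = uk.NonpolarModel().gamma
        sasa_ab = lcpo_sasa(coords, top).sum()
        sasa_a = lcpo_sasa(coords[a.indices],
                           _subset_topology(top, a.indices)).sum()
        sasa_b = lcpo_sasa(coords[b.indices],
                           _subset_topology(top, b.indices)).sum()
        g_np = gamma * (sasa_ab - sasa_a - sasa_b)
        assert abs(totals["E_ele"] - e_ele) < 1e-6
        assert abs(totals["E_vdw"] - e_vdw) < 1e-6
        assert abs(totals["G_pol"] - g_pol) < 1e-6
        assert abs(totals["G_nonpol"] - g_np) < 1e-6
        assert abs(totals["G_total"]
                   - (e_ele + e_vdw + g_pol + g_np)) < 1e-6

    def test_far_apart_neutral_groups_all_zero(self):
        n = 4
        top = uk.Topology(
            atom_names=[f"X{i + 1}" for i in range(2 * n)],
            elements=["C"] * 2 * n, res_ids=list(range(1, n + 1)) * 2,
            res_names=["NEU"] * 2 * n, chain_ids=["A"] * n + ["B"] * n,
            masses=[12.0] * 2 * n, charges=[0.0] * 2 * n,
            lj_radius=[1.7] * 2 * n, lj_epsilon=[0.0] * 2 * n,
            gb_radius=[1.5] * 2 * n,
            lcpo_params=np.tile([1.0, -1.0, 0.0, 0.0], (2 * n, 1)))
        coords = np.zeros((2 * n, 3))
        coords[:n, 0] = 10.0 * np.arange(n)
        coords[n:, 0] = 10.0 * np.arange(n)
        coords[n:, 1] = 500.0
        table = uk.decompose_interface(
            uk.Trajectory(top, coords[None]), top.select(chain="A"),
            top.select(chain="B"), n_snapshots=1)
        assert np.abs(table.frame[list(table.COLUMNS)].to_numpy()).max() < 1e-9

    def test_key_residue_filter_returns_planted_rows(self):
        """The |ΔG| >= 5 kcal/mol filter keeps exactly the planted rows."""
        import pandas as pd
        frame = pd.DataFrame({
            "chain": ["A"] * 4, "res_id": [1, 2, 3, 4],
            "res_name": ["AAA"] * 4,
            "E_ele": [-6.0, 0.0, 5.5, -1.0], "E_vdw": [0.0] * 4,
            "G_pol": [0.0] * 4, "G_nonpol": [0.0] * 4,
            "G_total": [-6.0, 0.0, 5.5, -1.0],
        })
        table = uk.DecompositionTable(frame, n_snapshots=1)
        key = table.key_rows(threshold=5.0)
        assert key["res_id"].tolist() == [1, 3]

    def test_full_mode_matches_cross_sums_per_side(self):
        top, coords, traj = self._system(9)
        a, b = top.select(chain="A"), top.select(chain="B")
        table = uk.decompose_interface(traj, a, b, n_snapshots=1, mode="full")
        e_ele, _, _ = uk.pairwise_coulomb_lj(coords, top, a, b)
        side_a = table.frame[table.frame["chain"] == "A"]["E_ele"].sum()
        side_b = table.frame[table.frame["chain"] == "B"]["E_ele"].sum()
        assert np.isclose(side_a, e_ele)
        assert np.isclose(side_b, e_ele)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        top, coords, traj = self._system(4)
        a, b = top.select(chain="A"), top.select(chain="B")
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 8.0])
        for fn in (
            lambda c: uk.pairwise_coulomb_lj(c, top, a, b)[:2],
            lambda c: uk.gb_polar_energy(c, top, uk.GBModel(), a, b)[0],
            lambda c: lcpo_sasa(c, top).sum(),
        ):
            assert np.allclose(fn(coords), fn(moved), rtol=1e-9, atol=1e-9)
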