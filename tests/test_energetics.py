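import math

import numpy as np
import pytest
from scipy.integrate import quad

from tgsite.energetics import (
    BindingEnergy,
    DecompositionRecord,
    K_COULOMB,
    debye_kappa,
    gb_effective_radii,
    gb_polar_energy,
    group_decomposition,
    mmgbsa_binding,
    pairwise_nonbonded,
    per_residue_decomposition,
    rank_binders,
    sasa,
    select_pocket_residues,
)
from tgsite.model import AtomRecord, Residue, Topology, Trajectory


def atom(name, resid, q, rmh=1.9, eps=0.1, rho=1.7, element="C"):
    return AtomRecord(name, element, resid, q, rmh, eps, rho)


def single_residue_topology(atoms):
    resids = sorted({a.residue_index for a in atoms})
    return Topology(atoms, [Residue(r, "XXX") for r in resids])


class TestPairwiseNonbonded:
    def test_unit_charges_give_minus_100(self):
        top = single_residue_topology(
            [atom("A", 1, 1.0, eps=0.0), atom("B", 2, -1.0, eps=0.0)]
        )
        xyz = np.array([[0, 0, 0], [3.320636, 0, 0]], float)
        elec, vdw = pairwise_nonbonded(xyz, top, [0], [1])
        assert elec == pytest.approx(-100.0, abs=1e-9)
        assert vdw == 0.0

    def test_vdw_at_rmin_is_minus_epsilon(self):
        top = single_residue_topology(
            [atom("A", 1, 0.0, rmh=1.9, eps=0.16), atom("B", 2, 0.0, rmh=1.7, eps=0.09)]
        )
        rmin = 1.9 + 1.7
        xyz = np.array([[0, 0, 0], [rmin, 0, 0]], float)
        _, vdw = pairwise_nonbonded(xyz, top, [0], [1])
        assert vdw == pytest.approx(-math.sqrt(0.16 * 0.09), abs=1e-12)

    def test_zero_charges_zero_elec(self):
        top = single_residue_topology([atom("A", 1, 0.0), atom("B", 2, 0.0)])
        elec, _ = pairwise_nonbonded(np.array([[0, 0, 0], [4.0, 0, 0]]), top, [0], [1])
        assert elec == 0.0

    def test_symmetric_in_groups(self):
        top = single_residue_topology(
            [atom("A", 1, 0.5), atom("B", 1, -0.2), atom("C", 2, -0.7), atom("D", 2, 0.1)]
        )
        xyz = np.array([[0, 0, 0], [1.4, 0, 0], [0, 3.1, 0], [1.2, 2.8, 1.0]])
        assert pairwise_nonbonded(xyz, top, [0, 1], [2, 3]) == pytest.approx(
            pairwise_nonbonded(xyz, top, [2, 3], [0, 1])
        )

    def test_overlapping_groups_rejected(self):
        top = single_residue_topology([atom("A", 1, 0.0), atom("B", 2, 0.0)])
        with pytest.raises(ValueError, match="overlap"):
            pairwise_nonbonded(np.zeros((2, 3)), top, [0, 1], [1])

    def test_clash_guard(self):
        top = single_residue_topology([atom("A", 1, 0.0), atom("B", 2, 0.0)])
        xyz = np.array([[0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(ValueError, match="clash"):
            pairwise_nonbonded(xyz, top, [0], [1])


class TestDecomposition:
    def make_traj(self, frames):
        atoms = [atom("L", 99, -1.0, eps=0.0), atom("R", 1, 1.0, eps=0.0)]
        top = Topology(
            atoms,
            [Residue(99, "PFC", polarity_class="ligand"),
             Residue(1, "LYS", polarity_class="basic")],
            ligand_residue_indices={99},
        )
        return Trajectory(top, np.asarray(frames, float), np.arange(float(len(frames))))

    def test_single_frame_hand_value(self):
        traj = self.make_traj([[[0, 0, 0], [3.320636, 0, 0]]])
        recs = per_residue_decomposition(traj, np.array([0]), {1})
        assert recs[0].elec_mean == pytest.approx(-100.0, abs=1e-9)
        assert recs[0].polarity_class == "basic"

    def test_two_frame_arithmetic_mean(self):
        # per-frame elec of -10 and -20 kcal/mol
        r1 = K_COULOMB / 10.0
        r2 = K_COULOMB / 20.0
        traj = self.make_traj(
            [[[0, 0, 0], [r1, 0, 0]], [[0, 0, 0], [r2, 0, 0]]]
        )
        recs = per_residue_decomposition(traj, np.array([0]), {1})
        assert recs[0].elec_mean == pytest.approx(-15.0, abs=1e-9)

    def test_zero_parameter_residue_gives_zero_record(self):
        atoms = [atom("L", 99, 0.0, eps=0.0), atom("R", 1, 0.0, eps=0.0)]
        top = Topology(
            atoms,
            [Residue(99, "PFC", polarity_class="ligand"),
             Residue(1, "ALA", polarity_class="nonpolar")],
            ligand_residue_indices={99},
        )
        traj = Trajectory(top, np.array([[[0, 0, 0], [4.0, 0, 0]]]), np.zeros(1))
        recs = per_residue_decomposition(traj, np.array([0]), {1})
        assert recs[0].elec_mean == recs[0].vdw_mean == 0.0
        assert recs[0].total_mean == 0.0

    def test_pocket_selection_union_over_frames(self):
        atoms = [atom("L", 99, 0.0), atom("N", 1, 0.0), atom("F", 2, 0.0)]
        top = Topology(
            atoms,
            [Residue(99, "PFC"), Residue(1, "ALA"), Residue(2, "ALA")],
            ligand_residue_indices={99},
        )
        # residue 1 at 5 Å always; residue 2 at 12 Å except one frame at 9 Å
        frames = [
            [[0, 0, 0], [5, 0, 0], [12, 0, 0]],
            [[0, 0, 0], [5, 0, 0], [9, 0, 0]],
            [[0, 0, 0], [5, 0, 0], [12, 0, 0]],
        ]
        traj = Trajectory(top, np.array(frames, float), np.arange(3.0))
        assert select_pocket_residues(traj, np.array([0]), 10.0) == {1, 2}
        # and a residue beyond the cutoff in every frame is excluded
        far = np.array(frames, float)
        far[:, 2, 0] = 15.0
        traj_far = Trajectory(top, far, np.arange(3.0))
        assert select_pocket_residues(traj_far, np.array([0]), 10.0) == {1}


# Published group subtotals (kcal/mol) for the PFAS series at Site B, used
# as inputs; columns whose printed subtotals and sum disagree by a rounding
# residual are checked through their addends only.
GROUP_SUBTOTALS = {
    "PFBA": (-49.45, -14.05, -63.50),
    "PFPA": (-26.79, -27.67, -54.46),
    "PFOA": (-20.23, -32.90, -53.13),
    "PFDA": (-33.59, -33.93, -67.52),
    "PFUnDA": (-27.55, -33.88, -61.43),
    "PFDoDA": (-60.72, -42.54, -103.26),
}


class TestGroupSums:
    @staticmethod
    def records(charged, polar_nonpolar):
        return [
            DecompositionRecord(1, charged, 0.0, "basic"),
            DecompositionRecord(2, polar_nonpolar, 0.0, "polar"),
        ]

    @pytest.mark.parametrize("name", sorted(GROUP_SUBTOTALS))
    def test_published_subtotals_reproduce_printed_sum(self, name):
        charged, pn, printed_sum = GROUP_SUBTOTALS[name]
        sums = group_decomposition(self.records(charged, pn))
        assert round(sums.total, 2) == printed_sum

    def test_empty_records_all_zero(self):
        sums = group_decomposition([])
        assert sums.charged == sums.polar_nonpolar == sums.total == 0.0

    def test_hormonogenic_reported_separately_and_excluded(self):
        recs = self.records(-10.0, -5.0) + [DecompositionRecord(3, -2.0, -1.0, "hormonogenic")]
        sums = group_decomposition(recs)
        assert sums.total == pytest.approx(-15.0)
        assert sums.hormonogenic == pytest.approx(-3.0)

    def test_acidic_counts_as_charged(self):
        recs = [DecompositionRecord(1, 2.0, 0.5, "acidic"),
                DecompositionRecord(2, -1.0, -0.5, "nonpolar")]
        sums = group_decomposition(recs)
        assert sums.charged == pytest.approx(2.5)
        assert sums.polar_nonpolar == pytest.approx(-1.5)


def born_energy(q, R, eps_out=78.5):
    return -(K_COULOMB / 2.0) * (1.0 - 1.0 / eps_out) * q * q / R


def hct_closed_form(d, rho_i, s):
    """Independent closed form of the descreening integral for
    non-overlapping spheres."""
    return 0.5 * (s / (d * d - s * s) + (1.0 / (2 * d)) * math.log((d - s) / (d + s)))


class TestGBRadii:
    def ion(self, rho=1.59):
        return single_residue_topology([atom("X", 1, 1.0, rho=rho)])

    def test_isolated_atom_radius_is_reduced_radius(self):
        top = self.ion(1.59)
        R = gb_effective_radii(np.zeros((1, 3)), top)
        assert R[0] == pytest.approx(1.50, abs=1e-12)

    def test_radius_grows_monotonically_as_neighbor_approaches(self):
        """Descreening by an approaching neighbor buries the atom, so its
        effective Born radius increases monotonically above the reduced
        radius (the tanh argument grows with the pairwise integral)."""
        top = single_residue_topology([atom("A", 1, 0.0, rho=1.7), atom("B", 1, 0.0, rho=1.7)])
        radii = []
        for d in np.linspace(12.0, 2.0, 15):
            xyz = np.array([[0, 0, 0], [d, 0, 0]])
            radii.append(gb_effective_radii(xyz, top)[0])
        assert all(b > a for a, b in zip(radii, radii[1:]))
        assert all(r >= 1.7 - 0.09 for r in radii)

    def test_descreening_matches_numeric_integral(self):
        """OBC's pairwise integral vs direct quadrature of 1/r⁴ over the
        neighbor sphere, in both separated and overlapping arrangements."""
        from tgsite.energetics import _hct_integral

        def numeric(d, rho_i, s):
            if d + s <= rho_i:
                return 0.0

            def frac(r):
                c = np.clip((r * r + d * d - s * s) / (2 * r * d), -1, 1)
                return (1 - c) / 2

            lo = max(rho_i, d - s) if d > s else rho_i
            val, _ = quad(lambda r: frac(r) / r**2, lo, d + s, limit=200)
            return val

        for d, ri, s in [(5.0, 1.5, 1.6), (2.0, 1.5, 1.6), (1.0, 1.5, 1.6),
                         (0.8, 1.5, 2.5), (3.0, 1.2, 1.0)]:
            got = _hct_integral(np.array([d]), ri, np.array([s]))[0]
            assert got == pytest.approx(numeric(d, ri, s), rel=1e-6)
            if d > ri + s:  # independent closed form where it applies
                assert got == pytest.approx(hct_closed_form(d, ri, s), rel=1e-9)


class TestGBEnergy:
    def test_born_equation_grid_to_1e6_relative(self):
        for q in (-2.0, -1.0, 1.0, 2.0):
            for R in np.linspace(1.0, 3.0, 9):
                top = single_residue_topology([atom("X", 1, q, rho=R + 0.09)])
                e = gb_polar_energy(np.zeros((1, 3)), top, np.array([R]), salt_molar=0.0)
                assert abs(e - born_energy(q, R)) <= 1e-6 * abs(born_energy(q, R))

    def test_reference_ion_value(self):
        top = single_residue_topology([atom("X", 1, 1.0)])
        e = gb_polar_energy(np.zeros((1, 3)), top, np.array([1.5]), salt_molar=0.0)
        assert e == pytest.approx(-109.3, abs=0.05)

    def test_two_distant_monopoles_approach_summed_born_terms(self):
        # small radii make the Born self terms dominate the 1/r cross term
        top = single_residue_topology(
            [atom("A", 1, 1.0, rho=1.0), atom("B", 1, 1.0, rho=1.0)]
        )
        xyz = np.array([[0, 0, 0], [50.0, 0, 0]])
        radii = gb_effective_radii(xyz, top)
        e = gb_polar_energy(xyz, top, radii, salt_molar=0.0)
        expected = born_energy(1.0, radii[0]) + born_energy(1.0, radii[1])
        assert abs(e - expected) / abs(expected) < 0.02

    def test_zero_charges_zero_energy(self):
        top = single_residue_topology([atom("A", 1, 0.0), atom("B", 1, 0.0)])
        xyz = np.array([[0, 0, 0], [3.0, 0, 0]])
        assert gb_polar_energy(xyz, top, np.array([1.5, 1.5])) == 0.0

    def test_salt_stabilizes_the_ion_further(self):
        top = single_residue_topology([atom("X", 1, 1.0)])
        e0 = gb_polar_energy(np.zeros((1, 3)), top, np.array([1.5]), salt_molar=0.0)
        e1 = gb_polar_energy(np.zeros((1, 3)), top, np.array([1.5]), salt_molar=0.1)
        assert e1 < e0 < 0  # Debye screening deepens ionic solvation

    def test_debye_length_at_physiological_salt(self):
        # 0.1 M 1:1 salt in water: Debye length ≈ 9.6 Å
        assert 1.0 / debye_kappa(0.1) == pytest.approx(9.6, abs=0.2)


class TestSasa:
    def test_single_sphere_analytic_area(self):
        top = single_residue_topology([atom("X", 1, 0.0, rho=1.5)])
        total, per_atom = sasa(np.zeros((1, 3)), top)
        analytic = 4 * math.pi * (1.5 + 1.4) ** 2
        assert abs(total - analytic) / analytic < 0.01
        assert per_atom[0] == total

    def test_distant_spheres_additive(self):
        top = single_residue_topology([atom("A", 1, 0.0, rho=1.5), atom("B", 1, 0.0, rho=2.0)])
        xyz = np.array([[0, 0, 0], [100.0, 0, 0]])
        total, per_atom = sasa(xyz, top)
        assert total == pytest.approx(
            4 * math.pi * (2.9**2 + 3.4**2), rel=0.01
        )
        assert total == pytest.approx(per_atom.sum())

    def test_fully_buried_atom_has_zero_area(self):
        # cage: central small atom enclosed by a shell of large spheres
        n_cage = 30
        k = np.arange(n_cage)
        phi = math.pi * (3 - math.sqrt(5)) * k
        z = 1 - 2 * (k + 0.5) / n_cage
        rho = np.sqrt(1 - z * z)
        shell = 2.2 * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        atoms = [atom("C0", 1, 0.0, rho=1.2)] + [
            atom(f"C{i+1}", 1, 0.0, rho=2.2) for i in range(n_cage)
        ]
        top = single_residue_topology(atoms)
        xyz = np.vstack([[0, 0, 0], shell])
        _, per_atom = sasa(xyz, top)
        assert per_atom[0] == 0.0


class TestMMGBSA:
    def test_empty_ligand_selection_rejected(self):
        top = single_residue_topology([atom("A", 1, 0.0)])
        traj = Trajectory(top, np.zeros((1, 1, 3)), np.zeros(1))
        with pytest.raises(ValueError, match="ligand"):
            mmgbsa_binding(traj, np.array([], dtype=int))

    def test_noninteracting_chargeless_ligand_binds_at_zero(self):
        atoms = [atom("A", 1, 0.5), atom("B", 1, -0.5),
                 atom("L", 9, 0.0, eps=0.0, rho=1.5)]
        top = Topology(
            atoms,
            [Residue(1, "ALA"), Residue(9, "PFC")],
            ligand_residue_indices={9},
        )
        xyz = np.array([[0, 0, 0], [3.0, 0, 0], [100.0, 0, 0]])
        traj = Trajectory(top, xyz[None], np.zeros(1))
        be = mmgbsa_binding(traj, np.array([2]), salt_molar=0.0)
        assert abs(be.mean) < 1e-3

    def test_three_atom_fixture_matches_scalar_hand_calculation(self):
        """Two-atom receptor plus one-atom ligand, all pairs separated far
        enough that the solvent-accessible areas are exactly additive; every
        term is recomputed with explicit scalar formulas."""
        qA, qB, qL = 0.3, -0.3, -1.0
        rhoA, rhoB, rhoL = 1.7, 1.5, 1.8
        epsA, epsB, epsL = 0.1, 0.2, 0.25
        rmhA, rmhB, rmhL = 1.9, 1.66, 2.0
        atoms = [
            AtomRecord("A", "C", 1, qA, rmhA, epsA, rhoA),
            AtomRecord("B", "O", 1, qB, rmhB, epsB, rhoB),
            AtomRecord("L", "C", 9, qL, rmhL, epsL, rhoL),
        ]
        top = Topology(atoms, [Residue(1, "ALA"), Residue(9, "PFC")], {9})
        pA = np.array([0.0, 0.0, 0.0])
        pB = np.array([7.0, 0.0, 0.0])
        pL = np.array([3.5, 7.0, 0.0])
        xyz = np.vstack([pA, pB, pL])
        traj = Trajectory(top, xyz[None], np.zeros(1))
        be = mmgbsa_binding(traj, np.array([2]), salt_molar=0.0)

        dAL = float(np.linalg.norm(pL - pA))
        dBL = float(np.linalg.norm(pL - pB))
        dAB = 7.0
        elec = K_COULOMB * (qA * qL / dAL + qB * qL / dBL)
        vdw = 0.0
        for (qi, rmi, ei, d) in [(qA, rmhA, epsA, dAL), (qB, rmhB, epsB, dBL)]:
            rmin = rmi + rmhL
            eij = math.sqrt(ei * epsL)
            vdw += eij * ((rmin / d) ** 12 - 2 * (rmin / d) ** 6)

        def obc_radius(rho, pairs):
            rho_t = rho - 0.09
            psi = rho_t * sum(hct_closed_form(d, rho_t, s - 0.09) for d, s in pairs)
            inv = 1 / rho_t - math.tanh(1.0 * psi - 0.8 * psi**2 + 4.8 * psi**3) / rho
            return 1 / inv

        def gb(charges, radii, dists):
            # dists[(i, j)] for i < j
            total = 0.0
            for i, (qi, Ri) in enumerate(zip(charges, radii)):
                total += qi * qi / Ri
                for j in range(i + 1, len(charges)):
                    r2 = dists[(i, j)] ** 2
                    f = math.sqrt(r2 + Ri * radii[j] * math.exp(-r2 / (4 * Ri * radii[j])))
                    total += 2 * charges[i] * charges[j] / f
            return -(K_COULOMB / 2.0) * (1 - 1 / 78.5) * total

        R_c = [
            obc_radius(rhoA, [(dAB, rhoB), (dAL, rhoL)]),
            obc_radius(rhoB, [(dAB, rhoA), (dBL, rhoL)]),
            obc_radius(rhoL, [(dAL, rhoA), (dBL, rhoB)]),
        ]
        gb_c = gb([qA, qB, qL], R_c, {(0, 1): dAB, (0, 2): dAL, (1, 2): dBL})
        R_r = [obc_radius(rhoA, [(dAB, rhoB)]), obc_radius(rhoB, [(dAB, rhoA)])]
        gb_r = gb([qA, qB], R_r, {(0, 1): dAB})
        gb_l = gb([qL], [rhoL - 0.09], {})
        expected = elec + vdw + (gb_c - gb_r - gb_l)  # SASA terms cancel exactly
        assert be.mean == pytest.approx(expected, abs=1e-6)

    def test_mean_and_sd_recomputable_from_per_frame(self):
        atoms = [atom("A", 1, 0.4), atom("L", 9, -0.4, rho=1.5)]
        top = Topology(atoms, [Residue(1, "ALA"), Residue(9, "PFC")], {9})
        rng = np.random.default_rng(3)
        frames = np.array(
            [[[0, 0, 0], [4.0 + rng.uniform(-0.3, 0.3), 0, 0]] for _ in range(6)]
        )
        traj = Trajectory(top, frames, np.arange(6.0))
        be = mmgbsa_binding(traj, np.array([1]))
        arr = np.array(be.per_frame)
        assert be.mean == pytest.approx(arr.mean(), abs=1e-9)
        assert be.sd == pytest.approx(arr.std(ddof=1), abs=1e-9)
        assert be.n_frames == 6
        assert be.components.total == pytest.approx(
            be.components.e_elec + be.components.e_vdw
            + be.components.g_gb + be.components.g_np
        )


class TestRanking:
    def test_two_element_order_and_ties(self):
        mk = lambda m: BindingEnergy(m, 0.0, 1, (m,))
        assert [k for k, _ in rank_binders({"A": mk(-12.0), "B": mk(-8.0)})] == ["A", "B"]
        assert [k for k, _ in rank_binders({"B": mk(-5.0), "A": mk(-5.0)})] == ["A", "B"]

    def test_planted_monotone_affinities_recovered(self):
        """Host-guest fixture: cationic host, anionic guest with charges
        scaled by λ; stronger charges must rank as stronger binders."""
        from dataclasses import replace

        from tgsite.synthetic import PfasSpec, build_pfas

        lig_top, lig_xyz = build_pfas(PfasSpec("carboxylate", 4))
        rng = np.random.default_rng(0)
        host_atoms = [
            AtomRecord("NZ", "N", 10, 1.0, 1.824, 0.17, 1.55),
            AtomRecord("C1", "C", 10, 0.0, 1.908, 0.086, 1.7),
            AtomRecord("C2", "C", 10, 0.0, 1.908, 0.086, 1.7),
        ]
        host_xyz = np.array([[0, 0, 0], [-1.5, 0, 1.0], [-1.5, 0, -1.0]], float)
        results = {}
        for lam in (0.25, 0.5, 0.75, 1.0):
            scaled = [replace(a, charge=a.charge * lam) for a in lig_top.atoms]
            top = Topology(
                host_atoms + scaled,
                [Residue(10, "LYS", polarity_class="basic")] + lig_top.residues,
                {2999},
            )
            full = np.vstack([host_xyz, lig_xyz + np.array([5.2, -0.8, 0.0])])
            frames = np.array([full + rng.normal(0, 0.03, full.shape) for _ in range(4)])
            traj = Trajectory(top, frames, np.arange(4.0))
            results[f"lam{lam:.2f}"] = mmgbsa_binding(traj, np.arange(3, 3 + len(scaled)))
        ranked = [k for k, _ in rank_binders(results)]
        assert ranked == ["lam1.00", "lam0.75", "lam0.50", "lam0.25"]
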