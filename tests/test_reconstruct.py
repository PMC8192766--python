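"""Rigid transforms, restraint energy, annealing, superposition RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from homointer import (AnnealConfig, RestraintSet, RigidTransform, anneal,
                       fold_upper, kabsch, make_complex, reconstruct_dimer,
                       restraint_energy, superpose_rmsd)
from homointer import SyntheticSpec, make_monomer


def true_restraints(inter):
    return RestraintSet(tuple(sorted(fold_upper(inter.entries))))


class TestRigidTransform:
    def test_rejects_non_orthonormal_and_reflections(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError, match="improper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        t = RigidTransform.random(rng)
        u = RigidTransform.random(rng)
        pts = rng.normal(size=(10, 3))
        np.testing.assert_allclose(t.compose(u).apply(pts),
                                   t.apply(u.apply(pts)), atol=1e-10)
        ident = t.compose(t.inverse())
        np.testing.assert_allclose(ident.apply(pts), pts, atol=1e-10)


class TestRestraintEnergy:
    def test_native_placement_with_true_restraints_is_zero(self, dimer):
        chains, _, inter = dimer
        mono = chains[0]
        # recover the generating transform from the two copies
        t, _ = kabsch(mono.ca_coords(), chains[1].ca_coords())
        e = restraint_energy(t, mono, true_restraints(inter))
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_flat_bottom_quadratic_closed_form(self, monomer):
        r = RestraintSet(((1, monomer.L),), contact_distance=6.0)
        cfg = AnnealConfig(clash_weight=0.0)
        # push the copy far along x: the energy must equal the flat-bottom
        # quadratic (d - d_c)^2 evaluated at the actual minimum heavy-atom
        # distance of the lighter orientation
        far = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        e_far = restraint_energy(far, monomer, r, cfg)
        assert e_far > 0
        # analytic: both orientations give min distance ~ 500 - span
        xyz, _ = monomer.heavy_atoms()
        assert e_far == pytest.approx(
            _closed_form(xyz, monomer, 500.0), rel=1e-6)

    def test_superposed_copies_have_clash_energy(self, dimer):
        chains, _, inter = dimer
        mono = chains[0]
        e = restraint_energy(RigidTransform.identity(), mono,
                             true_restraints(inter))
        assert e > 0

    def test_zero_restraints_rejected(self, monomer):
        with pytest.raises(ValueError, match="nothing to satisfy"):
            anneal(monomer, RestraintSet(()))


def _closed_form(xyz, monomer, shift):
    res_atoms = {r.index: np.array([a.xyz for a in r.atoms])
                 for r in monomer.residues}
    a1, aL = res_atoms[1], res_atoms[monomer.L]
    best = np.inf
    for fixed, moved in ((a1, aL), (aL, a1)):
        moved_s = moved + [shift, 0.0, 0.0]
        d = np.linalg.norm(fixed[:, None] - moved_s[None, :], axis=2).min()
        best = min(best, max(0.0, d - 6.0) ** 2)
    return best


class TestSuperposeRmsd:
    def test_identity_is_zero(self, dimer):
        chains, _, _ = dimer
        assert superpose_rmsd(chains, chains) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_model_is_zero(self, dimer):
        chains, _, _ = dimer
        t = RigidTransform.random(np.random.default_rng(1))
        moved = [c.transformed(t.rotation, t.translation) for c in chains]
        assert superpose_rmsd(moved, chains) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_arguments(self, dimer):
        chains, _, _ = dimer
        t = RigidTransform.random(np.random.default_rng(2))
        moved = [chains[0],
                 chains[1].transformed(t.rotation, t.translation)]
        assert superpose_rmsd(moved, chains) == pytest.approx(
            superpose_rmsd(chains, moved), abs=1e-6)

    def test_chain_swap_is_tried(self, dimer):
        chains, _, _ = dimer
        swapped = [chains[1].transformed(np.eye(3), np.zeros(3), "A"),
                   chains[0].transformed(np.eye(3), np.zeros(3), "B")]
        assert superpose_rmsd(swapped, chains) == pytest.approx(0.0, abs=1e-6)

    def test_three_point_analytic_case(self):
        from homointer import Atom, ChainRecord, Residue

        def chain(points, cid="A"):
            return ChainRecord(cid, [
                Residue(k, "ALA", [Atom("CA", "C", tuple(p))])
                for k, p in enumerate(points, start=1)
            ])

        native = [chain([(0, 0, 0), (4, 0, 0), (8, 0, 0)])]
        model = [chain([(0, 0, 0), (4, 0, 0), (8, 3, 0)])]
        got = superpose_rmsd(model, native)
        # independent check: brute-force minimization over planar poses
        from scipy.optimize import minimize
        P = np.array([[0, 0, 0], [4, 0, 0], [8, 3, 0]], float)
        Q = np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0]], float)

        def f(x):
            R = Rotation.from_rotvec([0, 0, x[0]]).as_matrix()
            moved = P @ R.T + [x[1], x[2], 0.0]
            return np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))

        best = min(minimize(f, g, method="Nelder-Mead").fun
                   for g in ([0, 0, 0], [0.3, -1, 0], [-0.3, 1, 0]))
        assert got == pytest.approx(best, abs=1e-4)

    def test_length_mismatch_is_error(self, dimer):
        chains, _, _ = dimer
        short = SyntheticSpec(L=20, seed=1)
        other = make_monomer(short)
        with pytest.raises(ValueError):
            superpose_rmsd([other, other], chains)


class TestAnneal:
    def test_same_seed_identical_report(self, dimer):
        chains, _, inter = dimer
        cfg = AnnealConfig(restarts=2, steps_per_temperature=20, seed=4)
        t1, r1 = anneal(chains[0], true_restraints(inter), cfg)
        t2, r2 = anneal(chains[0], true_restraints(inter), cfg)
        assert r1.best_energy == r2.best_energy
        np.testing.assert_array_equal(t1.rotation, t2.rotation)
        np.testing.assert_array_equal(t1.translation, t2.translation)

    def test_single_restraint_reaches_zero_energy(self, dimer):
        chains, _, inter = dimer
        pair = sorted(fold_upper(inter.entries))[0]
        cfg = AnnealConfig(restarts=3, seed=0)
        _, report = anneal(chains[0], RestraintSet((pair,)), cfg)
        assert report.best_energy == pytest.approx(0.0, abs=1e-6)
        assert report.satisfied_fraction == 1.0

    def test_recovery_on_true_restraints(self, dimer):
        chains, _, inter = dimer
        model, report = reconstruct_dimer(
            chains[0], true_restraints(inter),
            AnnealConfig(seed=1), native=chains)
        assert report.satisfied_fraction >= 0.9
        assert report.rmsd_to_native < 2.0

    def test_false_restraints_degrade_rmsd(self, dimer):
        chains, _, inter = dimer
        good = sorted(fold_upper(inter.entries))
        rng = np.random.default_rng(0)
        L = chains[0].L
        bad = []
        while len(bad) < 2 * len(good):
            i, j = sorted(rng.integers(1, L + 1, size=2))
            if i != j and (i, j) not in inter.entries and \
                    (j, i) not in inter.entries and (int(i), int(j)) not in bad:
                bad.append((int(i), int(j)))

        def median_rmsd(pairs):
            vals = []
            for seed in range(3):
                _, rep = reconstruct_dimer(
                    chains[0], RestraintSet(tuple(pairs)),
                    AnnealConfig(seed=seed, restarts=4), native=chains)
                vals.append(rep.rmsd_to_native)
            return float(np.median(vals))

        assert median_rmsd(good) <= median_rmsd(good + bad)
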