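"""Truth contact maps: distance definitions, pair selection, density."""

import numpy as np
import pytest

from homointer import (Atom, ChainRecord, ContactThresholds, Residue,
                       RigidTransform, SyntheticSpec, contact_density,
                       interchain_map, intrachain_map, make_monomer,
                       select_max_pair, translation_transform)
from homointer.contacts import ContactMap


def touching_shift(mono, lo=2.5, hi=5.5):
    """Largest x-translation at which the copies still touch (<= 6 A) while
    staying sterically separated (closest approach within [lo, hi])."""
    from scipy.spatial import cKDTree
    xyz, _ = mono.heavy_atoms()
    tree = cKDTree(xyz)
    span = xyz[:, 0].max() - xyz[:, 0].min()
    for t in np.arange(span + 8.0, 1.0, -0.25):
        d, _ = tree.query(xyz + [t, 0.0, 0.0], k=1)
        if lo <= d.min() <= hi:
            return float(t)
    raise AssertionError("no touching shift found")


def chain_with_cb(positions, chain_id="A", names=None):
    """One CB per residue at the given positions (CA colocated)."""
    residues = []
    for k, pos in enumerate(positions, start=1):
        name = (names or {}).get(k, "ALA")
        atoms = [Atom("CA", "C", tuple(pos))]
        if name != "GLY":
            atoms.append(Atom("CB", "C", tuple(pos)))
        residues.append(Residue(k, name, atoms))
    return ChainRecord(chain_id, residues)


class TestIntrachainMap:
    @pytest.mark.parametrize("d,expected", [(8.0, True), (8.01, False)])
    def test_cutoff_is_inclusive(self, d, expected):
        ch = chain_with_cb([(0, 0, 0), (d, 0, 0)])
        cmap = intrachain_map(ch)
        assert ((1, 2) in cmap) is expected

    def test_glycine_falls_back_to_calpha(self):
        ch = chain_with_cb([(0, 0, 0), (7.0, 0, 0)],
                           names={1: "GLY", 2: "GLY"})
        assert (1, 2) in intrachain_map(ch)

    def test_residue_without_ca_or_cb_excluded_with_warning(self):
        residues = [
            Residue(1, "ALA", [Atom("CB", "C", (0, 0, 0))]),
            Residue(2, "ALA", [Atom("SC1", "C", (1, 0, 0))]),  # no CA/CB
            Residue(3, "ALA", [Atom("CB", "C", (2, 0, 0))]),
        ]
        ch = ChainRecord("A", residues)
        with pytest.warns(UserWarning, match="lack both CB and CA"):
            cmap = intrachain_map(ch)
        assert cmap.entries == frozenset({(1, 3)})

    def test_matches_brute_force_double_loop(self, monomer):
        th = ContactThresholds()
        cmap = intrachain_map(monomer, th)
        coords, valid = monomer.contact_coords()
        expected = set()
        for i in range(monomer.L):
            for j in range(i + 1, monomer.L):
                if not (valid[i] and valid[j]):
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= th.intra_cb:
                    expected.add((i + 1, j + 1))
        assert cmap.entries == frozenset(expected)


class TestInterchainMap:
    def test_near_pair_included_far_pair_not(self):
        a = chain_with_cb([(0, 0, 0), (10, 0, 0)])
        b = chain_with_cb([(0, 5.5, 0), (40, 40, 40)], "B")
        cmap = interchain_map(a, b)
        assert (1, 1) in cmap and (2, 2) not in cmap

    def test_translation_dimer_with_flat_side_is_symmetric(self):
        # a monomer whose atoms all share x = 0 translated along x: the
        # displacement between any two residues is orthogonal to the shift,
        # so |a - t| = |a + t| and the map is exactly symmetric
        rng = np.random.default_rng(5)
        pts = np.column_stack([np.zeros(20), rng.uniform(0, 12, 20),
                               np.arange(20) * 1.0])
        a = chain_with_cb(pts)
        b = a.transformed(np.eye(3), np.array([5.0, 0.0, 0.0]), "B")
        cmap = interchain_map(a, b)
        assert cmap.entries  # the fixture must actually touch
        assert all((j, i) in cmap.entries for i, j in cmap.entries)

    def test_generic_translation_dimer_need_not_be_symmetric(self):
        spec = SyntheticSpec(seed=2, fold="walk",
                             transform=translation_transform([0, 0, 0]))
        mono = make_monomer(spec)
        shift = touching_shift(mono)
        b = mono.transformed(np.eye(3), np.array([shift, 0.0, 0.0]), "B")
        cmap = interchain_map(mono, b)
        assert cmap.entries
        # storage keeps orientations separate, so asymmetry is representable
        asym = [(i, j) for i, j in cmap.entries
                if (j, i) not in cmap.entries]
        assert isinstance(asym, list)

    def test_rotated_dimer_map_can_be_asymmetric(self, dimer):
        chains, _, inter = dimer
        asym = [(i, j) for i, j in inter.entries
                if (j, i) not in inter.entries]
        # the antiparallel fixture is genuinely asymmetric somewhere or the
        # map is symmetric; either way storage keeps orientations separate
        assert inter.kind == "inter"
        assert all(1 <= i <= inter.L and 1 <= j <= inter.L
                   for i, j in inter.entries)

    def test_all_far_gives_empty_map(self):
        a = chain_with_cb([(0, 0, 0)])
        b = chain_with_cb([(0, 6.5, 0)], "B")
        assert len(interchain_map(a, b)) == 0

    def test_requires_identical_sequences(self):
        a = chain_with_cb([(0, 0, 0)])
        b = chain_with_cb([(0, 1, 0)], "B", names={1: "GLY"})
        with pytest.raises(ValueError, match="identical sequences"):
            interchain_map(a, b)


class TestSelectMaxPair:
    @staticmethod
    def place(mono, dy, cid):
        return mono.transformed(np.eye(3), np.array([0.0, dy, 0.0]), cid)

    def test_partner_with_most_contacts_wins(self):
        mono = chain_with_cb([(x * 4.0, 0, 0) for x in range(8)])
        near = self.place(mono, 5.0, "B")
        far = self.place(mono, 50.0, "C")
        sel = select_max_pair([mono, near, far])
        assert sel.partner_chain_id == "B"
        assert sel.contact_count == max(sel.all_counts.values())
        assert sel.all_counts["C"] == 0

    def test_tie_breaks_to_earliest_chain(self):
        mono = chain_with_cb([(x * 4.0, 0, 0) for x in range(8)])
        b = self.place(mono, 5.0, "B")
        d = self.place(mono, -5.0, "D")
        sel = select_max_pair([mono, b, d])
        assert sel.all_counts["B"] == sel.all_counts["D"]
        assert sel.partner_chain_id == "B"

    def test_zero_contact_partner_loses(self):
        mono = chain_with_cb([(x * 4.0, 0, 0) for x in range(8)])
        b = self.place(mono, 50.0, "B")
        c = self.place(mono, 5.5, "C")
        assert select_max_pair([mono, b, c]).partner_chain_id == "C"

    def test_single_chain_is_an_error(self):
        mono = chain_with_cb([(0, 0, 0)])
        with pytest.raises(ValueError):
            select_max_pair([mono])


class TestContactDensity:
    @pytest.mark.parametrize("n,L,expected", [(30, 60, 0.5), (0, 10, 0.0),
                                              (235, 50, 4.7)])
    def test_entries_per_length(self, n, L, expected):
        full = [(i, j) for i in range(1, L + 1) for j in range(1, L + 1)
                if i != j][:n]
        cmap = ContactMap("inter", L, frozenset(full))
        assert contact_density(cmap) == pytest.approx(expected)

    def test_invariant_under_rigid_motion(self, default_spec, dimer):
        chains, _, inter = dimer
        t = RigidTransform.random(np.random.default_rng(0))
        moved = [c.transformed(t.rotation, t.translation) for c in chains]
        inter2 = interchain_map(moved[0], moved[1])
        assert contact_density(inter2) == pytest.approx(
            contact_density(inter))
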