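"""True contact maps for homomultimers.

Two distinct contact definitions are in play, matching common practice for
monomer contact prediction on one hand and interface analysis on the other:

* intrachain: Cbeta-Cbeta distance <= 8.0 A (Calpha substituted when Cbeta
  is absent, e.g. glycine), residue pairs within one chain, stored as the
  upper triangle i < j;
* interchain: minimum heavy-atom distance <= 6.0 A between residue i of the
  first chain and residue j of the partner chain.  The interchain map is a
  full asymmetric matrix: (i, j) and (j, i) are independent entries, because
  residue i of chain A touching residue j of chain B says nothing about
  residue j of chain A touching residue i of chain B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .chains import ChainRecord


@dataclass(frozen=True)
class ContactThresholds:
    """Distance cutoffs (Angstrom) and the short-range separation filter."""

    intra_cb: float = 8.0
    inter_heavy: float = 6.0
    min_sequence_separation: int = 6

    def __post_init__(self) -> None:
        if self.intra_cb <= 0 or self.inter_heavy <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.min_sequence_separation <= 0:
            raise ValueError("min_sequence_separation must be positive")


@dataclass(frozen=True)
class ContactMap:
    """Binary residue-pair contact map over an index space 1..L.

    ``kind`` is "intra" (symmetric, canonicalized to i < j) or "inter"
    (full asymmetric set; (i, j) means residue i of the first chain contacts
    residue j of the partner chain).
    """

    kind: str
    L: int
    entries: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise ValueError(f"unknown contact map kind {self.kind!r}")
        if self.L <= 0:
            raise ValueError("L must be positive")
        for i, j in self.entries:
            if not (1 <= i <= self.L and 1 <= j <= self.L):
                raise ValueError(f"entry ({i},{j}) outside 1..{self.L}")
            if self.kind == "intra" and i >= j:
                raise ValueError(
                    f"intra map entries must satisfy i < j, got ({i},{j})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self.entries

    def to_dense(self) -> np.ndarray:
        """0/1 matrix; intra maps are symmetrized for display."""
        m = np.zeros((self.L, self.L), dtype=np.int8)
        for i, j in self.entries:
            m[i - 1, j - 1] = 1
            if self.kind == "intra":
                m[j - 1, i - 1] = 1
        return m


@dataclass(frozen=True)
class PairSelection:
    """Partner chain chosen for analysis: the one with most contacts to A."""

    partner_chain_id: str
    contact_count: int
    all_counts: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if self.partner_chain_id not in self.all_counts:
            raise ValueError("partner chain missing from counts")
        if self.contact_count != max(self.all_counts.values()):
            raise ValueError("contact_count is not the maximum count")


def intrachain_map(chain: ChainRecord,
                   th: ContactThresholds = ContactThresholds()) -> ContactMap:
    """Upper-triangle intrachain contacts of one chain.

    A pair (i, j), i < j, is a contact when the distance between the contact
    atoms (CB, else CA) is <= ``th.intra_cb``.  Residues with neither atom
    are excluded from all pairs with a warning.
    """
    coords, valid = chain.contact_coords()
    if not np.all(valid):
        missing = [r.index for r, v in zip(chain.residues, valid) if not v]
        warnings.warn(
            f"chain {chain.chain_id}: residues {missing} lack both CB and CA; "
            "excluded from the intrachain map"
        )
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return ContactMap("intra", chain.L, frozenset())
    d = squareform(pdist(coords[idx]))
    entries = set()
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if d[a, b] <= th.intra_cb:
                entries.add((int(idx[a]) + 1, int(idx[b]) + 1))
    return ContactMap("intra", chain.L, frozenset(entries))


def interchain_map(a: ChainRecord, b: ChainRecord,
                   th: ContactThresholds = ContactThresholds()) -> ContactMap:
    """Asymmetric interchain contact map between two homogenized chains.

    (i, j) is included iff the minimum heavy-atom distance between residue i
    of ``a`` and residue j of ``b`` is <= ``th.inter_heavy``.  The map is not
    symmetrized: (i, j) and (j, i) are looked up independently downstream.
    """
    if a.sequence != b.sequence:
        raise ValueError("interchain_map requires homogenized chains "
                         "(identical sequences)")
    ca_xyz, ca_res = a.heavy_atoms()
    cb_xyz, cb_res = b.heavy_atoms()
    pairs = cKDTree(ca_xyz).query_ball_tree(cKDTree(cb_xyz), th.inter_heavy)
    entries = set()
    for ia, hits in enumerate(pairs):
        for ib in hits:
            entries.add((int(ca_res[ia]), int(cb_res[ib])))
    return ContactMap("inter", a.L, frozenset(entries))


def select_max_pair(chains: list[ChainRecord],
                    th: ContactThresholds = ContactThresholds()
                    ) -> PairSelection:
    """Pick the partner of the first chain with the most interchain contacts.

    For chains A, B, C, D the pairs AB, AC, AD are scored; ties go to the
    earliest chain in input order.
    """
    if len(chains) < 2:
        raise ValueError("select_max_pair needs at least two chains")
    first = chains[0]
    counts: dict[str, int] = {}
    best_id, best_n = None, -1
    for other in chains[1:]:
        n = len(interchain_map(first, other, th))
        counts[other.chain_id] = n
        if n > best_n:  # strict: first chain wins ties
            best_id, best_n = other.chain_id, n
    assert best_id is not None
    return PairSelection(best_id, best_n, counts)


def contact_density(inter: ContactMap) -> float:
    """Number of interchain contacts per residue of the monomer, |entries|/L."""
    if inter.L <= 0:
        raise ValueError("L must be positive")
    return len(inter.entries) / inter.L
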