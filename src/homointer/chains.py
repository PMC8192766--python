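"""Core chain containers shared by every stage of the pipeline.

A cleaned chain is a list of residues renumbered 1..L with per-residue
heavy-atom coordinates.  Coordinates are plain float64 arrays in Angstrom;
hydrogens are expected to have been stripped by the reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 3-letter -> 1-letter code for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB atom name, element symbol, position in Angstrom."""

    name: str
    element: str
    xyz: tuple[float, float, float]

    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    """A residue with a (possibly reindexed) number and its heavy atoms."""

    index: int
    name: str  # 3-letter residue name; non-standard names map to sequence 'X'
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def contact_atom(self) -> Atom | None:
        """Atom used for the intrachain contact definition.

        Cbeta when present, Calpha otherwise (glycine, or any residue with a
        missing Cbeta); ``None`` if the residue has neither.
        """
        return self.atom("CB") or self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class RawChain:
    """A chain as read from a coordinate file: author numbering, gaps allowed."""

    chain_id: str
    residues: list[Residue]


@dataclass
class RawComplex:
    """A multi-chain structure prior to cleaning."""

    chains: list[RawChain]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a complex must contain at least one chain")
        for ch in self.chains:
            for res in ch.residues:
                for a in res.atoms:
                    if not np.all(np.isfinite(a.coords())):
                        raise ValueError(
                            f"non-finite coordinates in chain {ch.chain_id}"
                        )


@dataclass
class ChainRecord:
    """A cleaned chain: residues numbered exactly 1..L, each with >=1 atom."""

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        for k, res in enumerate(self.residues, start=1):
            if res.index != k:
                raise ValueError(
                    f"chain {self.chain_id}: residue index {res.index} at "
                    f"position {k}; cleaned chains must be numbered 1..L"
                )
            if not res.atoms:
                raise ValueError(
                    f"chain {self.chain_id}: residue {k} has no atoms"
                )

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(res.one_letter for res in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) Calpha coordinates; raises if any residue lacks a CA."""
        out = np.empty((self.L, 3), dtype=float)
        for k, res in enumerate(self.residues):
            ca = res.atom("CA")
            if ca is None:
                raise ValueError(
                    f"chain {self.chain_id}: residue {res.index} has no CA"
                )
            out[k] = ca.xyz
        return out

    def contact_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-residue coordinates for the Cbeta/Calpha contact definition.

        Returns (coords, valid): coords is (L, 3) with rows undefined where
        valid is False (residue has neither CB nor CA).
        """
        coords = np.zeros((self.L, 3), dtype=float)
        valid = np.zeros(self.L, dtype=bool)
        for k, res in enumerate(self.residues):
            a = res.contact_atom()
            if a is not None:
                coords[k] = a.xyz
                valid[k] = True
        return coords, valid

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy atoms flattened: (coords (N,3), residue index (N,) 1-based)."""
        coords: list[np.ndarray] = []
        res_idx: list[int] = []
        for res in self.residues:
            for a in res.atoms:
                coords.append(a.coords())
                res_idx.append(res.index)
        return np.array(coords, dtype=float), np.array(res_idx, dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_id: str | None = None) -> "ChainRecord":
        """Rigidly moved copy of this chain (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_res = []
        for res in self.residues:
            atoms = [
                Atom(a.name, a.element, tuple(R @ a.coords() + t))
                for a in res.atoms
            ]
            new_res.append(Residue(res.index, res.name, atoms))
        return ChainRecord(chain_id or self.chain_id, new_res)
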