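"""Readers and writers for the formats the pipeline speaks.

* PDB coordinate files: read through gemmi (ATOM records only, hydrogens and
  waters dropped, first altloc kept); cleaned single-chain files are written
  as minimal ATOM + TER + END records.
* RR contact dialect: `i j d_low d_high prob`, whitespace separated, one
  pair per line; sequence/comment header lines are ignored on read.  Truth
  maps carry a leading `L <int> KIND <intra|inter>` header so the index
  space survives a round trip.
* Dense 0/1 matrix text, for eyeballing maps.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gemmi

from .chains import Atom, ChainRecord, RawChain, RawComplex, Residue
from .contacts import ContactMap
from .infer import PredictionSet

_NUCLEIC = {
    "DA", "DT", "DG", "DC", "DU", "DI", "A", "U", "G", "C", "T", "I",
}

_RR_CUTOFF = {"intra": 8.0, "inter": 6.0}


# ---------------------------------------------------------------------------
# PDB

def read_complex_pdb(path: str | Path, source_id: str = "") -> RawComplex:
    """Parse a PDB file into a RawComplex.

    Keeps ATOM records of amino-acid residues only; HETATM, waters, nucleic
    acids and hydrogens are dropped, and only the first altloc of each atom
    name within a residue is kept.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_waters()
    model = st[0]
    chains: list[RawChain] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag != "A" or res.name in _NUCLEIC:
                continue
            seen: set[str] = set()
            atoms: list[Atom] = []
            for atom in res:
                if atom.is_hydrogen() or atom.name in seen:
                    continue
                seen.add(atom.name)
                atoms.append(Atom(atom.name, atom.element.name,
                                  (atom.pos.x, atom.pos.y, atom.pos.z)))
            if atoms:
                residues.append(Residue(res.seqid.num, res.name, atoms))
        if residues:
            chains.append(RawChain(chain.name, residues))
    if not chains:
        raise ValueError(f"{path}: no protein ATOM records found")
    return RawComplex(chains, source_id or Path(path).stem)


def _format_atom_line(serial: int, atom: Atom, res: Residue,
                      chain_id: str) -> str:
    name = atom.name
    # column-13 convention: 1-letter elements start at column 14
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    x, y, z = atom.xyz
    return (
        f"ATOM  {serial:5d} {name} {res.name:<3s} {chain_id:1s}"
        f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_chain_pdb(chain: ChainRecord, path: str | Path) -> None:
    """Write a cleaned single-chain PDB file (ATOM + TER + END only)."""
    write_complex_pdb([chain], path)


def write_complex_pdb(chains: list[ChainRecord], path: str | Path) -> None:
    """Write one or more cleaned chains as a multi-chain PDB file."""
    buf = _io.StringIO()
    serial = 0
    for chain in chains:
        last_res = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                buf.write(_format_atom_line(serial, atom, res,
                                            chain.chain_id) + "\n")
            last_res = res
        serial += 1
        assert last_res is not None
        buf.write(f"TER   {serial:5d}      {last_res.name:<3s} "
                  f"{chain.chain_id:1s}{last_res.index:4d}\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def read_chain_pdb(path: str | Path) -> ChainRecord:
    """Read back a cleaned single-chain PDB file written by this module."""
    raw = read_complex_pdb(path)
    if len(raw.chains) != 1:
        raise ValueError(f"{path}: expected one chain, found "
                         f"{len(raw.chains)}")
    ch = raw.chains[0]
    return ChainRecord(ch.chain_id,
                       [Residue(k, r.name, r.atoms)
                        for k, r in enumerate(ch.residues, start=1)])


def read_cleaned_complex_pdb(path: str | Path) -> list[ChainRecord]:
    raw = read_complex_pdb(path)
    return [
        ChainRecord(ch.chain_id,
                    [Residue(k, r.name, r.atoms)
                     for k, r in enumerate(ch.residues, start=1)])
        for ch in raw.chains
    ]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(chain: ChainRecord, path: str | Path,
                header: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f">{header or chain.chain_id}\n")
        seq = chain.sequence
        for k in range(0, len(seq), 60):
            fh.write(seq[k:k + 60] + "\n")


# ---------------------------------------------------------------------------
# RR contact dialect

def write_rr_map(cmap: ContactMap, path: str | Path,
                 cutoff: float | None = None) -> None:
    """Serialize a truth map: header `L <int> KIND <kind>`, then RR lines."""
    cut = _RR_CUTOFF[cmap.kind] if cutoff is None else cutoff
    with open(path, "w") as fh:
        fh.write(f"L {cmap.L} KIND {cmap.kind}\n")
        for i, j in sorted(cmap.entries):
            fh.write(f"{i} {j} 0 {cut:.1f} 1.0\n")


def read_rr_map(path: str | Path) -> ContactMap:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "L" or header[2] != "KIND":
            raise ValueError(f"{path}: missing `L <int> KIND <kind>` header")
        L, kind = int(header[1]), header[3]
        entries = set()
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            entries.add((int(parts[0]), int(parts[1])))
    return ContactMap(kind, L, frozenset(entries))


def write_rr_predictions(pred: PredictionSet, path: str | Path,
                         d_high: float = 8.0) -> None:
    """Write scored predictions in the CASP RR dialect, sorted by score."""
    items = sorted(pred.items, key=lambda t: (-t[2], t[0], t[1]))
    with open(path, "w") as fh:
        for i, j, s in items:
            fh.write(f"{i} {j} 0 {d_high:.1f} {s:.6f}\n")


def read_rr_predictions(path: str | Path,
                        L: int | None = None) -> PredictionSet:
    """Parse an RR prediction file; non-numeric header lines are skipped.

    ``L`` defaults to the largest residue index seen (pass the true monomer
    length when known, so Top-L/k cutoffs resolve correctly).
    """
    items: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                continue
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                continue  # sequence or comment header
            score = float(parts[4]) if len(parts) >= 5 else 1.0
            items.append((i, j, score))
    if L is None:
        L = max((j for _, j, _ in items), default=1)
    return PredictionSet(L, tuple(items))


# ---------------------------------------------------------------------------
# Dense matrices

def write_dense(cmap: ContactMap, path: str | Path) -> None:
    m = cmap.to_dense()
    with open(path, "w") as fh:
        fh.write(f"# L {cmap.L} KIND {cmap.kind}\n")
        for row in m:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
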