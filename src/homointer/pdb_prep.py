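"""Cleaning cascade for multi-chain coordinate files.

A raw homomultimer entry is turned into analysis-ready chains in four steps:

1. split into chains and renumber residues 1..L, keeping ATOM content only;
2. homogenize chain pairs: chains whose global-alignment identity is below
   a threshold (default 95%) are rejected as not being copies of the same
   protein; above it, mismatched or gapped alignment columns are deleted
   from BOTH chains so the retained sequences are identical;
3. require at least one interchain contact (closest heavy atoms <= 6.0 A),
   otherwise the entry is not a physical complex for our purposes;
4. optional greedy redundancy removal across entries at 30% identity.

Validity here means "the chain parses and every residue has coordinates";
no secondary-structure gate is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from scipy.spatial import cKDTree

from .chains import ChainRecord, RawComplex, Residue


@dataclass(frozen=True)
class PrepConfig:
    """Thresholds of the cleaning cascade."""

    min_chain_similarity: float = 0.95
    dedup_identity: float = 0.30
    interchain_threshold: float = 6.0

    def __post_init__(self) -> None:
        for f in (self.min_chain_similarity, self.dedup_identity):
            if not (0.0 < f <= 1.0):
                raise ValueError("identity fractions must lie in (0, 1]")
        if self.interchain_threshold <= 0:
            raise ValueError("interchain_threshold must be positive")


class ChainRejection(ValueError):
    """A chain or chain pair failed a cleaning gate."""


def _aligner() -> Align.PairwiseAligner:
    # global alignment, match=1 / mismatch=0 / linear gap -1: a deliberately
    # plain scheme so the identity fraction is reproducible
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -1.0
    al.extend_gap_score = -1.0
    return al


def align_identity(seq_a: str, seq_b: str) -> tuple[float, str, str]:
    """Global-alignment identity = matches / aligned columns.

    Returns (identity, gapped_a, gapped_b) for the best alignment.
    'X' residues never match anything, including another 'X'.
    """
    if not seq_a or not seq_b:
        raise ChainRejection("cannot align an empty sequence")
    aln = _aligner().align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-" and x != "X")
    return matches / len(ga), ga, gb


def split_and_reindex(raw: RawComplex) -> list[ChainRecord]:
    """One ChainRecord per chain, residues renumbered 1..L in file order."""
    out: list[ChainRecord] = []
    for ch in raw.chains:
        if not ch.residues:
            raise ChainRejection(
                f"{raw.source_id}: empty chain {ch.chain_id!r}"
            )
        residues = [Residue(k, r.name, r.atoms)
                    for k, r in enumerate(ch.residues, start=1)]
        out.append(ChainRecord(ch.chain_id, residues))
    return out


def homogenize_pair(a: ChainRecord, b: ChainRecord,
                    cfg: PrepConfig = PrepConfig()
                    ) -> tuple[ChainRecord, ChainRecord]:
    """Make two near-identical chains exactly identical, or reject the pair.

    Identity below ``cfg.min_chain_similarity`` raises ChainRejection.
    Otherwise residues at mismatched or gapped columns are deleted from both
    chains, which are then renumbered 1..L'; the returned sequences are
    byte-identical.
    """
    if a.L == 0 or b.L == 0:
        raise ChainRejection("cannot homogenize an empty chain")
    identity, ga, gb = align_identity(a.sequence, b.sequence)
    if identity < cfg.min_chain_similarity:
        raise ChainRejection(
            f"chains {a.chain_id}/{b.chain_id}: identity {identity:.3f} "
            f"below {cfg.min_chain_similarity:.2f}"
        )
    keep_a: list[Residue] = []
    keep_b: list[Residue] = []
    ia = ib = 0
    for x, y in zip(ga, gb):
        res_a = a.residues[ia] if x != "-" else None
        res_b = b.residues[ib] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if res_a is not None and res_b is not None and x == y and x != "X":
            keep_a.append(res_a)
            keep_b.append(res_b)
    if not keep_a:
        raise ChainRejection(
            f"chains {a.chain_id}/{b.chain_id}: nothing left after "
            "removing mismatches"
        )
    new_a = ChainRecord(a.chain_id, [Residue(k, r.name, r.atoms)
                                     for k, r in enumerate(keep_a, start=1)])
    new_b = ChainRecord(b.chain_id, [Residue(k, r.name, r.atoms)
                                     for k, r in enumerate(keep_b, start=1)])
    assert new_a.sequence == new_b.sequence
    return new_a, new_b


def homogenize_complex(chains: list[ChainRecord],
                       cfg: PrepConfig = PrepConfig()
                       ) -> list[ChainRecord]:
    """Homogenize every chain against the first, iterating to a fixed point.

    Chains failing the identity gate against chain A are dropped with their
    rejection swallowed only if at least one partner survives; trimming A
    against one partner can desynchronize earlier partners, so passes repeat
    until no residue is removed.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    first = chains[0]
    partners: list[ChainRecord] = []
    rejections: list[str] = []
    for other in chains[1:]:
        try:
            first, kept = homogenize_pair(first, other, cfg)
            partners.append(kept)
        except ChainRejection as exc:
            rejections.append(str(exc))
    if not partners:
        raise ChainRejection(
            "no partner chain passed the identity gate: " + "; ".join(rejections)
        )
    # re-run passes until all partners match the (possibly shrunken) first
    for _ in range(len(partners) + 1):
        if all(p.sequence == first.sequence for p in partners):
            return [first] + partners
        redo = []
        for p in partners:
            first, p2 = homogenize_pair(first, p, cfg)
            redo.append(p2)
        partners = redo
    raise ChainRejection("homogenization did not converge")


def require_interchain_contact(chains: list[ChainRecord],
                               cfg: PrepConfig = PrepConfig()) -> bool:
    """True iff the first chain has any heavy atom within the cutoff of
    any other chain's heavy atoms (inclusive boundary)."""
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    xyz_a, _ = chains[0].heavy_atoms()
    tree_a = cKDTree(xyz_a)
    for other in chains[1:]:
        xyz_b, _ = other.heavy_atoms()
        d, _ = tree_a.query(xyz_b, k=1)
        if d.min() <= cfg.interchain_threshold:
            return True
    return False


def greedy_dedup(records: list[ChainRecord],
                 cfg: PrepConfig = PrepConfig()) -> list[ChainRecord]:
    """Greedy redundancy filter: scan in input order, drop any record whose
    identity to an already-kept record exceeds ``cfg.dedup_identity``."""
    kept: list[ChainRecord] = []
    for rec in records:
        redundant = any(
            align_identity(rec.sequence, prev.sequence)[0] > cfg.dedup_identity
            for prev in kept
        )
        if not redundant:
            kept.append(rec)
    return kept
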