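"""Synthetic homomultimers and fabricated monomer contact predictions.

The generator builds a toy monomer fold (an ideal alpha-helix Calpha trace,
or a self-avoiding random walk) decorated with a pseudo-Cbeta and one to
three pseudo side-chain heavy atoms per residue, duplicates it through a
rigid transform into a homodimer or a higher-order assembly, derives the
true intrachain and interchain contact maps, and fabricates a "predicted"
monomer contact map that superimposes intrachain and interchain truth with
configurable miss/false-positive rates and score noise — emulating what a
monomeric deep-learning contact predictor sees for a homomultimer, where
both signals share one upper-triangle map.

The default dimer places the second helix antiparallel alongside the first
(a coiled-coil-like interface), so that interchain contacts pair residue i
with residues near L+1-i: sequence-distant pairs that survive short-range
filtering, as interface contacts of real homodimers typically do.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chains import Atom, ChainRecord, Residue
from .contacts import (ContactMap, ContactThresholds, interchain_map,
                       intrachain_map, select_max_pair)
from .geometry import RigidTransform
from .infer import PredictionSet

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal alpha-helix Calpha parameters: 100 deg turn, 1.5 A rise, 2.3 A radius
_HELIX_TURN = np.deg2rad(100.0)
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_CA_STEP = 3.8  # consecutive Calpha spacing for the walk fold


@dataclass(frozen=True)
class PredictorModel:
    """Error model of the fabricated monomer prediction.

    keep rates are per-entry retention probabilities for the true intrachain
    and interchain signals; fp_rate is the fraction of non-contact upper
    triangle pairs injected as false positives; scores are base +- Gaussian
    noise, clipped to [0, 1].
    """

    intra_keep: float = 0.85
    inter_keep: float = 0.70
    fp_rate: float = 0.10
    score_noise_sd: float = 0.10
    true_base_score: float = 0.80
    false_base_score: float = 0.40

    def __post_init__(self) -> None:
        for r in (self.intra_keep, self.inter_keep, self.fp_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic homomultimer target."""

    L: int = 48
    fold: str = "helix"  # or "walk"
    n_copies: int = 2
    transform: RigidTransform | None = None  # None: auto antiparallel packing
    interface_gap: float = 3.0  # target closest heavy-atom approach, A
    min_clearance: float = 1.5  # steric floor between copies, A
    predictor: PredictorModel = field(default_factory=PredictorModel)
    thresholds: ContactThresholds = field(default_factory=ContactThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 12:
            raise ValueError(
                "L must be >= 12 so separation-6 filtering leaves pairs"
            )
        if self.fold not in ("helix", "walk"):
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.n_copies < 2:
            raise ValueError("a multimer needs at least two copies")


def _rng(tag: int, seed: int) -> np.random.Generator:
    # distinct independent streams per operation, all reproducible from seed
    return np.random.default_rng([tag, seed])


def _helix_trace(L: int) -> np.ndarray:
    k = np.arange(L)
    return np.column_stack([
        _HELIX_RADIUS * np.cos(k * _HELIX_TURN),
        _HELIX_RADIUS * np.sin(k * _HELIX_TURN),
        _HELIX_RISE * k,
    ])


def _walk_trace(L: int, rng: np.random.Generator,
                min_separation: float = 3.5, retries: int = 40,
                restarts: int = 25) -> np.ndarray:
    for _ in range(restarts):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(L - 1):
            placed = False
            for _ in range(retries):
                step = rng.normal(size=3)
                step *= _CA_STEP / np.linalg.norm(step)
                cand = pts[-1] + step
                prev = np.array(pts[:-1]) if len(pts) > 1 else None
                if prev is None or np.min(
                        np.linalg.norm(prev - cand, axis=1)) >= min_separation:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("self-avoiding walk failed after bounded retries")


def _sidechain_directions(ca: np.ndarray) -> np.ndarray:
    """Outward unit vector per residue: away from the local backbone."""
    L = len(ca)
    dirs = np.zeros((L, 3))
    for k in range(L):
        lo, hi = max(0, k - 1), min(L - 1, k + 1)
        v = ca[k] - 0.5 * (ca[lo] + ca[hi])
        n = np.linalg.norm(v)
        if n < 1e-6:  # straight segment: pick any perpendicular
            axis = ca[hi] - ca[lo]
            v = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(v) < 1e-6:
                v = np.cross(axis, [0.0, 1.0, 0.0])
            n = np.linalg.norm(v)
        dirs[k] = v / n
    return dirs


def make_monomer(spec: SyntheticSpec) -> ChainRecord:
    """Deterministic toy monomer with Calpha, pseudo-Cbeta and side chain.

    Glycines carry only a Calpha, exercising the Calpha fallback of the
    intrachain contact definition.  The chain is centered at its Calpha
    centroid.
    """
    rng = _rng(1, spec.seed)
    seq = "".join(rng.choice(list(_AA20), size=spec.L))
    if spec.fold == "helix":
        ca = _helix_trace(spec.L)
    else:
        ca = _walk_trace(spec.L, rng)
    ca = ca - ca.mean(axis=0)
    dirs = _sidechain_directions(ca)
    n_side = rng.integers(1, 4, size=spec.L)  # 1..3 pseudo heavy atoms
    jitter = rng.normal(scale=0.25, size=(spec.L, 3, 3))
    residues: list[Residue] = []
    from .chains import ONE_TO_THREE
    for k in range(spec.L):
        name3 = ONE_TO_THREE[seq[k]]
        atoms = [Atom("CA", "C", tuple(ca[k]))]
        if seq[k] != "G":
            atoms.append(Atom("CB", "C", tuple(ca[k] + 1.5 * dirs[k])))
            for m in range(int(n_side[k])):
                pos = ca[k] + (2.7 + 1.2 * m) * dirs[k] + jitter[k, m]
                atoms.append(Atom(f"SC{m + 1}", "C", tuple(pos)))
        residues.append(Residue(k + 1, name3, atoms))
    return ChainRecord("A", residues)


def antiparallel_transform(monomer: ChainRecord, gap: float = 4.5,
                           axis_flip: np.ndarray | None = None
                           ) -> RigidTransform:
    """Flip the monomer end-over-end and slide it along +x until the closest
    heavy-atom approach first reaches ``gap`` Angstrom."""
    flip = Rotation.from_rotvec([np.pi, 0.0, 0.0]).as_matrix() \
        if axis_flip is None else axis_flip
    xyz, _ = monomer.heavy_atoms()
    flipped = xyz @ flip.T
    tree = cKDTree(xyz)
    span = xyz[:, 0].max() - flipped[:, 0].min()
    for t in np.arange(0.5, span + gap + 10.0, 0.25):
        d, _ = tree.query(flipped + [t, 0.0, 0.0], k=1)
        if d.min() >= gap:
            return RigidTransform(flip, np.array([t, 0.0, 0.0]))
    raise RuntimeError("could not find an interface placement")


def translation_transform(offset: np.ndarray) -> RigidTransform:
    return RigidTransform(np.eye(3), np.asarray(offset, dtype=float))


def make_complex(spec: SyntheticSpec
                 ) -> tuple[list[ChainRecord], ContactMap, ContactMap]:
    """Build the assembly and its truth maps.

    Copy k receives the k-th power of the interface transform; chain ids run
    A, B, C, ...  Returns (chains, intrachain map of chain A, interchain map
    of the max-contact pair).  Raises if copies collapse sterically or no
    interchain contact exists.
    """
    monomer = make_monomer(spec)
    base = spec.transform or antiparallel_transform(monomer,
                                                    spec.interface_gap)
    chains = [monomer]
    current = RigidTransform.identity()
    for k in range(1, spec.n_copies):
        current = base.compose(current)
        chains.append(monomer.transformed(current.rotation,
                                          current.translation,
                                          chain_id=string.ascii_uppercase[k]))
    # steric check across all copy pairs
    trees = [cKDTree(c.heavy_atoms()[0]) for c in chains]
    min_d = np.inf
    for a in range(len(chains)):
        for b in range(a + 1, len(chains)):
            d, _ = trees[a].query(chains[b].heavy_atoms()[0], k=1)
            min_d = min(min_d, float(d.min()))
    if min_d <= spec.min_clearance:
        raise RuntimeError(
            f"copies collapse sterically (closest approach {min_d:.2f} A)"
        )
    intra = intrachain_map(monomer, spec.thresholds)
    sel = select_max_pair(chains, spec.thresholds)
    partner = next(c for c in chains if c.chain_id == sel.partner_chain_id)
    inter = interchain_map(monomer, partner, spec.thresholds)
    if not inter.entries:
        raise RuntimeError(
            f"no interchain contact (closest approach {min_d:.2f} A)"
        )
    return chains, intra, inter


def fold_upper(entries: frozenset[tuple[int, int]]) -> set[tuple[int, int]]:
    """Fold an asymmetric map into the upper triangle, dropping the diagonal."""
    out = set()
    for i, j in entries:
        if i < j:
            out.add((i, j))
        elif j < i:
            out.add((j, i))
    return out


def fabricate_prediction(intra: ContactMap, inter: ContactMap,
                         spec: SyntheticSpec) -> PredictionSet:
    """Mix intrachain and interchain truth into one noisy upper-triangle map.

    Emulates a monomeric predictor whose MSA carries both signals: kept true
    entries get a high base score, injected false positives a low one, both
    perturbed by Gaussian noise and clipped to [0, 1].
    """
    if intra.L != inter.L:
        raise ValueError("maps must share the monomer index space")
    pm = spec.predictor
    rng = _rng(2, spec.seed)
    L = intra.L
    true_pairs: dict[tuple[int, int], bool] = {}
    for p in sorted(intra.entries):
        true_pairs[p] = rng.random() < pm.intra_keep
    for p in sorted(fold_upper(inter.entries)):
        if true_pairs.get(p):
            continue
        keep = rng.random() < pm.inter_keep
        true_pairs[p] = true_pairs.get(p, False) or keep
    kept = [p for p, k in true_pairs.items() if k]
    non_contacts = [
        (i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)
        if (i, j) not in true_pairs
    ]
    n_fp = int(round(pm.fp_rate * len(non_contacts)))
    fp_idx = rng.choice(len(non_contacts), size=n_fp, replace=False) \
        if n_fp else np.array([], dtype=int)
    items: list[tuple[int, int, float]] = []
    for p in kept:
        s = pm.true_base_score + rng.normal(scale=pm.score_noise_sd)
        items.append((p[0], p[1], float(np.clip(s, 0.0, 1.0))))
    for c in sorted(fp_idx):
        p = non_contacts[int(c)]
        s = pm.false_base_score + rng.normal(scale=pm.score_noise_sd)
        items.append((p[0], p[1], float(np.clip(s, 0.0, 1.0))))
    return PredictionSet(L, tuple(sorted(items)))
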