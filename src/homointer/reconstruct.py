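"""Homodimer reconstruction from predicted interchain contacts.

Given the monomer tertiary structure (treated as rigid) and a list of
predicted interchain residue pairs, the second copy is placed by a
six-degree-of-freedom search: Metropolis simulated annealing over rigid
rotations and translations with a geometric cooling schedule, followed by a
derivative-free polish of the best pose.  The energy is a flat-bottom
quadratic on each restraint — zero while the minimum heavy-atom distance of
the pair is within the contact cutoff, growing as (d - d_c)^2 beyond it —
plus a quadratic steric clash penalty below a hard-core distance.

A predicted pair (i, j) from an upper-triangle monomer map may mean residue
i of copy one touching residue j of copy two, or the reverse; each restraint
therefore scores as the lighter of the (i, j) and (j, i) penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .chains import ChainRecord
from .geometry import RigidTransform, kabsch


@dataclass(frozen=True)
class RestraintSet:
    """Interchain distance restraints: pair (i, j) is satisfied when the
    minimum heavy-atom distance across copies is <= contact_distance."""

    pairs: tuple[tuple[int, int], ...]
    contact_distance: float = 6.0

    @classmethod
    def from_predictions(cls, items, contact_distance: float = 6.0
                         ) -> "RestraintSet":
        pairs = tuple((int(i), int(j)) for i, j, *_ in items)
        return cls(pairs, contact_distance)

    def __post_init__(self) -> None:
        if self.contact_distance <= 0:
            raise ValueError("contact_distance must be positive")


@dataclass(frozen=True)
class AnnealConfig:
    initial_temperature: float = 60.0
    final_temperature: float = 0.05
    cooling: float = 0.82
    steps_per_temperature: int = 50
    rotation_step: float = 0.35  # rad, at the initial temperature
    translation_step: float = 2.5  # A, at the initial temperature
    clash_distance: float = 2.5
    clash_weight: float = 1.0
    restarts: int = 6
    polish_maxfev: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0 or self.final_temperature <= 0:
            raise ValueError("temperatures must be positive")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must lie in (0, 1)")


@dataclass
class RestartTrace:
    restart: int
    best_energy: float
    accepted_moves: int


@dataclass
class ReconstructionReport:
    best_energy: float
    satisfied_fraction: float
    rmsd_to_native: float | None
    traces: list[RestartTrace] = field(default_factory=list)


class _Workspace:
    """Precomputed index arrays so one energy evaluation is a few gathers."""

    def __init__(self, monomer: ChainRecord, restraints: RestraintSet,
                 cfg: AnnealConfig):
        if not restraints.pairs:
            raise ValueError("nothing to satisfy: zero restraints")
        self.cfg = cfg
        self.d_c = restraints.contact_distance
        self.atoms0, res_idx = monomer.heavy_atoms()
        self.centroid0 = self.atoms0.mean(axis=0)
        groups = {int(r): np.flatnonzero(res_idx == r)
                  for r in np.unique(res_idx)}
        self.n_pairs = len(restraints.pairs)
        fa, ma, pid = [], [], []
        for orient in (0, 1):  # forward (i fixed, j moved) and mirror
            for p, (i, j) in enumerate(restraints.pairs):
                gi, gj = (groups.get(i), groups.get(j)) if orient == 0 \
                    else (groups.get(j), groups.get(i))
                if gi is None or gj is None:
                    raise ValueError(f"restraint ({i},{j}) outside 1..L")
                for a in gi:
                    for b in gj:
                        fa.append(a)
                        ma.append(b)
                        pid.append(orient * self.n_pairs + p)
        self.fa = np.array(fa)
        self.ma = np.array(ma)
        self.pid = np.array(pid)

    def pair_min_distances(self, moved: np.ndarray) -> np.ndarray:
        """(2, n_pairs): forward and mirror minimum heavy-atom distances."""
        d = np.linalg.norm(self.atoms0[self.fa] - moved[self.ma], axis=1)
        mins = np.full(2 * self.n_pairs, np.inf)
        np.minimum.at(mins, self.pid, d)
        return mins.reshape(2, self.n_pairs)

    def energy(self, moved: np.ndarray) -> float:
        both = self.pair_min_distances(moved)
        pen = np.maximum(0.0, both - self.d_c) ** 2
        e = float(np.minimum(pen[0], pen[1]).sum())
        d = cdist(self.atoms0, moved)
        clash = np.maximum(0.0, self.cfg.clash_distance - d)
        e += self.cfg.clash_weight * float((clash ** 2).sum())
        return e

    def satisfied_fraction(self, moved: np.ndarray) -> float:
        both = self.pair_min_distances(moved)
        return float(np.mean(both.min(axis=0) <= self.d_c))

    def place(self, t: RigidTransform) -> np.ndarray:
        return t.apply(self.atoms0)


def restraint_energy(t: RigidTransform, monomer: ChainRecord,
                     restraints: RestraintSet,
                     cfg: AnnealConfig = AnnealConfig()) -> float:
    """Energy of placing the second copy at ``t``; zero iff every restraint
    is satisfied (in at least one orientation) and no atoms clash."""
    ws = _Workspace(monomer, restraints, cfg)
    return ws.energy(ws.place(t))


def _pivot_move(state: RigidTransform, pivot: np.ndarray,
                rotvec: np.ndarray, shift: np.ndarray) -> RigidTransform:
    """Rotate the moved copy about ``pivot`` then translate by ``shift``."""
    dR = Rotation.from_rotvec(rotvec).as_matrix()
    R = dR @ state.rotation
    t = dR @ (state.translation - pivot) + pivot + shift
    return RigidTransform(R, t)


def anneal(monomer: ChainRecord, restraints: RestraintSet,
           cfg: AnnealConfig = AnnealConfig()
           ) -> tuple[RigidTransform, ReconstructionReport]:
    """Search the 6-DOF placement of the second copy.

    Multiple randomized restarts of Metropolis annealing (move sizes shrink
    with temperature) are followed by a Powell polish of the overall best
    pose; deterministic under ``cfg.seed``.
    """
    ws = _Workspace(monomer, restraints, cfg)
    radius = float(np.linalg.norm(ws.atoms0 - ws.centroid0, axis=1).max())
    best_t: RigidTransform | None = None
    best_e = np.inf
    traces: list[RestartTrace] = []
    for r in range(cfg.restarts):
        rng = np.random.default_rng([cfg.seed, r])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start_t = RigidTransform(
            Rotation.random(rng=rng).as_matrix(),
            direction * radius * rng.uniform(1.2, 2.2),
        )
        # express translation so that rotation acts about the monomer frame
        state = RigidTransform(start_t.rotation,
                               start_t.translation
                               + ws.centroid0 - start_t.rotation @ ws.centroid0)
        e = ws.energy(ws.place(state))
        r_best_t, r_best_e = state, e
        accepted = 0
        temp = cfg.initial_temperature
        while temp > cfg.final_temperature:
            frac = temp / cfg.initial_temperature
            scale_rot = cfg.rotation_step * max(frac, 0.05)
            scale_tr = cfg.translation_step * max(frac, 0.05)
            for _ in range(cfg.steps_per_temperature):
                pivot = state.apply(ws.centroid0)
                cand = _pivot_move(
                    state, pivot,
                    rng.normal(scale=scale_rot, size=3),
                    rng.normal(scale=scale_tr, size=3),
                )
                e_new = ws.energy(ws.place(cand))
                if e_new <= e or rng.random() < np.exp((e - e_new) / temp):
                    state, e = cand, e_new
                    accepted += 1
                    if e < r_best_e:
                        r_best_t, r_best_e = state, e
            temp *= cfg.cooling
        traces.append(RestartTrace(r, r_best_e, accepted))
        if r_best_e < best_e:
            best_t, best_e = r_best_t, r_best_e
    assert best_t is not None
    best_t, best_e = _polish(ws, best_t, cfg)
    moved = ws.place(best_t)
    report = ReconstructionReport(
        best_energy=best_e,
        satisfied_fraction=ws.satisfied_fraction(moved),
        rmsd_to_native=None,
        traces=traces,
    )
    return best_t, report


def _polish(ws: _Workspace, t0: RigidTransform,
            cfg: AnnealConfig) -> tuple[RigidTransform, float]:
    pivot = t0.apply(ws.centroid0)

    def from_x(x: np.ndarray) -> RigidTransform:
        return _pivot_move(t0, pivot, x[:3], x[3:])

    def f(x: np.ndarray) -> float:
        return ws.energy(ws.place(from_x(x)))

    res = minimize(f, np.zeros(6), method="Powell",
                   options={"maxfev": cfg.polish_maxfev, "xtol": 1e-4,
                            "ftol": 1e-8})
    if res.fun <= ws.energy(ws.place(t0)):
        return from_x(res.x), float(res.fun)
    return t0, float(ws.energy(ws.place(t0)))


def superpose_rmsd(model: list[ChainRecord],
                   native: list[ChainRecord]) -> float:
    """Full-complex Calpha RMSD after optimal superposition.

    Both chain pairings of the model onto the native are tried (copies of a
    homomultimer are interchangeable) and the minimum is returned.
    """
    if len(model) != len(native):
        raise ValueError("chain count mismatch")
    for m, n in zip(model, native):
        if m.L != n.L:
            raise ValueError("chain length mismatch")
    native_ca = np.vstack([c.ca_coords() for c in native])
    orders = [model, list(reversed(model))] if len(model) == 2 else [model]
    best = np.inf
    for order in orders:
        if any(m.L != n.L for m, n in zip(order, native)):
            continue
        model_ca = np.vstack([c.ca_coords() for c in order])
        _, rmsd = kabsch(model_ca, native_ca)
        best = min(best, rmsd)
    return float(best)


def reconstruct_dimer(monomer: ChainRecord, restraints: RestraintSet,
                      cfg: AnnealConfig = AnnealConfig(),
                      native: list[ChainRecord] | None = None
                      ) -> tuple[list[ChainRecord], ReconstructionReport]:
    """Convenience wrapper: anneal, build the two-chain model, and score it
    against a native complex when one is supplied."""
    t, report = anneal(monomer, restraints, cfg)
    model = [monomer,
             monomer.transformed(t.rotation, t.translation, chain_id="B")]
    if native is not None:
        report.rmsd_to_native = superpose_rmsd(model, native)
    return model, report
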