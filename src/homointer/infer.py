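"""From a monomeric contact prediction to ranked interchain candidates.

The key idea: a contact predictor run on a monomer that forms a homomultimer
sees both intrachain and interchain co-evolutionary signal superimposed in
one upper-triangle map.  Knowing the monomer's tertiary structure, the true
intrachain contacts can be subtracted out ("relax removal"), and whatever
survives is interpreted as interchain signal.

Relax removal with parameter n deletes, for every true intrachain contact
(i, j), all predicted pairs inside the (2n+1) x (2n+1) index window
[i-n, i+n] x [j-n, j+n] (and the mirror window around (j, i)); n = 0 deletes
exact matches only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .contacts import ContactMap, ContactThresholds

TOPK_LABELS = ("Top-5", "Top-10", "Top-L/10", "Top-L/5", "Top-L/2",
               "Top-L", "Top-2L")


@dataclass(frozen=True)
class PredictionSet:
    """Scored upper-triangle residue-pair predictions over 1..L."""

    L: int
    items: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, s in self.items:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"pair ({i},{j}) not in upper triangle 1..{self.L}")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} outside [0,1] for pair ({i},{j})")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i},{j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.items)

    def pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.items}


@dataclass(frozen=True)
class RelaxParams:
    """Window half-widths: n_removal for subtraction, n_eval for matching."""

    n_removal: int = 0
    n_eval: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_removal <= 2 and 0 <= self.n_eval <= 2):
            raise ValueError("relax parameters must lie in {0, 1, 2}")


@dataclass(frozen=True)
class TopKSpec:
    """A Top-k cutoff: a constant (5, 10) or a fraction of monomer length L."""

    label: str
    k: int

    @classmethod
    def resolve(cls, label: str, L: int) -> "TopKSpec":
        if label not in TOPK_LABELS:
            raise ValueError(f"unknown Top-k label {label!r}; "
                             f"expected one of {TOPK_LABELS}")
        raw = {
            "Top-5": 5.0,
            "Top-10": 10.0,
            "Top-L/10": L / 10,
            "Top-L/5": L / 5,
            "Top-L/2": L / 2,
            "Top-L": float(L),
            "Top-2L": 2.0 * L,
        }[label]
        k = math.floor(raw)
        if k < 1:
            warnings.warn(f"{label} resolves to k={k} at L={L}; clamping to 1")
            k = 1
        return cls(label, k)


def filter_short_range(pred: PredictionSet,
                       th: ContactThresholds = ContactThresholds()
                       ) -> PredictionSet:
    """Drop short-range pairs: keep (i, j) with j - i >= the separation cutoff."""
    kept = tuple(
        (i, j, s) for i, j, s in pred.items
        if j - i >= th.min_sequence_separation
    )
    return PredictionSet(pred.L, kept)


def _removal_mask(true_intra: ContactMap, n: int) -> np.ndarray:
    """(L+1, L+1) boolean mask of deleted cells, 1-based indexing."""
    L = true_intra.L
    mask = np.zeros((L + 1, L + 1), dtype=bool)
    for i, j in true_intra.entries:
        for ci, cj in ((i, j), (j, i)):  # mirror too: orientation-proof
            lo_i, hi_i = max(1, ci - n), min(L, ci + n)
            lo_j, hi_j = max(1, cj - n), min(L, cj + n)
            mask[lo_i:hi_i + 1, lo_j:hi_j + 1] = True
    return mask


def relax_remove(pred: PredictionSet, true_intra: ContactMap,
                 rp: RelaxParams) -> PredictionSet:
    """Subtract true intrachain contacts from the prediction with tolerance.

    Every predicted pair falling inside the (2n+1) x (2n+1) window around a
    true intrachain contact (or its mirror) is deleted; window indices
    outside 1..L are clipped.
    """
    if true_intra.kind != "intra":
        raise ValueError("relax_remove expects an intrachain truth map")
    if pred.L != true_intra.L:
        raise ValueError(f"length mismatch: pred L={pred.L}, "
                         f"truth L={true_intra.L}")
    mask = _removal_mask(true_intra, rp.n_removal)
    kept = tuple((i, j, s) for i, j, s in pred.items if not mask[i, j])
    return PredictionSet(pred.L, kept)


def rank_topk(pred: PredictionSet,
              spec: TopKSpec) -> list[tuple[int, int, float]]:
    """Top-k items by descending score; ties broken by (i, j) ascending.

    If fewer than k predictions remain, all are returned (the shortfall is
    reported via a warning; evaluation still divides by the resolved k).
    """
    ranked = sorted(pred.items, key=lambda t: (-t[2], t[0], t[1]))
    if len(ranked) < spec.k:
        warnings.warn(
            f"{spec.label}: only {len(ranked)} predictions available "
            f"for k={spec.k}"
        )
    return ranked[:spec.k]
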