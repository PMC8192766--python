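"""Random-prediction baseline.

Random predictions are drawn on the same support a monomeric predictor
emits — the upper triangle at sequence separation >= 6 — so that method and
baseline are compared on identical footing.  Scores are uniform, inducing a
random ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactMap
from .evaluate import relaxed_match
from .infer import PredictionSet


@dataclass(frozen=True)
class BaselineConfig:
    L: int
    n_pairs: int
    seed: int = 0
    respect_short_range_filter: bool = True
    min_sequence_separation: int = 6


def eligible_pairs(L: int, min_separation: int = 6,
                   respect_filter: bool = True) -> list[tuple[int, int]]:
    """Upper-triangle pairs surviving the short-range filter, in (i, j) order."""
    sep = min_separation if respect_filter else 1
    return [(i, j) for i in range(1, L + 1) for j in range(i + sep, L + 1)]


def random_prediction(cfg: BaselineConfig) -> PredictionSet:
    """Uniform sample of n_pairs eligible pairs with uniform(0,1) scores."""
    pool = eligible_pairs(cfg.L, cfg.min_sequence_separation,
                          cfg.respect_short_range_filter)
    if cfg.n_pairs > len(pool):
        raise ValueError(
            f"n_pairs={cfg.n_pairs} exceeds the {len(pool)} eligible pairs "
            f"at L={cfg.L}"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(len(pool), size=cfg.n_pairs, replace=False)
    scores = rng.uniform(0.0, 1.0, size=cfg.n_pairs)
    items = tuple(
        (pool[c][0], pool[c][1], float(s)) for c, s in zip(chosen, scores)
    )
    return PredictionSet(cfg.L, items)


def expected_random_precision(truth: ContactMap, n_eval: int,
                              eligible: list[tuple[int, int]]) -> float:
    """Expected single-draw precision: the fraction of eligible pairs that
    relax-match the truth at the given n_eval."""
    if not eligible:
        raise ValueError("eligible pair list is empty")
    hits = sum(1 for p in eligible if relaxed_match(p, truth, n_eval))
    return hits / len(eligible)
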