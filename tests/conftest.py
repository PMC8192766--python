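import numpy as np
import pytest

from homointer import (PredictorModel, SyntheticSpec, fabricate_prediction,
                       make_complex, make_monomer)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def dimer(default_spec):
    """Default synthetic homodimer: (chains, intra truth, inter truth)."""
    return make_complex(default_spec)


@pytest.fixture(scope="session")
def monomer(default_spec):
    return make_monomer(default_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return SyntheticSpec(
        seed=1,
        predictor=PredictorModel(intra_keep=1.0, inter_keep=1.0,
                                 fp_rate=0.0, score_noise_sd=0.0),
    )


@pytest.fixture(scope="session")
def noiseless_prediction(noiseless_spec):
    chains, intra, inter = make_complex(noiseless_spec)
    return fabricate_prediction(intra, inter, noiseless_spec), intra, inter


def random_instance(rng: np.random.Generator, L: int,
                    n_pred: int, n_truth: int, kind: str = "inter"):
    """A random scored prediction list and a random truth map for oracles."""
    from homointer import ContactMap, PredictionSet
    upper = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]
    pred_idx = rng.choice(len(upper), size=min(n_pred, len(upper)),
                          replace=False)
    items = tuple(
        (upper[c][0], upper[c][1], float(s))
        for c, s in zip(pred_idx, rng.uniform(size=len(pred_idx)))
    )
    if kind == "intra":
        truth_idx = rng.choice(len(upper), size=min(n_truth, len(upper)),
                               replace=False)
        entries = frozenset(upper[c] for c in truth_idx)
    else:
        full = [(i, j) for i in range(1, L + 1) for j in range(1, L + 1)
                if i != j]
        truth_idx = rng.choice(len(full), size=min(n_truth, len(full)),
                               replace=False)
        entries = frozenset(full[c] for c in truth_idx)
    return PredictionSet(L, items), ContactMap(kind, L, entries)
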