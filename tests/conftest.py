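import numpy as np
import pytest

import ncpmda
from ncpmda import AssociationNetwork


@pytest.fixture
def identity_net() -> AssociationNetwork:
    """Two diseases, two microbes, one association each (2x2 identity)."""
    return AssociationNetwork(("d1", "d2"), ("m1", "m2"), np.eye(2, dtype=int))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_network(A: np.ndarray) -> AssociationNetwork:
    nd, nm = np.asarray(A).shape
    return AssociationNetwork(
        tuple(f"d{i}" for i in range(nd)),
        tuple(f"m{j}" for j in range(nm)),
        A,
    )


@pytest.fixture(scope="session")
def planted_battery() -> dict:
    """Cross-validation battery over ten seeds of the default planted-block
    fixture, its density-matched Erdos-Renyi control, and a weak-separation
    variant. Session-scoped because it is by far the most expensive
    computation in the suite; several regression tests read from it.
    """
    seeds = list(range(1, 11))
    out = {
        "seeds": seeds, "global": [], "local": [], "kfold_mean": [],
        "er": [], "ratio2": [], "holdout_frac": [],
    }
    for seed in seeds:
        truth = ncpmda.generate_block_network(seed=seed)
        out["global"].append(ncpmda.global_loocv(truth.net).auc)
        out["local"].append(ncpmda.local_loocv(truth.net).auc)
        out["kfold_mean"].append(
            ncpmda.kfold_cv(truth.net, k=5, repeats=20, seed=7).auc_mean
        )
        er = ncpmda.erdos_renyi_network(seed=seed)
        out["er"].append(ncpmda.global_loocv(er.net).auc)
        # weak separation: p_in/p_out = 2 at the same expected density
        weak = ncpmda.generate_block_network(
            p_in=0.0822, p_out=0.0411, seed=seed
        )
        out["ratio2"].append(ncpmda.global_loocv(weak.net).auc)
        # 10% hold-out recovery: held-out true pairs vs the median unknown
        reduced = ncpmda.hold_out_positives(truth, 0.10, seed=seed + 1000)
        S = ncpmda.predict(reduced.net).S
        didx, midx = truth.net.disease_index, truth.net.microbe_index
        unknown_median = np.median(S[np.asarray(truth.net.A) == 0])
        above = [
            S[didx[d], midx[m]] > unknown_median for d, m in reduced.held_out
        ]
        out["holdout_frac"].append(float(np.mean(above)))
    return out
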