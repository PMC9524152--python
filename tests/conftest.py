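import numpy as np
import pytest

import ecprograms as ep


@pytest.fixture(scope="session")
def small_sim():
    """Small planted single-nucleus dataset shared across unit tests."""
    cfg = ep.SimulationConfig(
        arm_sizes={"untreated": 5, "CRT": 4, "CRTL": 2},
        nuclei_per_patient=(40, 60),
        n_genes=400,
        seed=123,
    )
    X, meta, truth = ep.simulate_snrnaseq(cfg)
    return cfg, X, meta, truth


@pytest.fixture(scope="session")
def small_prepared(small_sim):
    _, X, _, _ = small_sim
    return ep.prepare_matrix(X, n_hvg=300)


@pytest.fixture(scope="session")
def small_consensus(small_sim, small_prepared):
    """Consensus factorization of the small planted dataset at k_true."""
    cfg, _, _, _ = small_sim
    model = ep.ConsensusNMF(k=cfg.k_true, n_replicates=8, random_state=0)
    model.fit(small_prepared.matrix)
    return model


def hungarian_cosine(A, B):
    """Mean cosine similarity under the optimal row matching."""
    from scipy.optimize import linear_sum_assignment

    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    S = A @ B.T
    r, c = linear_sum_assignment(-S)
    return float(S[r, c].mean()), (r, c)
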