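import numpy as np
import pytest

from tmfuf import (
    DrugSet,
    FeatureMatrix,
    InteractionMatrix,
    SynthConfig,
    fit_tmfuf,
    generate,
)


@pytest.fixture
def drugs3():
    return DrugSet(("d1", "d2", "d3"))


@pytest.fixture
def tiny_interactions(drugs3):
    """d1-d2 enhancive, d2-d3 degressive."""
    return InteractionMatrix(
        np.array([[0, 1, 0], [1, 0, -1], [0, -1, 0]]), drugs3
    )


@pytest.fixture(scope="session")
def planted():
    """The default planted universe: m=60, p=80, r_true=3, no label noise."""
    return generate(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def planted_model(planted):
    """Model fitted on the full planted universe with the x1000 scaling."""
    return fit_tmfuf(planted.A, planted.F, r="auto", L=10, scale_factor=1000.0)


def make_feature_matrix(values, prefix="se"):
    values = np.asarray(values)
    drugs = DrugSet(tuple(f"d{i}" for i in range(values.shape[0])))
    names = tuple(f"{prefix}{j}" for j in range(values.shape[1]))
    return FeatureMatrix(values, drugs, names)


# ---------------------------------------------------------------- oracles


def auc_pairwise_oracle(labels, scores):
    """O(n^2) Wilcoxon probability that a positive outscores a negative;
    ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_threshold_oracle(labels, scores):
    """Exhaustive-threshold step-curve AUPR: sum of precision times recall
    increment at every distinct score value, descending, no interpolation."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        tp = int((labels[sel] == 1).sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def best_psd_rank_r_error(M, r):
    """Brute-force minimal ||M - G||_F over PSD Gram matrices built from any
    subset (size <= r) of M's positive eigenpairs, via an independent
    eigendecomposition route."""
    import itertools

    lam, U = np.linalg.eig(M)  # independent of eigh used by the package
    lam, U = np.real(lam), np.real(U)
    pos = [i for i in range(len(lam)) if lam[i] > 1e-12]
    best = np.linalg.norm(M)  # empty subset -> G = 0
    for k in range(1, min(r, len(pos)) + 1):
        for subset in itertools.combinations(pos, k):
            idx = list(subset)
            G = (U[:, idx] * lam[idx]) @ U[:, idx].T
            best = min(best, np.linalg.norm(M - G))
    return best
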