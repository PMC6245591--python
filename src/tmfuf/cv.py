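"""Cold-start cross-validation and evaluation for signed DDI prediction.

Predicting interactions for *new* drugs (nodes with no known edges) needs
stricter cross-validation than pair-level hold-out: whole drugs must be held
out, and every pair touching a held-out drug must be invisible to training.
Two schemes cover the two screening tasks:

* **CV1** (task T1, new vs known): drugs are partitioned into K folds; each
  round holds out one fold, trains on the pairs among the remaining drugs and
  tests on the pairs between held-out and training drugs.  K rounds.
* **CV2** (task T2, new vs new): the same partition, but test pairs lie
  entirely among held-out drugs.  K *within-group* rounds (pairs inside one
  fold; train on the other K-1 folds) plus K(K-1)/2 *between-group* rounds
  (pairs linking two held-out folds; train on the remaining K-2 folds) —
  K(K+1)/2 rounds in all.  Pairs linking test drugs to training drugs are
  blind: dropped from both training and testing.

Performance is measured by ROC AUC and the area under the precision-recall
curve (AUPR), which stays informative under the heavy class imbalance of
sparse networks.  The *conventional* protocol scores the binary network
(every interaction positive); the *comprehensive* protocol scores the signed
one: degressive pairs are relabeled positive with their score negated, so a
confidently negative score for a degressive pair counts as a correct,
confident prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .data_io import DrugSet, FeatureMatrix, InteractionMatrix
from .tmf import TmfModel, fit_tmfuf, predict_new_vs_known, predict_new_vs_new

__all__ = [
    "CvRound",
    "CvPlan",
    "EvalResult",
    "make_cv1_plan",
    "make_cv2_plan",
    "run_cv",
    "repeat_cv",
    "score_binary",
    "score_comprehensive",
    "tune_latent_factors",
    "DEFAULT_L_GRID",
]

#: the fixed grid used to tune the number of PLS latent factors
DEFAULT_L_GRID = (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150)

Pair = tuple[int, int]


def _pairs_within(idx: np.ndarray) -> set[Pair]:
    idx = np.sort(idx)
    return {(int(idx[i]), int(idx[j])) for i in range(len(idx)) for j in range(i + 1, len(idx))}


def _pairs_between(a: np.ndarray, b: np.ndarray) -> set[Pair]:
    return {(min(int(i), int(j)), max(int(i), int(j))) for i in a for j in b}


@dataclass(frozen=True)
class CvRound:
    """One train/test split of drug pairs.

    ``kind`` decides where the test pairs live: ``"cv1"`` between the test
    group and the training drugs, ``"cv2_within"`` inside the test group,
    ``"cv2_between"`` between the two test groups.  Every pair that is
    neither trained on nor tested is *blind*.
    """

    kind: Literal["cv1", "cv2_within", "cv2_between"]
    train_drugs: np.ndarray
    test_group_a: np.ndarray
    test_group_b: np.ndarray

    def train_pairs(self) -> set[Pair]:
        return _pairs_within(self.train_drugs)

    def test_pairs(self) -> set[Pair]:
        if self.kind == "cv1":
            return _pairs_between(self.test_group_a, self.train_drugs)
        if self.kind == "cv2_within":
            return _pairs_within(self.test_group_a)
        return _pairs_between(self.test_group_a, self.test_group_b)

    def blind_pairs(self, m: int) -> set[Pair]:
        universe = _pairs_within(np.arange(m))
        return universe - self.train_pairs() - self.test_pairs()


@dataclass(frozen=True)
class CvPlan:
    """A full enumeration of cross-validation rounds over one fold partition."""

    scheme: Literal["cv1", "cv2"]
    K: int
    m: int
    folds: tuple[np.ndarray, ...]
    rounds: tuple[CvRound, ...]
    seed: int


def _make_folds(m: int, K: int, seed: int) -> tuple[np.ndarray, ...]:
    """Shuffle drug indices and deal them round-robin into K near-equal folds."""
    if K < 2:
        raise ValueError(f"need K >= 2 folds, got {K}")
    if m < K:
        raise ValueError(f"cannot split {m} drugs into {K} folds")
    perm = np.random.default_rng(seed).permutation(m)
    return tuple(np.sort(perm[k::K]) for k in range(K))


def make_cv1_plan(m: int, K: int, seed: int) -> CvPlan:
    """CV1: K rounds; round k tests fold k against the other K-1 folds."""
    folds = _make_folds(m, K, seed)
    rounds = []
    for k in range(K):
        train = np.sort(np.concatenate([folds[j] for j in range(K) if j != k]))
        rounds.append(CvRound("cv1", train, folds[k], folds[k]))
    return CvPlan("cv1", K, m, folds, tuple(rounds), seed)


def make_cv2_plan(m: int, K: int, seed: int) -> CvPlan:
    """CV2: K within-group rounds plus K(K-1)/2 between-group rounds."""
    folds = _make_folds(m, K, seed)
    rounds = []
    for k in range(K):
        train = np.sort(np.concatenate([folds[j] for j in range(K) if j != k]))
        rounds.append(CvRound("cv2_within", train, folds[k], folds[k]))
    for a in range(K):
        for b in range(a + 1, K):
            rest = [folds[j] for j in range(K) if j not in (a, b)]
            train = np.sort(np.concatenate(rest)) if rest else np.array([], dtype=int)
            rounds.append(CvRound("cv2_between", train, folds[a], folds[b]))
    return CvPlan("cv2", K, m, folds, tuple(rounds), seed)


@dataclass(frozen=True)
class EvalResult:
    """ROC/PR evaluation of one scoring experiment."""

    auc: float
    aupr: float
    protocol: Literal["conventional", "comprehensive"]
    n_pos: int
    n_neg: int
    roc_points: tuple | None = None
    pr_points: tuple | None = None


def score_binary(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    protocol: str = "conventional",
) -> EvalResult:
    """AUC/AUPR of real-valued scores against binary labels.

    AUC equals the Wilcoxon rank-sum probability that a random positive
    outscores a random negative, with ties counting one half.  AUPR is the
    step-curve sum of precision times recall increments over every distinct
    score threshold, with no interpolation.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("binary labels must be in {0, 1}")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undefined metric: need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return EvalResult(
        auc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
        protocol=protocol,  # type: ignore[arg-type]
        n_pos=n_pos,
        n_neg=n_neg,
        roc_points=(fpr, tpr),
        pr_points=(prec, rec),
    )


def score_comprehensive(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
) -> EvalResult:
    """AUC/AUPR for signed {-1, 0, +1} labels via the sign-flip transform.

    Degressive pairs become positives with their score negated (a strongly
    negative score is a confident, correct degressive call); enhancive pairs
    stay positive with their original score; non-interacting pairs are the
    negatives.  The transformed problem is then scored as binary.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isin(y, (-1, 0, 1)).all():
        raise ValueError("comprehensive labels must be in {-1, 0, +1}")
    s_flipped = np.where(y == -1, -s, s)
    res = score_binary((y != 0).astype(int), s_flipped, protocol="comprehensive")
    return res


def _round_scores(
    model: TmfModel,
    F: FeatureMatrix,
    A: InteractionMatrix,
    rnd: CvRound,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed labels and raw confidence scores for one round's test pairs."""

    def _sub_features(idx: np.ndarray) -> FeatureMatrix:
        sub_drugs = DrugSet(tuple(F.drugs.ids[i] for i in idx))
        return FeatureMatrix(F.values[idx], sub_drugs, F.feature_names)

    ga, gb = rnd.test_group_a, rnd.test_group_b
    if rnd.kind == "cv1":
        conf = predict_new_vs_known(model, _sub_features(ga)).values
        labels = A.values[np.ix_(ga, rnd.train_drugs)].ravel()
        scores = conf.ravel()
    elif rnd.kind == "cv2_within":
        conf = predict_new_vs_new(model, _sub_features(ga), _sub_features(ga)).values
        iu = np.triu_indices(len(ga), k=1)
        labels = A.values[np.ix_(ga, ga)][iu]
        scores = conf[iu]
    else:
        conf = predict_new_vs_new(model, _sub_features(ga), _sub_features(gb)).values
        labels = A.values[np.ix_(ga, gb)].ravel()
        scores = conf.ravel()
    return labels, scores


def run_cv(
    A: InteractionMatrix,
    F: FeatureMatrix,
    plan: CvPlan,
    hyperparams: dict | None = None,
    protocol: Literal["conventional", "comprehensive"] = "comprehensive",
) -> dict:
    """Run every round of a CV plan and average AUC/AUPR.

    Each round refits the model from scratch on the training-pair submatrix
    only (conventional protocol: on its binarized form) and scores the test
    pairs from the held-out drugs' feature vectors.  Rounds whose test block
    contains no positive (or no negative) are skipped with a warning and
    excluded from the average, as the metrics are undefined there.

    Returns a dict with ``auc``/``aupr`` means, per-round results and
    bookkeeping.
    """
    if len(A.drugs) != plan.m:
        raise ValueError("plan was built for a different number of drugs")
    hp = {"r": "auto", "L": 10, "scale_factor": 1.0}
    hp.update(hyperparams or {})
    per_round: list[EvalResult | None] = []
    for rnd in plan.rounds:
        tr = rnd.train_drugs
        sub_drugs = DrugSet(tuple(A.drugs.ids[i] for i in tr))
        A_tr = InteractionMatrix(A.values[np.ix_(tr, tr)], sub_drugs)
        F_tr = FeatureMatrix(F.values[tr], sub_drugs, F.feature_names)
        try:
            model = fit_tmfuf(
                A_tr,
                F_tr,
                r=hp["r"],
                L=hp["L"],
                scale_factor=hp["scale_factor"],
                binary_mode=(protocol == "conventional"),
            )
        except ValueError as exc:
            warnings.warn(f"round skipped (fit failed: {exc})", stacklevel=2)
            per_round.append(None)
            continue
        labels, scores = _round_scores(model, F, A, rnd)
        try:
            if protocol == "conventional":
                res = score_binary(np.abs(labels), scores)
            else:
                res = score_comprehensive(labels, scores)
        except ValueError as exc:
            warnings.warn(f"round skipped ({exc})", stacklevel=2)
            per_round.append(None)
            continue
        per_round.append(res)
    valid = [r for r in per_round if r is not None]
    if not valid:
        raise ValueError("no round produced a defined metric")
    return {
        "scheme": plan.scheme,
        "protocol": protocol,
        "K": plan.K,
        "seed": plan.seed,
        "n_rounds": len(plan.rounds),
        "n_scored_rounds": len(valid),
        "auc": float(np.mean([r.auc for r in valid])),
        "aupr": float(np.mean([r.aupr for r in valid])),
        "per_round": per_round,
    }


def repeat_cv(
    A: InteractionMatrix,
    F: FeatureMatrix,
    scheme: Literal["cv1", "cv2"],
    K: int,
    n_repeats: int,
    seed: int,
    hyperparams: dict | None = None,
    protocol: Literal["conventional", "comprehensive"] = "comprehensive",
) -> dict:
    """Repeat a CV scheme under distinct fold seeds; report mean, SD and SEM.

    The drug partition is redrawn for every repetition (seed, seed+1, ...),
    mirroring repeated evaluation under independent random splits.
    """
    maker = make_cv1_plan if scheme == "cv1" else make_cv2_plan
    aucs, auprs = [], []
    for rep in range(n_repeats):
        plan = maker(len(A.drugs), K, seed + rep)
        res = run_cv(A, F, plan, hyperparams, protocol)
        aucs.append(res["auc"])
        auprs.append(res["aupr"])
    aucs_, auprs_ = np.array(aucs), np.array(auprs)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return {
        "scheme": scheme,
        "protocol": protocol,
        "K": K,
        "n_repeats": n_repeats,
        "base_seed": seed,
        "auc_mean": float(aucs_.mean()),
        "auc_sd": sd(aucs_),
        "auc_sem": sd(aucs_) / np.sqrt(len(aucs_)),
        "aupr_mean": float(auprs_.mean()),
        "aupr_sd": sd(auprs_),
        "aupr_sem": sd(auprs_) / np.sqrt(len(auprs_)),
        "auc_per_repeat": aucs,
        "aupr_per_repeat": auprs,
    }


def tune_latent_factors(
    A: InteractionMatrix,
    F: FeatureMatrix,
    grid: Sequence[int] = DEFAULT_L_GRID,
    K: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    full_output: bool = False,
):
    """Select the number of PLS latent factors L by binary-protocol CV1.

    Runs a conventional (binary) CV1 for every L in the grid over one shared
    fold partition and returns the L with the highest mean AUC (smallest L on
    ties).  With ``full_output=True`` also returns the tuning table
    ``[(L, mean_auc), ...]``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("tuning grid must be non-empty")
    plan = make_cv1_plan(len(A.drugs), K, seed)
    table = []
    for L in grid:
        hp = dict(hyperparams or {})
        hp["L"] = L
        res = run_cv(A, F, plan, hp, protocol="conventional")
        table.append((L, res["auc"]))
    best_L = max(sorted(table), key=lambda t: t[1])[0]
    return (best_L, table) if full_output else best_L
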