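"""Synthetic drug universes with planted bilinear structure.

Every stage of the pipeline is testable offline against data whose ground
truth is known: binary feature profiles F, a sparse signed coefficient
matrix B_true, the planted projection Theta_true = B_true B_true', and a
signed interaction network obtained by double-quantile thresholding of the
raw bilinear scores S = F Theta_true F'.  Thresholds are chosen from the
empirical distribution of the off-diagonal scores so the requested
interaction density and enhancive fraction are met regardless of the feature
density.  Optional label noise resamples each pair's label uniformly from
{-1, 0, +1}.

Defaults emulate the statistical shape of a curated comprehensive DDI
network: sparse (about one pair in eight interacting), with an enhancive
majority of roughly 78% of interactions, and a near-zero-dominated Theta
whose few large entries the significance scan should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import DrugSet, FeatureMatrix, InteractionMatrix
from .tmf import TmfModel, predict_new_vs_known
from .cv import score_comprehensive

__all__ = ["SynthConfig", "SynthDataset", "generate", "recovery_report"]

#: enhancive share observed in a real comprehensive DDI network (18710/24114)
DEFAULT_ENHANCIVE_FRACTION = 18710 / 24114


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; all probabilities in [0, 1].

    m, p, r_true : problem dimensions (drugs, features, planted latent rank).
    feature_density : expected fraction of 1s in the feature matrix.
    interaction_density : expected fraction of nonzero off-diagonal pairs.
    enhancive_fraction : expected share of interactions labeled +1.
    label_noise : per-pair probability of resampling the label uniformly
        from {-1, 0, +1}.
    b_density, b_magnitude : sparsity and magnitude range of B_true entries
        (signs are +/-1 with equal probability).
    """

    m: int = 60
    p: int = 80
    r_true: int = 3
    feature_density: float = 0.2
    interaction_density: float = 0.12
    enhancive_fraction: float = DEFAULT_ENHANCIVE_FRACTION
    label_noise: float = 0.0
    seed: int = 0
    b_density: float = 0.1
    b_magnitude: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError("need at least 4 drugs")
        if not 1 <= self.r_true < min(self.m, self.p):
            raise ValueError(f"r_true must be in [1, min(m, p)), got {self.r_true}")
        for name in ("feature_density", "interaction_density", "enhancive_fraction",
                     "label_noise", "b_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SynthDataset:
    """A generated universe together with its planted ground truth."""

    A: InteractionMatrix
    F: FeatureMatrix
    B_true: np.ndarray
    theta_true: np.ndarray
    config: SynthConfig
    thresholds: tuple[float, float] = (0.0, 0.0)  # (lower, upper) on raw scores


def generate(config: SynthConfig) -> SynthDataset:
    """Draw a synthetic dataset; bitwise reproducible from ``config.seed``.

    Raises on degenerate configurations that cannot yield any interaction
    (zero density with zero noise, or an all-zero thresholded network).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    drugs = DrugSet(tuple(f"drug{i:04d}" for i in range(cfg.m)))
    feature_names = tuple(f"se{j:04d}" for j in range(cfg.p))
    # sub-draws consume the single stream in a fixed documented order:
    # F, B_true mask, B_true signs, B_true magnitudes, noise mask, noise labels
    F_vals = (rng.random((cfg.m, cfg.p)) < cfg.feature_density).astype(np.int8)
    mask = rng.random((cfg.p, cfg.r_true)) < cfg.b_density
    signs = rng.choice((-1.0, 1.0), size=(cfg.p, cfg.r_true))
    mags = rng.uniform(*cfg.b_magnitude, size=(cfg.p, cfg.r_true))
    B_true = mask * signs * mags
    theta_true = B_true @ B_true.T

    G = F_vals @ B_true
    S = G @ G.T
    iu = np.triu_indices(cfg.m, k=1)
    s_off = S[iu]

    d, e = cfg.interaction_density, cfg.enhancive_fraction
    if d == 0.0 and cfg.label_noise == 0.0:
        raise ValueError("degenerate config: zero interaction density and zero noise")
    # quantile thresholds: top d*e of raw scores -> +1, bottom d*(1-e) -> -1
    hi = np.quantile(s_off, 1.0 - d * e) if d * e > 0 else np.inf
    lo = np.quantile(s_off, d * (1.0 - e)) if d * (1.0 - e) > 0 else -np.inf
    labels = np.zeros_like(s_off, dtype=np.int8)
    labels[s_off > hi] = 1
    labels[s_off < lo] = -1

    if cfg.label_noise > 0:
        flip = rng.random(labels.shape) < cfg.label_noise
        labels = np.where(
            flip, rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=labels.shape), labels
        ).astype(np.int8)

    if not np.any(labels):
        raise ValueError(
            "degenerate config: thresholding produced an empty interaction network"
        )

    A_vals = np.zeros((cfg.m, cfg.m), dtype=np.int8)
    A_vals[iu] = labels
    A_vals += A_vals.T
    return SynthDataset(
        A=InteractionMatrix(A_vals, drugs),
        F=FeatureMatrix(F_vals, drugs, feature_names),
        B_true=B_true,
        theta_true=theta_true,
        config=cfg,
        thresholds=(float(lo), float(hi)),
    )


def recovery_report(
    dataset: SynthDataset,
    model: TmfModel,
    heldout_pairs: Sequence[tuple[int, int]] | None = None,
) -> dict:
    """How well a fitted model recovers the planted structure.

    Returns
    -------
    dict with:
      theta_correlation : Pearson correlation between the upper triangles of
          the planted and the fitted Theta (scale-invariant).
      sign_agreement : fraction of the training network's nonzero pairs whose
          predicted sign matches the label.
      heldout_auc : comprehensive AUC over ``heldout_pairs`` (global index
          pairs of ``dataset``), or None when no held-out pairs are given.
    """
    p = dataset.F.n_features
    if model.coefficients.shape[0] != p:
        raise ValueError("model feature dimension does not match the dataset")
    theta_fit = model.theta().values
    iu = np.triu_indices(p)
    t_true, t_fit = dataset.theta_true[iu], theta_fit[iu]
    if np.ptp(t_true) == 0 or np.ptp(t_fit) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(t_true, t_fit)[0, 1])

    train_drugs = model.training_features.drugs
    pos = [dataset.A.drugs.position(d) for d in train_drugs.ids]
    A_tr = dataset.A.values[np.ix_(pos, pos)]
    pred_tr = predict_new_vs_known(model, model.training_features).values
    nz = np.nonzero(np.triu(A_tr, k=1))
    if nz[0].size:
        agreement = float(np.mean(np.sign(pred_tr[nz]) == A_tr[nz]))
    else:
        agreement = float("nan")

    heldout_auc = None
    if heldout_pairs:
        idx = np.array(heldout_pairs, dtype=int)
        sub = np.unique(idx)
        F_sub = FeatureMatrix(
            dataset.F.values[sub],
            DrugSet(tuple(dataset.F.drugs.ids[i] for i in sub)),
            dataset.F.feature_names,
        )
        B = model.coefficients
        G = F_sub.values @ B
        full = G @ G.T
        lut = {int(g): k for k, g in enumerate(sub)}
        scores = np.array([full[lut[i], lut[j]] for i, j in idx])
        labels = np.array([dataset.A.values[i, j] for i, j in idx])
        heldout_auc = score_comprehensive(labels, scores).auc

    return {
        "theta_correlation": corr,
        "sign_agreement": agreement,
        "heldout_auc": heldout_auc,
    }
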