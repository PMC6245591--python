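"""Triple matrix factorization for signed DDI prediction.

The model connects a drug-drug interaction network to drug features through a
bilinear form

    A  =  F Theta F',

where A is the m x m signed adjacency, F the m x p binary feature matrix and
Theta a symmetric p x p projection matrix whose entry theta_rs weighs how
strongly the feature pair (f_r, f_s) pushes a drug pair toward an enhancive
(theta_rs > 0) or degressive (theta_rs < 0) interaction.  Solving for Theta
directly is hopeless at p ~ 10^4, so the fit proceeds in three factorization
steps:

1. ``A ~ A_d A_d'`` — a rank-r Gram factorization of the adjacency obtained
   from its eigendecomposition; rows of A_d place drugs in an r-dimensional
   latent interaction space where large inner products mean interaction.
2. ``A_d ~ F B`` — a SIMPLS partial least squares regression bridging the
   observed feature space to the latent space (p >> m and collinear columns
   rule out ordinary least squares).
3. ``Theta = B B'`` — the projection matrix, positive semidefinite by
   construction and never materialized unless asked for: all predictions use
   the factored form (F_x B)(F B)'.

Fitted models score unseen (cold-start) drugs from their feature vectors
alone: ``F_x Theta F'`` against the known drugs and ``F_x Theta F_y'``
between two groups of new drugs.  Score signs encode the predicted
interaction type, magnitudes the confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .data_io import DrugSet, FeatureMatrix, InteractionMatrix, binarize
from .plsr import PlsrFit, simpls_fit

__all__ = [
    "LatentInteractionMatrix",
    "ProjectionMatrix",
    "ConfidenceMatrix",
    "TmfModel",
    "factorize_interactions",
    "fit_tmfuf",
    "predict_new_vs_known",
    "predict_new_vs_new",
    "reconstruction_error",
    "save_model",
    "load_model",
]

#: relative eigenvalue cutoff used by rank="auto" and the PSD truncation
_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class LatentInteractionMatrix:
    """Rank-r Gram factor A_d with the retained spectrum of A.

    ``values = eigen_vectors @ diag(sqrt(eigen_values))`` so that
    ``values @ values.T`` is the best PSD rank-<=r approximation of A in
    Frobenius norm.  Retained eigenvalues are strictly positive, descending.
    """

    values: np.ndarray
    eigen_values: np.ndarray
    eigen_vectors: np.ndarray

    @property
    def rank(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ProjectionMatrix:
    """Materialized symmetric PSD projection Theta = B B'."""

    values: np.ndarray
    scale_factor: float


@dataclass(frozen=True)
class ConfidenceMatrix:
    """Real-valued prediction scores for drug pairs.

    Positive entries predict enhancive interactions, negative degressive;
    the absolute value is the confidence.
    """

    values: np.ndarray
    row_drugs: DrugSet
    col_drugs: DrugSet


@dataclass(frozen=True)
class TmfModel:
    """Fitted triple-matrix-factorization artifact."""

    regression: PlsrFit
    latent: LatentInteractionMatrix
    training_features: FeatureMatrix
    hyperparams: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        """The p x r regression coefficient matrix B."""
        return self.regression.coefficients

    @property
    def scale_factor(self) -> float:
        return float(self.hyperparams.get("scale_factor", 1.0))

    def theta(self) -> ProjectionMatrix:
        """Materialize Theta = B B' (p x p); prefer the factored form when
        only products with Theta are needed."""
        B = self.coefficients
        return ProjectionMatrix(values=B @ B.T, scale_factor=self.scale_factor)

    def theta_rows(self, rows: np.ndarray | slice) -> np.ndarray:
        """A row block of Theta computed from B without forming all of it."""
        B = self.coefficients
        return B[rows] @ B.T

    def _train_scores(self) -> np.ndarray:
        return self.training_features.values @ self.coefficients


def factorize_interactions(
    A: InteractionMatrix | np.ndarray,
    r: int | Literal["auto"] = "auto",
) -> LatentInteractionMatrix:
    """Best PSD rank-<=r Gram factorization of a symmetric matrix.

    The signed adjacency is indefinite, so the square root of its full
    spectrum is not real; the optimal Gram factor ``A_d A_d'`` over rank-r PSD
    matrices keeps only the r largest **positive** eigenvalues:
    ``A_d = U_r sqrt(Lambda_r)``.

    Parameters
    ----------
    A : InteractionMatrix or symmetric ndarray
        May be pre-scaled (e.g. by the x1000 factor used for the
        significance analysis).
    r : int or "auto"
        Target rank; "auto" keeps every positive eigenvalue above
        ``1e-10 x largest``, capped at m - 1.
    """
    M = np.asarray(A.values if isinstance(A, InteractionMatrix) else A, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T):
        raise ValueError("interaction matrix must be symmetric")
    m = M.shape[0]
    if r != "auto":
        r = int(r)
        if not 1 <= r < m:
            raise ValueError(f"rank must satisfy 1 <= r < m={m}, got {r}")

    lam, U = np.linalg.eigh(M)  # ascending
    lam, U = lam[::-1], U[:, ::-1]
    cutoff = _EIG_RTOL * max(lam[0], 0.0)
    n_pos = int(np.sum(lam > cutoff))
    if n_pos == 0:
        raise ValueError("no latent structure: no positive eigenvalue above tolerance")
    keep = min(n_pos, m - 1) if r == "auto" else min(r, n_pos)
    lam_r, U_r = lam[:keep], U[:, :keep]
    return LatentInteractionMatrix(
        values=U_r * np.sqrt(lam_r),
        eigen_values=lam_r.copy(),
        eigen_vectors=U_r.copy(),
    )


def fit_tmfuf(
    A: InteractionMatrix,
    F: FeatureMatrix,
    r: int | Literal["auto"] = "auto",
    L: int = 60,
    scale_factor: float = 1.0,
    binary_mode: bool = False,
) -> TmfModel:
    """Fit the full pipeline: scale -> factorize -> regress -> Theta = B B'.

    Parameters
    ----------
    A, F : interaction and feature matrices over the same drug set.
    r : latent rank of the adjacency factorization ("auto" = positive
        spectrum).
    L : number of SIMPLS latent factors, the model's one tunable parameter.
    scale_factor : multiplier applied to A before solving; x1000 keeps the
        entries of Theta away from floating-point underflow when p is large
        and makes the |theta| > 1 significance threshold meaningful.
    binary_mode : fit on the conventional binary network (all nonzero
        entries mapped to +1) instead of the signed one.

    The result is deterministic up to eigenvector sign flips, which cancel in
    Theta and in every prediction.
    """
    if A.drugs.ids != F.drugs.ids:
        raise ValueError("interaction and feature matrices must share the same drug set")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if binary_mode:
        A = binarize(A)
    latent = factorize_interactions(A.values * float(scale_factor), r)
    fit = simpls_fit(F.values, latent.values, L)
    return TmfModel(
        regression=fit,
        latent=latent,
        training_features=F,
        hyperparams={
            "r": r,
            "r_effective": latent.rank,
            "L": L,
            "L_effective": fit.n_components,
            "scale_factor": float(scale_factor),
            "binary_mode": bool(binary_mode),
        },
    )


def _check_feature_dim(model: TmfModel, F: FeatureMatrix, name: str) -> None:
    p = model.training_features.n_features
    if F.n_features != p:
        raise ValueError(
            f"{name} has {F.n_features} feature columns, model expects {p}"
        )


def predict_new_vs_known(model: TmfModel, F_x: FeatureMatrix) -> ConfidenceMatrix:
    """Score interactions of u new drugs against the m training drugs.

    Returns the u x m confidence matrix ``F_x Theta F_train'``, evaluated in
    factored form ``(F_x B)(F_train B)'``.
    """
    _check_feature_dim(model, F_x, "F_x")
    scores = (F_x.values @ model.coefficients) @ model._train_scores().T
    return ConfidenceMatrix(scores, F_x.drugs, model.training_features.drugs)


def predict_new_vs_new(
    model: TmfModel, F_x: FeatureMatrix, F_y: FeatureMatrix
) -> ConfidenceMatrix:
    """Score interactions between two groups of new drugs.

    Returns the u x v confidence matrix ``F_x Theta F_y'``; swapping the two
    groups transposes the result because Theta is symmetric.
    """
    _check_feature_dim(model, F_x, "F_x")
    _check_feature_dim(model, F_y, "F_y")
    B = model.coefficients
    scores = (F_x.values @ B) @ (F_y.values @ B).T
    return ConfidenceMatrix(scores, F_x.drugs, F_y.drugs)


def reconstruction_error(model: TmfModel, A: InteractionMatrix) -> float:
    """Frobenius norm of ``A_scaled - F Theta F'`` over off-diagonal entries.

    Self-pairs are excluded: DDIs hold between distinct drugs only.
    """
    if A.drugs.ids != model.training_features.drugs.ids:
        raise ValueError("model was not fitted on this drug set")
    G = model._train_scores()
    diff = A.values * model.scale_factor - G @ G.T
    np.fill_diagonal(diff, 0.0)
    return float(np.linalg.norm(diff))


def save_model(model: TmfModel, path: str | Path) -> None:
    """Persist a fitted model as a single ``.npz`` archive."""
    np.savez_compressed(
        path,
        coefficients=model.regression.coefficients,
        x_weights=model.regression.x_weights,
        eigen_values=model.latent.eigen_values,
        eigen_vectors=model.latent.eigen_vectors,
        latent_values=model.latent.values,
        training_features=model.training_features.values,
        drug_ids=np.array(model.training_features.drugs.ids),
        feature_names=np.array(model.training_features.feature_names),
        hyperparams=np.array([str(model.hyperparams)]),
    )


def load_model(path: str | Path) -> TmfModel:
    import ast

    with np.load(path, allow_pickle=False) as z:
        drugs = DrugSet(tuple(str(d) for d in z["drug_ids"]))
        F = FeatureMatrix(
            z["training_features"], drugs, tuple(str(f) for f in z["feature_names"])
        )
        hyper = ast.literal_eval(str(z["hyperparams"][0]))
        latent = LatentInteractionMatrix(
            values=z["latent_values"],
            eigen_values=z["eigen_values"],
            eigen_vectors=z["eigen_vectors"],
        )
        coeff = z["coefficients"]
        fit = PlsrFit(
            coefficients=coeff,
            n_components=int(hyper.get("L_effective", coeff.shape[1])),
            training_dims=(F.values.shape[0], F.values.shape[1], coeff.shape[1]),
            x_weights=z["x_weights"],
        )
    return TmfModel(regression=fit, latent=latent, training_features=F, hyperparams=hyper)
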