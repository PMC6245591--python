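"""Multivariate partial least squares regression via the SIMPLS algorithm.

The latent interaction coordinates of drugs must be regressed on their binary
side-effect profiles, a setting with far more predictors than observations
(p >> m) and strong multicollinearity between side-effect columns.  Ordinary
least squares is singular there; PLS regression handles it by extracting a
small number L of latent factors that maximize covariance between predictor
and response.  SIMPLS operates directly on the cross-product matrix S = X'Y,
deflating S after each extracted factor, and exposes a single tuning
parameter: the number of latent factors L.

This implementation deliberately applies **no column centering or scaling**
by default: the downstream bilinear predictor F_x @ Theta @ F' is a pure
quadratic form with no intercept, and centering would introduce offsets that
predictor cannot express.  Centering remains available behind an explicit
flag for experimentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PlsrFit", "simpls_fit"]


@dataclass(frozen=True)
class PlsrFit:
    """Fitted PLS regression: Y ~ X @ coefficients.

    Attributes
    ----------
    coefficients : (p, r) ndarray
        Regression coefficient matrix B; ``X @ B`` is the L-factor
        approximation of Y.
    n_components : int
        Number of latent factors actually extracted (may be fewer than
        requested when the deflated cross-product vanishes).
    training_dims : (m, p, r)
        Shapes of the training problem.
    x_weights : (p, n_components) ndarray
        SIMPLS weight vectors R; scores are ``X @ R``.
    centered : bool
        Whether column means were removed before fitting.
    x_mean, y_mean : ndarray or None
        Stored column means when ``centered`` is True.
    """

    coefficients: np.ndarray
    n_components: int
    training_dims: tuple[int, int, int]
    x_weights: np.ndarray
    centered: bool = False
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.centered:
            return (X - self.x_mean) @ self.coefficients + self.y_mean
        return X @ self.coefficients


def simpls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    L: int,
    *,
    center: bool = False,
) -> PlsrFit:
    """Fit an L-factor SIMPLS regression of Y on X.

    Parameters
    ----------
    X : (m, p) array
        Predictor matrix (here: binary side-effect profiles).
    Y : (m, r) array
        Response matrix (here: latent interaction coordinates).
    L : int
        Requested number of latent factors, ``1 <= L <= min(m, p)``.  A
        request beyond the number of numerically extractable factors stops
        early with a warning rather than failing, so tiny fixtures behave
        gracefully.
    center : bool
        Remove column means first (conventional SIMPLS).  Off by default;
        see the module docstring.

    Returns
    -------
    PlsrFit with ``coefficients`` of shape (p, r).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    m, p = X.shape
    if Y.shape[0] != m:
        raise ValueError(f"X has {m} rows but Y has {Y.shape[0]}")
    if L < 1:
        raise ValueError(f"number of latent factors must be >= 1, got {L}")
    if not np.any(X):
        raise ValueError("degenerate predictor: X is all-zero")
    r = Y.shape[1]

    x_mean = y_mean = None
    if center:
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        X = X - x_mean
        Y = Y - y_mean

    cap = min(m, p)
    if L > cap:
        warnings.warn(
            f"requested L={L} exceeds min(m, p)={cap}; capping", stacklevel=2
        )
        L = cap

    S = X.T @ Y  # p x r cross-product, deflated in place
    s0 = np.linalg.norm(S)
    tol = max(m, p) * np.finfo(float).eps * max(s0, 1.0)

    R = np.zeros((p, L))  # x-weights
    Q = np.zeros((r, L))  # y-loadings
    V = np.zeros((p, L))  # orthonormal basis of x-loadings, drives deflation

    a = 0
    while a < L:
        if np.linalg.norm(S) <= tol:
            warnings.warn(
                f"cross-product matrix exhausted after {a} factor(s); "
                f"stopping early (requested {L})",
                stacklevel=2,
            )
            break
        # dominant singular pair of S: r_a = left vector scaled by sigma
        if r == 1:
            r_a = S[:, 0].copy()
        else:
            _, _, vt = np.linalg.svd(S, full_matrices=False)
            r_a = S @ vt[0]
        t_a = X @ r_a
        normt = np.linalg.norm(t_a)
        if normt <= tol:
            warnings.warn(
                f"score vector vanished after {a} factor(s); stopping early",
                stacklevel=2,
            )
            break
        t_a /= normt
        r_a /= normt
        p_a = X.T @ t_a
        q_a = Y.T @ t_a
        v_a = p_a - V[:, :a] @ (V[:, :a].T @ p_a)
        # second pass re-orthogonalization controls drift at large p
        v_a -= V[:, :a] @ (V[:, :a].T @ v_a)
        nv = np.linalg.norm(v_a)
        if nv <= tol:
            warnings.warn(
                f"loading basis degenerate after {a} factor(s); stopping early",
                stacklevel=2,
            )
            break
        v_a /= nv
        S -= v_a[:, None] * (v_a @ S)
        R[:, a], Q[:, a], V[:, a] = r_a, q_a, v_a
        a += 1

    if a == 0:
        raise ValueError("degenerate predictor: no latent factor extractable")
    R, Q = R[:, :a], Q[:, :a]
    return PlsrFit(
        coefficients=R @ Q.T,
        n_components=a,
        training_dims=(m, p, r),
        x_weights=R,
        centered=center,
        x_mean=x_mean,
        y_mean=y_mean,
    )
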