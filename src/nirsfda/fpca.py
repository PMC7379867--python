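"""Functional principal component analysis on basis-expanded curves.

Curves are represented by their B-spline coefficient vectors c_i. With
W the basis Gram matrix (the L2 inner product in coefficient space) and
W = L L' its Cholesky factor, the covariance operator eigenproblem reduces
to the symmetric matrix eigenproblem

    L' Cov(c) L u = rho u,      xi = L^{-T} u,

whose eigenfunctions xi_j are orthonormal under the Gram inner product
(xi_j' W xi_k = delta_jk) and whose eigenvalues rho_j are the component
variances in TSI^2 * s units. Subject scores are the Gram projections
f_ij = (c_i - cbar)' W xi_j; their sample variance (n-1 divisor, matching
the covariance estimator) equals rho_j exactly. Scores are optionally
standardized to Z-scores so a subject at +2 sits two between-subject SDs
above the mean on that mode of variation.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, eigh, solve_triangular
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .basis import BSplineBasis

#: window (s) whose integral fixes each eigenfunction's sign
SIGN_WINDOW = (0.0, 40.0)


class FunctionalPCA(TransformerMixin, BaseEstimator):
    """Functional PCA of curves given by coefficients on a common B-spline basis.

    Parameters
    ----------
    basis : BSplineBasis, optional
        Basis the coefficient vectors refer to; defaults to the standard
        active-stand basis.
    n_retained : int, optional
        Number of leading components exposed as "retained" views (scores,
        correlation rows, reconstructions). All components are always
        computed and stored; this is a view, not a truncation.

    Attributes
    ----------
    mean_coefficients_ : ndarray (n_basis,)
        Coefficients of the sample mean curve.
    components_ : ndarray (n_components, n_basis)
        Eigenfunction coefficient vectors xi_j, Gram-orthonormal.
    eigenvalues_ : ndarray (n_components,)
        Component variances rho_j, non-increasing.
    variance_ratio_ : ndarray (n_components,)
        rho_j / sum(rho), over all computed components.
    scores_, z_scores_ : ndarray (n_subjects, n_components)
        Raw Gram-projection scores and their per-column standardization.
    """

    def __init__(self, basis: BSplineBasis | None = None, n_retained: int | None = None):
        self.basis = basis
        self.n_retained = n_retained

    def fit(self, X, y=None):
        basis = self.basis if self.basis is not None else BSplineBasis()
        C = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = C.shape
        if n < 2:
            raise ValueError("functional PCA needs at least 2 subjects")
        if p != basis.n_basis:
            raise ValueError(
                f"coefficient vectors have length {p} but the basis has "
                f"{basis.n_basis} functions"
            )
        W = basis.gram_matrix()
        L = cholesky(W, lower=True)
        cbar = C.mean(axis=0)
        Cc = C - cbar
        # L' Cov L, with Cov = Cc'Cc/(n-1)
        B = Cc @ L  # (n, p)
        M = (B.T @ B) / (n - 1)
        rho, U = eigh(M)
        order = np.argsort(rho)[::-1]
        rho = np.maximum(rho[order], 0.0)
        U = U[:, order]
        Xi = solve_triangular(L, U, lower=True, trans="T").T  # (p_comp, p)

        # deterministic sign: integral over the post-stand window >= 0,
        # ties broken by the first nonzero coefficient being positive
        m = basis.window_integral(*SIGN_WINDOW)
        for j in range(Xi.shape[0]):
            s = Xi[j] @ m
            if s == 0.0:
                nz = np.flatnonzero(Xi[j])
                s = Xi[j][nz[0]] if nz.size else 1.0
            if s < 0:
                Xi[j] = -Xi[j]

        scores = Cc @ (W @ Xi.T)
        total = rho.sum()
        self.basis_ = basis
        self.gram_ = W
        self.n_subjects_ = n
        self.mean_coefficients_ = cbar
        self.components_ = Xi
        self.eigenvalues_ = rho
        self.variance_ratio_ = rho / total if total > 0 else rho
        self.scores_ = scores
        sd = scores.std(axis=0, ddof=1)
        self.score_sd_ = sd
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (scores - scores.mean(axis=0)) / sd, 0.0)
        self.z_scores_ = z
        self.n_retained_ = (
            int(self.n_retained) if self.n_retained is not None else rho.size
        )
        if not 1 <= self.n_retained_ <= rho.size:
            raise ValueError("n_retained out of range")
        return self

    # -- score computation -------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Scores of new coefficient vectors against the fitted components."""
        check_is_fitted(self, "components_")
        C = np.atleast_2d(np.asarray(X, dtype=float))
        return (C - self.mean_coefficients_) @ (self.gram_ @ self.components_.T)

    def standardize(self, scores: np.ndarray) -> np.ndarray:
        """Z-standardize scores using the fitted cohort's means and SDs."""
        check_is_fitted(self, "scores_")
        mu = self.scores_.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.score_sd_ > 0, (scores - mu) / self.score_sd_, 0.0)

    # -- variance accounting ----------------------------------------------

    def variance_explained(self, k: int) -> float:
        """Proportion of total variance carried by the first k components."""
        check_is_fitted(self, "eigenvalues_")
        if not 1 <= k <= self.eigenvalues_.size:
            raise ValueError(f"k must be in [1, {self.eigenvalues_.size}]")
        return float(self.variance_ratio_[:k].sum())

    def scree_table(self) -> "pd.DataFrame":
        """Per-component eigenvalue, proportion and cumulative proportion."""
        import pandas as pd

        check_is_fitted(self, "eigenvalues_")
        return pd.DataFrame(
            {
                "component": np.arange(1, self.eigenvalues_.size + 1),
                "eigenvalue": self.eigenvalues_,
                "proportion": self.variance_ratio_,
                "cumulative": np.cumsum(self.variance_ratio_),
            }
        )

    # -- reconstruction ----------------------------------------------------

    def single_component_reconstruction(
        self, j: int, n_sd: float = 2.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coefficients of (mean, mean + n_sd*sqrt(rho_j)*xi_j, mean - ...).

        The classic mean +/- 2 SD visualization of what component j encodes;
        ``j`` is 1-based. Evaluate with :meth:`evaluate`.
        """
        check_is_fitted(self, "components_")
        if not 1 <= j <= self.n_retained_:
            raise ValueError(f"component index must be in [1, {self.n_retained_}]")
        step = n_sd * np.sqrt(self.eigenvalues_[j - 1]) * self.components_[j - 1]
        mean = self.mean_coefficients_
        return mean, mean + step, mean - step

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Coefficient vectors mean + sum_j score_j * xi_j."""
        check_is_fitted(self, "components_")
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.mean_coefficients_ + scores @ self.components_[: scores.shape[1]]

    def evaluate(self, coefficients: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Evaluate coefficient vectors as curves at times ``t``."""
        check_is_fitted(self, "components_")
        phi = self.basis_.design_matrix(np.asarray(t, dtype=float))
        return np.atleast_2d(coefficients) @ phi.T


def fit_fpca(
    coefficients: np.ndarray,
    basis: BSplineBasis | None = None,
    n_retained: int | None = None,
) -> FunctionalPCA:
    """Convenience wrapper: fit and return the decomposition."""
    return FunctionalPCA(basis=basis, n_retained=n_retained).fit(coefficients)
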