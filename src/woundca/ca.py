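"""Arctangent-degree transform and from-scratch correspondence analysis.

Fold changes are mapped to degrees by ``d(FC) = (180/pi) * arctan(1/FC)``,
a strictly decreasing bijection from (0, inf) onto (0, 90) with d(1) = 45.
Unlike the log transform it is bounded, compressing extreme ratios
(FC > 10 or < 0.1) instead of letting them dominate; its complement identity
``d(FC) + d(1/FC) = 90`` makes up- and downregulation symmetric about 45.

Correspondence analysis (CA) of the resulting genes x 3 degree matrix is the
classical chi-square ordination: with correspondence matrix
``P = N / n`` (grand total ``n``), row masses ``r = P 1`` and column masses
``c = P' 1``, the standardized residuals

    S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)

are decomposed by SVD, ``S = U diag(s) V'``. Principal coordinates are the
mass-rescaled singular vectors scaled by the singular values,

    F = diag(r)^(-1/2) U diag(s)      (rows / genes)
    G = diag(c)^(-1/2) V diag(s)      (columns / time points)

principal inertias (eigenvalues) are ``s**2`` and their proportions of total
inertia are the contribution rates. A 3-column table has at most two
non-trivial dimensions, so the first two dimensions always carry 100% of the
inertia and the biplot is exact: Euclidean distances between full-rank row
principal coordinates equal chi-square distances between row profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "degree_transform",
    "fold_change_to_degrees",
    "CorrespondenceAnalysis",
    "CAResult",
    "correspondence_analysis",
    "transition_check",
]


def degree_transform(fc):
    """Degrees of the arctangent of the reciprocal fold change.

    Parameters
    ----------
    fc : float or array-like
        Strictly positive fold change(s).

    Returns
    -------
    float or ndarray
        ``(180/pi) * arctan(1/fc)``, strictly inside (0, 90); a fold change
        of 1 maps to exactly 45 degrees, values approach 90 as ``fc -> 0``
        and 0 as ``fc -> inf``.
    """
    arr = np.asarray(fc, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("fold changes must be finite and strictly positive")
    out = np.degrees(np.arctan(1.0 / arr))
    if np.ndim(fc) == 0:
        return float(out)
    return out


def fold_change_to_degrees(fc: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`degree_transform` to an FC6/FC12/FC24 table.

    Output columns are relabeled ``t6``/``t12``/``t24``; rows are the
    QC-retained genes. This is the CA input matrix.
    """
    deg = degree_transform(fc.to_numpy())
    cols = [f"t{c.removeprefix('FC')}" for c in fc.columns]
    return pd.DataFrame(deg, index=fc.index, columns=cols)


class CorrespondenceAnalysis(BaseEstimator, TransformerMixin):
    """Correspondence analysis of a nonnegative table, sklearn-style.

    Parameters
    ----------
    n_components : int, default 2
        Number of principal axes retained in coordinates and ``transform``.

    Attributes
    ----------
    row_coordinates_ : ndarray of shape (n_rows, n_components)
        Row principal coordinates (genes).
    column_coordinates_ : ndarray of shape (n_cols, n_components)
        Column principal coordinates (time points); together with the row
        coordinates this is the symmetric-map biplot.
    eigenvalues_ : ndarray
        Principal inertias (squared singular values), descending, for the
        retained axes.
    contributions_ : ndarray
        ``eigenvalues_ / total_inertia_`` (contribution rates); all
        non-trivial axes of the table sum to 1.
    total_inertia_ : float
        Total chi-square variation of the table divided by its grand total.
    row_masses_, column_masses_ : ndarray
        Marginal mass vectors ``r`` and ``c``.
    singular_values_ : ndarray
        Retained singular values of the standardized residual matrix.

    Notes
    -----
    SVD axes are sign-ambiguous. The convention here orients each retained
    axis jointly for rows and columns so that on axis 1 the *last* column's
    score is nonnegative and on axis 2 the *first* column's score is
    nonpositive (for the t6/t12/t24 degree matrix: the 24 h score points
    right, the 6 h score points down). Any analysis must treat coordinates
    as equivalent up to joint sign flips.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._validate_table(X)
        n_rows, n_cols = X.shape
        total = X.sum()
        P = X / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        expected = np.outer(r, c)
        S = (P - expected) / np.sqrt(expected)
        U, s, Vt = np.linalg.svd(S, full_matrices=False)
        rank = min(n_rows, n_cols) - 1
        k = min(self.n_components, rank)
        U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
        # joint sign convention (see class notes); only meaningful for s > 0
        G_full = Vt.T / np.sqrt(c)[:, None] * s[None, :]
        for ax in range(rank):
            ref = G_full[-1, ax] if ax == 0 else -G_full[0, ax]
            if ref < 0:
                U[:, ax] *= -1.0
                Vt[ax, :] *= -1.0
        self.row_masses_ = r
        self.column_masses_ = c
        self.singular_values_ = s[:k]
        self.eigenvalues_ = s[:k] ** 2
        self.total_inertia_ = float((S**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = self.eigenvalues_ / self.total_inertia_
        self.contributions_ = np.where(self.total_inertia_ > 0, contrib, 0.0)
        self.row_coordinates_ = (U[:, :k] / np.sqrt(r)[:, None]) * s[None, :k]
        self.column_coordinates_ = (Vt[:k].T / np.sqrt(c)[:, None]) * s[None, :k]
        # column standard coordinates, used to project (supplementary) rows
        with np.errstate(invalid="ignore", divide="ignore"):
            gamma = np.where(s[None, :k] > 0, self.column_coordinates_ / s[None, :k], 0.0)
        self._column_standard_ = gamma
        self.n_components_ = k
        self.n_features_in_ = n_cols
        return self

    def transform(self, X):
        """Project rows (e.g. supplementary genes) into principal coordinates.

        Each row profile is barycentrically placed via the transition
        formula ``f = (profile @ G) / s``; on the fitted table this
        reproduces ``row_coordinates_``.
        """
        check_is_fitted(self, "row_coordinates_")
        X = self._validate_table(X, fit=False)
        profiles = X / X.sum(axis=1, keepdims=True)
        return profiles @ self._column_standard_

    @staticmethod
    def _validate_table(X, fit: bool = True):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("input must be a 2-D table")
        if fit and arr.shape[0] < 3:
            raise ValueError("correspondence analysis needs at least 3 rows")
        if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
            raise ValueError("table entries must be finite and strictly positive")
        return arr


@dataclass
class CAResult:
    """Labeled biplot output of a fitted :class:`CorrespondenceAnalysis`."""

    row_coords: pd.DataFrame      # genes x (factor1, factor2)
    col_coords: pd.DataFrame      # time points x (factor1, factor2)
    eigenvalues: np.ndarray
    contributions: np.ndarray
    total_inertia: float
    row_masses: pd.Series
    col_masses: pd.Series
    singular_values: np.ndarray

    @property
    def cumulative_contribution(self) -> float:
        return float(self.contributions.sum())


def correspondence_analysis(degrees: pd.DataFrame, n_components: int = 2) -> CAResult:
    """Fit CA on a genes x time-points degree matrix and return labeled results."""
    est = CorrespondenceAnalysis(n_components=n_components).fit(degrees.to_numpy())
    axes = [f"factor{i + 1}" for i in range(est.n_components_)]
    return CAResult(
        row_coords=pd.DataFrame(est.row_coordinates_, index=degrees.index, columns=axes),
        col_coords=pd.DataFrame(est.column_coordinates_, index=degrees.columns, columns=axes),
        eigenvalues=est.eigenvalues_,
        contributions=est.contributions_,
        total_inertia=est.total_inertia_,
        row_masses=pd.Series(est.row_masses_, index=degrees.index, name="mass"),
        col_masses=pd.Series(est.column_masses_, index=degrees.columns, name="mass"),
        singular_values=est.singular_values_,
    )


def transition_check(res: CAResult, degrees: pd.DataFrame, tol: float = 1e-8) -> bool:
    """Verify the CA transition formulas on a result, to ``tol``.

    Each row coordinate must equal the profile-weighted average of column
    coordinates rescaled by the inverse singular value, and symmetrically
    for columns. Returns False if either identity fails; raises on shape
    mismatch.
    """
    X = np.asarray(degrees, dtype=float)
    F = res.row_coords.to_numpy()
    G = res.col_coords.to_numpy()
    if X.shape[0] != F.shape[0] or X.shape[1] != G.shape[0]:
        raise ValueError("degree matrix and CA result shapes do not match")
    s = res.singular_values
    keep = s > tol  # degenerate axes carry no constraint
    if not keep.any():
        return bool(np.allclose(F, 0, atol=tol) and np.allclose(G, 0, atol=tol))
    row_profiles = X / X.sum(axis=1, keepdims=True)
    col_profiles = (X / X.sum(axis=0, keepdims=True)).T
    F_hat = (row_profiles @ G[:, keep]) / s[keep]
    G_hat = (col_profiles @ F[:, keep]) / s[keep]
    return bool(
        np.allclose(F_hat, F[:, keep], atol=tol) and np.allclose(G_hat, G[:, keep], atol=tol)
    )
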