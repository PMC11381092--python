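"""Correlation PCA with Kaiser retention and varimax rotation.

Foraging and diving metric tables are reduced to rotated components (fRC1,
fRC2 / dRC1, dRC2): variables are standardized, components with eigenvalue
above the Kaiser threshold (1.0) are retained, and when at least two are
retained the loading matrix is varimax-rotated.  Scores use the regression
method.  Because the sign of a component is arbitrary, each loading column
is flipped so its largest-magnitude loading is positive; interpretation is
invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def varimax_criterion(loadings: np.ndarray) -> float:
    """The quantity varimax maximizes: sum over components of the variance
    of squared loadings."""
    L2 = np.asarray(loadings) ** 2
    p = L2.shape[0]
    return float(np.sum(L2 ** 2) / p - np.sum((L2.sum(axis=0) / p) ** 2))


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000,
            kaiser_normalize: bool = True):
    """Varimax rotation by iterative pairwise planar rotations.

    Returns (rotated loadings, orthogonal rotation matrix R) with
    ``rotated = loadings @ R``; per-variable communalities are preserved.
    The criterion trace is available via the third return value.
    """
    A = np.asarray(loadings, dtype=float).copy()
    p, m = A.shape
    if m < 2:
        raise ValueError("need at least two components to rotate")
    h = np.sqrt((A ** 2).sum(axis=1))
    if kaiser_normalize:
        hs = np.where(h > 0, h, 1.0)
        A = A / hs[:, None]
    R = np.eye(m)
    trace = [varimax_criterion(A)]
    for _ in range(max_iter):
        old = trace[-1]
        for i in range(m - 1):
            for j in range(i + 1, m):
                x, y = A[:, i], A[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * ((u * v).sum() - u.sum() * v.sum() / p)
                den = (u ** 2 - v ** 2).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.eye(m)
                G[i, i] = G[j, j] = c
                G[i, j] = -s
                G[j, i] = s
                A = A @ G
                R = R @ G
        trace.append(varimax_criterion(A))
        if trace[-1] - old < tol:
            break
    if kaiser_normalize:
        A = A * hs[:, None]
    return A, R, trace


def _sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-|loading| entry of each is positive."""
    flips = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flips[flips == 0] = 1.0
    return loadings * flips


class RotatedPCA(BaseEstimator, TransformerMixin):
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Parameters
    ----------
    kaiser : float
        Retain components with eigenvalue strictly greater than this.
    rotate : bool
        Varimax-rotate when >= 2 components are retained.
    strong_loading : float
        |loading| threshold used by :meth:`strong_loadings` for reporting.

    Fitted attributes
    -----------------
    variables_ : list of variable names
    eigenvalues_ : all eigenvalues, non-increasing (sum = n variables)
    n_retained_ : number of retained components
    loadings_ : (variables x retained) rotated loading matrix
    rotation_ : orthogonal rotation applied (identity when not rotated)
    var_explained_pct_ : 100 * sum(retained eigenvalues) / n variables
    """

    def __init__(self, kaiser: float = 1.0, rotate: bool = True,
                 strong_loading: float = 0.5):
        self.kaiser = kaiser
        self.rotate = rotate
        self.strong_loading = strong_loading

    def fit(self, X: pd.DataFrame, y=None) -> "RotatedPCA":
        X = pd.DataFrame(X).dropna()
        if len(X) < 2:
            raise ValueError("need at least two complete rows")
        sd = X.std(ddof=1)
        const = sd[sd == 0]
        if len(const):
            raise ValueError(f"constant variable(s): {', '.join(map(str, const.index))}")
        self.variables_ = list(X.columns)
        self.mean_ = X.mean()
        self.scale_ = sd
        Z = (X - self.mean_) / self.scale_
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.eigenvalues_ = np.clip(evals, 0.0, None)
        keep = self.eigenvalues_ > self.kaiser
        self.n_retained_ = int(keep.sum())
        self.var_explained_pct_ = float(
            100.0 * self.eigenvalues_[keep].sum() / len(self.variables_))
        L = evecs[:, keep] * np.sqrt(self.eigenvalues_[keep])
        self.rotation_ = np.eye(self.n_retained_)
        self.rotated_ = False
        if self.rotate and self.n_retained_ >= 2:
            L, self.rotation_, self.criterion_trace_ = varimax(L)
            self.rotated_ = True
        self.loadings_ = _sign_fix(L) if self.n_retained_ else L
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Regression-method component scores; rows with missing values dropped."""
        X = pd.DataFrame(X)[self.variables_].dropna()
        Z = ((X - self.mean_) / self.scale_).to_numpy()
        L = self.loadings_
        W = L @ np.linalg.inv(L.T @ L)
        S = Z @ W
        cols = [f"RC{i + 1}" for i in range(self.n_retained_)]
        return pd.DataFrame(S, index=X.index, columns=cols)

    def strong_loadings(self) -> pd.DataFrame:
        """Loadings with |value| >= strong_loading, NaN elsewhere (reporting aid)."""
        L = pd.DataFrame(self.loadings_, index=self.variables_,
                         columns=[f"RC{i + 1}" for i in range(self.n_retained_)])
        return L.where(L.abs() >= self.strong_loading)


def pca_kaiser(metrics: pd.DataFrame, kaiser: float = 1.0) -> RotatedPCA:
    """Fit a :class:`RotatedPCA` on a birds x variables metric table."""
    return RotatedPCA(kaiser=kaiser).fit(metrics)


def scores(result: RotatedPCA, metrics: pd.DataFrame) -> pd.DataFrame:
    return result.transform(metrics)
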