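"""Soft clustering of expression profiles (Mfuzz-style fuzzy c-means).

Tissue/condition expression profiles of candidate mobile transcripts are
z-scored on the log2(FPKM + 1) scale and partitioned into ``c`` soft
clusters by fuzzy c-means: each gene receives a membership in every
cluster, memberships summing to one, with the fuzzifier ``m`` controlling
how soft the partition is. The estimator follows scikit-learn
conventions (``fit`` / ``fit_predict`` / ``predict``, ``get_params``,
trailing-underscore fitted attributes) and composes with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_array, check_random_state

__all__ = ["FuzzyCMeans", "standardize_profiles", "fuzzy_cmeans"]


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering.

    Alternates membership updates
    ``u_gk \\propto d(x_g, v_k)^{-2/(m-1)}`` (row-normalized) and center
    updates ``v_k = sum_g u_gk^m x_g / sum_g u_gk^m`` until the largest
    center shift falls below ``tol``. A point coinciding exactly with a
    center receives membership 1 for that center. Centers are initialized
    k-means++-style from the seeded RNG, so a fixed ``random_state`` gives
    an identical clustering.

    Parameters
    ----------
    n_clusters : int, default 5
        Number of clusters ``c``.
    m : float, default 1.25
        Fuzzifier, > 1; values near 1 approach hard k-means.
    tol : float, default 1e-6
        Convergence threshold on the maximum center coordinate shift.
    max_iter : int, default 1000
    random_state : int | None

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) array
    membership_ : (n_samples, n_clusters) array, rows sum to 1
    labels_ : argmax cluster per sample
    n_iter_ : iterations run
    objective_ : final value of J = sum u^m d^2
    objective_history_ : J after each membership update (non-increasing)
    """

    def __init__(self, n_clusters: int = 5, m: float = 1.25, tol: float = 1e-6,
                 max_iter: int = 1000, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0.0
        u = np.zeros_like(d2)
        exact = zero.any(axis=1)
        if exact.any():
            # degenerate-distance rule: all mass on the coinciding center(s)
            u[exact] = zero[exact] / zero[exact].sum(axis=1, keepdims=True)
        rest = ~exact
        if rest.any():
            # normalize by the row minimum before exponentiating so the
            # largest weight is exactly 1 (no overflow for tiny distances)
            dmin = d2[rest].min(axis=1, keepdims=True)
            w = (d2[rest] / dmin) ** (-1.0 / (self.m - 1.0))
            u[rest] = w / w.sum(axis=1, keepdims=True)
        return u

    def _init_centers(self, X: np.ndarray, rng) -> np.ndarray:
        # k-means++ style seeding
        n = X.shape[0]
        centers = [X[rng.randint(n)]]
        for _ in range(1, self.n_clusters):
            d2 = np.min(((X[:, None, :] - np.asarray(centers)[None]) ** 2
                         ).sum(axis=2), axis=1)
            total = d2.sum()
            if total <= 0:
                centers.append(X[rng.randint(n)])
                continue
            centers.append(X[rng.choice(n, p=d2 / total)])
        return np.asarray(centers, dtype=float)

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1.0:
            raise ValueError("the fuzzifier m must be > 1")
        X = check_array(X, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters rows")
        rng = check_random_state(self.random_state)
        centers = self._init_centers(X, rng)
        history: list[float] = []
        for it in range(1, self.max_iter + 1):
            u = self._memberships(X, centers)
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            history.append(float(((u ** self.m) * d2).sum()))
            um = u ** self.m
            denom = um.sum(axis=0)[:, None]
            new_centers = np.where(denom > 0, um.T @ X / np.where(
                denom > 0, denom, 1.0), centers)
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < self.tol:
                break
        self.cluster_centers_ = centers
        self.membership_ = self._memberships(X, centers)
        self.labels_ = self.membership_.argmax(axis=1)
        self.n_iter_ = it
        self.objective_history_ = history
        self.objective_ = history[-1]
        return self

    def predict(self, X):
        X = check_array(X, dtype=float)
        return self._memberships(X, self.cluster_centers_).argmax(axis=1)

    def soft_predict(self, X):
        """Membership matrix of new profiles against the fitted centers."""
        X = check_array(X, dtype=float)
        return self._memberships(X, self.cluster_centers_)


def standardize_profiles(fpkm: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """z-score log2(FPKM + 1) per gene across samples.

    Returns the standardized frame (each row mean 0, population s.d. 1) and
    the list of constant rows, which are excluded from clustering because
    they carry no profile shape.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize profiles")
    logged = np.log2(fpkm.astype(float) + 1.0)
    sd = logged.std(axis=1, ddof=0)
    constant = sd.index[sd == 0.0].tolist()
    kept = logged.drop(index=constant)
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.drop(index=constant), axis=0)
    return z, constant


def fuzzy_cmeans(X, c: int = 5, m: float = 1.25, tol: float = 1e-6,
                 max_iter: int = 1000, seed=None) -> FuzzyCMeans:
    """Functional wrapper: fit a :class:`FuzzyCMeans` on ``X`` and return it."""
    est = FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                      random_state=seed)
    return est.fit(np.asarray(X, dtype=float))
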