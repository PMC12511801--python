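"""Trait-prediction harness for bandwidth selection.

Connectivity matrices are vectorized over the upper triangle, reduced by
PCA (at most n_subjects − 1 components), and a ridge regression predicts a
scalar trait from the first K principal components. Repeated random 80/20
train-test splits record out-of-sample MSE and prediction-outcome
correlation; the bandwidth whose smoothed matrices minimize mean test MSE
(or maximize correlation) wins, with ties going to the smaller bandwidth.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from surfconn.smoothing import ConnectivityMatrix

__all__ = [
    "PredictionResult",
    "pca_reduce",
    "ridge_cv_predict",
    "bandwidth_selection",
]

_ALPHAS = np.logspace(-3, 3, 13)


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    """Out-of-sample errors per (K, split)."""

    k_grid: tuple[int, ...]
    mse: np.ndarray  # (len(k_grid), n_splits)
    correlation: np.ndarray  # (len(k_grid), n_splits), NaN when undefined

    def mean_mse(self) -> np.ndarray:
        return self.mse.mean(axis=1)

    def mean_correlation(self) -> np.ndarray:
        return np.nanmean(self.correlation, axis=1)

    def best_k(self) -> int:
        return self.k_grid[int(np.argmin(self.mean_mse()))]


def _vectorize(matrices: Sequence[ConnectivityMatrix | np.ndarray]) -> np.ndarray:
    rows = []
    for P in matrices:
        v = P.values if isinstance(P, ConnectivityMatrix) else np.asarray(P)
        iu = np.triu_indices(v.shape[0])
        rows.append(v[iu])
    return np.vstack(rows)


def pca_reduce(
    matrices: Sequence[ConnectivityMatrix | np.ndarray],
    max_pcs: Optional[int] = None,
) -> np.ndarray:
    """Centered PCA scores of upper-triangle-vectorized matrices.

    At most n_subjects − 1 components carry variance; components are
    ordered by decreasing explained variance.
    """
    X = _vectorize(matrices)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    cap = n - 1
    k = cap if max_pcs is None else min(max_pcs, cap, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full" if min(X.shape) < 2000 else "auto")
    return pca.fit_transform(X)


def ridge_cv_predict(
    scores: np.ndarray,
    traits: np.ndarray,
    k_grid: Sequence[int],
    *,
    n_splits: int = 50,
    test_frac: float = 0.2,
    seed: int = 0,
    standardize: bool = True,
) -> PredictionResult:
    """Ridge prediction over PC counts K and random train-test splits.

    For each split and K, a ridge model is fit on the training fold only
    (penalty tuned by internal 5-fold CV on a log grid), then scored on
    the held-out fold. All randomness flows from ``seed``.
    """
    X = np.asarray(scores, dtype=np.float64)
    y = np.asarray(traits, dtype=np.float64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("scores and traits disagree on subject count")
    k_grid = tuple(int(k) for k in k_grid)
    if max(k_grid) > X.shape[1]:
        raise ValueError("K exceeds available components")
    rng = np.random.default_rng(seed)
    mse = np.empty((len(k_grid), n_splits))
    corr = np.full((len(k_grid), n_splits), np.nan)
    for s in range(n_splits):
        split_seed = int(rng.integers(2**31))
        tr, te = train_test_split(
            np.arange(y.size), test_size=test_frac, random_state=split_seed
        )
        for ki, k in enumerate(k_grid):
            Xtr, Xte = X[tr, :k], X[te, :k]
            if standardize:
                scaler = StandardScaler().fit(Xtr)
                Xtr = scaler.transform(Xtr)
                Xte = scaler.transform(Xte)
            cv = min(5, len(tr))
            model = RidgeCV(
                alphas=_ALPHAS, cv=cv, scoring="neg_mean_squared_error"
            ).fit(Xtr, y[tr])
            pred = model.predict(Xte)
            resid = pred - y[te]
            mse[ki, s] = float((resid**2).mean())
            if np.std(y[te]) > 0 and np.std(pred) > 0:
                corr[ki, s] = float(np.corrcoef(pred, y[te])[0, 1])
    return PredictionResult(k_grid=k_grid, mse=mse, correlation=corr)


def bandwidth_selection(
    bandwidths: Sequence[float],
    results: Sequence[PredictionResult],
    *,
    criterion: str = "mse",
) -> float:
    """Pick the bandwidth with best out-of-sample performance.

    ``criterion='mse'`` minimizes the per-bandwidth best mean test MSE;
    ``'correlation'`` maximizes the best mean correlation. Ties go to the
    smaller bandwidth.
    """
    if len(bandwidths) != len(results) or not bandwidths:
        raise ValueError("need one result per bandwidth")
    order = np.argsort(np.asarray(bandwidths))
    best_bw, best_score = None, None
    for i in order:  # ascending bandwidth; strict improvement required
        r = results[i]
        if criterion == "mse":
            score = float(np.min(r.mean_mse()))
            better = best_score is None or score < best_score
        elif criterion == "correlation":
            score = float(np.nanmax(r.mean_correlation()))
            better = best_score is None or score > best_score
        else:
            raise ValueError("criterion must be 'mse' or 'correlation'")
        if better:
            best_bw, best_score = float(np.asarray(bandwidths)[i]), score
    return best_bw
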