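"""PCA with explained variance R² and cross-validated Q².

The decomposition is by SVD of the preprocessed matrix (mean-centred,
autoscaled, or SNV-then-mean-centred).  Q² uses venetian-blind fold
assignment at the biological-sample level (replicates of one sample stay
in one fold) and predicts each held-out element from a projection that
excludes the predicted variable — the leave-one-variable-out scheme that
avoids the trivial Q² ≈ R² leak of naive row projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ftir import snv

PREPROCESSING = ("mean-center", "autoscale", "snv+mean-center")


@dataclass
class PcaModel:
    preprocessing: str
    mean_: np.ndarray
    scale_: np.ndarray | None
    loadings: np.ndarray  # n_components x n_variables, orthonormal rows
    scores: np.ndarray  # n_obs x n_components
    singular_values: np.ndarray
    r2_per_component: np.ndarray
    total_ss: float

    @property
    def r2_cum(self) -> float:
        return float(self.r2_per_component.sum())

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.preprocessing == "snv+mean-center":
            X = snv(X)
        X = X - self.mean_
        if self.scale_ is not None:
            X = X / self.scale_
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.preprocess(X) @ self.loadings.T


def _apply_preprocessing(X: np.ndarray, preprocessing: str):
    if preprocessing not in PREPROCESSING:
        raise ValueError(f"unknown preprocessing {preprocessing!r}")
    X = np.asarray(X, float)
    if preprocessing == "snv+mean-center":
        X = snv(X)
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if preprocessing == "autoscale":
        scale = Xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValueError("zero-variance column under autoscaling")
        Xc = Xc / scale
    return Xc, mean, scale


def pca_fit(X, n_components: int, preprocessing: str = "mean-center") -> PcaModel:
    """Fit a PCA model by SVD of the preprocessed matrix.

    ``r2_per_component`` is each singular value squared over the total sum
    of squares of the preprocessed matrix.  Loading signs follow the
    convention that each component's largest-magnitude element is positive.
    """
    X = np.asarray(X, float)
    n, v = X.shape
    if not (1 <= n_components <= min(n - 1, v)):
        raise ValueError("n_components must be in [1, min(rows-1, cols)]")
    Xc, mean, scale = _apply_preprocessing(X, preprocessing)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # deterministic sign: largest-|.| loading element positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    total_ss = float(np.sum(Xc**2))
    if total_ss == 0:
        raise ValueError("preprocessed matrix has zero total variance")
    return PcaModel(
        preprocessing=preprocessing,
        mean_=mean,
        scale_=scale,
        loadings=Vt,
        scores=U * s,
        singular_values=s,
        r2_per_component=s**2 / total_ss,
        total_ss=total_ss,
    )


def _predict_loo_variables(P: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Element-wise prediction where variable j is excluded from its own
    projection (Sherman–Morrison on the orthonormal loadings)."""
    k, v = P.shape
    T_full = X @ P.T  # n x k
    xhat = np.empty_like(X)
    # per variable j: t_(-j) = (I - p_j p_j^T)^{-1} (P x - p_j x_j)
    norms = np.sum(P**2, axis=0)  # ||p_j||^2 across components
    for j in range(v):
        pj = P[:, j]  # k
        rhs = T_full - np.outer(X[:, j], pj)  # n x k
        denom = 1.0 - norms[j]
        if denom <= 1e-12:
            # variable fully determined by the model; plain projection
            t = rhs
        else:
            t = rhs + np.outer(rhs @ pj, pj) / denom
        xhat[:, j] = t @ pj
    return xhat


def pca_q2(
    X,
    n_components: int,
    preprocessing: str = "mean-center",
    folds: int = 7,
    seed: int = 0,
    sample_ids=None,
) -> float:
    """Cross-validated Q² = 1 - PRESS/TSS of the preprocessed matrix.

    Venetian-blind fold assignment over biological samples (or rows when
    ``sample_ids`` is None): samples sorted by id are dealt to folds in
    rotation, so replicates of one sample share a fold.  For each fold the
    model (including preprocessing parameters) is refit on the remainder
    and held-out elements are predicted with the leave-one-variable-out
    projection.  ``seed`` rotates the dealing origin.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if not (2 <= folds <= n):
        raise ValueError("require 2 <= folds <= rows")
    if sample_ids is None:
        sample_ids = np.arange(n)
    sample_ids = np.asarray(sample_ids)
    uniq = np.array(sorted(set(sample_ids.tolist())))
    if folds > len(uniq):
        raise ValueError("more folds than biological samples")
    offset = int(np.random.default_rng(seed).integers(folds))
    fold_of_sample = {s: (i + offset) % folds for i, s in enumerate(uniq)}
    fold = np.array([fold_of_sample[s] for s in sample_ids])

    Xc_full, _, _ = _apply_preprocessing(X, preprocessing)
    tss = float(np.sum(Xc_full**2))
    press = 0.0
    for f in range(folds):
        test = fold == f
        train = ~test
        model = pca_fit(X[train], n_components, preprocessing)
        X_test = model.preprocess(X[test])
        xhat = _predict_loo_variables(model.loadings, X_test)
        press += float(np.sum((X_test - xhat) ** 2))
    return 1.0 - press / tss


def replicate_medians(
    scores: np.ndarray, sample_ids, stage=None
) -> pd.DataFrame:
    """Per-sample component-wise medians of technical-replicate scores."""
    scores = np.atleast_2d(np.asarray(scores, float))
    df = pd.DataFrame(scores, columns=[f"PC{k+1}" for k in range(scores.shape[1])])
    df["sample_id"] = np.asarray(sample_ids)
    if stage is not None:
        df["stage"] = np.asarray(stage)
        med = df.groupby(["sample_id", "stage"], as_index=False).median()
    else:
        med = df.groupby("sample_id", as_index=False).median()
    return med


def model_summary(model: PcaModel, q2: float | None = None) -> dict:
    """JSON-ready summary of a fitted PCA model."""
    out = {
        "preprocessing": model.preprocessing,
        "n_components": int(model.loadings.shape[0]),
        "r2_per_component": [float(r) for r in model.r2_per_component],
        "r2_cum": model.r2_cum,
    }
    if q2 is not None:
        out["q2_cum"] = float(q2)
    return out
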