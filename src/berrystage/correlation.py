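"""Two-block Pearson correlation maps with Ward clustering.

Correlates two feature blocks measured on the same observations (e.g.
e-nose sensors vs VOC abundances, chemistry vs colour features), tests
each coefficient at level alpha, clusters the correlation profiles by
Ward's method on Euclidean distances with the cluster count selected by
silhouette analysis, and exports dendrogram-ordered heatmaps with a
companion TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from sklearn.metrics import silhouette_score

#: Largest cluster count tried by silhouette selection.
MAX_K = 8


@dataclass
class CorrelationMap:
    """Pearson coefficients between two feature blocks, with significance
    and (optionally) cluster assignments per axis."""

    rho: pd.DataFrame  # block-A features x block-B features
    pvals: pd.DataFrame
    alpha: float
    row_clusters: pd.Series | None = None
    col_clusters: pd.Series | None = None
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None
    k_rows: int | None = None
    k_cols: int | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.pvals <= self.alpha


def two_block_pearson(A: pd.DataFrame, B: pd.DataFrame, alpha: float = 0.05) -> CorrelationMap:
    """Pearson correlation of every block-A feature with every block-B
    feature, with two-sided t-test p-values.

    Both blocks must share observations row-for-row; any zero-variance
    feature raises.
    """
    if len(A) != len(B):
        raise ValueError("both blocks must have the same observations (rows)")
    n = len(A)
    if n < 3:
        raise ValueError("at least 3 observations required")
    Xa = A.to_numpy(float)
    Xb = B.to_numpy(float)
    for block, name in ((Xa, "A"), (Xb, "B")):
        if np.any(block.std(axis=0) == 0):
            raise ValueError(f"zero-variance feature in block {name}")
    Za = (Xa - Xa.mean(0)) / Xa.std(0, ddof=1)
    Zb = (Xb - Xb.mean(0)) / Xb.std(0, ddof=1)
    r = np.clip(Za.T @ Zb / (n - 1), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return CorrelationMap(
        rho=pd.DataFrame(r, index=A.columns, columns=B.columns),
        pvals=pd.DataFrame(p, index=A.columns, columns=B.columns),
        alpha=alpha,
    )


def cluster_features(rho: pd.DataFrame, axis: int, k: int):
    """Ward clustering of correlation profiles along one axis of the map.

    ``axis=0`` clusters the row features on their profiles across columns;
    ``axis=1`` the transpose.  Returns (labels Series, linkage matrix).
    """
    profiles = rho.to_numpy(float) if axis == 0 else rho.to_numpy(float).T
    names = rho.index if axis == 0 else rho.columns
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    if not (1 <= k <= profiles.shape[0]):
        raise ValueError("k exceeds the feature count")
    Z = linkage(profiles, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=names, name="cluster"), Z


def silhouette_select_k(profiles: np.ndarray, k_range=None) -> tuple[int, dict[int, float]]:
    """Pick the cluster count maximising mean silhouette width.

    Candidate partitions come from cutting the Ward tree of the profiles
    at each k in ``k_range`` (default 2..min(8, n-1)); ties break to the
    smallest k.  Degenerate inputs (fewer than 3 profiles, or all profiles
    identical) raise.
    """
    profiles = np.asarray(profiles, float)
    n = profiles.shape[0]
    if n < 3:
        raise ValueError("need at least 3 features for silhouette selection")
    if np.allclose(profiles, profiles[0]):
        raise ValueError("all profiles identical; cluster count undefined")
    if k_range is None:
        k_range = range(2, min(MAX_K, n - 1) + 1)
    Z = linkage(profiles, method="ward", metric="euclidean")
    scores: dict[int, float] = {}
    for k in k_range:
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(profiles, labels, metric="euclidean"))
    if not scores:
        raise ValueError("no valid partition in k_range")
    best = min((k for k in scores), key=lambda k: (-scores[k], k))
    return best, scores


def attach_clusters(
    cmap: CorrelationMap,
    k_rows: int | None = None,
    k_cols: int | None = None,
    cluster_cols: bool = True,
) -> CorrelationMap:
    """Cluster the map's axes in place (silhouette-selected k when None).

    Column clustering can be disabled for very wide blocks (e.g. a full
    spectrum axis kept in natural wavenumber order).
    """
    if k_rows is None:
        k_rows, _ = silhouette_select_k(cmap.rho.to_numpy(float))
    cmap.row_clusters, cmap.row_linkage = cluster_features(cmap.rho, 0, k_rows)
    cmap.k_rows = k_rows
    if cluster_cols:
        if k_cols is None:
            k_cols, _ = silhouette_select_k(cmap.rho.to_numpy(float).T)
        cmap.col_clusters, cmap.col_linkage = cluster_features(cmap.rho, 1, k_cols)
        cmap.k_cols = k_cols
    return cmap


def _leaf_order(Z: np.ndarray | None, n: int):
    if Z is None:
        return np.arange(n)
    return np.asarray(dendrogram(Z, no_plot=True)["leaves"])


def heatmap_export(cmap: CorrelationMap, figure_path: str | Path, tsv_path: str | Path) -> None:
    """Write the dendrogram-ordered heatmap (PNG/SVG) and companion TSV.

    Non-significant coefficients (p > alpha) are rendered hollow (blank
    cell) in the figure but retained at full precision in the TSV, which
    holds one row per feature pair: rho, p, significance and cluster
    assignments.
    """
    if cmap.row_clusters is None:
        raise ValueError("clusters not assigned; call attach_clusters first")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r_ord = _leaf_order(cmap.row_linkage, cmap.rho.shape[0])
    c_ord = _leaf_order(cmap.col_linkage, cmap.rho.shape[1])
    rho = cmap.rho.to_numpy(float)[np.ix_(r_ord, c_ord)]
    sig = cmap.significant.to_numpy()[np.ix_(r_ord, c_ord)]
    shown = np.where(sig, rho, np.nan)

    h = max(3.0, 0.25 * len(r_ord) + 1.5)
    w = max(4.0, min(0.25 * len(c_ord) + 2.0, 14.0))
    fig, ax = plt.subplots(figsize=(w, h))
    im = ax.imshow(shown, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto",
                   interpolation="nearest")
    ax.set_yticks(range(len(r_ord)))
    ax.set_yticklabels(cmap.rho.index[r_ord], fontsize=7)
    if len(c_ord) <= 80:
        ax.set_xticks(range(len(c_ord)))
        ax.set_xticklabels(cmap.rho.columns[c_ord], fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, label=r"Pearson $\rho$ (hollow: p > $\alpha$)")
    # cluster colour bars along both axes
    row_cl = cmap.row_clusters.to_numpy()[r_ord]
    for i, cl in enumerate(row_cl):
        ax.plot([-0.8], [i], marker="s", ms=5, color=f"C{(cl - 1) % 10}",
                clip_on=False)
    if cmap.col_clusters is not None:
        col_cl = cmap.col_clusters.to_numpy()[c_ord]
        for j, cl in enumerate(col_cl):
            ax.plot([j], [-0.8], marker="s", ms=5, color=f"C{(cl - 1) % 10}",
                    clip_on=False)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)

    rows = []
    for a in cmap.rho.index:
        for b in cmap.rho.columns:
            rows.append(
                {
                    "feature_a": a,
                    "feature_b": b,
                    "rho": float(cmap.rho.loc[a, b]),
                    "p": float(cmap.pvals.loc[a, b]),
                    "significant": bool(cmap.pvals.loc[a, b] <= cmap.alpha),
                    "cluster_a": int(cmap.row_clusters[a]),
                    "cluster_b": (
                        int(cmap.col_clusters[b]) if cmap.col_clusters is not None else ""
                    ),
                }
            )
    # %.17g preserves doubles exactly, so the TSV round-trips rho/p
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")


def read_heatmap_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a heatmap companion TSV (rho/p at full precision)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["rho"] = df["rho"].astype(float)
    df["p"] = df["p"].astype(float)
    return df
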