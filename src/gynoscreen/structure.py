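"""Hierarchical clustering and SVD-with-imputation PCA of candidate expression.

The selected transcripts' expression across the eight egg samples is
summarised two ways: an agglomerative dendrogram on Euclidean distances
(average linkage by default) and principal components computed as a singular
value decomposition, with missing entries — if any — filled in by iterative
low-rank reconstruction.  Transcript rows are unit-variance scaled by
default before either analysis so that high-abundance transcripts do not
dominate the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .errors import DataError, UsageError

__all__ = [
    "scale_rows",
    "hierarchical_cluster",
    "Dendrogram",
    "pca_svd_impute",
    "PcaResult",
    "analyze_structure",
    "StructureResult",
]

LINKAGES = ("average", "complete", "single")
SCALINGS = ("none", "center", "unit_variance")


def scale_rows(matrix: np.ndarray, mode: str = "unit_variance"
               ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise centering / unit-variance scaling.

    Returns ``(scaled, kept)`` where ``kept`` indexes the surviving rows:
    under ``unit_variance`` zero-variance rows are dropped with a warning,
    otherwise all rows are kept.
    """
    if mode not in SCALINGS:
        raise UsageError(f"mode must be one of {SCALINGS}")
    X = np.asarray(matrix, dtype=float)
    kept = np.arange(X.shape[0])
    if mode == "none":
        return X.copy(), kept
    centered = X - X.mean(axis=1, keepdims=True)
    if mode == "center":
        return centered, kept
    sd = X.std(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(X.shape[0])
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance rows before scaling")
    return centered[keep] / sd[keep, None], kept[keep]


@dataclass
class Dendrogram:
    """Agglomerative merge structure over n leaves.

    ``merges`` lists n-1 rows ``(node_a, node_b, height)``; leaves are
    numbered 0..n-1 and merge i creates node n+i.  ``leaf_order`` is the
    left-to-right leaf sequence of the standard dendrogram layout.
    """

    merges: np.ndarray
    leaf_order: list[int]
    labels: list[str]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaves_of(self, node: int) -> set[int]:
        """Leaf set under an internal (or leaf) node index."""
        n = self.n_leaves
        if node < n:
            return {node}
        a, b, _ = self.merges[node - n]
        return self.leaves_of(int(a)) | self.leaves_of(int(b))

    def to_newick(self) -> str:
        """Newick string; branch lengths are drops in merge height."""
        n = self.n_leaves
        a, b, h = self.merges[-1]
        parts = []
        for c in (int(a), int(b)):
            if c < n:
                parts.append(f"{self.labels[c]}:{h:.6g}")
            else:
                child_h = self.merges[c - n][2]
                parts.append(_subtree(self.merges, self.labels, n, c)
                             + f":{h - child_h:.6g}")
        return "(" + ",".join(parts) + ");"


def _subtree(merges: np.ndarray, labels: list[str], n: int, node: int) -> str:
    if node < n:
        return labels[node]
    a, b, h = merges[node - n]
    parts = []
    for c in (int(a), int(b)):
        if c < n:
            parts.append(f"{labels[c]}:{h:.6g}")
        else:
            ch = merges[c - n][2]
            parts.append(_subtree(merges, labels, n, c) + f":{h - ch:.6g}")
    return "(" + ",".join(parts) + ")"


def hierarchical_cluster(matrix: np.ndarray, linkage: str = "average",
                         labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative clustering of matrix rows under Euclidean distance."""
    if linkage not in LINKAGES:
        raise UsageError(f"linkage must be one of {LINKAGES}")
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise UsageError("clustering needs at least 2 items")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    dist = scipy.spatial.distance.pdist(X, metric="euclidean")
    Z = scipy.cluster.hierarchy.linkage(dist, method=linkage)
    merges = Z[:, :3].copy()
    leaf_order = [int(i) for i in scipy.cluster.hierarchy.leaves_list(Z)]
    return Dendrogram(merges=merges, leaf_order=leaf_order,
                      labels=list(labels), linkage=linkage)


@dataclass
class PcaResult:
    """PCA by singular value decomposition of the column-centered matrix.

    ``scores`` are item coordinates (items x components), ``loadings`` the
    feature weights (features x components); ``explained`` is the percent of
    total variance per component over *all* components (sums to 100).
    Components are sign-fixed so the largest-magnitude loading is positive.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    n_components: int
    n_iter: int = 0
    converged: bool = True
    item_labels: list[str] = field(default_factory=list)
    feature_labels: list[str] = field(default_factory=list)

    def write(self, scores_path: str | Path, loadings_path: str | Path | None = None,
              variance_path: str | Path | None = None) -> None:
        comps = [f"PC{i + 1}" for i in range(self.n_components)]
        idx = self.item_labels or list(map(str, range(len(self.scores))))
        pd.DataFrame(self.scores, index=idx, columns=comps) \
            .rename_axis("item").to_csv(scores_path, sep="\t")
        if loadings_path is not None:
            fidx = self.feature_labels or list(map(str, range(len(self.loadings))))
            pd.DataFrame(self.loadings, index=fidx, columns=comps) \
                .rename_axis("feature").to_csv(loadings_path, sep="\t")
        if variance_path is not None:
            pd.Series(self.explained, name="explained_pct",
                      index=[f"PC{i + 1}" for i in range(len(self.explained))]) \
                .rename_axis("component").to_csv(variance_path, sep="\t")


def pca_svd_impute(matrix: np.ndarray, n_components: int = 2,
                   max_iter: int = 100, tol: float = 1e-6) -> PcaResult:
    """PCA of an items x features matrix, tolerating missing (NaN) entries.

    Missing values are initialized to feature (column) means, then refined
    by repeating: column-center, rank-``n_components`` SVD reconstruction,
    refill the missing cells; iteration stops when the largest absolute
    change of an imputed cell is below ``tol``.  With no missing entries
    this is a single plain SVD.
    """
    X = np.asarray(matrix, dtype=float).copy()
    if X.ndim != 2:
        raise UsageError("matrix must be 2-D")
    n, p = X.shape
    if not 1 <= n_components <= min(n, p):
        raise UsageError(f"n_components must be in [1, {min(n, p)}]")
    missing = np.isnan(X)
    if missing.all(axis=1).any() or missing.all(axis=0).any():
        raise DataError("a row or column is entirely missing")

    col_means = np.nanmean(X, axis=0)
    X[missing] = np.take(col_means, np.nonzero(missing)[1])
    n_iter = 0
    converged = True
    if missing.any():
        converged = False
        for n_iter in range(1, max_iter + 1):
            mu = X.mean(axis=0)
            C = X - mu
            U, s, Vt = np.linalg.svd(C, full_matrices=False)
            recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + mu
            delta = np.abs(recon[missing] - X[missing]).max()
            X[missing] = recon[missing]
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"SVD imputation did not converge in {max_iter} iterations")

    mu = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mu, full_matrices=False)
    # sign convention: largest-|loading| coordinate positive per component
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s ** 2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaResult(
        scores=U[:, :n_components] * s[:n_components],
        loadings=Vt[:n_components].T,
        explained=explained,
        n_components=n_components,
        n_iter=n_iter,
        converged=converged,
    )


@dataclass
class StructureResult:
    """Joint clustering/PCA view of a transcripts x samples expression block."""

    sample_dendrogram: Dendrogram
    transcript_dendrogram: Dendrogram | None
    pca: PcaResult
    scaling: str
    linkage: str
    sample_ids: list[str]
    transcript_ids: list[str]

    def metadata(self) -> dict:
        return {
            "scaling": self.scaling,
            "linkage": self.linkage,
            "n_transcripts": len(self.transcript_ids),
            "n_samples": len(self.sample_ids),
            "pca_explained_pct": [round(float(v), 4) for v in self.pca.explained],
        }

    def plot(self, path: str | Path) -> None:
        """PCA score scatter (PC1 vs PC2) saved as an image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        xs, ys = self.pca.scores[:, 0], self.pca.scores[:, 1] \
            if self.pca.scores.shape[1] > 1 else np.zeros(len(self.pca.scores))
        ax.scatter(xs, ys)
        for sid, x, y in zip(self.sample_ids, xs, np.atleast_1d(ys)):
            ax.annotate(sid, (x, y), fontsize=8)
        ax.set_xlabel(f"PC1 ({self.pca.explained[0]:.1f}%)")
        if len(self.pca.explained) > 1:
            ax.set_ylabel(f"PC2 ({self.pca.explained[1]:.1f}%)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def analyze_structure(values: np.ndarray, transcript_ids: list[str],
                      sample_ids: list[str], scaling: str = "unit_variance",
                      linkage: str = "average", n_components: int = 2
                      ) -> StructureResult:
    """Cluster samples and transcripts and compute sample-space PCA.

    ``values`` is transcripts x samples; rows are scaled per ``scaling``
    first, then samples are clustered / projected in the scaled transcript
    feature space.
    """
    scaled, kept = scale_rows(values, mode=scaling)
    kept_ids = [transcript_ids[i] for i in kept]
    if scaled.shape[0] < 1:
        raise DataError("no transcripts left after scaling")
    samples_x_feats = scaled.T
    sample_dend = hierarchical_cluster(samples_x_feats, linkage=linkage, labels=sample_ids)
    transcript_dend = None
    if scaled.shape[0] >= 2:
        transcript_dend = hierarchical_cluster(scaled, linkage=linkage, labels=kept_ids)
    n_comp = min(n_components, min(samples_x_feats.shape))
    pca = pca_svd_impute(samples_x_feats, n_components=n_comp)
    pca.item_labels = list(sample_ids)
    pca.feature_labels = kept_ids
    return StructureResult(
        sample_dendrogram=sample_dend,
        transcript_dendrogram=transcript_dend,
        pca=pca,
        scaling=scaling,
        linkage=linkage,
        sample_ids=list(sample_ids),
        transcript_ids=kept_ids,
    )
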