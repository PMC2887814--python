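"""Stage 3 — expression-pattern classification and sample-level QC.

* :func:`kmeans_patterns` splits the restricted genes into k expression
  patterns (default k = 4) over z-scored per-cell-type mean profiles,
  then labels each cluster ``pan`` (centroid above the per-gene mean in
  every target cell type), ``subgroup_only:<label>`` (high in exactly
  one target subgroup) or ``other``. Downstream promoter analysis
  consumes only the pan vs subgroup split.
* :func:`correlation_cluster` builds the classic unsupervised sample
  tree: distance = 1 - Pearson correlation between sample columns,
  average linkage, exported as Newick.
* :func:`tissue_percentages` converts a genes x tissues expression
  table into the relative-percentage form used for tissue-distribution
  reports (rows sum to 100%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .data_model import ExpressionMatrix, SampleSheet
from .errors import UsageError

PATTERN_PAN = "pan"
PATTERN_OTHER = "other"


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++ initialization."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:  # all points coincide with chosen centers
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def lloyd_kmeans(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 100,
                 tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Plain Lloyd k-means with k-means++ seeding.

    Empty clusters are repaired by re-seeding the centroid at the point
    farthest from its assigned centroid. Returns (labels, centers,
    inertia history); the within-cluster sum of squares is
    non-increasing over iterations.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise UsageError(f"k={k} exceeds the number of points {X.shape[0]}")
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(X, k, rng)
    history: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        point_d2 = d2[np.arange(X.shape[0]), labels]
        for j in range(k):  # empty-cluster repair: farthest point
            if not np.any(labels == j):
                far = int(point_d2.argmax())
                labels[far] = j
                point_d2[far] = 0.0
        inertia = float(((X - centers[labels]) ** 2).sum())
        history.append(inertia)
        new_centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        if np.allclose(new_centers, centers, atol=tol, rtol=0.0):
            centers = new_centers
            break
        centers = new_centers
    final = float(((X - centers[labels]) ** 2).sum())
    if not history or final < history[-1] - 1e-12:
        history.append(final)
    return labels, centers, history


def _celltype_profiles(matrix: ExpressionMatrix,
                       sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene z-scored vector of per-cell-type mean expression."""
    sheet.check_matches(matrix)
    frame = matrix.to_frame()
    cell_types = sheet.frame.groupby("cell_type", sort=True)["sample_id"].apply(list)
    prof = pd.DataFrame({ct: frame[ids].mean(axis=1)
                         for ct, ids in cell_types.items()})
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant rows -> all-zero profile
    return prof.sub(mu, axis=0).div(sd, axis=0)


def _label_centroid(centroid: pd.Series, sheet: SampleSheet) -> str:
    """pan / subgroup_only:<label> / other from which cell types sit high."""
    target_types = sheet.target_cell_types
    high = {ct for ct in target_types if centroid[ct] > 0}
    if high == set(target_types):
        return PATTERN_PAN
    by_subgroup: dict[str, set[str]] = {}
    for ct in target_types:
        by_subgroup.setdefault(sheet.subgroup_of_cell_type(ct), set()).add(ct)
    for sub, types in by_subgroup.items():
        if high == types:
            return f"subgroup_only:{sub}"
    return PATTERN_OTHER


def kmeans_patterns(matrix: ExpressionMatrix, sheet: SampleSheet, k: int = 4,
                    seed: int = 0, max_iter: int = 100) -> pd.DataFrame:
    """Cluster gene expression patterns; returns gene_id, cluster_id,
    pattern_label."""
    profiles = _celltype_profiles(matrix, sheet)
    if k > len(profiles):
        raise UsageError(f"k={k} exceeds the number of genes {len(profiles)}")
    labels, centers, _ = lloyd_kmeans(profiles.to_numpy(), k, seed, max_iter)
    center_frames = pd.DataFrame(centers, columns=profiles.columns)
    cluster_labels = {j: _label_centroid(center_frames.iloc[j], sheet)
                      for j in range(k)}
    return pd.DataFrame({
        "gene_id": list(profiles.index),
        "cluster_id": labels,
        "pattern_label": [cluster_labels[j] for j in labels],
    })


@dataclass(frozen=True)
class CorrelationTree:
    """Average-linkage tree over samples at 1 - Pearson distance."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    distance: pd.DataFrame

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        return str(tree).strip()


def correlation_cluster(matrix: ExpressionMatrix) -> CorrelationTree:
    """Hierarchical clustering of samples by 1 - Pearson correlation."""
    if matrix.n_samples < 2:
        raise UsageError("correlation clustering needs >= 2 samples")
    frame = matrix.to_frame()
    sds = frame.std(ddof=0)
    flat = list(sds.index[sds == 0])
    corr = frame.corr(method="pearson")
    if flat:
        warnings.warn(f"zero-variance sample columns {flat}: correlation "
                      "undefined, treated as distance 1 to all")
        corr.loc[flat, :] = 0.0
        corr.loc[:, flat] = 0.0
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    linkage = hierarchy.linkage(squareform(dist.to_numpy(), checks=False),
                                method="average")
    return CorrelationTree(tuple(frame.columns), linkage, dist)


@dataclass(frozen=True)
class TissuePercentTable:
    """Per-gene relative percentage of expression across tissues."""

    percent: pd.DataFrame        # genes x tissues, rows sum to 100
    all_zero_genes: tuple[str, ...]


def tissue_percentages(tissue_frame: pd.DataFrame) -> TissuePercentTable:
    """Convert a genes x tissues table to row-wise percentages.

    All-zero rows stay all-zero and are flagged rather than divided.
    """
    values = tissue_frame.to_numpy(dtype=float)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise UsageError("tissue expression values must be finite and >= 0")
    totals = values.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    percent = 100.0 * values / safe[:, None]
    percent[zero, :] = 0.0
    return TissuePercentTable(
        pd.DataFrame(percent, index=tissue_frame.index,
                     columns=tissue_frame.columns),
        tuple(tissue_frame.index[zero]),
    )
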