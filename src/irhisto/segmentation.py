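"""Common k-means spectral histology over one or more images.

Pixels of all images are pooled into one matrix and clustered jointly
(k-means, Euclidean distance, k-means++ initialization with restarts), so
that cluster identities are shared across images and false-color maps are
mutually comparable.  Cluster colors follow a fixed categorical palette
applied in centroid-brightness order.  Centroid spectra are summarized by a
hierarchical dendrogram exported as Newick.

The conventional clustering range quoted for follicle sections,
1800-800 cm^-1, extends below the acquired axis (which stops at 900 cm^-1);
windows are therefore clamped to the axis intersection with a logged
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .spectral_data import (
    STRUCTURES,
    LabelMap,
    SpectralImage,
    SpectralWindow,
    ValidationError,
    crop_to_window,
)

__all__ = [
    "ClusterModel",
    "ClusterMaps",
    "CentroidDendrogram",
    "CommonKMeans",
    "common_kmeans",
    "centroid_dendrogram",
    "annotate_clusters",
    "mapped_structure_ari",
]

logger = logging.getLogger(__name__)

# Fixed 10-entry categorical palette (RGB 0-255), assigned in
# centroid-brightness order so re-runs are visually comparable.
PALETTE = (
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207),
)


@dataclass
class ClusterModel:
    """Fitted common k-means model."""

    k: int
    centroids: np.ndarray               # (k, n_bands)
    window: SpectralWindow | None
    color_table: dict[int, tuple[int, int, int]]
    seed: int
    inertia: float
    axis: object | None = None


@dataclass
class ClusterMaps:
    """Per-image cluster label maps (1..k; 0 = masked out) and renderings."""

    labels: list[np.ndarray]
    false_color: list[np.ndarray]       # (rows, cols, 3) uint8


@dataclass
class CentroidDendrogram:
    """Ward/average/complete linkage tree over centroid spectra."""

    linkage_matrix: np.ndarray
    newick: str
    leaf_names: list[str]


class CommonKMeans(ClusterMixin, BaseEstimator):
    """K-means on pooled pixel spectra, scikit-learn style.

    Thin wrapper over :class:`sklearn.cluster.KMeans` (Euclidean distance,
    k-means++ with ``n_init`` restarts, best inertia kept); exists so the
    spectral-histology stage composes with sklearn model selection.
    """

    def __init__(self, k: int = 10, n_init: int = 10, seed: int = 0):
        self.k = k
        self.n_init = n_init
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")
        if X.shape[0] < self.k:
            raise ValidationError(f"{X.shape[0]} samples < k = {self.k}")
        km = KMeans(n_clusters=self.k, n_init=self.n_init, init="k-means++",
                    random_state=self.seed)
        km.fit(X)
        # On tiny problems the greedy k-means++ seeding is nearly
        # deterministic, so its restarts are redundant; add random-init
        # restarts there to keep the restart ensemble diverse.
        if X.shape[0] < 50 * self.k:
            km_r = KMeans(n_clusters=self.k, n_init=4 * self.n_init,
                          init="random", random_state=self.seed)
            km_r.fit(X)
            if km_r.inertia_ < km.inertia_:
                km = km_r
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1)
        return np.argmin(d, axis=1)


def common_kmeans(images: list[SpectralImage], k: int = 10,
                  window: SpectralWindow | None = None, seed: int = 0,
                  n_init: int = 10) -> tuple[ClusterModel, ClusterMaps]:
    """Joint k-means over the masked-in pixels of all images.

    Returns the fitted model (centroids in brightness-ordered color table)
    and per-image label maps with labels 1..k (0 = masked out).
    """
    if not images:
        raise ValidationError("need at least one image")
    if window is not None:
        clamped = window.clamp_to(images[0].axis)
        if (clamped.lo, clamped.hi) != (window.lo, window.hi):
            logger.warning(
                "window [%g, %g] clamped to axis intersection [%g, %g]",
                window.lo, window.hi, clamped.lo, clamped.hi,
            )
        window = clamped
        images = [crop_to_window(img, window) for img in images]
    mats, indices = [], []
    for img in images:
        X, idx = img.as_matrix()
        mats.append(X)
        indices.append(idx)
    pooled = np.concatenate(mats, axis=0)
    if pooled.shape[0] < 10 * k:
        raise ValidationError(
            f"{pooled.shape[0]} pooled masked-in pixels < 10 * k = {10 * k}"
        )
    est = CommonKMeans(k=k, n_init=n_init, seed=seed).fit(pooled)

    # Relabel clusters by centroid brightness (mean absorbance) so that the
    # label <-> color assignment is reproducible across runs.
    brightness = est.cluster_centers_.mean(axis=1)
    order = np.argsort(brightness)[::-1]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    centroids = est.cluster_centers_[order]
    labels_pooled = remap[est.labels_] + 1  # 1-based

    color_table = {i + 1: PALETTE[i % len(PALETTE)] for i in range(k)}
    label_maps, renders = [], []
    start = 0
    for img, idx in zip(images, indices):
        n = idx.shape[0]
        lab = np.zeros(img.shape, dtype=int)
        lab[idx[:, 0], idx[:, 1]] = labels_pooled[start:start + n]
        start += n
        rgb = np.zeros(img.shape + (3,), dtype=np.uint8)
        for cid, color in color_table.items():
            rgb[lab == cid] = color
        label_maps.append(lab)
        renders.append(rgb)
    model = ClusterModel(k=k, centroids=centroids, window=window,
                         color_table=color_table, seed=seed,
                         inertia=est.inertia_, axis=images[0].axis)
    return model, ClusterMaps(labels=label_maps, false_color=renders)


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage tree to Newick with merge-height branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def centroid_dendrogram(model: ClusterModel,
                        linkage: str = "ward") -> CentroidDendrogram:
    """Hierarchical clustering of centroid spectra (Euclidean distance)."""
    if linkage not in ("ward", "average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if model.k < 2:
        raise ValidationError("dendrogram needs k >= 2")
    Z = hierarchy.linkage(model.centroids, method=linkage, metric="euclidean")
    names = [f"c{i + 1}" for i in range(model.k)]
    return CentroidDendrogram(linkage_matrix=Z,
                              newick=_linkage_to_newick(Z, names),
                              leaf_names=names)


def annotate_clusters(maps: ClusterMaps, truth: list[LabelMap]
                      ) -> dict[int, tuple[str, float]]:
    """Assign each cluster its plurality ground-truth structure and purity.

    OCT is one structure.  Ties break deterministically toward the structure
    with the lower id in the closed vocabulary order.
    """
    if len(maps.labels) != len(truth):
        raise ValidationError("cluster maps and truth label maps differ in count")
    counts: dict[int, np.ndarray] = {}
    n_struct = len(STRUCTURES)
    for lab, lm in zip(maps.labels, truth):
        if lab.shape != lm.shape:
            raise ValidationError(
                f"cluster map shape {lab.shape} != truth shape {lm.shape}"
            )
        names = lm.structure_names()
        for cid in np.unique(lab):
            if cid == 0:
                continue
            vec = counts.setdefault(int(cid), np.zeros(n_struct, dtype=int))
            sel = lab == cid
            for s_idx, s_name in enumerate(STRUCTURES):
                vec[s_idx] += int(np.count_nonzero(sel & (names == s_name)))
    out = {}
    for cid, vec in sorted(counts.items()):
        total = vec.sum()
        best = int(np.argmax(vec))  # argmax takes the lowest index on ties
        out[cid] = (STRUCTURES[best], float(vec[best] / total) if total else 0.0)
    return out


def mapped_structure_ari(maps: ClusterMaps, truth: list[LabelMap]) -> float:
    """Adjusted Rand index between truth structures and annotated clusters.

    Cluster labels are first mapped to their plurality structure, so the
    statistic measures annotation-level agreement rather than penalizing the
    deliberate multi-cluster split of the OCT background.
    """
    annotation = annotate_clusters(maps, truth)
    y_true, y_pred = [], []
    for lab, lm in zip(maps.labels, truth):
        names = lm.structure_names()
        sel = lab > 0
        y_true.extend(names[sel].tolist())
        y_pred.extend(annotation[int(c)][0] for c in lab[sel])
    return float(adjusted_rand_score(y_true, y_pred))
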