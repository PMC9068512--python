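"""Conformational-cluster identification for gate trajectories.

The pipeline mirrors the trajectory-analysis recipe this package implements:
a coarse k-means pass over gate backbone geometry (k = 10 by default), a
nonlinear neighbour embedding (t-SNE) of the mixed angle/distance feature
vectors, flat-kernel mean-shift seeding with a deliberately small bandwidth,
and a two-cutoff hierarchical merge: two seed clusters fuse when their
centroids are within one cutoff AND any cross-pair of their points is within
a second, tighter cutoff.  Merging is transitive (union-find).  Final
clusters are labelled alphabetically by descending size; cluster statistics
use circular means and circular standard deviations for angles; each
cluster's representative frame minimises the periodicity-aware distance to
the cluster mean.
"""
from __future__ import annotations

import itertools
import logging
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from ._geom import circ_mean_deg, circ_sd_deg, wrap_deg

log = logging.getLogger(__name__)

__all__ = [
    "ClusterSet", "kmeans_gate", "embed", "mean_shift_seed",
    "hierarchical_merge", "cluster_stats", "representative_frame",
    "cluster_conformations", "default_bandwidth",
]


def _alpha_labels(n):
    """a, b, ..., z, aa, ab, ... — alphabetic labels."""
    letters = string.ascii_lowercase
    out, size = [], 1
    while len(out) < n:
        for combo in itertools.product(letters, repeat=size):
            out.append("".join(combo))
            if len(out) == n:
                break
        size += 1
    return out


@dataclass
class ClusterSet:
    """Frame labels plus per-cluster summary.

    ``labels`` holds one alphabetic cluster id per frame (assigned by
    descending cluster size).  ``summary`` has one row per cluster (label,
    size, representative_frame); ``stats`` holds per-feature means and SDs,
    circular for angles.
    """
    labels: np.ndarray
    summary: pd.DataFrame
    stats: pd.DataFrame | None = None
    centroids: dict = field(default_factory=dict)

    @property
    def cluster_ids(self):
        return list(self.summary["label"])

    def members(self, label) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def _relabel_by_size(raw_labels: np.ndarray):
    """Map arbitrary integer labels to alphabetic ids by descending size.

    Ties break deterministically by first frame of appearance."""
    ids, counts = np.unique(raw_labels, return_counts=True)
    first_seen = {i: int(np.argmax(raw_labels == i)) for i in ids}
    order = sorted(ids, key=lambda i: (-counts[list(ids).index(i)], first_seen[i]))
    names = _alpha_labels(len(order))
    mapping = {old: new for old, new in zip(order, names)}
    return np.array([mapping[i] for i in raw_labels]), mapping


def kmeans_gate(features=None, coords=None, k: int = 10, seed: int = 0,
                max_iter: int = 300) -> ClusterSet:
    """Coarse k-means pass over gate geometry.

    Operates either on a feature matrix (Euclidean metric) or on gate
    coordinates (n_frames, n_atoms, 3), where frames are iteratively
    superposed onto the evolving mean structure so that the Euclidean metric
    approximates pairwise-superposed backbone RMSD.  k-means++ seeding under
    the given seed; deterministic.
    """
    if (features is None) == (coords is None):
        raise ValueError("provide exactly one of features or coords")
    if coords is not None:
        from ._geom import kabsch_rotation
        X3 = np.asarray(coords, dtype=float)
        n, m, _ = X3.shape
        aligned = X3 - X3.mean(axis=1, keepdims=True)
        ref = aligned[0]
        for _ in range(5):
            for i in range(n):
                R = kabsch_rotation(aligned[i], ref)
                aligned[i] = aligned[i] @ R.T
            ref = aligned.mean(axis=0)
        X = aligned.reshape(n, -1) / np.sqrt(m)   # Euclidean == RMSD scale
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if k > len(X):
        raise ValueError(f"k = {k} exceeds the number of frames ({len(X)})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=max_iter)
    raw = km.fit_predict(X)
    labels, mapping = _relabel_by_size(raw)
    rows = []
    for old, name in mapping.items():
        members = np.nonzero(raw == old)[0]
        centroid = km.cluster_centers_[old]
        rep = members[int(np.argmin(np.linalg.norm(X[members] - centroid, axis=1)))]
        rows.append({"label": name, "size": len(members),
                     "representative_frame": int(rep)})
    summary = pd.DataFrame(rows).sort_values("label", key=lambda s: s.map(
        {l: i for i, l in enumerate(_alpha_labels(len(rows)))})).reset_index(drop=True)
    centroids = {mapping[old]: km.cluster_centers_[old] for old in mapping}
    return ClusterSet(labels=labels, summary=summary, centroids=centroids)


def embed(X: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of encoded feature vectors.

    Deterministic under a fixed seed (PCA initialisation).  The layout
    itself is not meaningful; the contract is neighbourhood preservation:
    well-separated clusters in feature space stay separated in the plane.
    Degenerate all-identical input returns a single point with a warning.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 2 or np.allclose(X, X[0]):
        warnings.warn("degenerate embedding input: all points identical",
                      stacklevel=2)
        return np.zeros((len(X), 2))
    if len(X) < 3 * perplexity:
        raise ValueError(
            f"need at least 3 x perplexity = {3 * perplexity:.0f} points, got {len(X)}")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
              init="pca")
    return ts.fit_transform(X)


def default_bandwidth(points: np.ndarray, fraction: float = 0.02) -> float:
    """Deliberately small bandwidth: a fraction of the bounding-box diagonal."""
    span = points.max(axis=0) - points.min(axis=0)
    return float(fraction * np.linalg.norm(span))


def mean_shift_seed(points: np.ndarray, bandwidth: float,
                    max_iter: int = 300, tol_factor: float = 1e-4):
    """Flat-kernel mean-shift seeding.

    Every point ascends to the mean of its bandwidth-neighbourhood until
    convergence; converged modes closer than bandwidth/2 are deduplicated
    (scan in point order, deterministic).  Returns (centroids, labels).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    P = np.asarray(points, dtype=float)
    tree = cKDTree(P)
    modes = P.copy()
    tol = tol_factor * bandwidth
    active = np.ones(len(P), dtype=bool)
    for _ in range(max_iter):
        if not np.any(active):
            break
        idx_lists = tree.query_ball_point(modes[active], r=bandwidth)
        new = np.array([P[ix].mean(axis=0) for ix in idx_lists])
        moved = np.linalg.norm(new - modes[active], axis=1) > tol
        modes[active] = new
        act = np.nonzero(active)[0]
        active[act[~moved]] = False

    centroids = []
    labels = np.empty(len(P), dtype=int)
    for i, m in enumerate(modes):
        for j, c in enumerate(centroids):
            if np.linalg.norm(m - c) < bandwidth / 2.0:
                labels[i] = j
                break
        else:
            centroids.append(m.copy())
            labels[i] = len(centroids) - 1
    return np.array(centroids), labels


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def hierarchical_merge(points: np.ndarray, seed_labels: np.ndarray,
                       centroids: np.ndarray, centroid_cutoff: float,
                       point_cutoff: float) -> np.ndarray:
    """Two-cutoff transitive merge of mean-shift seed clusters.

    A pair of seed clusters merges when their centroids are within
    ``centroid_cutoff`` and the closest cross-pair of member points is within
    ``point_cutoff``; merges propagate transitively via union-find.  Returns
    alphabetic labels ordered by descending merged-cluster size.  The
    operation never increases the cluster count and is idempotent once no
    pair qualifies.
    """
    if centroid_cutoff <= 0 or point_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    P = np.asarray(points, dtype=float)
    n_seed = len(centroids)
    members = [np.nonzero(seed_labels == i)[0] for i in range(n_seed)]
    trees = [cKDTree(P[m]) for m in members]
    uf = _UnionFind(n_seed)
    for i in range(n_seed):
        for j in range(i + 1, n_seed):
            if np.linalg.norm(centroids[i] - centroids[j]) > centroid_cutoff:
                continue
            d, _ = trees[j].query(P[members[i]], k=1)
            if np.min(d) <= point_cutoff:
                uf.union(i, j)
    merged = np.array([uf.find(seed_labels[k]) for k in range(len(P))])
    labels, _ = _relabel_by_size(merged)
    return labels


def cluster_stats(features: pd.DataFrame, labels: np.ndarray,
                  angle_cols=()) -> pd.DataFrame:
    """Per-cluster feature summaries: circular mean/SD (degrees) for angle
    columns, ordinary mean/SD otherwise.  Statistics are computed only from
    each cluster's own member rows."""
    rows = []
    for lab in sorted(np.unique(labels), key=lambda s: (len(s), s)):
        m = labels == lab
        if not np.any(m):
            raise ValueError(f"cluster {lab!r} is empty")
        row = {"label": lab, "size": int(m.sum())}
        for col in features.columns:
            x = features.loc[m, col].to_numpy(dtype=float)
            if col in angle_cols:
                row[f"{col}_mean"] = circ_mean_deg(x)
                row[f"{col}_sd"] = circ_sd_deg(x)
            else:
                row[f"{col}_mean"] = float(np.mean(x))
                row[f"{col}_sd"] = float(np.std(x))
        rows.append(row)
    return pd.DataFrame(rows)


def _periodic_distance(features: np.ndarray, mean: np.ndarray,
                       angle_mask: np.ndarray) -> np.ndarray:
    """Euclidean distance with angle coordinates compared on the circle."""
    d = features - mean
    d[:, angle_mask] = wrap_deg(d[:, angle_mask])
    return np.linalg.norm(d, axis=1)


def representative_frame(features: pd.DataFrame, labels: np.ndarray,
                         label, angle_cols=()) -> int:
    """Member frame closest (periodicity-aware) to the cluster mean.

    Angle columns are compared on the circle; ties resolve to the earliest
    frame index.
    """
    members = np.nonzero(labels == label)[0]
    if len(members) == 0:
        raise ValueError(f"cluster {label!r} is empty")
    X = features.iloc[members].to_numpy(dtype=float)
    angle_mask = np.array([c in angle_cols for c in features.columns])
    mean = np.empty(X.shape[1])
    for j, col in enumerate(features.columns):
        mean[j] = (circ_mean_deg(X[:, j]) if angle_mask[j]
                   else float(np.mean(X[:, j])))
    d = _periodic_distance(X, mean, angle_mask)
    return int(members[int(np.argmin(d))])   # argmin takes the earliest tie


def cluster_conformations(features: pd.DataFrame, angle_cols=(),
                          perplexity: float = 30.0, seed: int = 0,
                          bandwidth: float | None = None,
                          bandwidth_fraction: float = 0.02,
                          centroid_factor: float = 12.0,
                          point_factor: float = 2.0):
    """Full unsupervised pipeline: encode, embed, seed, merge, summarise.

    Returns (ClusterSet, embedding).  Cutoffs default to multiples of the
    bandwidth, which itself defaults to 2% of the embedding bounding-box
    diagonal.  The point-pair cutoff (2x bandwidth) is the discriminating
    barrier: embeddings often shed small same-conformation islets about one
    bandwidth away from their parent cluster, while genuinely distinct
    conformations stay several bandwidths apart, so the centroid cutoff is a
    generous pre-filter and the closest-cross-pair test decides the merge.
    """
    from .features import FeatureScaler
    scaler = FeatureScaler(angle_cols=angle_cols)
    X, _ = scaler.fit_transform(features)
    emb = embed(X, perplexity=perplexity, seed=seed)
    bw = bandwidth if bandwidth is not None else default_bandwidth(
        emb, bandwidth_fraction)
    centroids, seed_labels = mean_shift_seed(emb, bw)
    labels = hierarchical_merge(emb, seed_labels, centroids,
                                centroid_cutoff=centroid_factor * bw,
                                point_cutoff=point_factor * bw)
    stats = cluster_stats(features, labels, angle_cols=angle_cols)
    rows = []
    for lab in stats["label"]:
        rep = representative_frame(features, labels, lab, angle_cols=angle_cols)
        rows.append({"label": lab, "size": int(np.sum(labels == lab)),
                     "representative_frame": rep})
    cs = ClusterSet(labels=labels, summary=pd.DataFrame(rows), stats=stats)
    return cs, emb
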