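"""Low-dimensional embedding of seasonal harmonic shapes.

Each condition is represented by its pooled first-N harmonic bases
(p_1..p_N, q_1..q_N, a 10-vector at the default N=5) and embedded in 2-D
with Isomap (k-NN geodesics followed by classical MDS).  Group compactness
in the embedding quantifies how homogeneous the seasonal shapes of a
disease family are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph


@dataclass
class EmbeddingResult:
    """2-D Isomap coordinates and per-group dispersion."""

    coords: np.ndarray                  # (n_points, 2)
    labels: list[str]
    groups: list[str] | None = None
    n_neighbors: int = 5
    dispersion: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"condition": self.labels,
                            "dim1": self.coords[:, 0],
                            "dim2": self.coords[:, 1]})
        if self.groups is not None:
            out["group"] = self.groups
        return out


def _connected_k(X: np.ndarray, k: int) -> int:
    """Smallest neighbourhood size >= k whose k-NN graph is connected."""
    n = X.shape[0]
    for kk in range(k, n):
        graph = kneighbors_graph(X, kk, mode="connectivity")
        ncomp, _ = connected_components(graph, directed=False)
        if ncomp == 1:
            if kk > k:
                warnings.warn(f"k-NN graph disconnected at k={k}; using k={kk}")
            return kk
    raise ValueError("k-NN graph is disconnected even at maximal k")


def isomap_embed(features: np.ndarray, n_neighbors: int = 5,
                 n_components: int = 2, labels=None,
                 groups=None) -> EmbeddingResult:
    """Isomap embedding of harmonic feature vectors.

    A k-nearest-neighbour graph on Euclidean distances defines geodesic
    (shortest-path) distances, which classical MDS maps to
    ``n_components`` dimensions.  Axes follow a deterministic sign
    convention (the coordinate of largest magnitude on each axis is
    positive), so results are reproducible up to rotation inherent to MDS.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if X.shape[0] < n_neighbors + 2:
        raise ValueError("need at least n_neighbors + 2 points")
    k = _connected_k(X, n_neighbors)
    iso = Isomap(n_neighbors=k, n_components=n_components)
    coords = iso.fit_transform(X)
    for c in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, c])))
        if coords[j, c] < 0:
            coords[:, c] = -coords[:, c]
    labels = list(labels) if labels is not None else [str(i) for i in range(len(X))]
    res = EmbeddingResult(coords=coords, labels=labels,
                          groups=list(groups) if groups is not None else None,
                          n_neighbors=k)
    if groups is not None:
        res.dispersion = group_dispersion(coords, groups)
    return res


def group_dispersion(coords: np.ndarray, labels) -> dict[str, float]:
    """Mean Euclidean pairwise distance within each labelled group.

    Singleton groups are undefined and reported as NaN with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(list(labels))
    out: dict[str, float] = {}
    for g in np.unique(labels):
        pts = coords[labels == g]
        if len(pts) < 2:
            warnings.warn(f"group {g!r} has a single point; dispersion undefined")
            out[str(g)] = float("nan")
            continue
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        iu = np.triu_indices(len(pts), 1)
        out[str(g)] = float(dist[iu].mean())
    return out
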