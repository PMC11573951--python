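"""Spatial graph of tissue patches.

Patches of each image become nodes; undirected edges connect spatially
adjacent patches (k-nearest-neighbour graph symmetrised by union, or a
fixed-radius graph).  Edges never cross images; each image contributes
one subgraph.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .pcl import PatchEmbeddingSet

__all__ = ["build_graph"]


def build_graph(
    embedding_set: PatchEmbeddingSet,
    knn: int | None = 8,
    radius: float | None = None,
) -> nx.Graph:
    """Build the patch adjacency graph from patch coordinates.

    Exactly one of ``knn`` / ``radius`` selects the rule.  Node keys are
    patch ids; nodes carry ``image_id``, ``x``, ``y`` and the embedding
    row index, edges carry the Euclidean ``distance``.
    """
    if (knn is None) == (radius is None):
        raise ValueError("specify exactly one of knn or radius")
    if knn is not None and knn < 1:
        raise ValueError("knn must be >= 1")
    if radius is not None and radius <= 0:
        raise ValueError("radius must be positive")

    coords = embedding_set.coords
    g = nx.Graph()
    for row in coords.itertuples():
        g.add_node(
            int(row.patch_id), image_id=row.image_id, x=float(row.x), y=float(row.y)
        )
    for image_id, sub in coords.groupby("image_id", sort=False):
        pts = sub[["x", "y"]].to_numpy(float)
        ids = sub["patch_id"].to_numpy(int)
        n = len(ids)
        if n == 1:
            continue
        if knn is not None:
            if knn >= n:
                raise ValueError(
                    f"image {image_id!r}: k={knn} must be below its {n} patches"
                )
            nn = NearestNeighbors(n_neighbors=knn + 1).fit(pts)
            dist, idx = nn.kneighbors(pts)
            for i in range(n):
                for d, j in zip(dist[i, 1:], idx[i, 1:]):
                    g.add_edge(int(ids[i]), int(ids[j]), distance=float(d))
        else:
            nn = NearestNeighbors(radius=radius).fit(pts)
            dist, idx = nn.radius_neighbors(pts)
            for i in range(n):
                for d, j in zip(dist[i], idx[i]):
                    if j != i:
                        g.add_edge(int(ids[i]), int(ids[j]), distance=float(d))
    return g
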