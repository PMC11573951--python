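"""Low-dimensional UMAP views of images and TME compositions.

Two feature tracks mirror how the study visualises its data: a
raw-image track (per-image downsampled intensity summaries) and an
abundance track (per-image TME composition vectors).  Both reduce to
2-D with UMAP, color-coded by grade or by TME element downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = ["umap_embed", "image_summary_features", "silhouette_by_label"]


def umap_embed(
    features: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding, deterministic given the seed.

    Requires at least 10 rows and more rows than ``n_neighbors``.
    """
    import umap  # deferred: heavy import

    X = np.asarray(features, float)
    if X.ndim != 2 or len(X) < 10:
        raise ValueError("need a 2-D feature matrix with at least 10 rows")
    if len(X) <= n_neighbors:
        raise ValueError("need more rows than n_neighbors")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X))


def image_summary_features(images: list[np.ndarray], grid: int = 8) -> np.ndarray:
    """Raw-image track: downsampled per-channel intensity summaries."""
    rows = []
    for img in images:
        arr = img.astype(np.float64)
        if arr.max() > 1.0:
            arr /= 255.0
        rows.append(resize(arr, (grid, grid, 3), anti_aliasing=True).ravel())
    return np.asarray(rows)


def silhouette_by_label(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of known labels in the 2-D embedding."""
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(coords, labels))
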