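"""Deterministic image preparation and dataset splitting.

The supervised track prepares TMA well views by center-cropping the wide
acquisition strip to a square field, optionally converting to HSV, and
augmenting the minority grades with lossless 90/180-degree rotations —
applied only to the training split so validation and test never contain
rotated copies of a training image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FoldSplit",
    "center_crop",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "augment_minority",
    "stratified_kfold",
    "fold_manifest",
]

#: grades augmented by default: all but the overrepresented grade 2
MINORITY_CLASSES = frozenset({0, 1, 3, 4})

#: lossless rotation angles applied to minority-class training images
AUGMENT_ANGLES = (90, 180)


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: disjoint train/val/test id lists."""

    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test lists must be disjoint")


def center_crop(image: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Extract the central ``target_h x target_w`` window, no resampling.

    The study's acquisition strips are 19,200 x 1200 px and are reduced to
    the central 1200 x 1200 field this way.
    """
    h, w = image.shape[:2]
    if target_h > h or target_w > w:
        raise ValueError(
            f"crop target ({target_h}, {target_w}) exceeds image ({h}, {w})"
        )
    y0 = (h - target_h) // 2
    x0 = (w - target_w) // 2
    return image[y0 : y0 + target_h, x0 : x0 + target_w]


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """RGB -> HSV with all channels in [0, 1].

    Accepts float images in [0, 1] or 8-bit images, which are scaled to
    [0, 1] first so the transform domain is well defined.
    """
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    img = image.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    return rgb2hsv(img)


def hsv_to_rgb(image: np.ndarray) -> np.ndarray:
    """Inverse transform, for round-trip checks and display."""
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    return hsv2rgb(image)


def _rotate(image: np.ndarray, angle: int) -> np.ndarray:
    if angle % 90 != 0:
        raise ValueError("only lossless 90-degree multiples are supported")
    return np.rot90(image, k=(angle // 90) % 4)


def augment_minority(
    images: list[np.ndarray],
    labels: list[int],
    image_ids: list[str],
    classes: frozenset[int] | set[int] = MINORITY_CLASSES,
    role: str = "train",
) -> tuple[list[np.ndarray], list[int], list[str]]:
    """Add 90/180-degree rotated copies of each minority-class image.

    Each image of a listed class contributes two extra samples; other
    classes pass through unchanged.  Augmented ids get ``#rot<angle>``
    suffixes so provenance stays traceable.  Only the training split may
    be augmented — rotated copies in validation or test would duplicate
    training content.
    """
    if role != "train":
        raise ValueError("augmentation is applied to the training split only")
    out_imgs = list(images)
    out_labels = list(labels)
    out_ids = list(image_ids)
    for img, lab, iid in zip(images, labels, image_ids):
        if lab in classes:
            for angle in AUGMENT_ANGLES:
                out_imgs.append(_rotate(img, angle))
                out_labels.append(lab)
                out_ids.append(f"{iid}#rot{angle}")
    return out_imgs, out_labels, out_ids


def stratified_kfold(
    labels: pd.Series | dict[str, int], k: int = 10, seed: int = 0
) -> list[FoldSplit]:
    """Stratified k-fold with nested roles: 1 fold test, 1 val, k-2 train.

    Fold ``i`` uses fold ``i`` as test and fold ``(i+1) mod k`` as
    validation, so each image appears in test exactly once across the k
    splits and per-grade proportions in each subset stay within one
    sample of the stratified ideal.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    series = pd.Series(labels)
    ids = np.asarray(series.index, dtype=object)
    y = series.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(ids), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(ids, y)):
        fold_of[test_idx] = f
    splits = []
    for f in range(k):
        test = ids[fold_of == f]
        val = ids[fold_of == (f + 1) % k]
        train = ids[(fold_of != f) & (fold_of != (f + 1) % k)]
        splits.append(
            FoldSplit(f, tuple(train), tuple(val), tuple(test), seed)
        )
    return splits


def fold_manifest(splits: list[FoldSplit]) -> pd.DataFrame:
    """Long-format manifest: image_id, fold, role."""
    rows = []
    for s in splits:
        for role, id_list in (
            ("train", s.train_ids),
            ("val", s.val_ids),
            ("test", s.test_ids),
        ):
            rows.extend(
                {"image_id": i, "fold": s.fold_index, "role": role} for i in id_list
            )
    return pd.DataFrame(rows)
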