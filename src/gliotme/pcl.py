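"""Patch contrastive learning (PCL).

Core images are tiled into small patches — the per-cell analysis unit —
and an encoder is trained without labels so that augmented views of the
same or nearby patches agree while distant patches disagree.  The
training objective is the normalised-temperature cross-entropy (NT-Xent)
over cosine similarities.  Output embeddings are 256-dimensional unit
vectors.

The encoder is a compact NumPy network: a fixed stain-aware featuriser
(optical-density statistics of the DAB-like and hematoxylin-like
channels, texture energy) followed by a trainable two-layer projection
onto the unit sphere, optimised with hand-derived NT-Xent gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "PatchEmbeddingSet",
    "PCLConfig",
    "PatchEncoder",
    "tile_image",
    "contrastive_loss",
    "train_encoder",
    "embed",
]

_ABS_DAB = np.array([0.27, 0.57, 0.78])
_ABS_HEM = np.array([0.65, 0.70, 0.29])
_ABS_DAB = _ABS_DAB / np.linalg.norm(_ABS_DAB)
_ABS_HEM = _ABS_HEM / np.linalg.norm(_ABS_HEM)


@dataclass
class Patch:
    """One square tile of a core image, addressed by its center pixel."""

    image_id: str
    center: tuple[int, int]  # (x, y), origin top-left, 0-based
    size: int
    pixels: np.ndarray  # size x size x 3


@dataclass
class PatchEmbeddingSet:
    """Unit-norm patch embeddings with their spatial coordinates."""

    embeddings: np.ndarray  # n x dim, rows L2-normalized
    coords: pd.DataFrame  # patch_id, image_id, x, y
    encoder_tag: str = "untagged"

    def __post_init__(self) -> None:
        if len(self.embeddings) != len(self.coords):
            raise ValueError("one coordinate row per embedding required")

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]


def tile_image(
    image: np.ndarray,
    mask: np.ndarray | None,
    patch_size: int,
    stride: int | None = None,
    image_id: str = "img",
) -> list[Patch]:
    """Tile an image into a grid of patches with centers inside the mask.

    Patches start at the top-left corner and advance by ``stride``
    (default: non-overlapping).  A patch is kept when it lies fully
    inside the image and its center pixel is in the tissue mask.
    """
    h, w = image.shape[:2]
    if patch_size > h or patch_size > w:
        raise ValueError("patch_size exceeds image dimensions")
    stride = stride or patch_size
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    patches = []
    for y0 in range(0, h - patch_size + 1, stride):
        for x0 in range(0, w - patch_size + 1, stride):
            cy, cx = y0 + patch_size // 2, x0 + patch_size // 2
            if mask[cy, cx]:
                patches.append(
                    Patch(
                        image_id,
                        (cx, cy),
                        patch_size,
                        image[y0 : y0 + patch_size, x0 : x0 + patch_size],
                    )
                )
    return patches


def contrastive_loss(
    anchor_emb: np.ndarray,
    positive_emb: np.ndarray,
    negatives: np.ndarray,
    temperature: float = 0.5,
) -> float:
    """NT-Xent for one anchor.

    ``-log( exp(cos(a,p)/t) / sum_k exp(cos(a,k)/t) )`` where the sum
    runs over the positive and every negative.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    a = np.asarray(anchor_emb, float)
    p = np.asarray(positive_emb, float)
    negs = np.atleast_2d(np.asarray(negatives, float))
    a = a / np.linalg.norm(a)
    p = p / np.linalg.norm(p)
    negs = negs / np.linalg.norm(negs, axis=1, keepdims=True)
    logits = np.concatenate([[a @ p], negs @ a]) / temperature
    logits -= logits.max()
    return float(-logits[0] + np.log(np.exp(logits).sum()))


def patch_features(pixels: np.ndarray) -> np.ndarray:
    """Fixed stain-aware descriptor of one patch.

    Converts RGB to optical density, projects onto the DAB-like and
    hematoxylin-like absorbance directions, and summarises each stain
    channel (mean, s.d., max, stained fraction) together with overall
    intensity and gradient texture energy.
    """
    arr = pixels.astype(np.float64)
    if arr.max() > 1.0:
        arr /= 255.0
    od = -np.log(np.clip(arr, 1e-3, 1.0))
    brown = od @ _ABS_DAB
    blue = od @ _ABS_HEM
    gy, gx = np.gradient(arr.mean(axis=2))
    grad_energy = np.sqrt(gy**2 + gx**2)
    stained = brown > 0.2
    sf = float(stained.mean())
    feats = [brown.mean(), brown.std(), sf]
    if stained.any():
        bs = brown[stained]
        # per-stained-pixel intensity, robust to cell coverage
        feats += [
            float(np.median(bs)),
            float(np.percentile(bs, 75)),
            float(np.mean(brown > 0.7)) / max(sf, 1e-9),
        ]
    else:
        feats += [0.0, 0.0, 0.0]
    feats += [
        blue.mean(),
        float(np.mean(blue > 0.3)),
        grad_energy.mean(),
        grad_energy.std(),
    ]
    return np.asarray(feats)


@dataclass
class PCLConfig:
    patch_size: int = 16
    temperature: float = 0.5
    positive_radius: float | None = None  # default 1.5 x patch_size
    negative_min_distance: float | None = None  # default 8 x patch_size
    embedding_dim: int = 256
    hidden_dim: int = 64
    epochs: int = 5
    batch_negatives: int = 16
    max_anchors_per_epoch: int | None = None  # subsample anchors when set
    lr: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positive_radius is None:
            self.positive_radius = 1.5 * self.patch_size
        if self.negative_min_distance is None:
            self.negative_min_distance = 8.0 * self.patch_size
        if self.positive_radius >= self.negative_min_distance:
            raise ValueError(
                "positive_radius must be smaller than negative_min_distance"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


class PatchEncoder:
    """Two-layer projection of patch descriptors onto the unit sphere."""

    def __init__(self, config: PCLConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n_feat = patch_features(np.zeros((4, 4, 3))).size
        self.W1 = rng.normal(0, np.sqrt(2.0 / n_feat), (n_feat, config.hidden_dim))
        self.b1 = np.zeros(config.hidden_dim)
        self.W2 = rng.normal(
            0, np.sqrt(1.0 / config.hidden_dim), (config.hidden_dim, config.embedding_dim)
        )
        self.b2 = np.zeros(config.embedding_dim)
        self._mu = np.zeros(n_feat)
        self._sd = np.ones(n_feat)
        self.trained = False

    def fit_standardizer(self, F: np.ndarray) -> None:
        self._mu = F.mean(axis=0)
        self._sd = F.std(axis=0) + 1e-8

    # forward pass; returns intermediates for backprop
    def _forward(self, F: np.ndarray):
        Fs = (F - self._mu) / self._sd
        h_pre = Fs @ self.W1 + self.b1
        h = np.maximum(h_pre, 0.0)
        g = h @ self.W2 + self.b2
        norm = np.linalg.norm(g, axis=1, keepdims=True) + 1e-12
        z = g / norm
        return Fs, h_pre, h, g, norm, z

    def transform_features(self, F: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(F))[-1]

    def transform_pixels(self, blocks: list[np.ndarray]) -> np.ndarray:
        F = np.asarray([patch_features(b) for b in blocks])
        return self.transform_features(F)


def _augment(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-free, stain-plausible view: flip / rotate / brightness."""
    out = np.rot90(pixels, k=rng.integers(0, 4))
    if rng.random() < 0.5:
        out = out[:, ::-1]
    arr = out.astype(np.float64)
    if arr.max() > 1.0:
        arr /= 255.0
    arr = np.clip(arr * rng.uniform(0.9, 1.1), 0.0, 1.0)
    return arr


def train_encoder(patches: list[Patch], config: PCLConfig | None = None) -> PatchEncoder:
    """Train the patch encoder with NT-Xent over near/far patch pairs.

    Positives are augmented views of the anchor itself or of patches
    within ``positive_radius`` in the same image; negatives are sampled
    beyond ``negative_min_distance`` or from other images.
    """
    config = config or PCLConfig()
    per_image: dict[str, list[int]] = {}
    for i, p in enumerate(patches):
        per_image.setdefault(p.image_id, []).append(i)
    if any(len(v) < 2 for v in per_image.values()):
        raise ValueError("need at least 2 patches per image")

    rng = np.random.default_rng(config.seed)
    enc = PatchEncoder(config)
    F_clean = np.asarray([patch_features(p.pixels) for p in patches])
    enc.fit_standardizer(F_clean)
    coords = np.asarray([p.center for p in patches], dtype=float)
    img_ids = np.asarray([p.image_id for p in patches])

    tau = config.temperature
    adam_m = {k: np.zeros_like(v) for k, v in vars(enc).items() if k.startswith(("W", "b"))}
    adam_v = {k: np.zeros_like(v) for k, v in adam_m.items()}
    beta1, beta2, eps, t = 0.9, 0.999, 1e-8, 0
    n = len(patches)

    for _ in range(config.epochs):
        anchors = rng.permutation(n)
        if config.max_anchors_per_epoch is not None:
            anchors = anchors[: config.max_anchors_per_epoch]
        for anchor_idx in anchors:
            same = img_ids == img_ids[anchor_idx]
            dist = np.linalg.norm(coords - coords[anchor_idx], axis=1)
            near = np.flatnonzero(same & (dist <= config.positive_radius))
            pos_idx = int(rng.choice(near))
            far = np.flatnonzero(~same | (dist >= config.negative_min_distance))
            if far.size == 0:
                continue
            neg_idx = rng.choice(far, size=min(config.batch_negatives, far.size), replace=False)

            batch = [anchor_idx, pos_idx, *neg_idx.tolist()]
            F = np.asarray(
                [patch_features(_augment(patches[i].pixels, rng)) for i in batch]
            )
            Fs, h_pre, h, g, norm, z = enc._forward(F)

            # similarity logits of anchor vs positive(0) and negatives
            others = z[1:]
            logits = (others @ z[0]) / tau
            logits -= logits.max()
            soft = np.exp(logits)
            soft /= soft.sum()
            target = np.zeros_like(soft)
            target[0] = 1.0
            dlogit = soft - target  # dL/dlogits

            dz = np.zeros_like(z)
            dz[0] = (dlogit @ others) / tau
            dz[1:] = np.outer(dlogit, z[0]) / tau
            # through the normalisation z = g / |g|
            dg = (dz - z * np.sum(dz * z, axis=1, keepdims=True)) / norm
            dh = dg @ enc.W2.T
            dh_pre = dh * (h_pre > 0)
            grads = {
                "W2": h.T @ dg,
                "b2": dg.sum(axis=0),
                "W1": Fs.T @ dh_pre,
                "b1": dh_pre.sum(axis=0),
            }
            t += 1
            for k, gkey in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * gkey
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * gkey**2
                step = (adam_m[k] / (1 - beta1**t)) / (
                    np.sqrt(adam_v[k] / (1 - beta2**t)) + eps
                )
                setattr(enc, k, getattr(enc, k) - config.lr * step)
    enc.trained = True
    return enc


def embed(
    encoder: PatchEncoder, patches: list[Patch], allow_untrained: bool = False
) -> PatchEmbeddingSet:
    """Encode patches into a :class:`PatchEmbeddingSet`.

    Batched evaluation; identical (within float tolerance) to encoding
    patches one at a time.
    """
    if not encoder.trained and not allow_untrained:
        raise ValueError("encoder is untrained; pass allow_untrained=True to proceed")
    sizes = {p.size for p in patches}
    if len(sizes) > 1:
        raise ValueError(f"mixed patch sizes {sizes}; one size per run")
    Z = encoder.transform_pixels([p.pixels for p in patches])
    coords = pd.DataFrame(
        {
            "patch_id": np.arange(len(patches)),
            "image_id": [p.image_id for p in patches],
            "x": [p.center[0] for p in patches],
            "y": [p.center[1] for p in patches],
        }
    )
    return PatchEmbeddingSet(Z, coords, encoder_tag=f"pcl-seed{encoder.config.seed}")
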