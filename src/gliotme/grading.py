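"""Architecture-zoo grading benchmark with fold-wise statistics.

Builds 5-class grading models over the six benchmark architectures in two
regimes — trained from scratch (every parameter trainable) or transfer
learning (only the final classification layer updated) — trains them
under stratified 10-fold cross-validation with cross-entropy, and
compares per-fold accuracies between models with the Shapiro-Wilk
normality check and the two-sided Mann-Whitney U test.

Parameter accounting is exact per-architecture layer arithmetic (see
:mod:`gliotme.architectures`).  The trainable component is a compact
NumPy classifier: a fixed, seeded feature bank summarising each image,
followed by a multilayer softmax head.  In the transfer regime the
hidden layer is frozen at its seeded initialisation and only the final
linear layer learns, mirroring the last-layer-only update; from scratch
the whole head learns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize

from .architectures import ARCHITECTURES, count_parameters
from .preprocessing import FoldSplit, augment_minority, rgb_to_hsv

__all__ = [
    "ModelSpec",
    "ParamReport",
    "GradingModel",
    "MetricsRecord",
    "StatResult",
    "build_model",
    "extract_features",
    "train_eval",
    "confusion",
    "compare_models",
]


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    pretrained: bool = False
    colorspace: str = "rgb"
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        if self.colorspace not in ("rgb", "hsv"):
            raise ValueError("colorspace must be 'rgb' or 'hsv'")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class ParamReport:
    total_params: int
    trainable_params: int

    def __post_init__(self) -> None:
        if self.trainable_params > self.total_params:
            raise ValueError("trainable cannot exceed total")


class GradingModel:
    """A grading classifier: seeded feature bank + softmax head.

    ``params`` reports the named reference architecture's parameter
    accounting for the requested regime; the trainable head used for
    fitting is sized for desk-scale synthetic cores.
    """

    N_BINS = 8  # spatial grid per channel for pooled features
    HIDDEN = 64

    def __init__(self, spec: ModelSpec, params: ParamReport, seed: int = 0):
        self.spec = spec
        self.params = params
        self.seed = seed
        rng = np.random.default_rng(seed)
        n_feat = self.N_BINS * self.N_BINS * 3 + 6  # grid + channel mean/sd
        scale = np.sqrt(2.0 / n_feat)
        self.W1 = rng.normal(0.0, scale, (n_feat, self.HIDDEN))
        self.b1 = np.zeros(self.HIDDEN)
        # zero-initialised head => untrained model emits a uniform softmax
        self.W2 = np.zeros((self.HIDDEN, spec.n_classes))
        self.b2 = np.zeros(spec.n_classes)
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    # -- forward --------------------------------------------------------
    def _standardize(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            self._mu = X.mean(axis=0)
            self._sd = X.std(axis=0) + 1e-8
        if self._mu is None:
            return X
        return (X - self._mu) / self._sd

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(X @ self.W1 + self.b1, 0.0)

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self._hidden(self._standardize(X, fit=False)) @ self.W2 + self.b2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.logits(X)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)

    # -- training -------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 10,
        lr: float = 1e-3,
        batch_size: int = 16,
        seed: int = 0,
    ) -> "GradingModel":
        if len(X) == 0:
            raise ValueError("empty training fold")
        rng = np.random.default_rng(seed)
        Xs = self._standardize(X, fit=True)
        n, k = len(Xs), self.spec.n_classes
        Y = np.eye(k)[y]
        train_hidden = not self.spec.pretrained
        params = [self.W2, self.b2] + ([self.W1, self.b1] if train_hidden else [])
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps, t = 0.9, 0.999, 1e-8, 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = Xs[idx], Y[idx]
                h_pre = xb @ self.W1 + self.b1
                h = np.maximum(h_pre, 0.0)
                z = h @ self.W2 + self.b2
                z -= z.max(axis=1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(axis=1, keepdims=True)
                dz = (p - yb) / len(idx)
                grads = [h.T @ dz, dz.sum(axis=0)]
                if train_hidden:
                    dh = (dz @ self.W2.T) * (h_pre > 0)
                    grads += [xb.T @ dh, dh.sum(axis=0)]
                t += 1
                for p_, g_, m_, v_ in zip(params, grads, m, v):
                    m_ *= beta1
                    m_ += (1 - beta1) * g_
                    v_ *= beta2
                    v_ += (1 - beta2) * g_**2
                    p_ -= lr * (m_ / (1 - beta1**t)) / (
                        np.sqrt(v_ / (1 - beta2**t)) + eps
                    )
        return self

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))


def build_model(spec: ModelSpec, seed: int = 0) -> GradingModel:
    """Instantiate a grading model and its trainable-parameter report.

    In the transfer regime the final classification layer is the only
    trainable part, so ``trainable_params`` is that layer's count; from
    scratch every parameter of the 5-class architecture is trainable.
    """
    total, head = count_parameters(spec.architecture, spec.n_classes)
    trainable = head if spec.pretrained else total
    return GradingModel(spec, ParamReport(total, trainable), seed=seed)


def extract_features(images: list[np.ndarray], colorspace: str = "rgb") -> np.ndarray:
    """Per-image pooled feature vector (spatial grid + channel stats)."""
    n_bins = GradingModel.N_BINS
    feats = []
    for img in images:
        arr = img.astype(np.float64)
        if arr.max() > 1.0:
            arr /= 255.0
        if colorspace == "hsv":
            arr = rgb_to_hsv(arr)
        grid = resize(arr, (n_bins, n_bins, 3), anti_aliasing=True)
        stats_ = np.concatenate([arr.mean(axis=(0, 1)), arr.std(axis=(0, 1))])
        feats.append(np.concatenate([grid.ravel(), stats_]))
    return np.asarray(feats)


@dataclass
class MetricsRecord:
    """Per-fold train/val/test metrics plus across-fold mean and s.d."""

    per_fold: pd.DataFrame

    COLUMNS = (
        "train_accuracy",
        "val_accuracy",
        "val_f1",
        "val_loss",
        "test_accuracy",
        "test_f1",
        "test_loss",
    )

    def summary(self) -> pd.DataFrame:
        return self.per_fold[list(self.COLUMNS)].agg(["mean", "std"])


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    f1s = []
    for c in range(n_classes):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def train_eval(
    spec: ModelSpec,
    images: dict[str, np.ndarray],
    labels: dict[str, int],
    folds: list[FoldSplit],
    epochs: int = 10,
    lr: float = 1e-3,
    seed: int = 0,
    augment: bool = True,
) -> MetricsRecord:
    """Train and evaluate one model spec across cross-validation folds.

    The training split of each fold is optionally augmented with 90/180
    degree rotations of minority grades before feature extraction;
    validation and test stay untouched.
    """
    records = []
    for split in folds:
        if not split.train_ids or not split.test_ids:
            raise ValueError(f"fold {split.fold_index} has an empty subset")
        tr_imgs = [images[i] for i in split.train_ids]
        tr_y = [labels[i] for i in split.train_ids]
        tr_ids = list(split.train_ids)
        if augment:
            tr_imgs, tr_y, tr_ids = augment_minority(tr_imgs, tr_y, tr_ids)
        model = build_model(spec, seed=seed)
        Xtr = extract_features(tr_imgs, spec.colorspace)
        ytr = np.asarray(tr_y)
        model.fit(Xtr, ytr, epochs=epochs, lr=lr, seed=seed + split.fold_index)
        row: dict[str, float] = {"fold": split.fold_index}
        for name, id_list in (
            ("train", tr_ids),
            ("val", split.val_ids),
            ("test", split.test_ids),
        ):
            if name == "train":
                X, y = Xtr, ytr
            else:
                X = extract_features([images[i] for i in id_list], spec.colorspace)
                y = np.asarray([labels[i] for i in id_list])
            pred = model.predict(X)
            row[f"{name}_accuracy"] = float(np.mean(pred == y))
            row[f"{name}_f1"] = _macro_f1(y, pred, spec.n_classes)
            row[f"{name}_loss"] = model.loss(X, y)
        records.append(row)
    return MetricsRecord(pd.DataFrame(records).set_index("fold"))


def confusion(predictions: np.ndarray, labels: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Count matrix: entry (i, j) = true grade i predicted as grade j."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    for arr in (predictions, labels):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (labels, predictions), 1)
    return mat


@dataclass(frozen=True)
class StatResult:
    """Fold-wise model comparison: Mann-Whitney U with normality check."""

    U: float
    p_value: float
    median_difference: float
    normality_p: tuple[float, float]  # Shapiro-Wilk p for each sample


def compare_models(acc_a: np.ndarray, acc_b: np.ndarray) -> StatResult:
    """Two-sided Mann-Whitney U between two sets of per-fold accuracies.

    Uses the exact enumerative null distribution when both samples have
    at most 10 values and no ties (fold counts are small), otherwise the
    normal approximation with tie correction.  The reported U is the
    statistic of the first sample, so ``U(a, b) + U(b, a) = n1 * n2``
    in the tie-free case.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per sample")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    sw_a = stats.shapiro(a).pvalue if len(np.unique(a)) > 1 else 1.0
    sw_b = stats.shapiro(b).pvalue if len(np.unique(b)) > 1 else 1.0
    return StatResult(
        U=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=float(np.median(a) - np.median(b)),
        normality_p=(float(sw_a), float(sw_b)),
    )
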