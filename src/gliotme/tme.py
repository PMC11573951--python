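"""Three-level interpretable TME assignment and patient classification.

Patches are assigned, at increasing spatial scale, to

* **phenotypes** (default P = 8): prototypes learned directly from patch
  embeddings;
* **neighborhoods** (default N = 8): prototypes of the hop-limited mean
  phenotype composition around each patch;
* **areas** (default A = 7): prototypes of the wider-radius distribution
  of neighborhood labels, separating interaction from segregation.

Defaults give the 23 TME element patterns (8 + 8 + 7).  Prototypes are
learned by seeded k-means with a softmax-over-negative-distance soft
assignment; per-image abundances (each level block normalised to sum 1)
feed a multinomial logistic patient classifier trained with
cross-entropy on patient-level grade labels only, whose weights are the
interpretation surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .pcl import PatchEmbeddingSet

__all__ = [
    "LevelAssignment",
    "TMEAssignment",
    "BinaryEvalRecord",
    "assign_phenotypes",
    "assign_neighborhoods",
    "assign_areas",
    "assign_all",
    "patient_abundance",
    "abundance_matrix",
    "PatientClassifier",
    "train_patient_classifier",
    "binary_eval",
    "evaluate_binary_pairs",
]

DEFAULT_P = 8
DEFAULT_N = 8
DEFAULT_A = 7


@dataclass
class LevelAssignment:
    """Soft and hard assignment of every patch at one spatial level."""

    level: str  # "P", "N" or "A"
    soft: np.ndarray  # n_patches x k, rows sum to 1
    prototypes: np.ndarray  # k x d (unused padded rows are NaN)

    def __post_init__(self) -> None:
        rs = self.soft.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("soft assignment rows must sum to 1")

    @property
    def hard(self) -> np.ndarray:
        return np.argmax(self.soft, axis=1)

    @property
    def k(self) -> int:
        return self.soft.shape[1]

    def labels(self) -> list[str]:
        return [f"{self.level}{i + 1}" for i in range(self.k)]


@dataclass
class TMEAssignment:
    """Bundle of the three per-patch levels plus patch coordinates."""

    phenotypes: LevelAssignment
    neighborhoods: LevelAssignment
    areas: LevelAssignment
    coords: pd.DataFrame  # patch_id, image_id, x, y

    def frame(self) -> pd.DataFrame:
        out = self.coords.copy()
        out["P"] = [f"P{i + 1}" for i in self.phenotypes.hard]
        out["N"] = [f"N{i + 1}" for i in self.neighborhoods.hard]
        out["A"] = [f"A{i + 1}" for i in self.areas.hard]
        return out


def _soft_from_distances(d2: np.ndarray) -> np.ndarray:
    """Softmax over negative squared distances, temperature from scale."""
    temp = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    z = -d2 / (temp + 1e-12)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _prototype_assign(X: np.ndarray, k: int, seed: int, level: str) -> LevelAssignment:
    """Seeded k-means prototypes with soft assignment over k slots.

    Degenerate inputs with fewer distinct rows than k occupy only the
    leading prototypes; unused slots get (numerically) zero weight.
    """
    if k < 2:
        raise ValueError("need at least 2 prototypes")
    if k > len(X):
        raise ValueError(f"{level}: k={k} exceeds {len(X)} patches")
    uniq = np.unique(X, axis=0)
    k_eff = min(k, len(uniq))
    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=10).fit(X)
    centers = km.cluster_centers_
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    if k_eff < k:
        d2 = np.hstack([d2, np.full((len(X), k - k_eff), 1e12)])
        centers = np.vstack([centers, np.full((k - k_eff, X.shape[1]), np.nan)])
    return LevelAssignment(level, _soft_from_distances(d2), centers)


def assign_phenotypes(
    embedding_set: PatchEmbeddingSet, P: int = DEFAULT_P, seed: int = 0
) -> LevelAssignment:
    """Assign every patch to one of P phenotype prototypes."""
    return _prototype_assign(embedding_set.embeddings, P, seed, "P")


def _hop_reachability(graph: nx.Graph, order: np.ndarray, hops: int) -> np.ndarray:
    """Boolean n x n matrix: within ``hops`` edges (incl. self), by image."""
    index = {pid: i for i, pid in enumerate(order)}
    n = len(order)
    reach = np.eye(n, dtype=bool)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges():
        if u in index and v in index:
            adj[index[u], index[v]] = adj[index[v], index[u]] = True
    for _ in range(hops):
        reach = reach | (reach @ adj)
    return reach


def _neighborhood_composition(
    graph: nx.Graph, coords: pd.DataFrame, soft: np.ndarray, hops: int
) -> np.ndarray:
    """Mean lower-level composition over each patch's hop neighborhood.

    Isolated patches fall back to their own composition.
    """
    comp = np.zeros_like(soft)
    pos = {pid: i for i, pid in enumerate(coords["patch_id"].to_numpy(int))}
    for _, sub in coords.groupby("image_id", sort=False):
        ids = sub["patch_id"].to_numpy(int)
        rows = np.array([pos[i] for i in ids])
        reach = _hop_reachability(graph, ids, hops)
        weights = reach.astype(float)
        weights /= weights.sum(axis=1, keepdims=True)
        comp[rows] = weights @ soft[rows]
    return comp


def assign_neighborhoods(
    graph: nx.Graph,
    coords: pd.DataFrame,
    phenotype_assignment: LevelAssignment,
    N: int = DEFAULT_N,
    hops: int = 1,
    seed: int = 0,
) -> LevelAssignment:
    """Cluster hop-limited phenotype compositions into N neighborhoods."""
    comp = _neighborhood_composition(graph, coords, phenotype_assignment.soft, hops)
    return _prototype_assign(comp, N, seed, "N")


def assign_areas(
    graph: nx.Graph,
    coords: pd.DataFrame,
    neighborhood_assignment: LevelAssignment,
    A: int = DEFAULT_A,
    hops_area: int = 3,
    seed: int = 0,
) -> LevelAssignment:
    """Cluster wider-radius neighborhood distributions into A areas."""
    comp = _neighborhood_composition(
        graph, coords, neighborhood_assignment.soft, hops_area
    )
    return _prototype_assign(comp, A, seed, "A")


def assign_all(
    embedding_set: PatchEmbeddingSet,
    graph: nx.Graph,
    P: int = DEFAULT_P,
    N: int = DEFAULT_N,
    A: int = DEFAULT_A,
    hops: int = 1,
    hops_area: int = 3,
    seed: int = 0,
) -> TMEAssignment:
    """Run the three levels in sequence (23 patterns at the defaults)."""
    coords = embedding_set.coords
    ph = assign_phenotypes(embedding_set, P, seed)
    nb = assign_neighborhoods(graph, coords, ph, N, hops, seed)
    ar = assign_areas(graph, coords, nb, A, hops_area, seed)
    return TMEAssignment(ph, nb, ar, coords)


def patient_abundance(assignment: TMEAssignment, image_id: str) -> np.ndarray:
    """Per-image TME composition: hard-label fractions per level block.

    Returns the concatenated (P + N + A)-vector; each block sums to 1.
    """
    sel = (assignment.coords["image_id"] == image_id).to_numpy()
    if not sel.any():
        raise ValueError(f"image {image_id!r} has no patches")
    blocks = []
    for level in (assignment.phenotypes, assignment.neighborhoods, assignment.areas):
        counts = np.bincount(level.hard[sel], minlength=level.k).astype(float)
        blocks.append(counts / counts.sum())
    return np.concatenate(blocks)


def abundance_matrix(
    assignment: TMEAssignment, grades: dict[str, int] | pd.Series
) -> pd.DataFrame:
    """Rows = images, columns = P/N/A elements, plus a ``grade`` column."""
    grades = pd.Series(grades)
    cols = (
        assignment.phenotypes.labels()
        + assignment.neighborhoods.labels()
        + assignment.areas.labels()
    )
    image_ids = assignment.coords["image_id"].unique()
    mat = pd.DataFrame(
        [patient_abundance(assignment, iid) for iid in image_ids],
        index=image_ids,
        columns=cols,
    )
    mat["grade"] = grades.loc[mat.index].to_numpy()
    return mat


@dataclass
class PatientClassifier:
    """Multinomial logistic model over abundance vectors."""

    model: LogisticRegression
    feature_names: list[str]
    classes: np.ndarray

    @property
    def weights(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.model.coef_, index=self.classes, columns=self.feature_names
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.atleast_2d(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.atleast_2d(X))


def train_patient_classifier(
    abundance: pd.DataFrame, seed: int = 0, C: float = 100.0
) -> PatientClassifier:
    """Fit the weakly supervised patient classifier.

    ``abundance`` is an :func:`abundance_matrix`-style frame with a
    ``grade`` column; only these image-level labels supervise training.
    """
    y = abundance["grade"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 grades to train a classifier")
    X = abundance.drop(columns="grade").to_numpy(float)
    model = LogisticRegression(max_iter=5000, C=C, random_state=seed)
    model.fit(X, y)
    return PatientClassifier(model, list(abundance.columns.drop("grade")), model.classes_)


@dataclass(frozen=True)
class BinaryEvalRecord:
    """One pairwise grade comparison (higher grade = positive class)."""

    pair: tuple[int, int]
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.sensitivity, self.specificity, self.auc):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


def binary_eval(
    scores: np.ndarray, grades: np.ndarray, pair: tuple[int, int]
) -> BinaryEvalRecord:
    """Evaluate one grade pair from positive-class scores.

    ``scores`` are the probability (or any monotone score) of the higher
    grade of ``pair``; AUC uses midranks so tied scores contribute 1/2.
    """
    lo, hi = sorted(pair)
    grades = np.asarray(grades)
    mask = np.isin(grades, [lo, hi])
    y = (grades[mask] == hi).astype(int)
    s = np.asarray(scores)[mask]
    if y.min() == y.max():
        raise ValueError(f"grade pair {pair}: one class absent from the held-out set")
    pred = (s >= 0.5).astype(int)
    tp = np.sum((pred == 1) & (y == 1))
    tn = np.sum((pred == 0) & (y == 0))
    return BinaryEvalRecord(
        pair=(lo, hi),
        accuracy=float(np.mean(pred == y)),
        sensitivity=float(tp / np.sum(y == 1)),
        specificity=float(tn / np.sum(y == 0)),
        auc=float(roc_auc_score(y, s)),
    )


def evaluate_binary_pairs(
    abundance: pd.DataFrame, seed: int = 0, n_splits: int = 5, C: float = 100.0
) -> pd.DataFrame:
    """Held-out evaluation of all 10 grade pairs.

    For each pair, a binary logistic model on the pair's images is
    scored under stratified cross-validation; records mirror the
    benchmark's 10-binary-comparison table.
    """
    from sklearn.model_selection import StratifiedKFold

    y_all = abundance["grade"].to_numpy()
    X_all = abundance.drop(columns="grade").to_numpy(float)
    grades = sorted(np.unique(y_all))
    rows = []
    for i, lo in enumerate(grades):
        for hi in grades[i + 1 :]:
            mask = np.isin(y_all, [lo, hi])
            X, y = X_all[mask], (y_all[mask] == hi).astype(int)
            splits = min(n_splits, np.bincount(y).min())
            skf = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
            scores = np.empty(len(y), dtype=float)
            for tr, te in skf.split(X, y):
                clf = LogisticRegression(max_iter=5000, C=C, random_state=seed)
                clf.fit(X[tr], y[tr])
                scores[te] = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
            rec = binary_eval(scores, np.where(y == 1, hi, lo), (lo, hi))
            rows.append(
                {
                    "pair": f"{lo},{hi}",
                    "accuracy": rec.accuracy,
                    "sensitivity": rec.sensitivity,
                    "specificity": rec.specificity,
                    "auc": rec.auc,
                }
            )
    return pd.DataFrame(rows).set_index("pair")
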