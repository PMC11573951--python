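"""Differential TME analysis across WHO grades.

Given the per-image abundance matrix, this module tests each TME element
for differential abundance between grade pairs (two-sided Mann-Whitney
rank-sum), maps p-values to the conventional star levels (* p < 0.05,
** p < 0.01, *** p < 0.001, strict inequalities), aggregates
significant elements into a grade-pair graph weighted by the x1/x2/x3
star multipliers, quantifies per-patient predictive influence of each
element, and orders heatmap rows and columns by average-linkage
hierarchical clustering.

P-values are reported raw (star levels are nominal, not adjusted for
multiple comparisons); the output metadata records both choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .tme import PatientClassifier

__all__ = [
    "DifferentialResult",
    "star_level",
    "STAR_MULTIPLIER",
    "differential_tme",
    "differential_all_pairs",
    "shared_cluster_graph",
    "predictive_influence",
    "heatmap_order",
    "plot_heatmap",
    "plot_violin",
    "plot_shared_cluster_graph",
]

#: per-element weight contributed to the shared-cluster graph
STAR_MULTIPLIER = {"*": 1, "**": 2, "***": 3}


def star_level(p: float) -> str:
    """Map a p-value to its star level with strict thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class DifferentialResult:
    element: str
    pair: tuple[int, int]
    p_value: float
    direction: int  # +1: more abundant in the higher grade, -1: lower, 0: tie
    stars: str

    def __post_init__(self) -> None:
        if self.stars != star_level(self.p_value):
            raise ValueError("star level inconsistent with p-value")


def differential_tme(
    abundance: pd.DataFrame, pair: tuple[int, int], min_n: int = 3
) -> list[DifferentialResult]:
    """Rank-sum test per TME element between two grades.

    ``abundance`` has element columns plus a ``grade`` column.  Elements
    whose values are constant across both groups are skipped with a
    warning (the rank-sum test is undefined there), as are comparisons
    with fewer than ``min_n`` images per grade.
    """
    lo, hi = sorted(pair)
    a = abundance[abundance["grade"] == hi].drop(columns="grade")
    b = abundance[abundance["grade"] == lo].drop(columns="grade")
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"pair {pair}: need >= {min_n} images per grade")
    results = []
    for element in a.columns:
        x, y = a[element].to_numpy(), b[element].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"element {element} constant for pair {pair}; skipped")
            continue
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        med_diff = float(np.median(x) - np.median(y))
        results.append(
            DifferentialResult(
                element=element,
                pair=(lo, hi),
                p_value=p,
                direction=int(np.sign(med_diff)),
                stars=star_level(p),
            )
        )
    return results


def differential_all_pairs(
    abundance: pd.DataFrame, min_n: int = 3
) -> dict[tuple[int, int], list[DifferentialResult]]:
    """Differential analysis over every available grade pair."""
    grades = sorted(abundance["grade"].unique())
    return {
        (lo, hi): differential_tme(abundance, (lo, hi), min_n=min_n)
        for lo, hi in combinations(grades, 2)
    }


def shared_cluster_graph(
    results: dict[tuple[int, int], list[DifferentialResult]],
) -> nx.Graph:
    """Grade graph weighted by significance-weighted shared clusters.

    For each grade pair, every significantly different element counts
    with its star multiplier (* -> 1, ** -> 2, *** -> 3); the pair's edge
    weight is the sum.  Pairs with no significant element get weight 0.
    """
    g = nx.Graph()
    for (lo, hi), res in results.items():
        g.add_node(lo)
        g.add_node(hi)
        weight = sum(STAR_MULTIPLIER.get(r.stars, 0) for r in res)
        g.add_edge(lo, hi, weight=weight)
    return g


def predictive_influence(
    classifier: PatientClassifier,
    abundance_row: pd.Series,
    cohort_mean: pd.Series,
    block_sizes: tuple[int, ...] = (8, 8, 7),
) -> pd.Series:
    """Per-element influence ratio on one patient's prediction.

    Each element is, in turn, replaced by its cohort-mean abundance and
    its level block renormalised to sum 1; the influence ratio is the
    predicted-class probability before the perturbation divided by the
    probability after it.  Ratios above 1 mark elements whose observed
    abundance supports the prediction; an element whose perturbation
    degenerates its block (division by a zero sum) is reported NaN.
    """
    names = classifier.feature_names
    x0 = abundance_row.loc[names].to_numpy(float)
    proba0 = classifier.predict_proba(x0)[0]
    cls = int(np.argmax(proba0))
    p0 = proba0[cls]

    bounds = np.cumsum((0,) + block_sizes)
    out = {}
    for j, name in enumerate(names):
        blk = np.searchsorted(bounds, j, side="right") - 1
        lo, hi = bounds[blk], bounds[blk + 1]
        x = x0.copy()
        x[j] = float(cohort_mean.loc[name])
        s = x[lo:hi].sum()
        if s <= 0:
            out[name] = np.nan
            continue
        x[lo:hi] = x[lo:hi] / s
        p1 = classifier.predict_proba(x)[0][cls]
        out[name] = float(p0 / p1) if p1 > 0 else np.inf
    return pd.Series(out, name="influence_ratio")


def plot_heatmap(abundance: pd.DataFrame, path) -> None:
    """Clustered sum-to-1 abundance heatmap, rows coloured by grade."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_order, col_order = heatmap_order(abundance)
    data = abundance.drop(columns="grade", errors="ignore")
    mat = data.iloc[row_order, :].iloc[:, col_order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("TME element")
    ax.set_ylabel("images (hierarchically ordered)")
    fig.colorbar(im, ax=ax, label="relative abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_violin(abundance: pd.DataFrame, element: str, path) -> None:
    """Per-grade violin of one element's relative abundance with stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grades = sorted(abundance["grade"].unique())
    groups = [
        abundance.loc[abundance["grade"] == g, element].to_numpy() for g in grades
    ]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.violinplot(groups, positions=range(len(grades)), showmedians=True)
    ax.set_xticks(range(len(grades)), [str(g) for g in grades])
    ax.set_xlabel("WHO grade")
    ax.set_ylabel(f"{element} relative abundance")
    top = max(g.max() for g in groups if len(g))
    res = differential_all_pairs(abundance)
    y = top * 1.05
    for (lo, hi), rs in res.items():
        stars = next((r.stars for r in rs if r.element == element), "ns")
        if stars != "ns":
            ax.plot([grades.index(lo), grades.index(hi)], [y, y], "k-", lw=0.8)
            ax.text(
                (grades.index(lo) + grades.index(hi)) / 2, y, stars, ha="center"
            )
            y *= 1.08
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_shared_cluster_graph(graph: nx.Graph, path) -> None:
    """Grade graph with edge widths scaled by shared-cluster weight."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    pos = nx.circular_layout(graph)
    weights = [d["weight"] for _, _, d in graph.edges(data=True)]
    wmax = max(weights) if weights else 1
    nx.draw_networkx(
        graph,
        pos,
        ax=ax,
        node_color="lightsteelblue",
        width=[0.5 + 4 * w / max(wmax, 1) for w in weights],
    )
    nx.draw_networkx_edge_labels(
        graph,
        pos,
        ax=ax,
        edge_labels={(u, v): d["weight"] for u, v, d in graph.edges(data=True)},
        font_size=7,
    )
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_order(abundance: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row and column leaf orders by average-linkage clustering.

    Euclidean distance, average linkage, on the element columns (the
    ``grade`` column, if present, is excluded).  Deterministic given the
    input order.  A single row (or column) maps to the identity order.
    """
    data = abundance.drop(columns="grade", errors="ignore").to_numpy(float)

    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        return leaves_list(linkage(mat, method="average", metric="euclidean"))

    return order(data), order(data.T)
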