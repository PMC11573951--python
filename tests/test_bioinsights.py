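"""Differential abundance analysis, star levels, cluster graph, influence."""

import numpy as np
import pandas as pd
import pytest

from gliotme import bioinsights as bi
from gliotme import synthetic, tme


class TestStarLevel:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.0005, "***"),
            (0.009, "**"),
            (0.03, "*"),
            (0.07, "ns"),
            # strict thresholds: boundary values do not qualify
            (0.05, "ns"),
            (0.01, "*"),
            (0.001, "**"),
        ],
    )
    def test_threshold_mapping(self, p, stars):
        assert bi.star_level(p) == stars

    def test_result_rejects_inconsistent_stars(self):
        with pytest.raises(ValueError):
            bi.DifferentialResult("N1", (0, 4), 0.5, 1, "***")


def _null_frame(n, rng, cols=4):
    rows = [rng.dirichlet(np.ones(cols)) for _ in range(2 * n)]
    out = pd.DataFrame(rows, columns=[f"N{i+1}" for i in range(cols)])
    out["grade"] = [0] * n + [4] * n
    return out


class TestDifferentialTme:
    def test_identical_distributions_all_ns(self):
        block = pd.DataFrame(
            {"N1": [0.2, 0.3, 0.4, 0.5] * 2, "N2": [0.8, 0.7, 0.6, 0.5] * 2}
        )
        block["grade"] = [0] * 4 + [4] * 4
        res = bi.differential_tme(block, (0, 4))
        assert all(r.stars == "ns" for r in res)

    def test_planted_effect_reaches_three_stars(self, rng):
        ab = _null_frame(20, rng)
        # plant: N1 high in grade 4, low in grade 0
        ab.loc[ab["grade"] == 4, "N1"] = 0.6 + rng.normal(0, 0.03, 20)
        ab.loc[ab["grade"] == 0, "N1"] = 0.1 + rng.normal(0, 0.03, 20)
        res = {r.element: r for r in bi.differential_tme(ab, (0, 4))}
        assert res["N1"].stars == "***"
        assert res["N1"].direction == 1  # more abundant in the higher grade

    def test_insufficient_samples_rejected(self, rng):
        ab = _null_frame(2, rng)
        with pytest.raises(ValueError):
            bi.differential_tme(ab, (0, 4))

    def test_constant_element_skipped_with_warning(self, rng):
        ab = _null_frame(5, rng)
        ab["N1"] = 0.25
        with pytest.warns(UserWarning, match="constant"):
            res = bi.differential_tme(ab, (0, 4))
        assert "N1" not in {r.element for r in res}

    def test_all_pairs_cover_ten_comparisons(self, rng):
        ab = synthetic.sample_abundance_cohort(
            synthetic.small_test_config(5), seed=0
        )
        res = bi.differential_all_pairs(ab)
        assert len(res) == 10


def _mk_results(star_lists):
    out = {}
    for pair, stars in star_lists.items():
        out[pair] = [
            bi.DifferentialResult(f"N{i+1}", pair, p, 1, s)
            for i, (p, s) in enumerate(stars)
        ]
    return out


class TestSharedClusterGraph:
    def test_single_three_star_element_weighs_three(self):
        res = _mk_results({(0, 4): [(0.0001, "***")]})
        g = bi.shared_cluster_graph(res)
        assert g[0][4]["weight"] == 3

    def test_no_significant_elements_weighs_zero(self):
        res = _mk_results({(1, 2): [(0.5, "ns"), (0.9, "ns")]})
        g = bi.shared_cluster_graph(res)
        assert g[1][2]["weight"] == 0

    def test_one_of_each_level_weighs_six(self):
        res = _mk_results({(0, 3): [(0.03, "*"), (0.005, "**"), (0.0005, "***")]})
        g = bi.shared_cluster_graph(res)
        assert g[0][3]["weight"] == 6  # 1 + 2 + 3

    def test_weights_are_nonnegative_integers(self, rng):
        ab = synthetic.sample_abundance_cohort(synthetic.small_test_config(8), seed=2)
        g = bi.shared_cluster_graph(bi.differential_all_pairs(ab))
        for _, _, d in g.edges(data=True):
            assert d["weight"] >= 0 and float(d["weight"]).is_integer()


class TestPredictiveInfluence:
    def _toy_classifier(self, coef, n_features=6):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(3), 40)
        X = np.hstack([X, rng.dirichlet(np.ones(3), 40)])
        y = (X @ coef > np.median(X @ coef)).astype(int)
        clf = LogisticRegression(max_iter=2000).fit(X, y)
        names = [f"P{i}" for i in range(1, 4)] + [f"N{i}" for i in range(1, 4)]
        return tme.PatientClassifier(clf, names, clf.classes_)

    def test_zero_weight_classifier_gives_unit_ratio(self):
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression()
        clf.classes_ = np.array([0, 1])
        clf.coef_ = np.zeros((1, 6))
        clf.intercept_ = np.array([0.3])
        names = [f"P{i}" for i in range(1, 4)] + [f"N{i}" for i in range(1, 4)]
        pc = tme.PatientClassifier(clf, names, clf.classes_)
        row = pd.Series(
            np.concatenate([np.full(3, 1 / 3), [0.5, 0.3, 0.2]]), index=names
        )
        mean = pd.Series(np.full(6, 1 / 3), index=names)
        infl = bi.predictive_influence(pc, row, mean, block_sizes=(3, 3))
        assert np.allclose(infl.to_numpy(), 1.0)

    def test_influence_increases_with_weight_magnitude(self):
        """Logistic toy: a stronger weight on a deviant element moves the
        prediction more when that element is averaged away."""
        from sklearn.linear_model import LogisticRegression

        names = ["N1", "N2"]
        row = pd.Series([0.9, 0.1], index=names)
        # averaging N1 to the cohort mean balances the block exactly, so
        # the perturbed logit is 0 and only the unperturbed one grows
        mean = pd.Series([0.1, 0.9], index=names)
        ratios = []
        for w in (1.0, 2.0, 4.0, 8.0):
            clf = LogisticRegression()
            clf.classes_ = np.array([0, 1])
            clf.coef_ = np.array([[w, -w]])
            clf.intercept_ = np.array([0.0])
            pc = tme.PatientClassifier(clf, names, clf.classes_)
            infl = bi.predictive_influence(pc, row, mean, block_sizes=(2,))
            ratios.append(infl["N1"])
        assert all(r2 > r1 for r1, r2 in zip(ratios, ratios[1:]))
        # closed form: sigma(w*(0.9-0.1)) / sigma(0)
        def sig(z):
            return 1 / (1 + np.exp(-z))

        assert ratios[0] == pytest.approx(sig(0.8) / 0.5, rel=1e-9)

    def test_ranking_stable_for_fixed_model(self, rng):
        pc = self._toy_classifier(np.array([3.0, -1, 0.5, 2, -2, 0.1]))
        row = pd.Series(
            np.concatenate([rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))]),
            index=pc.feature_names,
        )
        mean = pd.Series(np.full(6, 1 / 3), index=pc.feature_names)
        r1 = bi.predictive_influence(pc, row, mean, block_sizes=(3, 3))
        r2 = bi.predictive_influence(pc, row, mean, block_sizes=(3, 3))
        assert list(r1.sort_values().index) == list(r2.sort_values().index)


class TestHeatmapOrder:
    def test_identical_rows_are_adjacent_leaves(self):
        ab = pd.DataFrame(
            [[0.2, 0.8], [0.9, 0.1], [0.2, 0.8], [0.5, 0.5]],
            columns=["N1", "N2"],
        )
        row_order, _ = bi.heatmap_order(ab)
        pos = {r: i for i, r in enumerate(row_order)}
        assert abs(pos[0] - pos[2]) == 1

    def test_average_linkage_matches_hand_computation(self):
        # 1-D points 0, 1, 5, 7: merges (0,1), then (5,7), then the pair
        ab = pd.DataFrame({"v": [0.0, 1.0, 5.0, 7.0]})
        from scipy.cluster.hierarchy import linkage

        lk = linkage(ab.to_numpy(), method="average", metric="euclidean")
        assert {int(lk[0, 0]), int(lk[0, 1])} == {0, 1}
        assert {int(lk[1, 0]), int(lk[1, 1])} == {2, 3}
        # average-linkage distance between the two pairs: mean of 4 gaps
        assert lk[2, 2] == pytest.approx(np.mean([5, 7, 4, 6]))
        row_order, _ = bi.heatmap_order(ab)
        assert set(map(int, row_order[:2])) in ({0, 1}, {2, 3})

    def test_permutation_gives_same_clustering(self, rng):
        """Row permutation leaves the dendrogram (cophenetic structure)
        unchanged even though leaf traversal order may flip subtrees."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        ab = pd.DataFrame(rng.random((6, 4)), columns=list("ABCD"))
        perm = rng.permutation(6)
        coph1 = squareform(cophenet(linkage(ab.to_numpy(), method="average")))
        permuted = ab.iloc[perm].reset_index(drop=True).to_numpy()
        coph2 = squareform(cophenet(linkage(permuted, method="average")))
        # map permuted cophenetic matrix back to original labelling
        inv = np.argsort(perm)
        assert np.allclose(coph1, coph2[np.ix_(inv, inv)])

    def test_single_row_identity(self):
        ab = pd.DataFrame([[0.3, 0.7]], columns=["N1", "N2"])
        row_order, col_order = bi.heatmap_order(ab)
        assert list(row_order) == [0]
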