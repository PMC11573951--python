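"""Three-level TME assignment, abundances and patient-level evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from gliotme import tissue_graph, tme
from gliotme.pcl import PatchEmbeddingSet


def _grid_embedding_set(side, per_image_vecs, spacing=16.0, noise=0.05, seed=0):
    """One or more images of side x side patch grids with planted vectors.

    ``per_image_vecs`` maps image_id -> callable (col, row) -> base vector.
    """
    rng = np.random.default_rng(seed)
    rows, Z = [], []
    pid = 0
    for image_id, vec_fn in per_image_vecs.items():
        for r in range(side):
            for c in range(side):
                rows.append(
                    {
                        "patch_id": pid,
                        "image_id": image_id,
                        "x": c * spacing,
                        "y": r * spacing,
                    }
                )
                v = vec_fn(c, r) + rng.normal(0, noise, len(vec_fn(c, r)))
                Z.append(v / np.linalg.norm(v))
                pid += 1
    return PatchEmbeddingSet(np.asarray(Z), pd.DataFrame(rows))


class TestAssignPhenotypes:
    def test_two_orthogonal_clusters_match_kmeans(self, rng):
        base = np.eye(2, 8)
        Z = np.vstack([base[i % 2] + rng.normal(0, 0.05, 8) for i in range(40)])
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        es = PatchEmbeddingSet(
            Z,
            pd.DataFrame(
                {
                    "patch_id": range(40),
                    "image_id": "img",
                    "x": rng.uniform(0, 100, 40),
                    "y": rng.uniform(0, 100, 40),
                }
            ),
        )
        ours = tme.assign_phenotypes(es, P=2, seed=0).hard
        km = KMeans(2, random_state=0, n_init=10).fit_predict(Z)
        same = np.mean(ours == km)
        assert max(same, 1 - same) == 1.0  # identical up to label swap

    def test_soft_vectors_sum_to_one(self, rng):
        Z = rng.normal(0, 1, (30, 16))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        es = PatchEmbeddingSet(
            Z,
            pd.DataFrame(
                {"patch_id": range(30), "image_id": "i", "x": range(30), "y": 0}
            ),
        )
        asg = tme.assign_phenotypes(es, P=4, seed=0)
        assert np.allclose(asg.soft.sum(axis=1), 1.0, atol=1e-9)

    def test_default_levels_give_23_patterns(self):
        assert tme.DEFAULT_P == 8 and tme.DEFAULT_N == 8 and tme.DEFAULT_A == 7
        assert tme.DEFAULT_P + tme.DEFAULT_N + tme.DEFAULT_A == 23

    def test_more_prototypes_than_patches_rejected(self, rng):
        Z = rng.normal(0, 1, (3, 4))
        es = PatchEmbeddingSet(
            Z, pd.DataFrame({"patch_id": range(3), "image_id": "i", "x": range(3), "y": 0})
        )
        with pytest.raises(ValueError):
            tme.assign_phenotypes(es, P=5, seed=0)


class TestAssignNeighborhoods:
    def test_uniform_phenotype_collapses_to_one_neighborhood(self):
        es = _grid_embedding_set(
            6, {"img": lambda c, r: np.array([1.0, 0, 0, 0])}, noise=0.0
        )
        g = tissue_graph.build_graph(es, knn=4)
        ph = tme.LevelAssignment(
            "P", np.tile([1.0, 0.0], (36, 1)), np.zeros((2, 2))
        )
        nb = tme.assign_neighborhoods(g, es.coords, ph, N=3, seed=0)
        assert len(np.unique(nb.hard)) == 1

    def test_two_region_boundary_recovery(self):
        side = 12
        def vec(c, r):
            return np.array([1.0, 0, 0, 0]) if c < side // 2 else np.array([0, 1.0, 0, 0])

        es = _grid_embedding_set(side, {"img": vec}, noise=0.05, seed=1)
        g = tissue_graph.build_graph(es, knn=4)
        ph = tme.assign_phenotypes(es, P=2, seed=0)
        nb = tme.assign_neighborhoods(g, es.coords, ph, N=2, hops=1, seed=0)
        cols = es.coords["x"].to_numpy() / 16.0
        planted = (cols >= side // 2).astype(int)
        interior = np.abs(cols - (side // 2 - 0.5)) > 1.0  # > 1 patch from boundary
        agree = np.mean(nb.hard[interior] == planted[interior])
        assert max(agree, 1 - agree) >= 0.90

    def test_isolated_patch_keeps_own_composition(self):
        # a 2-patch image where the pair is connected plus one far singleton image
        rows = pd.DataFrame(
            {
                "patch_id": [0, 1, 2, 3],
                "image_id": ["a", "a", "b", "b"],
                "x": [0.0, 16.0, 0.0, 1000.0],
                "y": [0.0, 0.0, 0.0, 0.0],
            }
        )
        Z = np.eye(4)
        es = PatchEmbeddingSet(Z, rows)
        g = tissue_graph.build_graph(es, knn=1)
        g.remove_edge(2, 3)  # isolate both patches of image b
        soft = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        ph = tme.LevelAssignment("P", soft, np.zeros((2, 4)))
        comp = tme._neighborhood_composition(g, rows, ph.soft, hops=1)
        assert np.allclose(comp[2], ph.soft[2])


class TestAssignAreas:
    def test_single_neighborhood_occupies_one_area(self):
        es = _grid_embedding_set(6, {"img": lambda c, r: np.array([1.0, 0])}, noise=0.0)
        g = tissue_graph.build_graph(es, knn=4)
        nb = tme.LevelAssignment("N", np.tile([1.0, 0.0], (36, 1)), np.zeros((2, 2)))
        ar = tme.assign_areas(g, es.coords, nb, A=3, seed=0)
        assert len(np.unique(ar.hard)) == 1

    def test_checkerboard_vs_segregated_blocks_differ(self):
        side = 8
        es = _grid_embedding_set(
            side,
            {
                "checker": lambda c, r: np.array([1.0, 0, 0, 0]),
                "blocks": lambda c, r: np.array([1.0, 0, 0, 0]),
            },
            noise=0.0,
        )
        g = tissue_graph.build_graph(es, knn=4)
        coords = es.coords
        soft = np.zeros((len(coords), 2))
        for i, row in coords.iterrows():
            c, r = int(row.x // 16), int(row.y // 16)
            if row.image_id == "checker":
                lab = (c + r) % 2  # interleaved neighborhoods
            else:
                lab = int(c >= side // 2)  # segregated halves
            soft[i, lab] = 1.0
        nb = tme.LevelAssignment("N", soft, np.zeros((2, 2)))
        ar = tme.assign_areas(g, coords, nb, A=2, hops_area=2, seed=0)
        checker_mask = (coords["image_id"] == "checker").to_numpy()
        # compare area labels well inside each regime
        inner = (
            (coords["x"] / 16 % side >= 2)
            & (coords["x"] / 16 % side < 3)
            & (coords["y"] / 16 >= 2)
            & (coords["y"] / 16 < side - 2)
        ).to_numpy()
        checker_mode = np.bincount(ar.hard[checker_mask & inner]).argmax()
        blocks_mode = np.bincount(ar.hard[~checker_mask & inner]).argmax()
        assert checker_mode != blocks_mode


class TestPatientAbundance:
    def _assignment(self):
        es = _grid_embedding_set(
            4,
            {
                "a": lambda c, r: np.array([1.0, 0, 0, 0]),
                "b": lambda c, r: np.array([0.0, 1, 0, 0]),
            },
            noise=0.02,
            seed=2,
        )
        g = tissue_graph.build_graph(es, knn=3)
        return tme.assign_all(es, g, P=2, N=2, A=2, seed=0), es

    def test_blocks_sum_to_one(self):
        asg, _ = self._assignment()
        v = tme.patient_abundance(asg, "a")
        assert len(v) == 6
        assert np.allclose([v[:2].sum(), v[2:4].sum(), v[4:].sum()], 1.0, atol=1e-9)

    def test_pure_image_block_is_one_hot(self):
        asg, _ = self._assignment()
        v = tme.patient_abundance(asg, "a")
        n_block = v[2:4]
        assert np.isclose(n_block.max(), 1.0) and np.isclose(n_block.min(), 0.0)

    def test_matches_brute_force_counting(self):
        asg, es = self._assignment()
        v = tme.patient_abundance(asg, "b")
        sel = (es.coords["image_id"] == "b").to_numpy()
        hard = asg.phenotypes.hard[sel]
        expected = np.bincount(hard, minlength=2) / sel.sum()
        assert np.allclose(v[:2], expected)

    def test_unknown_image_rejected(self):
        asg, _ = self._assignment()
        with pytest.raises(ValueError):
            tme.patient_abundance(asg, "missing")


def _abundance_frame(n_per_grade, rng, signal=True):
    """Toy abundance frame: grade encoded (or not) in the N block."""
    rows, grades = [], []
    for g in range(5):
        for _ in range(n_per_grade):
            p = rng.dirichlet(np.ones(8))
            n = np.zeros(8)
            if signal:
                n[g] = 1.0
            else:
                n = rng.dirichlet(np.ones(8))
            a = rng.dirichlet(np.ones(7))
            rows.append(np.concatenate([p, n, a]))
            grades.append(g)
    cols = [f"P{i+1}" for i in range(8)] + [f"N{i+1}" for i in range(8)] + [
        f"A{i+1}" for i in range(7)
    ]
    out = pd.DataFrame(rows, columns=cols)
    out["grade"] = grades
    return out


class TestPatientClassifier:
    def test_disjoint_one_hot_blocks_are_separable(self, rng):
        ab = _abundance_frame(6, rng, signal=True)
        clf = tme.train_patient_classifier(ab, seed=0)
        X = ab.drop(columns="grade").to_numpy()
        assert np.mean(clf.predict(X) == ab["grade"].to_numpy()) == 1.0

    def test_permuted_labels_score_at_chance(self, rng):
        ab = _abundance_frame(8, rng, signal=False)
        ab["grade"] = rng.permutation(ab["grade"].to_numpy())
        from sklearn.model_selection import cross_val_score

        X = ab.drop(columns="grade").to_numpy()
        y = ab["grade"].to_numpy()
        from sklearn.linear_model import LogisticRegression

        acc = cross_val_score(
            LogisticRegression(max_iter=2000), X, y, cv=5
        ).mean()
        assert abs(acc - 0.2) < 3 * np.sqrt(0.2 * 0.8 / len(y))

    def test_deterministic_given_seed(self, rng):
        ab = _abundance_frame(5, rng)
        w1 = tme.train_patient_classifier(ab, seed=4).weights
        w2 = tme.train_patient_classifier(ab, seed=4).weights
        pd.testing.assert_frame_equal(w1, w2)

    def test_single_grade_rejected(self, rng):
        ab = _abundance_frame(4, rng)
        ab["grade"] = 2
        with pytest.raises(ValueError):
            tme.train_patient_classifier(ab)


class TestBinaryEval:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        grades = np.array([0, 0, 0, 4, 4, 4])
        rec = tme.binary_eval(scores, grades, (0, 4))
        assert rec.auc == 1.0 and rec.accuracy == 1.0

    def test_constant_scores_give_auc_half(self):
        rec = tme.binary_eval(np.full(6, 0.5), np.array([0, 0, 0, 4, 4, 4]), (0, 4))
        assert rec.auc == 0.5  # midrank tie convention

    def test_auc_equals_concordant_pair_count(self, rng):
        scores = rng.random(6)
        grades = np.array([1, 1, 1, 3, 3, 3])
        rec = tme.binary_eval(scores, grades, (1, 3))
        pos, neg = scores[3:], scores[:3]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert rec.auc == pytest.approx(conc / 9)

    def test_higher_grade_is_positive_class(self):
        scores = np.array([0.9, 0.9, 0.1, 0.1])
        grades = np.array([2, 2, 4, 4])
        rec = tme.binary_eval(scores, grades, (2, 4))
        assert rec.sensitivity == 0.0 and rec.specificity == 0.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            tme.binary_eval(np.array([0.5, 0.6]), np.array([1, 1]), (1, 2))

    def test_ten_pairs_for_five_grades(self, rng):
        ab = _abundance_frame(6, rng, signal=True)
        table = tme.evaluate_binary_pairs(ab, seed=0, n_splits=3)
        assert len(table) == 10
        assert table.to_numpy().min() >= 0 and table.to_numpy().max() <= 1
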