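"""Normalization, K-means++, silhouette, level ordering and classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from oracle_kmeans import brute_force_wcss

from metalrisk.risklevels import (
    ClusterModel,
    apply_bounds,
    invert_bounds,
    kmeans_fit,
    kmeanspp_seed,
    level_distribution,
    minmax_normalize,
    order_levels,
    scan_k,
    select_k,
    silhouette,
)

#: Printed normalized cluster centers of the published 4-level model
#: (NIPI, TCR, THQ per row; rows are categories 1..4).
PUBLISHED_CENTERS = np.array(
    [
        [0.0841556, 0.0898703, 0.1717660],
        [0.2272796, 0.1375510, 0.3194492],
        [0.1693235, 0.6068999, 0.3582518],
        [0.3463198, 0.1970221, 0.6196991],
    ]
)
PUBLISHED_NORMS = [0.21133483, 0.41548066, 0.72480507, 0.73673754]

PUBLISHED_SILHOUETTES = {3: 0.37741, 4: 0.38230, 5: 0.36543, 6: 0.36067, 7: 0.30792}


def _frame(arr):
    return pd.DataFrame(np.asarray(arr, dtype=float), columns=["nipi", "tcr", "thq"])


class TestMinMax:
    def test_hand_values(self):
        df = pd.DataFrame({"nipi": [2.0, 4.0, 6.0], "tcr": [0, 1, 2], "thq": [1, 2, 3]})
        norm, bounds = minmax_normalize(df)
        np.testing.assert_allclose(norm["nipi"], [0, 0.5, 1])
        assert bounds.loc["min", "nipi"] == 2.0 and bounds.loc["max", "nipi"] == 6.0

    def test_identity_when_already_unit(self):
        df = pd.DataFrame({"nipi": [0.0, 1.0], "tcr": [0.0, 1.0], "thq": [0.0, 1.0]})
        norm, _ = minmax_normalize(df)
        np.testing.assert_allclose(norm.to_numpy(), df.to_numpy())

    def test_constant_column_errors(self):
        df = pd.DataFrame({"nipi": [1.0, 1.0], "tcr": [0, 1], "thq": [0, 1]})
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(df)

    def test_apply_and_invert_roundtrip(self):
        rng = np.random.default_rng(0)
        df = _frame(rng.uniform(0, 5, (10, 3)))
        norm, bounds = minmax_normalize(df)
        new = _frame(rng.uniform(0, 5, (4, 3)))
        back = invert_bounds(apply_bounds(new, bounds), bounds)
        np.testing.assert_allclose(back.to_numpy(), new.to_numpy(), rtol=1e-12)


class TestSeeding:
    def test_deterministic_given_seed(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        a = kmeanspp_seed(pts, 4, np.random.default_rng(5))
        b = kmeanspp_seed(pts, 4, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_far_point_selected_second_with_high_probability(self):
        # two coincident points at 0 and one far away: squared-distance
        # seeding picks the far point second almost surely
        pts = np.array([[0.0], [0.0], [100.0]])
        trials = 0
        for s in range(200):
            centers = kmeanspp_seed(pts, 2, np.random.default_rng(s))
            if centers[0, 0] == 0.0:  # first center fell in the tight cluster
                trials += 1
                # d² weighting then makes the far point all but certain
                assert centers[1, 0] == 100.0
        assert trials > 0

    def test_k_exceeding_distinct_points_errors(self):
        pts = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ValueError, match="distinct"):
            kmeanspp_seed(pts, 3, np.random.default_rng(0))


class TestKmeansFit:
    def test_two_well_separated_triples_match_enumeration(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))])
        centers, labels, inertia = kmeans_fit(pts, 2, rng=0, n_restarts=10)
        assert inertia == pytest.approx(brute_force_wcss(pts, 2), rel=1e-9)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_k_equals_n_gives_zero_inertia(self):
        pts = np.random.default_rng(3).normal(size=(5, 3))
        _, _, inertia = kmeans_fit(pts, 5, rng=0, n_restarts=5)
        assert inertia == pytest.approx(0.0, abs=1e-18)

    def test_fewer_points_than_clusters_errors(self):
        with pytest.raises(ValueError, match="fewer points"):
            kmeans_fit(np.zeros((2, 2)), 3)


class TestSilhouette:
    def test_two_tight_pairs_hand_value(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        s, sc = silhouette(pts, labels)
        assert sc == pytest.approx(0.98999975, abs=1e-6)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        _, sc = silhouette(pts, labels)
        assert sc == pytest.approx(silhouette_score(pts, labels), abs=1e-12)

    def test_mixed_identical_points_score_nonpositive(self):
        pts = np.zeros((6, 2))
        labels = np.array([0, 1, 0, 1, 0, 1])
        _, sc = silhouette(pts, labels)
        assert sc <= 0

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [0.1], [5.0]])
        s, _ = silhouette(pts, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(np.zeros((3, 1)), np.zeros(3, dtype=int))


class TestSelectK:
    def test_published_silhouette_table_selects_four(self):
        assert select_k(PUBLISHED_SILHOUETTES) == 4

    def test_tie_goes_to_smaller_k(self):
        assert select_k({3: 0.5, 5: 0.5, 4: 0.2}) == 3

    def test_scan_recovers_two_blobs(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.05, (20, 2)), rng.normal(1, 0.05, (20, 2))])
        scores = scan_k(pts, (2, 3, 4), rng=0, n_restarts=5)
        assert select_k(scores) == 2


class TestOrderLevels:
    def test_published_centers_norms_and_names(self):
        order = order_levels(PUBLISHED_CENTERS)
        names = [name for _, name, _ in order]
        assert names == ["Low-Risk", "Medium-Risk", "Second-Highest Risk", "High-Risk"]
        for (idx, _, norm), expected in zip(order, PUBLISHED_NORMS):
            assert norm == pytest.approx(expected, abs=5e-7)

    def test_common_sphere_tie_breaks_lexicographically(self):
        centers = np.array([[0.0, 1.0], [1.0, 0.0]])
        order = order_levels(centers)
        assert [i for i, _, _ in order] == [0, 1]  # (0,1) < (1,0)

    def test_generic_names_for_k_not_four(self):
        order = order_levels(np.array([[2.0, 0], [1.0, 0]]))
        assert [name for _, name, _ in order] == ["Level 1", "Level 2"]


def _published_model():
    bounds = pd.DataFrame(
        {"nipi": [0, 1], "tcr": [0, 1], "thq": [0, 1]}, index=["min", "max"]
    )
    return ClusterModel(
        k=4,
        centers=PUBLISHED_CENTERS,
        norm_bounds=bounds,
        silhouette_by_k=dict(PUBLISHED_SILHOUETTES),
        level_order=order_levels(PUBLISHED_CENTERS),
        rng_seed=0,
    )


class TestClassify:
    def test_center_classifies_to_its_own_level_at_distance_zero(self):
        model = _published_model()
        for i in range(4):
            name, d = model.classify(PUBLISHED_CENTERS[i])
            assert name == model.level_of_center(i)
            assert d == 0.0

    def test_hand_point_is_low_risk(self):
        model = _published_model()
        name, _ = model.classify(np.array([0.1, 0.1, 0.2]))
        assert name == "Low-Risk"

    def test_equidistant_point_takes_lower_risk_level(self):
        bounds = pd.DataFrame(
            {"nipi": [0, 1], "tcr": [0, 1], "thq": [0, 1]}, index=["min", "max"]
        )
        centers = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        model = ClusterModel(
            k=2,
            centers=centers,
            norm_bounds=bounds,
            silhouette_by_k={},
            level_order=order_levels(centers),
            rng_seed=0,
        )
        name, d = model.classify(np.array([0.5, 0.0, 0.0]))
        assert name == "Level 1" and d == pytest.approx(0.5)

    def test_classify_frame_matches_pointwise(self):
        model = _published_model()
        rng = np.random.default_rng(8)
        pts = _frame(rng.uniform(0, 1, (25, 3)))
        framed = model.classify_frame(pts)
        for i in range(len(pts)):
            name, d = model.classify(pts.iloc[i].to_numpy())
            assert framed["level"].iloc[i] == name
            assert framed["distance"].iloc[i] == pytest.approx(d)

    def test_json_roundtrip(self, tmp_path):
        model = _published_model()
        p = tmp_path / "model.json"
        model.to_json(p)
        back = ClusterModel.from_json(p)
        np.testing.assert_allclose(back.centers, model.centers)
        assert back.level_order == model.level_order
        assert back.k == model.k


class TestLevelDistribution:
    def test_counting(self):
        props = level_distribution(
            ["Low", "Low", "Medium", "High"], all_levels=["Low", "Medium", "SH", "High"]
        )
        assert props == {"Low": 0.5, "Medium": 0.25, "SH": 0.0, "High": 0.25}

    def test_single_label_and_normalization(self):
        assert level_distribution(["x"]) == {"x": 1.0}
        props = level_distribution(list("aabbbc"))
        assert sum(props.values()) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            level_distribution([])
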