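"""knn label transfer: confidence formula, rejection rules, frequencies."""
import numpy as np
import pandas as pd
import pytest

from xegmap.atlas import (
    NOT_ASSIGNED,
    RejectionRule,
    apply_rejection,
    map_to_atlas,
    type_frequencies,
)
from xegmap.containers import AtlasReference, CorrectedSpace


def atlas_from(coords, types, ages=None):
    coords = np.asarray(coords, dtype=float)
    ages = np.zeros(len(coords)) if ages is None else np.asarray(ages, dtype=float)
    return AtlasReference(coords, np.asarray(types, dtype=object), ages)


def query_from(coords):
    coords = np.asarray(coords, dtype=float)
    ids = np.array([f"q{i}" for i in range(len(coords))], dtype=object)
    return CorrectedSpace(coords, ids, np.zeros(len(coords), dtype=int))


def line_atlas(n_a, n_b, k):
    """1-D atlas: type A at negative coordinates, B at positive ones."""
    coords = np.concatenate([-1 - np.arange(n_a), 1 + np.arange(n_b)])[:, None]
    types = ["A"] * n_a + ["B"] * n_b
    return atlas_from(coords, types)


class TestMapToAtlas:
    def test_confidence_is_modal_count_over_k(self):
        # 30 of 50 neighbors type A -> assigned A, confidence 0.6
        coords = np.arange(50)[:, None] * 0.01
        types = ["A"] * 30 + ["B"] * 20
        ages = [7.0] * 30 + [8.0] * 20
        atlas = atlas_from(coords, types, ages)
        out = map_to_atlas(query_from([[0.25]]), atlas, k=50)
        assert out.loc[0, "assigned_type"] == "A"
        assert out.loc[0, "confidence"] == pytest.approx(0.6)

    def test_coincident_cell_pure_region(self):
        coords = np.arange(10)[:, None]
        atlas = atlas_from(coords, ["A"] * 10, ages=[7.5] * 10)
        out = map_to_atlas(query_from([[3.0]]), atlas, k=5)
        assert out.loc[0, "confidence"] == 1.0
        assert out.loc[0, "age_sd"] == 0.0
        assert out.loc[0, "mean_nn_distance"] == pytest.approx(
            np.mean([0, 1, 1, 2, 2])
        )

    def test_age_statistics_over_neighbors(self):
        coords = np.zeros((4, 1)) + np.arange(4)[:, None] * 0.001
        atlas = atlas_from(coords, ["A"] * 4, ages=[6.5, 7.5, 8.5, 9.5])
        out = map_to_atlas(query_from([[0.0]]), atlas, k=4)
        assert out.loc[0, "age_mean"] == pytest.approx(8.0)
        assert out.loc[0, "age_sd"] == pytest.approx(np.std([6.5, 7.5, 8.5, 9.5]))

    def test_tie_breaks_by_mean_distance_then_name(self):
        # 2 A's and 2 B's among 4 neighbors; A's closer
        coords = [[1.0], [1.5], [2.0], [2.5]]
        atlas = atlas_from(coords, ["A", "A", "B", "B"])
        out = map_to_atlas(query_from([[0.0]]), atlas, k=4)
        assert out.loc[0, "assigned_type"] == "A"
        # exactly symmetric distances: lexicographic
        coords = [[-1.0], [1.0], [-2.0], [2.0]]
        atlas = atlas_from(coords, ["B", "A", "A", "B"])
        out = map_to_atlas(query_from([[0.0]]), atlas, k=4)
        assert out.loc[0, "assigned_type"] == "A"

    def test_dimension_mismatch_raises(self):
        atlas = atlas_from([[0.0, 0.0]], ["A"])
        with pytest.raises(ValueError, match="dimension"):
            map_to_atlas(query_from([[0.0]]), atlas, k=1)

    def test_k_exceeding_atlas_raises(self):
        atlas = atlas_from([[0.0]], ["A"])
        with pytest.raises(ValueError, match="atlas"):
            map_to_atlas(query_from([[0.0]]), atlas, k=5)

    def test_rigid_rotation_invariance(self, rng):
        coords = rng.normal(size=(100, 3))
        types = rng.choice(["A", "B", "C"], 100)
        q = rng.normal(size=(20, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        out1 = map_to_atlas(query_from(q), atlas_from(coords, types), k=10)
        out2 = map_to_atlas(query_from(q @ R.T), atlas_from(coords @ R.T, types), k=10)
        assert list(out1["assigned_type"]) == list(out2["assigned_type"])
        assert np.allclose(out1["mean_nn_distance"], out2["mean_nn_distance"])

    def test_brute_force_knn_oracle(self, rng):
        coords = rng.normal(size=(150, 4))
        types = rng.choice(["A", "B"], 150)
        ages = rng.choice([7.0, 8.0], 150)
        atlas = atlas_from(coords, types, ages)
        q = rng.normal(size=(30, 4))
        out = map_to_atlas(query_from(q), atlas, k=12)
        for i in range(30):
            d = np.linalg.norm(coords - q[i], axis=1)
            nn = np.argsort(d, kind="stable")[:12]
            assert out.loc[i, "mean_nn_distance"] == pytest.approx(d[nn].mean())
            vals, counts = np.unique(types[nn], return_counts=True)
            assert out.loc[i, "confidence"] == pytest.approx(counts.max() / 12)


class TestApplyRejection:
    @staticmethod
    def frame(**overrides):
        base = dict(
            cell_id=[f"q{i}" for i in range(6)],
            assigned_type=["A"] * 6,
            confidence=[0.9] * 6,
            mean_nn_distance=[1.0] * 6,
            age_mean=[7.5] * 6,
            age_sd=[0.1] * 6,
            k=[50] * 6,
        )
        base.update(overrides)
        return pd.DataFrame(base)

    def test_confidence_boundary_strict(self):
        a = self.frame(confidence=[0.49, 0.5, 0.51, 0.9, 0.9, 0.9])
        out = apply_rejection(a, dist_rule=RejectionRule(threshold=np.inf), min_cluster=1)
        assert out.loc[0, "assigned_type"] == NOT_ASSIGNED
        assert out.loc[1, "assigned_type"] == "A"  # exactly 0.5 retained
        assert out.loc[2, "assigned_type"] == "A"

    def test_distance_threshold(self):
        a = self.frame(mean_nn_distance=[1, 1, 1, 1, 1, 9])
        out = apply_rejection(a, dist_rule=RejectionRule(threshold=5.0), min_cluster=1)
        assert out.loc[5, "assigned_type"] == NOT_ASSIGNED
        assert (out.loc[:4, "assigned_type"] == "A").all()

    def test_small_cluster_rule_counts_after_other_rules(self):
        # 9 B survivors + 1 rejected-by-confidence B: all 9 demoted
        a = self.frame(
            assigned_type=["B"] * 6,
            confidence=[0.45] + [0.9] * 5,
        )
        extra = self.frame()
        extra["cell_id"] = [f"x{i}" for i in range(6)]
        extra["assigned_type"] = ["B"] * 4 + ["A", "A"]
        merged = pd.concat([a, extra], ignore_index=True)
        out = apply_rejection(
            merged, dist_rule=RejectionRule(threshold=np.inf), min_cluster=10
        )
        assert (out.loc[out["confidence"] >= 0.5, "assigned_type"] == NOT_ASSIGNED).all()

    def test_excluded_type(self):
        a = self.frame(assigned_type=["A", "A", "A", "Blood progenitors 2", "A", "A"])
        out = apply_rejection(
            a,
            dist_rule=RejectionRule(threshold=np.inf),
            min_cluster=1,
            excluded_types={"Blood progenitors 2"},
        )
        assert out.loc[3, "assigned_type"] == NOT_ASSIGNED

    def test_conf_min_monotonicity(self, rng):
        a = self.frame(confidence=list(rng.uniform(0.3, 1.0, 6)))
        counts = []
        for conf_min in (0.3, 0.5, 0.7, 0.9):
            out = apply_rejection(
                a, conf_min=conf_min, dist_rule=RejectionRule(threshold=np.inf),
                min_cluster=1,
            )
            counts.append((out["assigned_type"] == NOT_ASSIGNED).sum())
        assert counts == sorted(counts)

    def test_mad_rule_cuts_long_tail(self, rng):
        d = np.concatenate([rng.normal(1.0, 0.05, 500), rng.normal(3.0, 0.1, 50)])
        cut = RejectionRule().cutoff(d)
        assert np.all(d[:500] < cut) and np.all(d[500:] > cut)


class TestTypeFrequencies:
    def test_simple_fractions(self):
        a = pd.DataFrame(
            {
                "cell_id": ["a", "b", "c", "d"],
                "assigned_type": ["A", "A", "B", NOT_ASSIGNED],
                "sample": ["s1"] * 4,
            }
        )
        out = type_frequencies(a).set_index("type")
        assert out.loc["A", "fraction"] == 0.5
        assert out.loc["B", "fraction"] == 0.25
        assert out.loc[NOT_ASSIGNED, "fraction"] == 0.25

    def test_fractions_sum_to_one_per_group(self, rng):
        a = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(300)],
                "assigned_type": rng.choice(["A", "B", "C"], 300),
                "sample": rng.choice(["s1", "s2"], 300),
            }
        )
        out = type_frequencies(a)
        sums = out.groupby("sample")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_mixture_recovery_within_binomial_bounds(self, rng):
        n = 4000
        probs = {"A": 0.6, "B": 0.3, "C": 0.1}
        a = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "assigned_type": rng.choice(list(probs), n, p=list(probs.values())),
                "sample": "s1",
            }
        )
        out = type_frequencies(a).set_index("type")
        for t, p in probs.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(out.loc[t, "fraction"] - p) <= 3 * sd

    def test_missing_group_column_raises(self):
        a = pd.DataFrame({"cell_id": ["a"], "assigned_type": ["A"]})
        with pytest.raises(ValueError):
            type_frequencies(a, group_col="sample")


def test_knn_transfer_recovers_types_on_separated_blobs(rng):
    """Well-separated synthetic types: accuracy >= 0.99 among assigned cells."""
    centers = np.array([[0, 0], [6, 0], [0, 6], [6, 6], [3, 10]], dtype=float)
    types = np.array(["A", "B", "C", "D", "E"], dtype=object)
    a_coords = np.concatenate(
        [rng.normal(c, 0.5, (200, 2)) for c in centers]
    )
    a_types = np.repeat(types, 200)
    q_idx = rng.integers(0, 5, 300)
    q_coords = rng.normal(centers[q_idx], 0.5)
    atlas = atlas_from(a_coords, a_types)
    out = apply_rejection(map_to_atlas(query_from(q_coords), atlas, k=50))
    assigned = out["assigned_type"] != NOT_ASSIGNED
    acc = (out.loc[assigned, "assigned_type"].to_numpy() == types[q_idx][assigned.to_numpy()]).mean()
    assert acc >= 0.99
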