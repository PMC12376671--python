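import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from defekit.biometric import (
    BINARY_FEATURES,
    CATEGORIES,
    FEATURES,
    GROUPINGS,
    assemble_features,
    default_perplexity,
    embed_2d,
    enumerate_subsets,
    minmax_normalize,
    rank_subsets,
    silhouette_score,
)
from defekit.errors import UndefinedScoreError


def brute_force_silhouette(points, labels):
    """Independent pairwise-loop silhouette used as the oracle."""
    n = len(points)
    out = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            out.append(0.0)
            continue
        a = sum(math.dist(points[i], points[j]) for j in same) / len(same)
        b = math.inf
        for lab in set(labels):
            if lab == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == lab]
            b = min(b, sum(math.dist(points[i], points[j]) for j in other) / len(other))
        m = max(a, b)
        out.append(0.0 if m == 0 else (b - a) / m)
    return sum(out) / n


class TestMinMaxNormalize:
    def test_forced_values(self):
        out = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert out[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(np.array([[5.0], [5.0], [5.0]]))
        assert out[:, 0] == pytest.approx([0.0, 0.0, 0.0])

    def test_binary_column_passes_through(self):
        x = np.array([[0.0, 3.0], [1.0, 9.0], [0.0, 6.0]])
        out = minmax_normalize(x, binary_columns=[0])
        assert out[:, 0] == pytest.approx(x[:, 0])
        assert out[:, 1] == pytest.approx([0.0, 1.0, 0.5])

    @given(
        st.lists(
            st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=3, max_size=3),
            min_size=2,
            max_size=12,
        )
    )
    def test_bounded_and_idempotent(self, rows):
        x = np.array(rows)
        out = minmax_normalize(x)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        assert np.allclose(minmax_normalize(out), out)


class TestSubsetEnumeration:
    def test_eleven_biomarker_universe(self):
        assert len(enumerate_subsets(FEATURES, 3)) == 1981

    def test_small_universes_match_binomial_sums(self):
        assert len(enumerate_subsets(["a", "b", "c", "d"], 3)) == 5
        assert len(enumerate_subsets(["a", "b", "c"], 3)) == 1

    @pytest.mark.parametrize("p", range(3, 12))
    def test_count_matches_closed_form(self, p):
        expected = sum(math.comb(p, k) for k in range(3, p + 1))
        assert len(enumerate_subsets([f"f{i}" for i in range(p)], 3)) == expected

    def test_deterministic_order_and_duplicates(self):
        a = enumerate_subsets(["x", "y", "z", "w"], 3)
        b = enumerate_subsets(["x", "y", "z", "w"], 3)
        assert a == b
        with pytest.raises(ValueError):
            enumerate_subsets(["x", "x", "y"], 2)


class TestEmbedding:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (20, 4))
        e1 = embed_2d(x, seed=5, perplexity=5)
        e2 = embed_2d(x, seed=5, perplexity=5)
        assert np.array_equal(e1, e2)

    def test_separated_blobs_stay_separable(self):
        rng = np.random.default_rng(0)
        blob_a = rng.normal(0, 1, (10, 5))
        blob_b = rng.normal(20, 1, (10, 5))  # 20 SDs apart
        x = np.vstack([blob_a, blob_b])
        labels = ["a"] * 10 + ["b"] * 10
        emb = embed_2d(x, seed=0, perplexity=5)
        assert silhouette_score(emb, labels) > 0.8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(np.zeros((3, 2)), seed=0)

    def test_perplexity_must_be_below_n(self):
        with pytest.raises(ValueError):
            embed_2d(np.zeros((5, 2)), seed=0, perplexity=5)

    def test_default_perplexity_heuristic(self):
        assert default_perplexity(55) == pytest.approx(18.0)
        assert default_perplexity(200) == 30.0


class TestSilhouette:
    def test_hand_computed_two_cluster_example(self):
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        s = silhouette_score(pts, ["A", "A", "B", "B"])
        # a = 1, b = (10 + sqrt(101)) / 2 for every point
        b = (10 + math.sqrt(101)) / 2
        assert s == pytest.approx(1 - 1 / b, abs=1e-12)
        assert s == pytest.approx(0.9002, abs=1e-4)

    def test_all_singletons_score_zero(self):
        pts = np.arange(10, dtype=float).reshape(5, 2)
        assert silhouette_score(pts, list(range(5))) == 0.0

    def test_single_label_undefined(self):
        with pytest.raises(UndefinedScoreError):
            silhouette_score(np.zeros((4, 2)), ["a"] * 4)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(6, 61))
            k = int(rng.integers(2, 6))
            pts = rng.normal(0, 1, (n, 3))
            labels = rng.integers(0, k, n).tolist()
            if len(set(labels)) < 2:
                continue
            assert silhouette_score(pts, labels) == pytest.approx(
                brute_force_silhouette(pts.tolist(), labels), abs=1e-12
            )

    def test_matches_sklearn_where_defined(self):
        from sklearn.metrics import silhouette_score as sk_sil

        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (30, 2))
        labels = np.repeat([0, 1, 2], 10)
        assert silhouette_score(pts, labels) == pytest.approx(
            float(sk_sil(pts, labels)), abs=1e-12
        )

    def test_invariant_to_relabelling(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (24, 2))
        labels = rng.integers(0, 4, 24)
        renamed = np.array(["pqrs"[i] for i in labels])
        assert silhouette_score(pts, labels) == pytest.approx(
            silhouette_score(pts, renamed), abs=1e-15
        )


class TestAssembleFeatures:
    def test_hour_of_day_from_sitdown_time(self):
        from defekit.synthetic import generate_cohort, simulate_dataset

        cohort = generate_cohort(2, 1, seed=3)
        ds = simulate_dataset(cohort, 3, seed=3)
        table = assemble_features(ds)
        for _, row in table.iterrows():
            truth = next(
                ev.truth for ev in ds.events
                if ev.participant_id == row["participant"]
                and ev.day_index == row["day_index"]
            )
            assert row["DT"] == int(truth.timeline.t0 // 3600)

    def test_empty_dataset(self):
        from defekit.synthetic import CohortDataset, GeneratorConfig

        empty = CohortDataset([], [], GeneratorConfig())
        assert len(assemble_features(empty)) == 0

    def test_rows_satisfy_schema_invariants(self, feature_table):
        t = feature_table
        assert len(t) > 0
        assert t["DT"].between(0, 23).all()
        assert t["BSFS"].between(1, 7).all()
        assert t["CT"].isin([0, 1]).all() and t["U"].isin([0, 1]).all()
        assert (t["ADD"] <= t["TDD"] + 1e-9).all()
        assert (t["FSD"] <= t["TDD"] + 1e-9).all()
        assert (t["ST"] > 0).all() and (t["SC"] >= 1).all()

    def test_extracted_biomarkers_track_truth(self, default_dataset, feature_table):
        """Stream-derived durations and thickness agree with ground truth."""
        truth = default_dataset.truth_table()
        merged = feature_table.merge(
            truth, on=["participant", "day_index"], suffixes=("", "_true")
        )
        assert len(merged) == len(feature_table)
        for col, tol in [("ADD", 0.21), ("TDD", 0.21), ("ETD", 0.21), ("FSD", 0.21)]:
            assert (merged[col] - merged[f"{col}_true"]).abs().max() <= tol
        rel = (merged["ST"] - merged["ST_true"]).abs() / merged["ST_true"]
        assert rel.max() < 0.05
        assert (merged["SDD"] - merged["SDD_true"]).abs().max() <= 0.11


class TestRanking:
    def test_single_participant_rejected(self):
        table = pd.DataFrame(
            {f: np.random.default_rng(0).normal(size=6) for f in FEATURES}
        )
        table["participant"] = 1
        with pytest.raises(UndefinedScoreError):
            rank_subsets(table, "shape+behavior", seed=0)

    def test_grouping_pools_cover_expected_features(self):
        assert set(GROUPINGS["all"]) == set(FEATURES)
        assert set(GROUPINGS["shape+behavior"]) == set(
            CATEGORIES["shape"] + CATEGORIES["behavior"]
        )
        assert set(BINARY_FEATURES) == {"CT", "U"}

    def test_shape_behavior_ranking_complete_and_sorted(self, feature_table):
        results = rank_subsets(feature_table, "shape+behavior", seed=1)
        assert len(results) == 16  # 2^5 - 1 - 5 - 10
        scores = [r.score for r in results]
        assert scores == sorted(scores, reverse=True)
        assert all(-1.0 <= s <= 1.0 for s in scores)
        assert all(len(r.subset) >= 3 for r in results)
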