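import math

import numpy as np
import pytest

from clusterfold import (
    compare_datasets,
    concordance_weight,
    feature_products,
    intersect_features,
    label_transfer,
    sc_scores,
    similarity_score,
    stabilized_fc_frames,
)
from clusterfold.foldchange import FoldChangeFrame
from clusterfold.similarity import SimilarityRecord


def make_frame(dataset, group, fc, contrasts=None, feature_ids=None):
    fc = np.asarray(fc, float)
    if fc.ndim == 1:
        fc = fc[:, None]
    return FoldChangeFrame(
        dataset=dataset,
        focal_group=group,
        contrast_groups=contrasts or [f"j{i}" for i in range(fc.shape[1])],
        feature_ids=feature_ids or [f"g{i:02d}" for i in range(fc.shape[0])],
        fc=fc,
    )


def reference_similarity(fa, fb, threshold=0.2):
    """Nested-loop reference: products, SC, omega and similarity from scratch."""
    nfeat, p = fa.shape
    q = fb.shape[1]
    sc = []
    for f in range(nfeat):
        prods = []
        for s in range(p):
            for t in range(q):
                prods.append(fa[f, s] * fb[f, t])
        sc.append(sum(prods) / len(prods))
    n_pos = sum(1 for v in sc if v > threshold)
    n_neg = sum(1 for v in sc if v < -threshold)
    d = n_pos - n_neg
    omega = 0.0 if d == 0 else math.log(abs(d)) * (1 if d > 0 else -1)
    s = sum(sc)
    sim = 0.0 if s == 0 else (math.sqrt(abs(s)) + omega) * (1 if s > 0 else -1)
    return np.array(sc), omega, sim


class TestFeatureProducts:
    def test_single_column_frames(self):
        out = feature_products(make_frame("a", "i", [1, -2]), make_frame("b", "j", [3, 2]))
        np.testing.assert_allclose(out, [[3], [-4]])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        fa = rng.normal(size=(5, 2))
        fb = rng.normal(size=(5, 3))
        out = feature_products(make_frame("a", "i", fa), make_frame("b", "j", fb))
        assert out.shape == (5, 6)
        for f in range(5):
            expected = [fa[f, s] * fb[f, t] for s in range(2) for t in range(3)]
            np.testing.assert_allclose(out[f], expected)

    def test_self_products_diagonal_nonnegative(self):
        rng = np.random.default_rng(4)
        fa = rng.normal(size=(6, 3))
        frame = make_frame("a", "i", fa)
        out = feature_products(frame, frame)
        assert out.shape == (6, 9)
        for s in range(3):
            assert np.all(out[:, s * 3 + s] >= 0)

    def test_feature_space_mismatch(self):
        fa = make_frame("a", "i", [1.0, 2.0])
        fb = make_frame("b", "j", [1.0, 2.0], feature_ids=["x", "y"])
        with pytest.raises(ValueError, match="feature space"):
            feature_products(fa, fb)


class TestScores:
    def test_sc_is_row_mean(self):
        rng = np.random.default_rng(5)
        prods = rng.normal(size=(5, 6))
        np.testing.assert_allclose(sc_scores(prods), prods.mean(axis=1))
        np.testing.assert_allclose(sc_scores(np.array([[3.0, -1.0]])), [1.0])

    @pytest.mark.parametrize(
        "sc,expected",
        [
            ([0.5, 0.3, -0.25], (0.0, 2, 1)),
            ([0.5, 0.5, 0.5, 0.5, 0.5, -0.3], (math.log(4), 5, 1)),
            ([0.1, -0.1, 0.15], (0.0, 0, 0)),
            ([-0.5, -0.4, -0.3, 0.5], (-math.log(2), 1, 3)),
        ],
    )
    def test_concordance_weight(self, sc, expected):
        omega, n_pos, n_neg = concordance_weight(np.array(sc))
        assert (n_pos, n_neg) == expected[1:]
        assert omega == pytest.approx(expected[0])

    @pytest.mark.parametrize(
        "sc,omega,expected",
        [
            ([4.0], 0.0, 2.0),
            ([-4.0], 1.0, -3.0),
            ([1.0, -1.0], 5.0, 0.0),
        ],
    )
    def test_similarity_score(self, sc, omega, expected):
        assert similarity_score(np.array(sc), omega) == pytest.approx(expected)


class TestOracleEquivalence:
    def test_pipeline_matches_nested_loop_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            nfeat = rng.integers(1, 9)
            p = rng.integers(1, 5)
            q = rng.integers(1, 5)
            fa = rng.normal(scale=1.5, size=(nfeat, p))
            fb = rng.normal(scale=1.5, size=(nfeat, q))
            frame_a = make_frame("a", "i", fa)
            frame_b = make_frame("b", "j", fb)
            sc = sc_scores(feature_products(frame_a, frame_b))
            omega, _, _ = concordance_weight(sc)
            sim = similarity_score(sc, omega)
            ref_sc, ref_omega, ref_sim = reference_similarity(fa, fb)
            np.testing.assert_allclose(sc, ref_sc, atol=1e-12)
            assert omega == pytest.approx(ref_omega, abs=1e-12)
            assert sim == pytest.approx(ref_sim, abs=1e-12)

    def test_exchange_symmetry(self):
        rng = np.random.default_rng(13)
        fa = rng.normal(size=(7, 2))
        fb = rng.normal(size=(7, 3))
        frames = {"a": [make_frame("a", "i", fa)], "b": [make_frame("b", "j", fb)]}
        fwd, rev = compare_datasets(frames)
        assert fwd.sum_sc == pytest.approx(rev.sum_sc, rel=1e-12)
        assert fwd.omega == pytest.approx(rev.omega)
        assert fwd.similarity == pytest.approx(rev.similarity, rel=1e-12)


class TestCompareDatasets:
    def test_record_count_all_combinations(self):
        rng = np.random.default_rng(6)
        frames = {
            "a": [make_frame("a", f"A{i}", rng.normal(size=(4, 2))) for i in range(3)],
            "b": [make_frame("b", f"B{i}", rng.normal(size=(4, 3))) for i in range(4)],
        }
        records = compare_datasets(frames)
        assert len(records) == 3 * 4 * 2
        keys = [(r.dataset_a, r.group_a, r.dataset_b, r.group_b) for r in records]
        assert keys == sorted(keys)

    def test_record_invariants(self):
        rng = np.random.default_rng(7)
        frames = {
            "a": [make_frame("a", f"A{i}", rng.normal(size=(6, 2))) for i in range(2)],
            "b": [make_frame("b", f"B{i}", rng.normal(size=(6, 2))) for i in range(2)],
        }
        for r in compare_datasets(frames, top_n_features=3):
            if r.sum_sc != 0:
                rederived = (math.sqrt(abs(r.sum_sc)) + r.omega) * math.copysign(1, r.sum_sc)
                assert r.similarity == pytest.approx(rederived, rel=1e-12)
            scs = [fc.sc for fc in r.top_features]
            assert scs == sorted(scs, reverse=True)
            assert len(r.top_features) == 3

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_datasets({"a": [make_frame("a", "i", [1.0, 2.0])]})

    def test_self_copy_matches_diagonal(self, small_pair):
        """A dataset compared against its own copy peaks at the same group."""
        _, (ds, _), _ = small_pair
        import dataclasses

        copy = dataclasses.replace(ds, name="copy")
        space = intersect_features([ds, copy])
        frames = {
            d.name: stabilized_fc_frames(d, space, n_subsamples=3, seed=21)
            for d in (ds, copy)
        }
        records = compare_datasets(frames)
        for g in ds.groups:
            cands = [r for r in records if r.dataset_a == ds.name and r.group_a == g]
            best = max(cands, key=lambda r: r.similarity)
            assert best.group_b == g

    def test_planted_markers_dominate_top_features(self, small_pair):
        cfg, datasets, _ = small_pair
        space = intersect_features(datasets)
        frames = {
            d.name: stabilized_fc_frames(d, space, n_subsamples=5, seed=17)
            for d in datasets
        }
        records = compare_datasets(frames, top_n_features=10)
        planted = {
            f"gene{i:05d}"
            for g in range(cfg.n_groups)
            for i in cfg.marker_features(g)
        }
        for g in [cfg.group_label(i) for i in range(cfg.n_groups)]:
            (rec,) = [
                r
                for r in records
                if r.dataset_a == "dataset0" and r.group_a == g
                and r.dataset_b == "dataset1" and r.group_b == g
            ]
            hits = sum(1 for fc in rec.top_features if fc.feature_id in planted)
            assert hits >= 8


class TestLabelTransfer:
    def _records(self, sims):
        out = []
        for qa, targets in sims.items():
            for tb, s in targets.items():
                out.append(
                    SimilarityRecord(
                        dataset_a="q", group_a=qa, dataset_b="ref", group_b=tb,
                        similarity=s, omega=0.0, sum_sc=s, n_pos=0, n_neg=0,
                    )
                )
        return out

    def test_perfect_diagonal(self):
        recs = self._records(
            {"A": {"A": 2.0, "B": 0.1}, "B": {"A": -1.0, "B": 3.0}}
        )
        acc = label_transfer(recs, reference="ref", truth={"A": "A", "B": "B"})
        assert acc == 1.0

    def test_all_equal_ties_warn_and_break_lexicographically(self):
        recs = self._records({"A": {"X": 1.0, "Y": 1.0}})
        with pytest.warns(UserWarning, match="tied"):
            acc = label_transfer(recs, reference="ref", truth={"A": "X"})
        assert acc == 1.0

    def test_cell_weighted_accuracy(self):
        recs = self._records(
            {"A": {"A": 2.0, "B": 0.0}, "B": {"A": 5.0, "B": 1.0}}
        )
        acc = label_transfer(
            recs, reference="ref", truth={"A": "A", "B": "B"},
            group_sizes={"A": 90, "B": 10},
        )
        assert acc == pytest.approx(0.9)

    def test_missing_pairs_error(self):
        recs = self._records({"A": {"A": 1.0}})
        with pytest.raises(ValueError, match="B"):
            label_transfer(recs, reference="ref", truth={"A": "A", "B": "B"})
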