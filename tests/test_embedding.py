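"""Feature extraction, record vectors, PCA/t-SNE reduction, BGM clustering."""

import numpy as np
import pandas as pd
import pytest

import spectroseize as sz
from spectroseize import embedding as emb
from spectroseize.spectro import SpectrogramImage


def _image(rng):
    return SpectrogramImage(rng.uniform(-1, 1, (299, 299, 3)), "embedding", "grayscale")


class TestExtractFeatures:
    def test_standard_depth_vector_length(self, rng):
        ext = emb.SurrogateExtractor(depth=2048, seed=0)
        vec = emb.extract_features(_image(rng), ext)
        assert vec.shape == (131072,)

    def test_deterministic_for_fixed_extractor(self, rng):
        ext = emb.SurrogateExtractor(depth=16, seed=3)
        img = _image(rng)
        np.testing.assert_array_equal(emb.extract_features(img, ext),
                                      emb.extract_features(img, ext))

    def test_single_pixel_change_alters_vector(self, rng):
        ext = emb.SurrogateExtractor(depth=16, seed=3)
        img = _image(rng)
        v1 = emb.extract_features(img, ext)
        px = img.pixels.copy()
        px[150, 150, :] += 0.25
        v2 = emb.extract_features(SpectrogramImage(px, "embedding", "grayscale"), ext)
        assert not np.array_equal(v1, v2)

    def test_wrong_shape_rejected(self, rng):
        ext = emb.SurrogateExtractor(depth=16, seed=0)
        bad = SpectrogramImage(rng.uniform(-1, 1, (224, 224, 3)), "classifier", "jet")
        with pytest.raises(ValueError, match="299"):
            emb.extract_features(bad, ext)


class TestBuildRecordVector:
    def test_four_channels_full_length(self, rng):
        vecs = [rng.standard_normal(131072) for _ in range(4)]
        out = emb.build_record_vector(vecs, [0, 1, 2, 3])
        assert out.shape == (524288,)

    def test_missing_channel_block_zero_filled(self, rng):
        vecs = [rng.standard_normal(100) + 1 for _ in range(3)]
        out = emb.build_record_vector(vecs, [0, 1, 2])
        assert np.all(out[300:] == 0.0)
        assert np.all(out[:300] != 0.0)

    def test_declared_indices_canonicalise_order(self, rng):
        vecs = [rng.standard_normal(50) for _ in range(3)]
        a = emb.build_record_vector(vecs, [2, 0, 3])
        b = emb.build_record_vector([vecs[1], vecs[0], vecs[2]], [0, 2, 3])
        np.testing.assert_array_equal(a, b)

    def test_too_many_vectors_rejected(self, rng):
        vecs = [rng.standard_normal(10) for _ in range(5)]
        with pytest.raises(ValueError):
            emb.build_record_vector(vecs, [0, 1, 2, 3, 0])


class TestFitReduce:
    def test_output_is_2d_per_record(self, rng):
        X = rng.standard_normal((40, 200))
        ids = [f"R{i}" for i in range(40)]
        pts = emb.fit_reduce(X, ids, rng=rng)
        assert list(pts.columns) == ["record_id", "x", "y"]
        assert len(pts) == 40

    def test_small_n_caps_pca_rank(self, rng):
        """With 40 records PCA is fitted on all 40 and components <= 40."""
        X = rng.standard_normal((40, 500))
        pts = emb.fit_reduce(X, [f"R{i}" for i in range(40)], rng=rng)
        assert np.isfinite(pts[["x", "y"]].to_numpy()).all()

    def test_fewer_than_two_records_rejected(self, rng):
        with pytest.raises(ValueError):
            emb.fit_reduce(rng.standard_normal((1, 10)), ["R0"], rng=rng)

    def test_seeded_reproducibility(self, rng):
        X = np.random.default_rng(0).standard_normal((30, 64))
        ids = [f"R{i}" for i in range(30)]
        a = emb.fit_reduce(X, ids, rng=np.random.default_rng(42))
        b = emb.fit_reduce(X, ids, rng=np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)


class TestBgmMaxComponents:
    @pytest.mark.parametrize("n,expected", [(5000, 50), (200, 10), (1234, 12),
                                            (99, 10), (100, 10), (1100, 11)])
    def test_rule(self, n, expected):
        assert emb.bgm_max_components(n) == expected


def _blob_points(rng, centers, per=30):
    rows = []
    k = 0
    for cx, cy in centers:
        for _ in range(per):
            rows.append((f"R{k:04d}", cx + 0.3 * rng.standard_normal(),
                         cy + 0.3 * rng.standard_normal()))
            k += 1
    return pd.DataFrame(rows, columns=["record_id", "x", "y"])


class TestClusterBgm:
    def test_assignments_partition_all_points(self, rng):
        pts = _blob_points(rng, [(0, 0), (10, 0), (0, 10)])
        model = emb.cluster_bgm(pts, rng=rng)
        assert set(model.assignments.index) == set(pts["record_id"])
        assert model.effective_clusters <= model.n_components_max
        assert model.effective_clusters >= 3

    def test_well_separated_blobs_recovered(self, rng):
        pts = _blob_points(rng, [(0, 0), (20, 0), (0, 20)])
        model = emb.cluster_bgm(pts, rng=rng)
        truth = np.repeat([0, 1, 2], 30)
        # every true blob maps into a single fitted cluster
        for g in range(3):
            labels = model.assignments.iloc[truth == g]
            assert labels.nunique() == 1

    def test_identical_points_single_cluster_no_crash(self, rng):
        pts = pd.DataFrame({"record_id": [f"R{i}" for i in range(10)],
                            "x": 1.0, "y": 2.0})
        model = emb.cluster_bgm(pts, rng=rng)
        assert model.effective_clusters == 1
        assert model.centroid_records[0] == "R0"  # lexicographic tie-break


class TestFindCentroids:
    def test_singleton_cluster_returns_its_member(self):
        pts = pd.DataFrame({"record_id": ["A", "B"], "x": [0.0, 5.0], "y": [0.0, 0.0]})
        model = emb.ClusterModel(
            n_components_max=10,
            assignments=pd.Series([0, 1], index=pd.Index(["A", "B"], name="record_id")),
            member_means={0: np.array([0.0, 0.0]), 1: np.array([5.0, 0.0])})
        assert emb.find_centroids(model, pts) == {0: "A", 1: "B"}

    def test_agrees_with_brute_force_argmin(self, rng):
        pts = pd.DataFrame({"record_id": [f"R{i}" for i in range(5)],
                            "x": rng.standard_normal(5), "y": rng.standard_normal(5)})
        assign = pd.Series(0, index=pd.Index(pts["record_id"], name="record_id"))
        mean = pts[["x", "y"]].mean().to_numpy()
        model = emb.ClusterModel(10, assign, 1, {0: mean})
        got = emb.find_centroids(model, pts)[0]
        d = np.hypot(pts["x"] - mean[0], pts["y"] - mean[1])
        assert got == pts["record_id"].iloc[int(np.argmin(d.to_numpy()))]

    def test_equidistant_tie_prefers_smaller_record_id(self):
        pts = pd.DataFrame({"record_id": ["R2", "R1"], "x": [1.0, -1.0], "y": [0.0, 0.0]})
        assign = pd.Series(0, index=pd.Index(pts["record_id"], name="record_id"))
        model = emb.ClusterModel(10, assign, 1, {0: np.array([0.0, 0.0])})
        assert emb.find_centroids(model, pts)[0] == "R1"
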