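"""Per-patient 2-D embedding and Bayesian Gaussian mixture clustering.

Each channel's embedding-dialect spectrogram image is mapped to an
8 x 8 x depth deep-feature grid and flattened (131,072 values at the
standard depth of 2048); the four channel vectors are concatenated, with
zero-filled blocks for absent channels, into a 524,288-feature record
vector. PCA (fitted on at most 1,024 randomly chosen record vectors)
reduces to 50 components, t-SNE reduces those to 2-D, and a Bayesian
Gaussian mixture with ``max(floor(N/100), 10)`` maximum components clusters
the 2-D points. The record nearest each cluster's member mean is its
centroid — the record a human labels first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.mixture import BayesianGaussianMixture

from .spectro import SpectrogramImage

GRID = 8
STANDARD_DEPTH = 2048
N_CHANNEL_SLOTS = 4
EMBEDDING_SIDE = 299


class SurrogateExtractor:
    """Seeded random-projection stand-in for a pretrained image backbone.

    Synthetic, hermetic extractor: the 299x299 grayscale image is split into
    an 8x8 grid of 37x37 patches (after cropping the 3 trailing rows and
    columns) and each patch is linearly projected by one fixed
    seed-determined Gaussian matrix to ``depth`` features. The map is
    deterministic, locality-preserving and uses every interior pixel, which
    is all the downstream clustering needs. A real pretrained backbone can
    be plugged in behind the same ``__call__`` interface (image ->
    8 x 8 x depth array).
    """

    def __init__(self, depth: int = STANDARD_DEPTH, seed: int = 0):
        self.depth = depth
        self.seed = seed
        self._patch = (EMBEDDING_SIDE // GRID)  # 37
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEA7]))
        d_in = self._patch * self._patch
        self._proj = rng.standard_normal((d_in, depth)) / np.sqrt(d_in)

    def __call__(self, image: SpectrogramImage) -> np.ndarray:
        px = np.asarray(image.pixels)
        if px.shape != (EMBEDDING_SIDE, EMBEDDING_SIDE, 3):
            raise ValueError(
                f"extractor requires a {EMBEDDING_SIDE}x{EMBEDDING_SIDE}x3 image, got {px.shape}")
        gray = px.mean(axis=2)
        p = self._patch
        crop = gray[:GRID * p, :GRID * p]
        patches = crop.reshape(GRID, p, GRID, p).transpose(0, 2, 1, 3).reshape(GRID, GRID, p * p)
        return patches @ self._proj  # (8, 8, depth)

    @property
    def feature_length(self) -> int:
        return GRID * GRID * self.depth


def extract_features(image: SpectrogramImage, extractor) -> np.ndarray:
    """Flatten the extractor's 8 x 8 x depth map to one channel vector.

    Flattening is row-major over the 8x8 grid, then feature depth; at the
    standard depth the vector has exactly 131,072 entries.
    """
    fmap = np.asarray(extractor(image))
    if fmap.ndim != 3 or fmap.shape[:2] != (GRID, GRID):
        raise ValueError(f"extractor must produce an {GRID}x{GRID}xD map, got {fmap.shape}")
    return fmap.reshape(-1)


def build_record_vector(channel_vectors: list[np.ndarray],
                        channel_indices: list[int],
                        n_slots: int = N_CHANNEL_SLOTS) -> np.ndarray:
    """Concatenate per-channel feature vectors in channel-slot order.

    Missing slots are zero-filled, so the record vector always has
    ``n_slots * len(channel_vector)`` entries (524,288 at standard depth)
    and block ``i`` is all-zero iff channel ``i`` is absent.
    """
    if not 1 <= len(channel_vectors) <= n_slots:
        raise ValueError(f"need 1-{n_slots} channel vectors, got {len(channel_vectors)}")
    if len(channel_vectors) != len(channel_indices):
        raise ValueError("channel_vectors and channel_indices must align")
    if len(set(channel_indices)) != len(channel_indices):
        raise ValueError("duplicate channel indices")
    L = channel_vectors[0].shape[0]
    out = np.zeros(n_slots * L)
    for vec, idx in zip(channel_vectors, channel_indices):
        if vec.shape != (L,):
            raise ValueError("all channel vectors must have the same length")
        if not 0 <= idx < n_slots:
            raise ValueError(f"channel index {idx} outside [0, {n_slots})")
        out[idx * L:(idx + 1) * L] = vec
    return out


def fit_reduce(record_vectors: np.ndarray, record_ids: list[str],
               pca_sample_size: int = 1024, n_components_pca: int = 50,
               perplexity: float = 30.0,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """PCA (fitted on a random sample) then t-SNE to a patient 2-D embedding.

    PCA is fitted on ``min(N, pca_sample_size)`` randomly selected record
    vectors and applied to all of them; its component count is capped by the
    fitting-sample rank. The 50 components go to t-SNE (perplexity clipped
    below the sample count) for the final 2-D coordinates. Returns a
    DataFrame ``(record_id, x, y)``.
    """
    X = np.asarray(record_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(record_ids):
        raise ValueError("record_vectors must be (N, D) aligned with record_ids")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 records to embed")
    if rng is None:
        rng = np.random.default_rng(0)
    n_fit = min(n, pca_sample_size)
    sample = rng.choice(n, size=n_fit, replace=False)
    n_comp = min(n_components_pca, n_fit, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=int(rng.integers(2**31)))
    pca.fit(X[sample])
    reduced = pca.transform(X)
    perp = min(perplexity, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, perplexity=perp, init="pca",
                random_state=int(rng.integers(2**31)))
    coords = tsne.fit_transform(reduced)
    return pd.DataFrame({"record_id": record_ids,
                         "x": coords[:, 0].astype(float),
                         "y": coords[:, 1].astype(float)})


def bgm_max_components(n_records: int) -> int:
    """Maximum mixture components for a patient: ``max(floor(N/100), 10)``."""
    if n_records < 1:
        raise ValueError("n_records must be positive")
    return max(n_records // 100, 10)


@dataclass
class ClusterModel:
    """Fitted per-patient clustering of 2-D embedding points."""

    n_components_max: int
    assignments: pd.Series  # record_id -> cluster id
    effective_clusters: int = 0
    member_means: dict[int, np.ndarray] = field(default_factory=dict)
    centroid_records: dict[int, str] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return self.assignments.index[self.assignments == cluster].tolist()


def cluster_bgm(points: pd.DataFrame,
                rng: np.random.Generator | None = None,
                max_iter: int = 500) -> ClusterModel:
    """Cluster 2-D embedding points with a Dirichlet-process Bayesian
    Gaussian mixture.

    The maximum component count follows the per-patient rule
    ``max(floor(N/100), 10)`` (capped at N, which the mixture fit requires);
    the effective cluster count — the number of components that actually
    received members — can be smaller. Assignment is by highest posterior
    responsibility.
    """
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    if rng is None:
        rng = np.random.default_rng(0)
    ncmax = bgm_max_components(n)
    X = points[["x", "y"]].to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        assign = pd.Series(0, index=pd.Index(points["record_id"], name="record_id"))
        model = ClusterModel(n_components_max=ncmax, assignments=assign,
                             effective_clusters=1,
                             member_means={0: X[0].copy()})
        model.centroid_records = find_centroids(model, points)
        return model
    bgm = BayesianGaussianMixture(
        n_components=min(ncmax, n),
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        max_iter=max_iter,
        random_state=int(rng.integers(2**31)),
    )
    labels = bgm.fit_predict(X)
    assign = pd.Series(labels, index=pd.Index(points["record_id"], name="record_id"))
    used = np.unique(labels)
    means = {int(c): X[labels == c].mean(axis=0) for c in used}
    model = ClusterModel(n_components_max=ncmax, assignments=assign,
                         effective_clusters=len(used), member_means=means)
    model.centroid_records = find_centroids(model, points)
    return model


def find_centroids(model: ClusterModel, points: pd.DataFrame) -> dict[int, str]:
    """Centroid record per non-empty cluster: the member nearest (Euclidean)
    to the cluster's member mean, ties broken by smallest record_id."""
    pts = points.set_index("record_id")
    out: dict[int, str] = {}
    for cluster, mean in sorted(model.member_means.items()):
        members = model.members(cluster)
        if not members:
            continue
        best = None
        for rid in sorted(members):
            d = float(np.hypot(*(pts.loc[rid, ["x", "y"]].to_numpy(dtype=float) - mean)))
            if best is None or d < best[0] - 1e-12:
                best = (d, rid)
        out[cluster] = best[1]
    return out
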