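"""End-to-end glue: records -> images -> features -> embedding -> labels,
and records -> training arrays for the classifier harness."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import embedding as emb
from . import preprocess, spectro
from .labeling import to_binary
from .records import GroundTruth, TimeSeriesRecord


def record_images(record: TimeSeriesRecord, dialect: str = "classifier",
                  colormap: str = "jet", size: int | None = None,
                  reject_artifacts: bool = True,
                  policy: preprocess.LengthPolicy = preprocess.LengthPolicy(),
                  ) -> list[tuple[int, spectro.SpectrogramImage]]:
    """Preprocess one record and render a spectrogram image per channel.

    Applies stimulation-artifact rejection, then length normalisation, then
    the spectrogram/render chain. Returns ``(channel_index, image)`` pairs.
    """
    rec = preprocess.reject_record_artifacts(record) if reject_artifacts else record
    rec = preprocess.normalize_length(rec, policy)
    out = []
    for row, ch in enumerate(rec.channel_indices):
        mat = spectro.compute_spectrogram(rec.data[row])
        out.append((ch, spectro.render_image(mat, dialect, colormap, size=size)))
    return out


def record_vector(record: TimeSeriesRecord, extractor,
                  reject_artifacts: bool = True) -> np.ndarray:
    """The record's concatenated deep-feature vector (zero-filled blocks for
    absent channel slots), from embedding-dialect grayscale images."""
    images = record_images(record, dialect="embedding", colormap="grayscale",
                           reject_artifacts=reject_artifacts)
    vecs = [emb.extract_features(img, extractor) for _, img in images]
    return emb.build_record_vector(vecs, [ch for ch, _ in images])


def embed_patient(records: list[TimeSeriesRecord], extractor,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[pd.DataFrame, emb.ClusterModel]:
    """Full per-patient embedding and clustering.

    Returns the 2-D points table (record_id, x, y, cluster, is_centroid)
    and the fitted cluster model.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ids = [r.record_id for r in records]
    X = np.stack([record_vector(r, extractor) for r in records])
    points = emb.fit_reduce(X, ids, rng=rng)
    model = emb.cluster_bgm(points, rng=rng)
    points = points.copy()
    points["cluster"] = model.assignments.loc[points["record_id"]].to_numpy()
    centroids = set(model.centroid_records.values())
    points["is_centroid"] = points["record_id"].isin(centroids)
    return points, model


def training_arrays(records_truths: list[tuple[TimeSeriesRecord, GroundTruth]],
                    side: int = 24, colormap: str = "jet",
                    reject_artifacts: bool = True,
                    ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render every labeled channel to a classifier-dialect image array.

    Returns ``(X, y, keys)``: NHWC images in [-1, 1], integer classes
    (0 = nsz, 1 = sz), and a key table (patient_id, record_id,
    channel_index, cls). Channels whose label maps to 'excluded' are
    dropped.
    """
    xs, ys, rows = [], [], []
    for rec, truth in records_truths:
        images = record_images(rec, dialect="classifier", colormap=colormap,
                               size=side, reject_artifacts=reject_artifacts)
        for ch, img in images:
            cls = to_binary(truth.channel_labels[ch])
            if cls == "excluded":
                continue
            xs.append(img.pixels.astype(np.float32))
            ys.append(1 if cls == "sz" else 0)
            rows.append((rec.patient_id, rec.record_id, ch, cls))
    keys = pd.DataFrame(rows, columns=["patient_id", "record_id", "channel_index", "cls"])
    return np.stack(xs), np.asarray(ys, dtype=int), keys
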