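"""On-disk formats: record CSV + JSON sidecar, label tables, spectrogram PNGs.

The canonical time-series container is a per-record CSV (columns
``sample_index, ch1..ch4`` in microvolts) with a JSON sidecar holding the
metadata (patient/record ids, record type, trigger sample). Spectrogram
images are 8-bit RGB PNGs in a ``root/class_label/patient_id/`` layout with
deterministic names, so the directory tree is a pure function of
(class, patient, record, channel).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labeling import CHANNEL_LABELS
from .records import MAX_CHANNELS, TimeSeriesRecord

LABEL_TABLE_COLUMNS = ["patient_id", "record_id", "channel_index", "label", "source"]
LABEL_SOURCES = ("centroid", "propagated", "corrected", "expert")
#: directory names accepted by save_spectrogram_png: the binary classes plus
#: the six channel labels.
IMAGE_CLASS_LABELS = ("sz", "nsz") + CHANNEL_LABELS


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".csv"), base.with_suffix(".json")


def write_record(record: TimeSeriesRecord, path: str | Path) -> Path:
    """Write one record as ``<path>.csv`` plus ``<path>.json`` sidecar."""
    csv_path, json_path = _paths(path)
    cols = {"sample_index": np.arange(record.n_samples)}
    for row, ch in enumerate(record.channel_indices):
        cols[f"ch{ch + 1}"] = record.data[row]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "patient_id": record.patient_id,
        "record_id": record.record_id,
        "record_type": record.record_type,
        "trigger_sample": record.trigger_sample,
        "sampling_rate": record.sampling_rate,
        "channel_indices": list(record.channel_indices),
    }
    json_path.write_text(json.dumps(meta, indent=1) + "\n")
    return csv_path


def read_record(path: str | Path) -> TimeSeriesRecord:
    """Read a record written by :func:`write_record`.

    Raises ``ValueError`` naming the offending field on malformed input and
    rejects tables with more than four channel columns.
    """
    csv_path, json_path = _paths(path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not json_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {json_path}")
    df = pd.read_csv(csv_path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if not ch_cols:
        raise ValueError(f"{csv_path}: no channel columns (ch1..ch4) found")
    if len(ch_cols) > MAX_CHANNELS:
        raise ValueError(f"{csv_path}: {len(ch_cols)} channel columns, at most {MAX_CHANNELS} allowed")
    try:
        indices = tuple(int(c[2:]) - 1 for c in ch_cols)
    except ValueError as e:
        raise ValueError(f"{csv_path}: bad channel column name: {e}") from e
    meta = json.loads(json_path.read_text())
    for key in ("patient_id", "record_id", "record_type"):
        if key not in meta:
            raise ValueError(f"{json_path}: missing field '{key}'")
    data = df[ch_cols].to_numpy(dtype=float).T
    return TimeSeriesRecord(
        patient_id=meta["patient_id"],
        record_id=meta["record_id"],
        data=data,
        channel_indices=indices,
        trigger_sample=meta.get("trigger_sample"),
        record_type=meta["record_type"],
        sampling_rate=meta.get("sampling_rate", 250),
    )


def image_path(root: str | Path, class_label: str, patient_id: str,
               record_id: str, channel_index: int) -> Path:
    """Deterministic PNG location: root/class/patient/{record}_ch{k}.png."""
    if class_label not in IMAGE_CLASS_LABELS:
        raise ValueError(
            f"unknown class label '{class_label}'; expected one of {IMAGE_CLASS_LABELS}")
    return Path(root) / class_label / patient_id / f"{record_id}_ch{channel_index}.png"


def save_spectrogram_png(image, root: str | Path, class_label: str,
                         patient_id: str, record_id: str, channel_index: int) -> Path:
    """Save a spectrogram image (pixels in [-1, 1]) as 8-bit RGB PNG.

    Pixel ``p`` is stored as ``round((p + 1) / 2 * 255)``, so a save/load
    round trip is exact to within one quantisation step (2/255 on the
    [-1, 1] scale).
    """
    pixels = np.asarray(image.pixels if hasattr(image, "pixels") else image, dtype=float)
    if pixels.min() < -1.0 - 1e-9 or pixels.max() > 1.0 + 1e-9:
        raise ValueError("pixel range must lie within [-1, 1]")
    path = image_path(root, class_label, patient_id, record_id, channel_index)
    path.parent.mkdir(parents=True, exist_ok=True)
    u8 = np.rint((pixels + 1.0) / 2.0 * 255.0).astype(np.uint8)
    Image.fromarray(u8, mode="RGB").save(path)
    return path


def load_spectrogram_png(path: str | Path) -> np.ndarray:
    """Load a PNG back onto the [-1, 1] pixel scale."""
    u8 = np.asarray(Image.open(path).convert("RGB"), dtype=float)
    return u8 / 255.0 * 2.0 - 1.0


def _validate_label_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LABEL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"label table missing columns {missing}")
    bad = sorted(set(table["label"]) - set(CHANNEL_LABELS))
    if bad:
        raise ValueError(
            f"unknown labels {bad}; valid labels are {list(CHANNEL_LABELS)}")
    bad_src = sorted(set(table["source"]) - set(LABEL_SOURCES))
    if bad_src:
        raise ValueError(f"unknown label sources {bad_src}; valid: {list(LABEL_SOURCES)}")
    keys = table[["patient_id", "record_id", "channel_index"]]
    dup = keys.duplicated()
    if dup.any():
        first = keys[dup].iloc[0].tolist()
        raise ValueError(f"duplicate (patient, record, channel) key: {first}")
    return table


def write_label_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    _validate_label_table(table)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_label_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path), dtype={"patient_id": str, "record_id": str})
    if table.empty and "label" not in table.columns:
        raise ValueError(f"{path}: not a label table (missing header)")
    if table.empty:
        return table
    table["channel_index"] = table["channel_index"].astype(int)
    return _validate_label_table(table)
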