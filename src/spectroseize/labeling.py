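"""Six-label channel schema, centroid label propagation, review ordering,
binary class mapping, and labeler agreement.

The semi-supervised workflow: a human labels only each cluster's centroid
record; every other member is pre-assigned the centroid's channel labels;
members are then reviewed in ascending distance from the centroid, fifteen
thumbnails per page, and corrected where the pre-assignment is wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The six channel labels used by the human labelers.
CHANNEL_LABELS = (
    "ictal",
    "interictal",
    "baseline",
    "noise",
    "low_voltage_fast_only",
    "unsure",
)

#: Binary classes for classifier training. 'unsure' channels are excluded
#: from training, validation and testing.
BINARY_CLASSES = ("sz", "nsz", "excluded")

_TO_BINARY = {
    "ictal": "sz",
    "interictal": "nsz",
    "baseline": "nsz",
    "noise": "nsz",
    "low_voltage_fast_only": "nsz",
    "unsure": "excluded",
}

PAGE_SIZE = 15


def to_binary(label: str) -> str:
    """Map a channel label to its training class (total and deterministic)."""
    try:
        return _TO_BINARY[label]
    except KeyError:
        raise ValueError(f"unknown label '{label}'; valid labels: {list(CHANNEL_LABELS)}") from None


def record_binary_label(channel_labels) -> str:
    """Record-level class by OR over channels: seizure iff any channel ictal.

    Channels mapping to 'excluded' do not contribute; a record whose every
    channel is excluded is itself excluded.
    """
    classes = [to_binary(l) for l in channel_labels]
    if any(c == "sz" for c in classes):
        return "sz"
    if any(c == "nsz" for c in classes):
        return "nsz"
    return "excluded"


def propagate_labels(
    patient_id: str,
    member_ids: list[str],
    centroid_id: str,
    centroid_labels: dict[int, str],
) -> pd.DataFrame:
    """Pre-assign every cluster member the centroid's per-channel labels.

    Returns label-table rows: the centroid's own rows carry
    ``source='centroid'``, all other members ``source='propagated'``.
    """
    if centroid_id not in member_ids:
        raise ValueError(f"centroid {centroid_id!r} is not a cluster member")
    if not centroid_labels:
        raise ValueError("centroid has no labeled channels")
    for ch, lab in centroid_labels.items():
        if lab not in CHANNEL_LABELS:
            raise ValueError(f"centroid channel {ch} has unknown label '{lab}'")
    rows = []
    for rid in member_ids:
        src = "centroid" if rid == centroid_id else "propagated"
        for ch in sorted(centroid_labels):
            rows.append((patient_id, rid, ch, centroid_labels[ch], src))
    return pd.DataFrame(rows, columns=["patient_id", "record_id", "channel_index", "label", "source"])


@dataclass
class ReviewQueue:
    """Cluster members ordered by ascending distance to the centroid record,
    paginated fifteen thumbnails per page."""

    ordered_ids: list[str]
    distances: list[float]
    page_size: int = PAGE_SIZE

    @property
    def n_pages(self) -> int:
        return math.ceil(len(self.ordered_ids) / self.page_size)

    def page(self, i: int) -> list[str]:
        if not 0 <= i < self.n_pages:
            raise IndexError(f"page {i} out of range (0..{self.n_pages - 1})")
        return self.ordered_ids[i * self.page_size:(i + 1) * self.page_size]

    @property
    def pages(self) -> list[list[str]]:
        return [self.page(i) for i in range(self.n_pages)]


def build_review_queue(points: pd.DataFrame, member_ids: list[str],
                       centroid_id: str, page_size: int = PAGE_SIZE) -> ReviewQueue:
    """Order cluster members by Euclidean distance to the centroid record's
    2-D embedding point; ties broken by record_id so the order is stable."""
    pts = points.set_index("record_id")
    if centroid_id not in pts.index:
        raise ValueError(f"centroid {centroid_id!r} has no embedding point")
    cx, cy = pts.loc[centroid_id, ["x", "y"]]
    rows = []
    for rid in member_ids:
        x, y = pts.loc[rid, ["x", "y"]]
        rows.append((float(np.hypot(x - cx, y - cy)), rid))
    rows.sort(key=lambda r: (r[0], r[1]))
    return ReviewQueue([r[1] for r in rows], [r[0] for r in rows], page_size)


def apply_correction(table: pd.DataFrame, patient_id: str, record_id: str,
                     channel_index: int, new_label: str) -> pd.DataFrame:
    """Manually correct one channel label, keeping the prior value in an
    audit column (``previous_label``) and marking ``source='corrected'``."""
    if new_label not in CHANNEL_LABELS:
        raise ValueError(f"unknown label '{new_label}'; valid labels: {list(CHANNEL_LABELS)}")
    out = table.copy()
    if "previous_label" not in out.columns:
        out["previous_label"] = pd.NA
    mask = (
        (out["patient_id"] == patient_id)
        & (out["record_id"] == record_id)
        & (out["channel_index"] == channel_index)
    )
    if not mask.any():
        raise KeyError(f"no row for ({patient_id}, {record_id}, ch{channel_index})")
    out.loc[mask, "previous_label"] = out.loc[mask, "label"]
    out.loc[mask, "label"] = new_label
    out.loc[mask, "source"] = "corrected"
    return out


def labeler_agreement(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      level: str = "record") -> tuple[float, pd.DataFrame]:
    """Percent agreement between two labelers on the seizure/non-seizure class.

    Rows whose label maps to 'excluded' (the 'unsure' label) are dropped from
    both tables first; the remaining key sets must then match exactly.
    At ``level='record'`` channel labels are combined by the OR rule before
    comparison. Returns ``(percentage to one decimal, disagreement table)``.
    """
    if level not in ("channel", "record"):
        raise ValueError("level must be 'channel' or 'record'")
    keys = ["patient_id", "record_id"] + (["channel_index"] if level == "channel" else [])

    def prep(t: pd.DataFrame) -> pd.Series:
        t = t.copy()
        t["cls"] = t["label"].map(to_binary) if t["label"].isin(CHANNEL_LABELS).all() \
            else t["label"]
        t = t[t["cls"] != "excluded"]
        if level == "record":
            s = t.groupby(["patient_id", "record_id"])["cls"].agg(
                lambda c: "sz" if (c == "sz").any() else "nsz")
        else:
            s = t.set_index(keys)["cls"]
        return s

    a, b = prep(table_a), prep(table_b)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"key sets differ: {len(only_a)} only in A (e.g. {list(only_a[:3])}), "
            f"{len(only_b)} only in B (e.g. {list(only_b[:3])})")
    joined = pd.DataFrame({"a": a, "b": b})
    match = (joined["a"] == joined["b"]).sum()
    pct = round(100.0 * match / len(joined), 1)
    disagreements = joined[joined["a"] != joined["b"]].reset_index()
    return pct, disagreements
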