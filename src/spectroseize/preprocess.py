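"""Stimulation-artifact rejection, record-length normalisation, 60 Hz notch.

Responsive stimulation blanks the amplifier, writing runs of a constant
blank value into the trace, followed by a brief recovery transient. Blank
runs are detected, extended by a 10-sample leading and 30-sample trailing
margin (to cover the recovery artifact), merged where the extended regions
overlap, and the flanking data concatenated over the gap.

Length normalisation targets 90 s (22,500 samples at 250 Hz): records under
80 s are grown to 90 s by prepending a duplicate of their start (or zeros),
records over 100 s are cropped to the 60 s before / 30 s after the storage
trigger, and records of 80-100 s pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import SAMPLING_RATE_HZ, TimeSeriesRecord

DEFAULT_MIN_BLANK_RUN = 5  # 20 ms: device blanking, not a natural zero crossing
PRE_MARGIN = 10
POST_MARGIN = 30


@dataclass(frozen=True)
class BlankRegion:
    """Half-open run [start, end) of samples equal to the blank value."""

    start: int
    end: int
    channel_index: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("BlankRegion requires start < end")


@dataclass(frozen=True)
class LengthPolicy:
    """Thresholds for length normalisation (all in seconds)."""

    short_threshold_s: float = 80.0
    long_threshold_s: float = 100.0
    target_s: float = 90.0
    pre_trigger_s: float = 60.0
    post_trigger_s: float = 30.0
    short_mode: str = "duplicate_prepend"  # or "zero_pad"

    def __post_init__(self):
        if self.pre_trigger_s + self.post_trigger_s != self.target_s:
            raise ValueError("pre_trigger_s + post_trigger_s must equal target_s")
        if self.short_mode not in ("duplicate_prepend", "zero_pad"):
            raise ValueError("short_mode must be 'duplicate_prepend' or 'zero_pad'")

    @property
    def target_samples(self) -> int:
        return int(round(self.target_s * SAMPLING_RATE_HZ))


def detect_blank_regions(channel_samples: np.ndarray, blank_value: float = 0.0,
                         min_run: int = DEFAULT_MIN_BLANK_RUN,
                         channel_index: int = 0) -> list[BlankRegion]:
    """Maximal runs of >= ``min_run`` consecutive samples exactly equal to
    ``blank_value``."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    x = np.asarray(channel_samples)
    eq = np.concatenate([[False], x == blank_value, [False]])
    d = np.diff(eq.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [BlankRegion(int(s), int(e), channel_index)
            for s, e in zip(starts, ends) if e - s >= min_run]


def _extended_merged(regions: list[BlankRegion], n: int,
                     pre: int = PRE_MARGIN, post: int = POST_MARGIN) -> list[tuple[int, int]]:
    """Extend each region by the margins, clip to the record, merge overlaps."""
    ext = sorted((max(r.start - pre, 0), min(r.end + post, n)) for r in regions)
    merged: list[tuple[int, int]] = []
    for s, e in ext:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def reject_stimulation_artifacts(channel_samples: np.ndarray,
                                 regions: list[BlankRegion],
                                 pre: int = PRE_MARGIN,
                                 post: int = POST_MARGIN) -> np.ndarray:
    """Remove blank regions plus margins and concatenate the flanking data.

    Margins are applied per merged artifact train (never double-counted) and
    clipped at the record edges, so the output length is the input length
    minus the total extent of the merged, extended regions.
    """
    x = np.asarray(channel_samples)
    n = x.shape[0]
    for r in regions:
        if r.start < 0 or r.end > n:
            raise ValueError(f"region [{r.start}, {r.end}) outside record of {n} samples")
    keep = np.ones(n, dtype=bool)
    for s, e in _extended_merged(regions, n, pre, post):
        keep[s:e] = False
    return x[keep]


def reject_record_artifacts(record: TimeSeriesRecord, blank_value: float = 0.0,
                            min_run: int = DEFAULT_MIN_BLANK_RUN) -> TimeSeriesRecord:
    """Detect and reject stimulation artifacts on every channel of a record.

    Channels are cut with a common mask (union of per-channel artifact
    regions) so they stay sample-aligned; the trigger index is shifted by
    the number of samples removed before it.
    """
    n = record.n_samples
    all_regions: list[BlankRegion] = []
    for row in range(record.n_channels):
        all_regions.extend(detect_blank_regions(record.data[row], blank_value, min_run, row))
    keep = np.ones(n, dtype=bool)
    for s, e in _extended_merged(all_regions, n):
        keep[s:e] = False
    trigger = record.trigger_sample
    if trigger is not None:
        trigger = int(keep[:trigger].sum())
    return record.with_data(record.data[:, keep], trigger_sample=trigger)


def normalize_length(record: TimeSeriesRecord,
                     policy: LengthPolicy = LengthPolicy()) -> TimeSeriesRecord:
    """Normalise a record to the 90 s training length.

    * shorter than 80 s: prepend the first ``d`` samples of the record
      (``d`` = disparity to 22,500; tiled if the record is shorter than the
      disparity) or ``d`` zeros under ``zero_pad``;
    * longer than 100 s: keep the 60 s before and 30 s after the trigger,
      shifted inward where the trigger sits near an edge;
    * 80-100 s: unchanged.
    """
    fs = record.sampling_rate
    n = record.n_samples
    target = policy.target_samples
    if n == 0:
        raise ValueError("empty record")
    if n < policy.short_threshold_s * fs:
        d = target - n
        if policy.short_mode == "zero_pad":
            prefix = np.zeros((record.n_channels, d))
        else:
            reps = int(np.ceil(d / n))
            prefix = np.tile(record.data, (1, reps))[:, :d]
        trigger = record.trigger_sample
        data = np.concatenate([prefix, record.data], axis=1)
        return record.with_data(data, trigger_sample=None if trigger is None else trigger + d)
    if n > policy.long_threshold_s * fs:
        if record.trigger_sample is None:
            raise ValueError("cropping a long record requires a trigger_sample")
        start = record.trigger_sample - int(policy.pre_trigger_s * fs)
        start = min(max(start, 0), n - target)
        data = record.data[:, start:start + target]
        return record.with_data(data, trigger_sample=record.trigger_sample - start)
    return record


def notch_60hz(channel_samples: np.ndarray, fs: int = SAMPLING_RATE_HZ,
               quality: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at 60 Hz (for mains-contaminated
    scalp EEG; device ECoG does not need it)."""
    b, a = sps.iirnotch(60.0, quality, fs=fs)
    x = np.asarray(channel_samples, dtype=float)
    if x.size == 0:
        return x.copy()
    return sps.filtfilt(b, a, x)
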