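"""Core in-memory containers for intracranial ECoG records.

An ECoG record, as captured by a responsive-neurostimulation device, holds up
to four channels sampled at 250 Hz, lasts 30-180 s (typically 90 s), and may
carry a storage-trigger index marking the device detection that caused the
record to be saved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SAMPLING_RATE_HZ = 250
MAX_CHANNELS = 4

RECORD_TYPES = ("LE", "scheduled", "magnet", "saturation")


@dataclass
class TimeSeriesRecord:
    """One multichannel ECoG record.

    Parameters
    ----------
    patient_id, record_id
        Identifiers; file naming downstream is a pure function of these.
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    channel_indices
        Hardware channel slots (0-based, < 4) each row of ``data`` occupies.
        Absent slots are zero-filled later in the feature pipeline.
    trigger_sample
        0-based index of the storage trigger, or ``None`` for records
        (e.g. scheduled ones) stored without a detection.
    record_type
        One of ``LE`` (long episode), ``scheduled``, ``magnet``,
        ``saturation``.
    """

    patient_id: str
    record_id: str
    data: np.ndarray
    channel_indices: tuple[int, ...] = (0, 1, 2, 3)
    trigger_sample: Optional[int] = None
    record_type: str = "LE"
    sampling_rate: int = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        n_ch = self.data.shape[0]
        if not 1 <= n_ch <= MAX_CHANNELS:
            raise ValueError(f"record must have 1-{MAX_CHANNELS} channels, got {n_ch}")
        if len(self.channel_indices) != n_ch:
            raise ValueError("channel_indices must match number of data rows")
        if any(not 0 <= c < MAX_CHANNELS for c in self.channel_indices):
            raise ValueError("channel indices must lie in [0, 4)")
        if len(set(self.channel_indices)) != n_ch:
            raise ValueError("channel indices must be unique")
        if self.record_type not in RECORD_TYPES:
            raise ValueError(f"record_type must be one of {RECORD_TYPES}")
        if self.sampling_rate != SAMPLING_RATE_HZ:
            raise ValueError(f"sampling_rate must be {SAMPLING_RATE_HZ} Hz")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, trigger_sample: Optional[int] = None) -> "TimeSeriesRecord":
        """Copy of this record with new samples (and optionally new trigger)."""
        out = replace(self, data=data)
        out.trigger_sample = trigger_sample if trigger_sample is not None else self.trigger_sample
        return out


@dataclass
class GroundTruth:
    """Simulator truth attached to a synthetic record.

    ``channel_labels`` maps each present channel slot to one of the six
    channel labels; ``seizure_spans`` maps seizure-bearing slots to the
    half-open ``(onset, offset)`` sample interval of the inserted discharge;
    ``morphology`` is the index of the patient seizure template used, or
    ``None`` when no seizure was inserted.
    """

    channel_labels: dict[int, str] = field(default_factory=dict)
    seizure_spans: dict[int, tuple[int, int]] = field(default_factory=dict)
    morphology: Optional[int] = None
    seizure_freq_span_hz: Optional[tuple[float, float]] = None

    @property
    def has_seizure(self) -> bool:
        return bool(self.seizure_spans)
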