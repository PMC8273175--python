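"""Synthetic multi-patient ECoG generator.

Emulates the statistical structure of ambulatory ECoG captured by a
responsive neurostimulator: variable-length records (90 s dominant),
patient-stereotyped electrographic seizures (evolving rhythmic discharges
lasting at least 10 s, realised as a logarithmic frequency chirp with a
sigmoidal amplitude envelope), interictal spikes (biphasic ~70 ms sharp
transients), low-voltage-fast onsets, background rhythm plus broadband
noise, and stimulation artifacts (a block of blanked samples followed by a
decaying amplifier-recovery transient).

This is signal-level emulation for pipeline testing, not neural mass
modelling: waveform amplitudes are free parameters chosen to look plausible
on a microvolt scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .records import SAMPLING_RATE_HZ, GroundTruth, TimeSeriesRecord

MIN_LENGTH_S = 30
MAX_LENGTH_S = 180
MIN_SEIZURE_S = 10.0
SPIKE_WIDTH_S = 0.07  # biphasic sharp transient ~70 ms

DEFAULT_BLANK_VALUE = 0.0


@dataclass(frozen=True)
class SeizureMorphology:
    """One patient-stereotyped seizure template.

    A seizure is a logarithmic chirp from ``f0_hz`` to ``f1_hz`` (2-4x the
    background rhythm) whose amplitude grows sigmoidally to
    ``amplitude_factor`` times the background scale, on the channels in
    ``channel_mask``.
    """

    f0_hz: float
    f1_hz: float
    duration_s: float
    amplitude_factor: float
    channel_mask: tuple[int, ...]
    lvf_onset: bool = False

    def __post_init__(self):
        if self.duration_s < MIN_SEIZURE_S:
            raise ValueError(f"seizure template must last >= {MIN_SEIZURE_S} s")


@dataclass
class PatientArchetype:
    """Generative parameters for one synthetic patient.

    Seizure morphologies are stereotyped within a patient: the templates are
    derived deterministically from ``seed`` so every record drawn from the
    archetype reuses the same small library of discharge shapes.

    Non-seizure records are not quiet: channels carry interictal spikes and
    short (< 10 s, non-evolving) rhythmic bursts whose peak power matches
    seizure activity, occasional broadband noise channels, and occasional
    low-voltage-fast activity without a following discharge. This keeps the
    seizure/non-seizure distinction in the *evolving, sustained* structure
    of the discharge rather than in mere image contrast.
    """

    patient_id: str
    n_seizure_morphologies: int = 2
    seizure_rate: float = 0.35
    spike_rate: float = 6.0  # interictal events / minute
    base_freq_hz: float = 8.0
    noise_level: float = 20.0  # microvolts RMS of broadband background
    seed: int = 0
    n_channels: int = 4
    burst_rate: float = 0.35  # per-channel chance of interictal burst trains
    noise_channel_rate: float = 0.08  # per-record chance of a 'noise' channel
    lvf_channel_rate: float = 0.05  # per-record chance of an LVF-only channel
    morphologies: tuple[SeizureMorphology, ...] = field(default=None, repr=False)
    #: stereotyped interictal burst template (freq Hz, duration s, amplitude
    #: factor); like seizures, interictal activity repeats a patient-typical
    #: shape. Derived from ``seed`` when left unset.
    burst_template: tuple[float, float, float] = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_seizure_morphologies < 1:
            raise ValueError("n_seizure_morphologies must be >= 1")
        if not 0.0 <= self.seizure_rate <= 1.0:
            raise ValueError("seizure_rate must lie in [0, 1]")
        if not 1 <= self.n_channels <= 4:
            raise ValueError("n_channels must lie in [1, 4]")
        if self.morphologies is None:
            self.morphologies = self._draw_morphologies()
        if self.burst_template is None:
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xB525]))
            self.burst_template = (
                float(self.base_freq_hz * rng.uniform(1.5, 3.5)),
                float(rng.uniform(2.0, 6.0)),
                float(rng.uniform(3.5, 5.5)),
            )

    def _draw_morphologies(self) -> tuple[SeizureMorphology, ...]:
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xEC06]))
        temps = []
        for m in range(self.n_seizure_morphologies):
            chirp_factor = rng.uniform(2.0, 4.0)
            n_sz_ch = int(rng.integers(1, self.n_channels + 1))
            mask = tuple(sorted(rng.choice(self.n_channels, size=n_sz_ch, replace=False).tolist()))
            temps.append(
                SeizureMorphology(
                    f0_hz=self.base_freq_hz * rng.uniform(0.8, 1.2),
                    f1_hz=self.base_freq_hz * chirp_factor,
                    duration_s=float(rng.uniform(14.0, 30.0)),
                    amplitude_factor=float(rng.uniform(3.5, 6.0)),
                    channel_mask=mask,
                    lvf_onset=bool(rng.random() < 0.3),
                )
            )
        return tuple(temps)


def _background(n: int, base_freq_hz: float, noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Ongoing rhythm + 1/f-ish broadband noise, microvolt scale."""
    t = np.arange(n) / SAMPLING_RATE_HZ
    phase = rng.uniform(0, 2 * np.pi)
    rhythm = 0.8 * noise_level * np.sin(2 * np.pi * base_freq_hz * t + phase)
    # low-passed white noise approximates the spectral roll-off of field potentials
    white = rng.standard_normal(n)
    b, a = sps.butter(2, 40 / (SAMPLING_RATE_HZ / 2), btype="low")
    colored = sps.lfilter(b, a, white)
    sd = colored.std()
    if sd > 0:
        colored = colored / sd
    return rhythm + noise_level * colored


def _spike_kernel() -> np.ndarray:
    """Biphasic sharp transient: positive lobe then undershoot, ~70 ms."""
    n = int(round(SPIKE_WIDTH_S * SAMPLING_RATE_HZ))
    t = np.linspace(-1.0, 1.0, n)
    return np.sin(np.pi * t) * np.exp(-3.0 * t * t) * -1.0


def _seizure_waveform(m: SeizureMorphology, noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Evolving rhythmic discharge: log chirp with sigmoidal amplitude growth."""
    n = int(round(m.duration_s * SAMPLING_RATE_HZ))
    t = np.arange(n) / SAMPLING_RATE_HZ
    carrier = sps.chirp(t, f0=m.f0_hz, f1=m.f1_hz, t1=m.duration_s, method="logarithmic",
                        phi=float(rng.uniform(0, 360)))
    # sigmoid rise over the first third, cosine taper over the final 10%
    rise = 1.0 / (1.0 + np.exp(-(t - m.duration_s / 4) / (m.duration_s / 12)))
    n_tail = max(int(0.1 * n), 1)
    taper = np.ones(n)
    taper[-n_tail:] = 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_tail)))
    wave = m.amplitude_factor * noise_level * carrier * rise * taper
    if m.lvf_onset:
        n_lvf = int(3.0 * SAMPLING_RATE_HZ)
        t_lvf = np.arange(n_lvf) / SAMPLING_RATE_HZ
        lvf = 0.6 * noise_level * np.sin(2 * np.pi * 45.0 * t_lvf + rng.uniform(0, 2 * np.pi))
        wave = np.concatenate([lvf, wave])
    return wave


def _interictal_burst(template: tuple[float, float, float], noise_level: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Short (< 10 s) patient-stereotyped rhythmic burst.

    Peak power is in the seizure range, but the burst neither evolves nor
    satisfies the >= 10 s rule, so its channel stays 'interictal'. Frequency,
    duration and amplitude follow the patient's burst template with ~10%
    per-event jitter.
    """
    freq0, dur0, amp0 = template
    dur = dur0 * rng.uniform(0.9, 1.1)
    n = int(round(dur * SAMPLING_RATE_HZ))
    t = np.arange(n) / SAMPLING_RATE_HZ
    freq = freq0 * rng.uniform(0.95, 1.05)
    env = np.sin(np.pi * np.linspace(0, 1, n)) ** 0.5
    amp = amp0 * rng.uniform(0.9, 1.1) * noise_level
    return amp * env * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def _noise_burst(noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Broadband high-amplitude noise burst (electrode/connection artifact)."""
    dur = float(rng.uniform(2.0, 10.0))
    n = int(round(dur * SAMPLING_RATE_HZ))
    env = np.sin(np.pi * np.linspace(0, 1, n)) ** 0.5
    return rng.uniform(6.0, 10.0) * noise_level * env * rng.standard_normal(n)


def _lvf_burst(noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Low-voltage fast activity: low-amplitude 40-60 Hz run, a few seconds."""
    dur = float(rng.uniform(3.0, 8.0))
    n = int(round(dur * SAMPLING_RATE_HZ))
    t = np.arange(n) / SAMPLING_RATE_HZ
    freq = rng.uniform(40.0, 60.0)
    env = np.sin(np.pi * np.linspace(0, 1, n)) ** 0.5
    return 0.7 * noise_level * env * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def _add_at_random(data_row: np.ndarray, wave: np.ndarray,
                   rng: np.random.Generator) -> tuple[int, int]:
    n = data_row.shape[0]
    if wave.size >= n:
        wave = wave[:n - 1]
    at = int(rng.integers(0, n - wave.size))
    data_row[at:at + wave.size] += wave
    return at, at + wave.size


def insert_stimulation_artifact(
    channel_samples: np.ndarray,
    at_sample: int,
    blank_len: int,
    rng: np.random.Generator,
    blank_value: float = DEFAULT_BLANK_VALUE,
    recovery_len: int = 50,
    recovery_amplitude: float = 150.0,
) -> np.ndarray:
    """Insert a device stimulation artifact in place.

    The device blanks its amplifier during stimulation: ``blank_len`` samples
    at ``at_sample`` are overwritten with the exact ``blank_value``, followed
    by a decaying recovery transient of ``recovery_len`` samples riding on
    the signal.

    Returns a new array; the input is not modified.
    """
    n = channel_samples.shape[0]
    if at_sample < 0 or at_sample + blank_len > n:
        raise ValueError(
            f"blank [{at_sample}, {at_sample + blank_len}) exceeds record of {n} samples"
        )
    out = channel_samples.copy()
    if blank_len == 0:
        return out
    out[at_sample:at_sample + blank_len] = blank_value
    rec_end = min(at_sample + blank_len + recovery_len, n)
    m = rec_end - (at_sample + blank_len)
    if m > 0:
        t = np.arange(m)
        transient = recovery_amplitude * np.exp(-t / (recovery_len / 4.0)) * np.cos(
            2 * np.pi * 20.0 * t / SAMPLING_RATE_HZ + rng.uniform(0, 2 * np.pi)
        )
        out[at_sample + blank_len:rec_end] += transient
    return out


def simulate_record(
    archetype: PatientArchetype,
    length_s: float = 90.0,
    record_type: str = "LE",
    rng: np.random.Generator | None = None,
    record_id: str = "R0000",
    n_stim_artifacts: int = 0,
) -> tuple[TimeSeriesRecord, GroundTruth]:
    """Simulate one labelled ECoG record drawn from a patient archetype.

    A seizure is inserted with probability ``archetype.seizure_rate``; its
    template is chosen uniformly from the patient's morphology library and
    always lasts >= 10 s. For LE records the trigger index is placed inside
    the abnormal activity. Channels without a seizure carry interictal spikes
    (Poisson at ``spike_rate``/min) or plain background.
    """
    if not MIN_LENGTH_S <= length_s <= MAX_LENGTH_S:
        raise ValueError(f"length_s must lie in [{MIN_LENGTH_S}, {MAX_LENGTH_S}] s")
    if rng is None:
        rng = np.random.default_rng(archetype.seed)
    n = int(round(length_s * SAMPLING_RATE_HZ))
    n_ch = archetype.n_channels

    data = np.stack([
        _background(n, archetype.base_freq_hz, archetype.noise_level, rng)
        for _ in range(n_ch)
    ])
    truth = GroundTruth(channel_labels={c: "baseline" for c in range(n_ch)})

    noise_ch = int(rng.integers(0, n_ch)) if rng.random() < archetype.noise_channel_rate else None
    lvf_ch = int(rng.integers(0, n_ch)) if rng.random() < archetype.lvf_channel_rate else None
    if lvf_ch == noise_ch:
        lvf_ch = None
    if noise_ch is not None:
        for _ in range(int(rng.integers(1, 3))):
            _add_at_random(data[noise_ch], _noise_burst(archetype.noise_level, rng), rng)
        truth.channel_labels[noise_ch] = "noise"
    if lvf_ch is not None:
        _add_at_random(data[lvf_ch], _lvf_burst(archetype.noise_level, rng), rng)
        truth.channel_labels[lvf_ch] = "low_voltage_fast_only"

    # interictal spikes and short rhythmic bursts, per channel
    kernel = _spike_kernel()
    spike_amp = 4.0 * archetype.noise_level
    for c in range(n_ch):
        if c == noise_ch or c == lvf_ch:
            continue
        n_spikes = rng.poisson(archetype.spike_rate * length_s / 60.0)
        for _ in range(n_spikes):
            at = int(rng.integers(0, n - kernel.size))
            data[c, at:at + kernel.size] += spike_amp * rng.uniform(0.7, 1.3) * kernel
        n_bursts = 0
        if rng.random() < archetype.burst_rate:
            n_bursts = int(rng.integers(1, 4))
            for _ in range(n_bursts):
                _add_at_random(data[c], _interictal_burst(
                    archetype.burst_template, archetype.noise_level, rng), rng)
        if n_spikes > 0 or n_bursts > 0:
            truth.channel_labels[c] = "interictal"

    trigger = None
    if rng.random() < archetype.seizure_rate:
        m_idx = int(rng.integers(0, len(archetype.morphologies)))
        morph = archetype.morphologies[m_idx]
        wave = _seizure_waveform(morph, archetype.noise_level, rng)
        if wave.size > n:
            wave = wave[:n]
        # The device stores LE records around the detection: ~60 s before and
        # ~30 s after the trigger for a 90 s record (2/3 of the record before
        # the trigger in general), so discharges are roughly aligned in time
        # across records. Detection fires a few seconds after onset.
        detect_delay = int(rng.uniform(1.0, 4.0) * SAMPLING_RATE_HZ)
        target_trigger = int(2 * n / 3) + int(rng.uniform(-3.0, 3.0) * SAMPLING_RATE_HZ)
        onset = int(np.clip(target_trigger - detect_delay, 0, n - wave.size))
        for c in morph.channel_mask:
            if c < n_ch:
                jitter = rng.uniform(0.9, 1.1)
                data[c, onset:onset + wave.size] += jitter * wave
                truth.channel_labels[c] = "ictal"
                truth.seizure_spans[c] = (onset, onset + wave.size)
        truth.morphology = m_idx
        truth.seizure_freq_span_hz = (morph.f0_hz, morph.f1_hz)
        trigger = min(onset + detect_delay, onset + wave.size - 1)
    elif record_type == "LE":
        # long episodes without a true seizure: the device triggered on
        # interictal or noise activity; trigger placed at a random spike-rich point
        trigger = int(rng.integers(n // 4, 3 * n // 4))

    for _ in range(n_stim_artifacts):
        blank_len = int(rng.integers(15, 40))
        at = int(rng.integers(0, n - blank_len - 60))
        for c in range(n_ch):
            data[c] = insert_stimulation_artifact(data[c], at, blank_len, rng)

    rec = TimeSeriesRecord(
        patient_id=archetype.patient_id,
        record_id=record_id,
        data=data,
        channel_indices=tuple(range(n_ch)),
        trigger_sample=trigger if record_type == "LE" else None,
        record_type=record_type,
    )
    return rec, truth


def _draw_length_s(rng: np.random.Generator) -> float:
    """Record length mix: 90 s dominant, with short and long tails."""
    u = rng.random()
    if u < 0.70:
        return 90.0
    if u < 0.85:
        return float(rng.uniform(MIN_LENGTH_S, 80.0))
    return float(rng.uniform(100.0, MAX_LENGTH_S))


def generate_dataset(
    archetypes: list[PatientArchetype],
    records_per_patient: int,
    seed: int,
    out_dir: str | Path | None = None,
    length_s: float | None = 90.0,
    stim_artifact_rate: float = 0.0,
) -> tuple[list[tuple[TimeSeriesRecord, GroundTruth]], "object"]:
    """Generate a labelled multi-patient dataset, optionally writing it to disk.

    Returns ``(records, label_table)`` where ``label_table`` is the
    ground-truth channel-label table (a pandas DataFrame in io_formats
    layout). When ``out_dir`` is given, each record is written as CSV + JSON
    sidecar and the label table as ``labels.csv`` under it.
    ``length_s=None`` draws variable lengths (90 s dominant).
    """
    from . import io as io_formats  # local import to avoid cycle at import time

    if not archetypes:
        raise ValueError("need at least one archetype")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDA7A]))
    records: list[tuple[TimeSeriesRecord, GroundTruth]] = []
    rows = []
    for arch in archetypes:
        for i in range(records_per_patient):
            rid = f"R{i:04d}"
            ln = _draw_length_s(rng) if length_s is None else length_s
            n_art = rng.poisson(stim_artifact_rate) if stim_artifact_rate > 0 else 0
            rec, truth = simulate_record(arch, ln, "LE", rng, record_id=rid,
                                         n_stim_artifacts=int(n_art))
            records.append((rec, truth))
            for c in rec.channel_indices:
                rows.append((arch.patient_id, rid, c, truth.channel_labels[c], "expert"))

    import pandas as pd

    table = pd.DataFrame(rows, columns=["patient_id", "record_id", "channel_index", "label", "source"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        for rec, _ in records:
            pdir = out_dir / rec.patient_id
            pdir.mkdir(parents=True, exist_ok=True)
            io_formats.write_record(rec, pdir / rec.record_id)
        io_formats.write_label_table(table, out_dir / "labels.csv")
    return records, table
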