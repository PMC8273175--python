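"""Simulate a labeled synthetic ECoG dataset and inspect one record.

Builds one patient archetype, draws a few 90 s long-episode records from it,
and prints what the simulator inserted: per-channel labels, seizure spans
(always >= 10 s of evolving rhythmic discharge), and the storage trigger,
which the virtual device places a few seconds after seizure onset.
"""

import numpy as np

import spectroseize as sz

archetype = sz.PatientArchetype("P00", n_seizure_morphologies=2, seizure_rate=0.5,
                                spike_rate=6.0, base_freq_hz=8.0, noise_level=20.0,
                                seed=42)
rng = np.random.default_rng(42)

print(f"patient {archetype.patient_id}: {len(archetype.morphologies)} stereotyped "
      "seizure morphologies")
for i, m in enumerate(archetype.morphologies):
    print(f"  morphology {i}: chirp {m.f0_hz:.1f} -> {m.f1_hz:.1f} Hz over "
          f"{m.duration_s:.0f} s on channels {m.channel_mask}")

for k in range(4):
    record, truth = sz.simulate_record(archetype, length_s=90, record_type="LE",
                                       rng=rng, record_id=f"R{k:04d}")
    print(f"\n{record.record_id}: {record.n_channels} channels x "
          f"{record.n_samples} samples ({record.duration_s:.0f} s), "
          f"trigger at sample {record.trigger_sample}")
    print(f"  channel labels: {truth.channel_labels}")
    for ch, (on, off) in truth.seizure_spans.items():
        print(f"  seizure on ch{ch}: samples [{on}, {off}) = {(off - on) / 250:.1f} s")

# The labels are what a human reviewer would assign per channel; 'ictal'
# channels become the seizure class for classifier training, everything
# except 'unsure' becomes non-seizure.
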