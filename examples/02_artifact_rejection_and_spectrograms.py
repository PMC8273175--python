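"""Stimulation-artifact rejection, length normalisation, spectrogram images.

Inserts a device stimulation artifact (blanked samples + recovery transient)
into a synthetic trace, detects and removes it with the 10-sample-before /
30-sample-after margins, normalises the record length to 90 s, and renders
the two spectrogram image dialects.
"""

import numpy as np

import spectroseize as sz
from spectroseize import preprocess, spectro

rng = np.random.default_rng(7)
archetype = sz.PatientArchetype("P00", seizure_rate=1.0, seed=7)
record, truth = sz.simulate_record(archetype, length_s=90, rng=rng)

# insert a stimulation artifact on every channel at the same time
data = np.stack([sz.insert_stimulation_artifact(row, at_sample=4000, blank_len=25,
                                                rng=rng)
                 for row in record.data])
record = record.with_data(data)

regions = preprocess.detect_blank_regions(record.data[0], blank_value=0.0)
print(f"detected blank regions on ch0: {[(r.start, r.end) for r in regions]}")

clean = preprocess.reject_record_artifacts(record)
removed = record.n_samples - clean.n_samples
print(f"artifact rejection removed {removed} samples "
      f"(25 blank + 10 leading + 30 trailing margin = 65)")

normalised = preprocess.normalize_length(clean)
print(f"length normalisation: {clean.n_samples} -> {normalised.n_samples} samples "
      f"({normalised.n_samples / 250:.0f} s)")

mat = spectro.compute_spectrogram(normalised.data[0])
print(f"spectrogram: {mat.n_freq_bins} frequency bins (0-125 Hz) x "
      f"{mat.n_frames} frames (256-sample window, 128-sample step)")

embed_img = spectro.render_image(mat, dialect="embedding", colormap="grayscale")
cls_img = spectro.render_image(mat, dialect="classifier", colormap="jet")
print(f"embedding dialect: {embed_img.shape}, classifier dialect: {cls_img.shape}, "
      f"pixel range [{cls_img.pixels.min():.2f}, {cls_img.pixels.max():.2f}]")
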