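"""Spectrogram computation and the two image dialects.

Spectrograms use a 256-sample Hann window with a 128-sample step, one-sided
over 0-125 Hz (129 bins at 250 Hz sampling), in dB with a 1e-12 power floor.
Two renderings are used downstream:

* ``embedding`` dialect — 299x299, grayscale replicated to three identical
  channels, for the pretrained feature extractor;
* ``classifier`` dialect — 224x224, jet (or grayscale) colormapped, for CNN
  training.

Both are per-image min-max normalised before colormapping and linearly
scaled to pixel range [-1, 1], which makes them invariant to global
amplitude scaling of the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from scipy import signal as sps

from .records import SAMPLING_RATE_HZ

WINDOW_SIZE = 256
STEP_SIZE = 128
DB_FLOOR = 1e-12

DIALECT_SIZES = {"embedding": 299, "classifier": 224}
COLORMAPS = ("jet", "grayscale")

_JET = matplotlib.colormaps["jet"]


def n_frames(n_samples: int, window: int = WINDOW_SIZE, step: int = STEP_SIZE) -> int:
    """Number of spectrogram time frames for an ``n_samples`` trace."""
    if n_samples < window:
        raise ValueError(f"need at least {window} samples, got {n_samples}")
    return (n_samples - window) // step + 1


@dataclass
class SpectrogramMatrix:
    """Power in dB on a (frequency bin x time frame) grid, 0-125 Hz one-sided."""

    values: np.ndarray  # (n_freq_bins, n_frames)
    freqs_hz: np.ndarray
    times_s: np.ndarray

    @property
    def n_freq_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectrogramImage:
    """Rendered H x W x 3 image with pixels in [-1, 1]."""

    pixels: np.ndarray
    dialect: str
    colormap: str

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


def compute_spectrogram(channel_samples: np.ndarray,
                        fs: int = SAMPLING_RATE_HZ,
                        window: int = WINDOW_SIZE,
                        step: int = STEP_SIZE) -> SpectrogramMatrix:
    """One-sided Hann-window PSD spectrogram in dB.

    Frame count follows ``floor((n - window) / step) + 1``; frequencies span
    0 to the Nyquist frequency (125 Hz at the device sampling rate).
    """
    x = np.asarray(channel_samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel_samples must be 1-D")
    if x.shape[0] < window:
        raise ValueError(
            f"record shorter than one window ({x.shape[0]} < {window} samples)")
    f, t, sxx = sps.spectrogram(
        x, fs=fs, window="hann", nperseg=window, noverlap=window - step,
        mode="psd", detrend=False)
    values = 10.0 * np.log10(np.maximum(sxx, DB_FLOOR))
    return SpectrogramMatrix(values=values, freqs_hz=f, times_s=t)


def _nearest_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbour resize of a 2-D (or 2-D + channel) array."""
    h, w = img.shape[:2]
    rows = np.minimum((np.arange(out_h) * h / out_h).astype(int), h - 1)
    cols = np.minimum((np.arange(out_w) * w / out_w).astype(int), w - 1)
    return img[np.ix_(rows, cols)]


def render_image(spec: SpectrogramMatrix, dialect: str = "classifier",
                 colormap: str = "jet", size: int | None = None) -> SpectrogramImage:
    """Render a spectrogram matrix to an image dialect.

    Values are min-max normalised to [0, 1] per image (a constant matrix
    maps to mid-scale), drawn with low frequencies at the bottom, the
    colormap applied, nearest-neighbour resized, and rescaled to [-1, 1].
    """
    if dialect not in DIALECT_SIZES:
        raise ValueError(f"unknown dialect '{dialect}'; expected {list(DIALECT_SIZES)}")
    if colormap not in COLORMAPS:
        raise ValueError(f"unknown colormap '{colormap}'; expected {list(COLORMAPS)}")
    side = size if size is not None else DIALECT_SIZES[dialect]
    v = np.asarray(spec.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("spectrogram matrix contains non-finite values")
    lo, hi = v.min(), v.max()
    norm = np.full_like(v, 0.5) if hi == lo else (v - lo) / (hi - lo)
    norm = norm[::-1]  # image row 0 = highest frequency
    if colormap == "jet":
        rgb = _JET(norm)[..., :3]
    else:
        rgb = np.repeat(norm[..., None], 3, axis=2)
    rgb = _nearest_resize(rgb, side, side)
    return SpectrogramImage(pixels=rgb * 2.0 - 1.0, dialect=dialect, colormap=colormap)


def time_freq_mask(n_samples: int, t_span_samples: tuple[int, int],
                   f_span_hz: tuple[float, float], side: int,
                   fs: int = SAMPLING_RATE_HZ) -> np.ndarray:
    """Boolean H x W mask of a time-frequency band in rendered-image pixels.

    Maps a sample interval and a frequency band of the underlying trace to
    the corresponding region of a ``side x side`` rendered image (row 0 =
    Nyquist frequency). Used to locate inserted seizure activity in saliency
    maps.
    """
    nyq = fs / 2.0
    t0 = t_span_samples[0] / n_samples
    t1 = t_span_samples[1] / n_samples
    # row 0 is the highest frequency
    r0 = (1.0 - min(f_span_hz[1], nyq) / nyq)
    r1 = (1.0 - max(f_span_hz[0], 0.0) / nyq)
    mask = np.zeros((side, side), dtype=bool)
    rows = slice(int(r0 * side), max(int(np.ceil(r1 * side)), int(r0 * side) + 1))
    cols = slice(int(t0 * side), max(int(np.ceil(t1 * side)), int(t0 * side) + 1))
    mask[rows, cols] = True
    return mask
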