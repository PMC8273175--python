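"""Artifact rejection (against a brute-force oracle), length normalisation,
and the 60 Hz notch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spectroseize as sz
from spectroseize import preprocess as pp
from spectroseize.records import TimeSeriesRecord


def oracle_reject(x, blank_value=0.0, min_run=5, pre=10, post=30):
    """Independent mask-and-compress reference: scan runs, extend, delete."""
    n = len(x)
    keep = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if x[i] == blank_value:
            j = i
            while j < n and x[j] == blank_value:
                j += 1
            if j - i >= min_run:
                keep[max(i - pre, 0):min(j + post, n)] = False
            i = j
        else:
            i += 1
    return x[keep]


class TestDetectBlankRegions:
    def test_clean_signal_yields_nothing(self, rng):
        x = rng.standard_normal(1000) + 2.0
        assert pp.detect_blank_regions(x) == []

    def test_single_run_located_exactly(self):
        x = np.ones(1000)
        x[500:520] = 0.0
        regions = pp.detect_blank_regions(x, 0.0, min_run=5)
        assert [(r.start, r.end) for r in regions] == [(500, 520)]

    def test_nearby_runs_stay_distinct(self):
        x = np.ones(100)
        x[10:20] = 0.0
        x[23:31] = 0.0
        regions = pp.detect_blank_regions(x, 0.0, min_run=5)
        assert [(r.start, r.end) for r in regions] == [(10, 20), (23, 31)]

    def test_runs_below_min_run_ignored(self):
        x = np.ones(100)
        x[10:13] = 0.0
        assert pp.detect_blank_regions(x, 0.0, min_run=5) == []

    def test_min_run_must_be_positive(self):
        with pytest.raises(ValueError):
            pp.detect_blank_regions(np.ones(10), 0.0, min_run=0)


class TestRejectArtifacts:
    def test_no_regions_is_identity(self, rng):
        x = rng.standard_normal(500)
        np.testing.assert_array_equal(pp.reject_stimulation_artifacts(x, []), x)

    def test_interior_blank_removes_margins_too(self):
        """20-sample blank at 500 plus 10/30 margins: 1000 -> 940 samples."""
        x = np.arange(1000, dtype=float) + 1.0
        x[500:520] = 0.0
        regions = pp.detect_blank_regions(x)
        out = pp.reject_stimulation_artifacts(x, regions)
        assert len(out) == 940
        np.testing.assert_array_equal(out, oracle_reject(np.where(x == 0, 0.0, x)))

    def test_leading_blank_clips_front_margin(self):
        """Blank at the record start: only the trailing margin applies."""
        x = np.arange(1000, dtype=float) + 1.0
        x[0:20] = 0.0
        out = pp.reject_stimulation_artifacts(x, pp.detect_blank_regions(x))
        assert len(out) == 1000 - (20 + 30)

    def test_overlapping_extended_regions_merge(self):
        # two blanks 25 samples apart: extensions (10 pre + 30 post) overlap
        x = np.ones(1000)
        x[100:110] = 0.0
        x[135:145] = 0.0
        out = pp.reject_stimulation_artifacts(x, pp.detect_blank_regions(x))
        np.testing.assert_array_equal(out, oracle_reject(x))
        # merged extent [90, 175) = 85 samples, not 2 * 50
        assert len(out) == 1000 - 85

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1900), st.integers(1, 60)), max_size=5),
           st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_blank_patterns(self, blanks, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(2000) + 10.0  # strictly away from 0
        for at, ln in blanks:
            x[at:at + ln] = 0.0
        out = pp.reject_stimulation_artifacts(x, pp.detect_blank_regions(x))
        np.testing.assert_array_equal(out, oracle_reject(x))

    def test_idempotent_after_redetection(self, rng):
        x = rng.standard_normal(2000) + 10.0
        x[300:330] = 0.0
        once = pp.reject_stimulation_artifacts(x, pp.detect_blank_regions(x))
        again = pp.reject_stimulation_artifacts(once, pp.detect_blank_regions(once))
        np.testing.assert_array_equal(once, again)


def _record(n_samples, trigger=None, n_ch=2):
    data = np.tile(np.arange(n_samples, dtype=float), (n_ch, 1))
    data += np.arange(n_ch)[:, None] * 1e5  # channel-distinct values
    return TimeSeriesRecord("P", "R", data, tuple(range(n_ch)),
                            trigger_sample=trigger)


class TestNormalizeLength:
    def test_short_record_duplicate_prepend(self):
        """70 s -> 90 s by prepending the first 5,000 samples."""
        rec = _record(17500)
        out = pp.normalize_length(rec)
        assert out.n_samples == 22500
        np.testing.assert_array_equal(out.data[:, :5000], rec.data[:, :5000])
        np.testing.assert_array_equal(out.data[:, 5000:], rec.data)

    def test_short_record_zero_pad(self):
        rec = _record(17500)
        out = pp.normalize_length(rec, pp.LengthPolicy(short_mode="zero_pad"))
        assert out.n_samples == 22500
        assert np.all(out.data[:, :5000] == 0)
        np.testing.assert_array_equal(out.data[:, 5000:], rec.data)

    def test_very_short_record_tiles_from_start(self):
        """A 30 s record's 15,000-sample disparity re-tiles the record."""
        rec = _record(7500)
        out = pp.normalize_length(rec)
        assert out.n_samples == 22500
        np.testing.assert_array_equal(out.data[:, -7500:], rec.data)
        np.testing.assert_array_equal(out.data[:, :7500], rec.data)

    def test_90s_record_unchanged(self):
        rec = _record(22500, trigger=11000)
        out = pp.normalize_length(rec)
        assert out is rec

    def test_long_record_crops_around_trigger(self):
        """180 s with trigger at 150 s keeps [90 s, 180 s)."""
        rec = _record(45000, trigger=37500)
        out = pp.normalize_length(rec)
        assert out.n_samples == 22500
        np.testing.assert_array_equal(out.data, rec.data[:, 22500:45000])

    def test_long_record_trigger_near_start_clamps(self):
        rec = _record(30000, trigger=1000)
        out = pp.normalize_length(rec)
        assert out.n_samples == 22500
        np.testing.assert_array_equal(out.data, rec.data[:, :22500])

    def test_crop_without_trigger_errors(self):
        with pytest.raises(ValueError, match="trigger"):
            pp.normalize_length(_record(30000))

    @pytest.mark.parametrize("n", [7500, 12000, 19999, 25001, 30000, 45000])
    def test_output_always_22500_outside_passthrough_band(self, n):
        out = pp.normalize_length(_record(n, trigger=n // 2))
        assert out.n_samples == 22500

    @pytest.mark.parametrize("n", [20000, 22500, 25000])
    def test_passthrough_band_unchanged(self, n):
        assert pp.normalize_length(_record(n, trigger=n // 2)).n_samples == n


class TestNotch60:
    def test_60hz_attenuated_20db(self):
        t = np.arange(5000) / 250.0
        x = np.sin(2 * np.pi * 60 * t)
        y = pp.notch_60hz(x)
        core = slice(500, 4500)  # avoid filter edge transients
        assert np.sqrt((y[core] ** 2).mean()) <= 0.1 * np.sqrt((x[core] ** 2).mean())

    def test_10hz_passband_preserved(self):
        t = np.arange(5000) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        y = pp.notch_60hz(x)
        core = slice(500, 4500)
        assert abs(np.sqrt((y[core] ** 2).mean()) / np.sqrt((x[core] ** 2).mean()) - 1) < 0.01

    def test_zero_signal_maps_to_zero(self):
        np.testing.assert_allclose(pp.notch_60hz(np.zeros(1000)), 0.0, atol=1e-12)


def test_record_level_rejection_keeps_channels_aligned(rng):
    arch = sz.PatientArchetype("P00", seed=5, seizure_rate=0.0)
    rec, _ = sz.simulate_record(arch, 90, "LE", rng, n_stim_artifacts=3)
    out = pp.reject_record_artifacts(rec)
    assert out.n_samples < rec.n_samples
    assert out.data.shape[0] == rec.data.shape[0]
    for row in range(out.n_channels):
        assert pp.detect_blank_regions(out.data[row]) == []
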