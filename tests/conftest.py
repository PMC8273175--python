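import numpy as np
import pytest

import spectroseize as sz


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def archetype():
    return sz.PatientArchetype("P00", n_seizure_morphologies=2, seizure_rate=0.4,
                               spike_rate=6.0, base_freq_hz=8.0, noise_level=20.0,
                               seed=7)


@pytest.fixture
def le_record(archetype):
    rec, truth = sz.simulate_record(archetype, 90.0, "LE",
                                    np.random.default_rng(3), record_id="R0001")
    return rec, truth


def make_patient_records(patient_id="P00", n=60, seizure_rate=0.5, seed=11,
                         n_morphologies=2, length_s=90.0):
    arch = sz.PatientArchetype(patient_id, n_seizure_morphologies=n_morphologies,
                               seizure_rate=seizure_rate, seed=seed)
    rng = np.random.default_rng(seed)
    return arch, [sz.simulate_record(arch, length_s, "LE", rng, record_id=f"R{i:04d}")
                  for i in range(n)]
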