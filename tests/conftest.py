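"""Shared fixtures: small synthetic cohorts and envelope-matrix helpers."""

import numpy as np
import pytest

from tkagait import emg, synthetic as sd


@pytest.fixture(scope="session")
def level_truth():
    return sd.default_truth("level")


@pytest.fixture(scope="session")
def stair_truth():
    return sd.default_truth("stair")


def subject_envelope_matrix(spec, truth, subject=0, **emg_kwargs):
    """Generate one subject's EMG, run the full conditioning chain and stack
    the normalized cycles into the 8 x (200 * cycles) matrix NMF consumes."""
    trials = sd.generate_emg(spec, truth, **emg_kwargs)
    cycles = []
    for tr in trials[subject]:
        env = emg.filter_chain(tr.raw.signals, tr.raw.rate)
        cycles.append(emg.time_normalize_200(env, tr.raw.events))
    normed, _ = emg.normalize_amplitude(cycles)
    return np.hstack(normed)
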