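"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from somnoscope import (
    Hypnogram,
    Recording,
    SimParams,
    downsample,
    simulate_hypnogram,
    synthesize_signals,
)

SUSTAIN = 3


def brute_force_effective_labels(labels: np.ndarray) -> np.ndarray:
    """Independent sustain-rule oracle.

    For each epoch i, scan all length-3 homogeneous windows starting at or
    before i; the epoch belongs to the bout opened by the latest such window
    (or to the initial state if none exists yet).  Quadratic and dumb on
    purpose: it shares no code with the production scanner.
    """
    n = len(labels)
    out = []
    for i in range(n):
        state = labels[0]
        for j in range(min(i, n - SUSTAIN) + 1):
            if len(set(labels[j : j + SUSTAIN])) == 1:
                state = labels[j]
        out.append(state)
    return np.array(out)


def make_burst_recording(
    bursts, total_s=120.0, noise=5.0, freq=12.5, fs=125.0, seed=0
):
    """All-NREMS recording of white noise plus constant-amplitude sigma-band
    bursts given as (start_s, duration_s, amplitude)."""
    rng = np.random.default_rng(seed)
    n = int(total_s * fs)
    t = np.arange(n) / fs
    x = rng.standard_normal(n) * noise
    for start, dur, amp in bursts:
        i0, i1 = int(start * fs), int((start + dur) * fs)
        x[i0:i1] += amp * np.sin(2 * np.pi * freq * t[i0:i1])
    hyp = Hypnogram(np.array(["N"] * int(total_s / 4)))
    rec = Recording(
        {"eeg_frontal": x, "eeg_occipital": x.copy(), "emg": np.zeros(n)}, fs
    )
    return rec, hyp


#: background bursts that give the detector a realistic baseline level
FILLER_BURSTS = [(10 + 8 * i, 1.0, 30.0) for i in range(8)]


@pytest.fixture(scope="session")
def short_sim():
    """One 2-h synthetic mouse at full fidelity, analyzed at 125 Hz."""
    params = SimParams(recording_hours=2.0, rng_seed=3)
    hyp = simulate_hypnogram(params)
    rec, gt = synthesize_signals(hyp, params)
    rec125 = downsample(rec, 125.0)
    return dict(params=params, hyp=hyp, rec=rec, rec125=rec125, gt=gt)


@pytest.fixture(scope="session")
def spindle_recovery_sim():
    """High-SNR spindle-recovery fixture: 1 h of NREMS, dense bright spindles.

    The injection amplitude is far above the sigma-band background and the
    duration range leaves headroom for the 750-ms RMS smear inside the
    detector's [0.5, 2] s duration gate.
    """
    hyp = Hypnogram(np.array(["N"] * 900))
    params = SimParams(
        recording_hours=1.0,
        rng_seed=7,
        spindle_amplitude=100.0,
        spindle_rate=2.0,
        spindle_duration_range=(0.6, 1.4),
    )
    rec, gt = synthesize_signals(hyp, params)
    return dict(params=params, hyp=hyp, rec125=downsample(rec, 125.0), gt=gt)
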