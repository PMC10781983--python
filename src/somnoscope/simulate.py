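"""Synthetic mouse polysomnography with ground-truth event logs.

The generator produces (a) a hypnogram from a two-phase (light/dark) Markov
chain over {WAKE, NREMS, REMS} at epoch resolution, with the WAKE->REMS
transition forbidden, and (b) matching EEG/EMG signals built from 1/f (pink)
background noise plus state-specific band-limited oscillations:

- NREMS: delta (0.5-5 Hz) dominant, a weaker 5-30 Hz component, and injected
  sleep-spindle bursts (Hann-windowed 10-15 Hz sinusoids);
- REMS: theta (6-9 Hz) dominant;
- WAKE: broadband activity, EMG bursts on the EMG channel, and occasional
  high-amplitude movement artifacts.

"Genotype" knobs scale dark-phase WAKE dwell, NREMS delta amplitude, NREMS
5-30 Hz amplitude, and spindle amplitude, so that group contrasts analogous
to a transgenic-vs-wildtype comparison can be synthesized with known ground
truth.  Every injected spindle and artifact is logged for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.ndimage import uniform_filter1d

from .io import Hypnogram, Recording, STATES

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_hypnogram",
    "synthesize_signals",
    "tg_like_params",
    "save_ground_truth",
]


def _default_light_matrix() -> np.ndarray:
    # rows/cols ordered W, N, R; WAKE->REMS is structurally zero
    return np.array(
        [
            [0.970, 0.030, 0.000],
            [0.020, 0.965, 0.015],
            [0.060, 0.040, 0.900],
        ]
    )


def _default_dark_matrix() -> np.ndarray:
    return np.array(
        [
            [0.9875, 0.0125, 0.000],
            [0.0300, 0.9600, 0.010],
            [0.0800, 0.0400, 0.880],
        ]
    )


@dataclass
class SimParams:
    """Parameters of the synthetic polysomnography generator.

    Amplitudes are in the arbitrary (microvolt-scale) units of the output
    signals.  The transition matrices act at epoch resolution with state
    order (WAKE, NREMS, REMS).
    """

    epoch_length: float = 4.0
    sampling_rate: float = 256.0
    recording_hours: float = 24.0
    light_hours: float = 12.0

    light_matrix: np.ndarray = field(default_factory=_default_light_matrix)
    dark_matrix: np.ndarray = field(default_factory=_default_dark_matrix)

    # genotype-contrast knobs (1.0 = wildtype-like)
    wake_dark_boost: float = 1.0
    delta_scale: float = 1.0
    hf_scale: float = 1.0
    spindle_amp_scale: float = 1.0

    # spindle injection
    spindle_rate: float = 1.0  # events per NREMS minute
    spindle_freq_range: Tuple[float, float] = (10.0, 15.0)
    spindle_duration_range: Tuple[float, float] = (0.5, 2.0)
    spindle_amplitude: float = 40.0  # envelope peak before scaling
    spindle_min_separation: float = 0.2  # s between consecutive events
    spindle_edge_margin: float = 1.0  # s from NREMS-run boundaries

    # background / state oscillation levels
    noise_amplitude: float = 20.0  # pink-noise SD
    delta_amplitude: float = 60.0  # NREMS 0.5-5 Hz band-noise SD
    theta_amplitude: float = 40.0  # REMS 6-9 Hz band-noise SD
    wake_broadband_amplitude: float = 15.0  # WAKE 0.5-40 Hz band-noise SD
    nrems_hf_amplitude: float = 8.0  # NREMS 5-30 Hz band-noise SD
    crossfade_s: float = 0.5  # state-envelope crossfade length

    # EMG + movement artifacts (WAKE only)
    emg_noise: float = 5.0
    emg_burst_rate: float = 6.0  # per WAKE minute
    emg_burst_amplitude: float = 50.0
    artifact_rate: float = 4.0  # per WAKE hour
    artifact_amplitude: float = 400.0
    artifact_duration_range: Tuple[float, float] = (0.3, 1.0)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.light_matrix = np.asarray(self.light_matrix, dtype=float)
        self.dark_matrix = np.asarray(self.dark_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, mat in (("light", self.light_matrix), ("dark", self.dark_matrix)):
            if mat.shape != (3, 3):
                raise ValueError(f"{name}_matrix must be 3x3 over (W, N, R)")
            if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"{name}_matrix rows must be non-negative and sum to 1")
            if mat[0, 2] != 0.0:
                raise ValueError(f"{name}_matrix WAKE->REMS entry must be exactly 0")
        for knob in ("wake_dark_boost", "delta_scale", "hf_scale", "spindle_amp_scale"):
            if getattr(self, knob) <= 0:
                raise ValueError(f"{knob} must be > 0")
        lo, hi = self.spindle_duration_range
        if not 0 < lo < hi:
            raise ValueError("spindle_duration_range must be increasing and positive")
        if self.spindle_rate < 0:
            raise ValueError("spindle_rate must be >= 0")

    def effective_dark_matrix(self) -> np.ndarray:
        """Dark-phase matrix after applying ``wake_dark_boost``.

        The boost divides the WAKE exit probability by the boost factor and
        multiplies the NREMS->WAKE entry by it (capped so the row stays
        stochastic), which weakly increases dark-phase WAKE dwell time.
        """
        mat = self.dark_matrix.copy()
        b = self.wake_dark_boost
        if b != 1.0:
            exit_w = 1.0 - mat[0, 0]
            mat[0, 1] = exit_w / b  # WAKE->REMS stays 0
            mat[0, 0] = 1.0 - mat[0, 1]
            extra = min(mat[1, 0] * (b - 1.0), 0.9 * mat[1, 1])
            mat[1, 0] += extra
            mat[1, 1] -= extra
        return mat


def tg_like_params(base: SimParams | None = None, **overrides) -> SimParams:
    """Preset emulating the transgenic contrast: more dark-phase WAKE,
    reduced NREMS delta with elevated 5-30 Hz power, reduced spindle
    amplitude."""
    base = base or SimParams()
    knobs = dict(wake_dark_boost=2.0, delta_scale=0.6, hf_scale=1.3, spindle_amp_scale=0.7)
    knobs.update(overrides)
    return replace(base, **knobs)


@dataclass
class GroundTruth:
    """Injected-event logs paired with the hypnogram that produced them."""

    hypnogram: Hypnogram
    spindle_log: List[Tuple[float, float, float]]  # (start_s, duration_s, amplitude)
    artifact_log: List[Tuple[float, float]]  # (start_s, duration_s)

    def spindle_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.spindle_log, columns=["start_s", "duration_s", "amplitude"])

    def artifact_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.artifact_log, columns=["start_s", "duration_s"])


# ---------------------------------------------------------------------------
# hypnogram simulation
# ---------------------------------------------------------------------------

def simulate_hypnogram(params: SimParams) -> Hypnogram:
    """Simulate a hypnogram from the two phase-specific Markov chains.

    The light matrix governs epochs with ZT < ``light_hours``, the (boosted)
    dark matrix the rest.  The chain starts in WAKE at ZT0.  Reproducible
    given ``rng_seed``.
    """
    params.validate()
    n_epochs = int(round(params.recording_hours * 3600.0 / params.epoch_length))
    light_epochs = int(round(params.light_hours * 3600.0 / params.epoch_length))
    cum = {
        "light": np.cumsum(params.light_matrix, axis=1),
        "dark": np.cumsum(params.effective_dark_matrix(), axis=1),
    }
    rng = np.random.default_rng([0, params.rng_seed])
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.int8)
    s = 0  # start in WAKE at lights-on
    for i in range(n_epochs):
        row = cum["light" if i < light_epochs else "dark"][s]
        s = int(np.searchsorted(row, u[i], side="right"))
        states[i] = s
    labels = np.array(STATES)[states]
    return Hypnogram(labels, epoch_length=params.epoch_length)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float,
                sd: float, slope: float = 0.0) -> np.ndarray:
    """Gaussian noise spectrally confined to [f_lo, f_hi] with optional
    1/f^slope shaping, scaled to standard deviation ``sd``.

    Synthesized in single precision (amplitudes are arbitrary units; float32
    noise keeps long recordings cheap)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = (
        rng.standard_normal(freqs.size, dtype=np.float32)
        + 1j * rng.standard_normal(freqs.size, dtype=np.float32)
    )
    shape = np.zeros(freqs.size, dtype=np.float32)
    inside = (freqs >= f_lo) & (freqs <= f_hi)
    shape[inside] = 1.0
    if slope > 0:
        with np.errstate(divide="ignore"):
            shape = shape / np.maximum(freqs, freqs[1] if n > 1 else 1.0).astype(
                np.float32
            ) ** (slope / 2.0)
        shape[0] = 0.0
    x = sp_fft.irfft(spec * shape, n=n)
    s = x.std()
    if s > 0:
        x *= np.float32(sd / s)
    return x


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    return _band_noise(rng, n, fs, 0.0, fs / 2.0, sd, slope=1.0)


def _state_envelopes(hyp: Hypnogram, fs: float, n: int, crossfade_s: float) -> dict:
    codes_epoch = np.zeros(hyp.n_epochs, dtype=np.int8)
    codes_epoch[hyp.labels == "N"] = 1
    codes_epoch[hyp.labels == "R"] = 2
    spe = int(round(hyp.epoch_length * fs))
    codes = np.repeat(codes_epoch, spe)
    if codes.size < n:
        codes = np.concatenate([codes, np.full(n - codes.size, codes[-1], dtype=np.int8)])
    codes = codes[:n]
    win = max(1, int(round(crossfade_s * fs / 2.0)))
    envs = {}
    for i, st in enumerate(STATES):
        mask = (codes == i).astype(np.float32)
        # two box smooths = triangular crossfade of ~crossfade_s total width
        env = uniform_filter1d(uniform_filter1d(mask, win, mode="nearest"), win, mode="nearest")
        envs[st] = env
    return envs


def _epoch_runs(hyp: Hypnogram, state: str) -> List[Tuple[float, float]]:
    """Maximal runs of ``state`` in the raw hypnogram, as (start_s, end_s)."""
    mask = hyp.labels == state
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    return [(s * hyp.epoch_length, e * hyp.epoch_length) for s, e in zip(starts, ends)]


def _poisson_events(
    rng: np.random.Generator,
    runs: List[Tuple[float, float]],
    rate_per_s: float,
    dur_range: Tuple[float, float],
    margin: float,
    min_gap: float,
) -> List[Tuple[float, float]]:
    """Place non-overlapping (start, duration) events within runs.

    Exponential waiting times at ``rate_per_s``; events keep ``margin`` from
    run edges and ``min_gap`` between consecutive events.
    """
    events: List[Tuple[float, float]] = []
    if rate_per_s <= 0:
        return events
    for run_start, run_end in runs:
        lo, hi = run_start + margin, run_end - margin
        if hi - lo <= dur_range[0]:
            continue
        t = lo
        while True:
            t = t + rng.exponential(1.0 / rate_per_s)
            dur = rng.uniform(*dur_range)
            if t + dur > hi:
                break
            events.append((t, dur))
            t = t + dur + min_gap
    return events


def synthesize_signals(hyp: Hypnogram, params: SimParams) -> Tuple[Recording, GroundTruth]:
    """Render EEG/EMG signals for a hypnogram; returns the recording and the
    ground-truth spindle/artifact logs.

    State-specific oscillation tracks are multiplied by crossfaded state
    envelopes, so segment boundaries have no discontinuity clicks.  Spindles
    are Hann-windowed sinusoids at a frequency drawn uniformly from
    ``spindle_freq_range``, placed as a Poisson process within NREMS runs,
    never overlapping, and all logged.
    """
    params.validate()
    fs = params.sampling_rate
    n = int(round(hyp.duration_s * fs))
    if n == 0:
        raise ValueError("hypnogram is empty")
    rng = np.random.default_rng([1, params.rng_seed])

    envs = _state_envelopes(hyp, fs, n, params.crossfade_s)
    t = np.arange(n) / fs

    # oscillation tracks shared between the two EEG derivations
    delta = _band_noise(rng, n, fs, 0.5, 5.0, params.delta_amplitude * params.delta_scale)
    theta = _band_noise(rng, n, fs, 6.0, 9.0, params.theta_amplitude)
    wake_bb = _band_noise(rng, n, fs, 0.5, 40.0, params.wake_broadband_amplitude)
    nrem_hf = _band_noise(rng, n, fs, 5.0, 30.0, params.nrems_hf_amplitude * params.hf_scale)

    osc = (
        envs["N"] * (delta + nrem_hf)
        + envs["R"] * theta
        + envs["W"] * wake_bb
    )
    del delta, theta, wake_bb, nrem_hf

    # injected spindles (NREMS only)
    spindle_track = np.zeros(n, dtype=np.float32)
    spindle_log: List[Tuple[float, float, float]] = []
    nrems_runs = _epoch_runs(hyp, "N")
    for start, dur in _poisson_events(
        rng,
        nrems_runs,
        params.spindle_rate / 60.0,
        params.spindle_duration_range,
        params.spindle_edge_margin,
        params.spindle_min_separation,
    ):
        freq = rng.uniform(*params.spindle_freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        amp = params.spindle_amplitude * params.spindle_amp_scale * np.exp(rng.normal(0, 0.15))
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        seg = np.arange(i0, i1)
        window = np.hanning(seg.size)
        spindle_track[i0:i1] += amp * window * np.sin(2 * np.pi * freq * t[i0:i1] + phase)
        spindle_log.append((start, dur, float(amp)))
    spindle_log.sort()

    # movement artifacts (WAKE only): large slow deflections
    artifact_track = np.zeros(n, dtype=np.float32)
    artifact_log: List[Tuple[float, float]] = []
    wake_runs = _epoch_runs(hyp, "W")
    for start, dur in _poisson_events(
        rng, wake_runs, params.artifact_rate / 3600.0, params.artifact_duration_range,
        margin=0.5, min_gap=1.0,
    ):
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        artifact_track[i0:i1] += params.artifact_amplitude * np.hanning(i1 - i0)
        artifact_log.append((start, dur))
    artifact_log.sort()

    eeg_frontal = _pink_noise(rng, n, fs, params.noise_amplitude) + osc + spindle_track + artifact_track
    eeg_occipital = _pink_noise(rng, n, fs, params.noise_amplitude) + 0.8 * (osc + spindle_track) + artifact_track

    # EMG: baseline noise, elevated tone + bursts during WAKE
    emg = rng.standard_normal(n, dtype=np.float32) * np.float32(params.emg_noise) * (
        np.float32(1.0) + envs["W"]
    )
    for start, dur in _poisson_events(
        rng, wake_runs, params.emg_burst_rate / 60.0, (0.2, 0.8), margin=0.0, min_gap=0.1
    ):
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        emg[i0:i1] += params.emg_burst_amplitude * np.hanning(i1 - i0) * rng.standard_normal(i1 - i0)

    rec = Recording(
        channels={"eeg_frontal": eeg_frontal, "eeg_occipital": eeg_occipital, "emg": emg},
        sampling_rate=fs,
        zt_start=0.0,
    )
    gt = GroundTruth(hypnogram=hyp, spindle_log=spindle_log, artifact_log=artifact_log)
    return rec, gt


def save_ground_truth(gt: GroundTruth, out_dir: str | Path, stem: str = "ground_truth") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt.spindle_frame().to_csv(out_dir / f"{stem}_spindles.csv", index=False)
    gt.artifact_frame().to_csv(out_dir / f"{stem}_artifacts.csv", index=False)
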