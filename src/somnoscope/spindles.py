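"""Two-threshold sleep-spindle detection on the cubed moving RMS.

The detector band-passes the EEG to the spindle (sigma) band, computes a
centered 750-ms moving RMS, cubes it to sharpen the separation between
bursts and background, and applies two thresholds expressed as multiples of
the mean cubed RMS over the NREMS baseline: candidate events are maximal
runs above the lower threshold, events closer together than the inter-event
interval are merged, and a candidate is kept only if its peak exceeds the
upper threshold, its duration lies within [0.5, 2] s, and it falls inside
NREMS.

The band-pass is a zero-phase Butterworth whose order is the minimal one
meeting the specified 24 dB/octave stopband slope (order 4 per edge); corner
frequencies 10-15 Hz with stopband edges at 3 and 22 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .architecture import effective_labels
from .io import ArtifactMask, Hypnogram, Recording

__all__ = [
    "SpindleParams",
    "SpindleEvent",
    "SpindleSummary",
    "detect_spindles",
    "merge_intervals",
    "summarize_spindles",
]


@dataclass
class SpindleParams:
    """Detection parameters (defaults follow the standard rodent paradigm)."""

    passband: Tuple[float, float] = (10.0, 15.0)
    stopband: Tuple[float, float] = (3.0, 22.0)
    stopband_atten_db_per_octave: float = 24.0
    rms_window: float = 0.75  # s, centered
    lower_threshold_factor: float = 1.0  # x mean cubed RMS
    upper_threshold_factor: float = 2.5  # x mean cubed RMS
    min_duration: float = 0.5  # s
    max_duration: float = 2.0  # s
    merge_interval: float = 0.1  # s: closer events are merged
    baseline: str = "nrems"  # "nrems" | "recording"
    amplitude_mode: str = "literal"  # "literal" | "cubed"

    def __post_init__(self) -> None:
        if not 0 < self.min_duration < self.max_duration:
            raise ValueError("need 0 < min_duration < max_duration")
        if self.lower_threshold_factor >= self.upper_threshold_factor:
            raise ValueError("lower threshold factor must be below the upper")
        if self.baseline not in ("nrems", "recording"):
            raise ValueError("baseline must be 'nrems' or 'recording'")
        if self.amplitude_mode not in ("literal", "cubed"):
            raise ValueError("amplitude_mode must be 'literal' or 'cubed'")

    @property
    def filter_order(self) -> int:
        # a Butterworth rolls off at 6 dB/octave per pole; the minimal order
        # meeting the requested slope per band edge
        return max(1, int(np.ceil(self.stopband_atten_db_per_octave / 6.0)))


@dataclass(frozen=True)
class SpindleEvent:
    start: float  # s
    duration: float  # s
    peak_envelope: float  # peak cubed RMS (amplitude^3 units)
    normalized_amplitude: float  # envelope peak / upper threshold

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class SpindleSummary:
    amount: int
    density: float  # events per NREMS minute
    median_duration: float  # s
    median_normalized_amplitude: float
    nrems_minutes: float
    phase: str = ""


def moving_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving RMS (uniform window)."""
    return np.sqrt(uniform_filter1d(x * x, size=max(1, window_samples), mode="nearest"))


def merge_intervals(
    intervals: Sequence[Tuple[int, int]], gap_samples: int
) -> List[Tuple[int, int]]:
    """Merge half-open sample intervals separated by less than ``gap_samples``.

    Idempotent: re-merging the output changes nothing.
    """
    if not intervals:
        return []
    srt = sorted(intervals)
    out = [list(srt[0])]
    for s, e in srt[1:]:
        if s - out[-1][1] < gap_samples:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _runs_above(x: np.ndarray, thresh: float) -> List[Tuple[int, int]]:
    above = x > thresh
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_spindles(
    rec: Recording,
    hyp: Hypnogram,
    params: SpindleParams | None = None,
    mask: ArtifactMask | None = None,
    channel: str = "eeg_frontal",
) -> List[SpindleEvent]:
    """Detect NREMS sleep spindles; returns events sorted by start time.

    Thresholds are ``factor x mean cubed RMS`` over the baseline (NREMS
    samples by default, artifact-free).  Event boundaries are the lower-
    threshold crossings of the cubed RMS, per the two-threshold convention.
    """
    params = params or SpindleParams()
    fs = rec.sampling_rate
    sig = rec.channels[channel]
    labels = hyp.sample_labels(fs, sig.size)
    eff_epoch = effective_labels(hyp)
    spe = int(round(hyp.epoch_length * fs))
    eff = np.repeat(eff_epoch, spe)[: sig.size]
    if eff.size < sig.size:
        eff = np.concatenate([eff, np.full(sig.size - eff.size, eff_epoch[-1])])
    nrems = eff == "N"
    if not np.any(nrems):
        warnings.warn("no NREMS epochs: no spindles can be detected")
        return []

    sos = butter(params.filter_order, params.passband, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, sig)
    rms3 = moving_rms(filtered, int(round(params.rms_window * fs))) ** 3

    base_sel = nrems if params.baseline == "nrems" else np.ones_like(nrems)
    if mask is not None:
        base_sel = base_sel & ~mask.flags
    baseline = float(np.mean(rms3[base_sel]))
    lower = params.lower_threshold_factor * baseline
    upper = params.upper_threshold_factor * baseline

    candidates = merge_intervals(_runs_above(rms3, lower), int(round(params.merge_interval * fs)))

    envelope = np.abs(hilbert(filtered))
    events: List[SpindleEvent] = []
    for s, e in candidates:
        dur = (e - s) / fs
        if not params.min_duration <= dur <= params.max_duration:
            continue
        peak3 = float(rms3[s:e].max())
        if peak3 <= upper:
            continue
        if not np.all(nrems[s:e]):
            continue
        if params.amplitude_mode == "literal":
            norm_amp = float(envelope[s:e].max()) / upper
        else:
            norm_amp = peak3 / upper
        events.append(
            SpindleEvent(
                start=s / fs, duration=dur, peak_envelope=peak3, normalized_amplitude=norm_amp
            )
        )
    return events


def summarize_spindles(
    events: Sequence[SpindleEvent], hyp: Hypnogram, phase: str = ""
) -> SpindleSummary:
    """Amount, density per NREMS minute, and median duration/amplitude."""
    eff = effective_labels(hyp)
    nrems_minutes = float(np.sum(eff == "N")) * hyp.epoch_length / 60.0
    if nrems_minutes == 0:
        raise ValueError("zero NREMS time: spindle density undefined")
    amount = len(events)
    return SpindleSummary(
        amount=amount,
        density=amount / nrems_minutes,
        median_duration=float(np.median([e.duration for e in events])) if events else float("nan"),
        median_normalized_amplitude=(
            float(np.median([e.normalized_amplitude for e in events])) if events else float("nan")
        ),
        nrems_minutes=nrems_minutes,
        phase=phase,
    )


def spindles_frame(events: Sequence[SpindleEvent], **meta) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            dict(
                start_s=e.start,
                duration_s=e.duration,
                peak_env=e.peak_envelope,
                norm_amp=e.normalized_amplitude,
            )
            for e in events
        ]
    )
    for k, v in reversed(meta.items()):
        df.insert(0, k, v)
    return df
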