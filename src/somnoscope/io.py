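"""Recording / hypnogram containers, file I/O, downsampling, artifact masks.

Conventions
-----------
Vigilance states are encoded by the single characters ``"W"`` (WAKE),
``"N"`` (NREMS) and ``"R"`` (REMS).  Hypnograms live on a fixed epoch grid
(4 s by default) anchored at Zeitgeber time 0 (lights on); partial trailing
epochs are discarded when a recording is epoched.

Recordings are plain CSV (one column per channel, a ``# sampling_rate_hz=...``
comment line above the header) and hypnograms are one-label-per-line text
files.  Signal amplitudes are in arbitrary units (microvolt-scale for the
simulator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

STATES: Tuple[str, ...] = ("W", "N", "R")
STATE_NAMES: Dict[str, str] = {"W": "WAKE", "N": "NREMS", "R": "REMS"}

CANONICAL_CHANNELS: Tuple[str, ...] = ("eeg_frontal", "eeg_occipital", "emg")

#: accepted spellings for each canonical channel name (lower-cased keys)
_CHANNEL_ALIASES: Dict[str, str] = {
    "eeg_frontal": "eeg_frontal",
    "eeg_fr": "eeg_frontal",
    "eeg frontal": "eeg_frontal",
    "frontal": "eeg_frontal",
    "eeg_occipital": "eeg_occipital",
    "eeg_occ": "eeg_occipital",
    "eeg occipital": "eeg_occipital",
    "occipital": "eeg_occipital",
    "emg": "emg",
    "emg_l": "emg",
    "emg_r": "emg",
}


@dataclass
class Recording:
    """Multichannel EEG/EMG time series.

    Parameters
    ----------
    channels
        Mapping channel name -> 1-D signal vector; all channels must have
        equal length.
    sampling_rate
        Sampling rate in Hz.
    zt_start
        Zeitgeber hour at the first sample (0 = lights on).
    """

    channels: Dict[str, np.ndarray]
    sampling_rate: float
    zt_start: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels have inconsistent lengths: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=float) for name, sig in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def slice_seconds(self, start_s: float, end_s: float) -> "Recording":
        i0 = int(round(start_s * self.sampling_rate))
        i1 = int(round(end_s * self.sampling_rate))
        return Recording(
            channels={k: v[i0:i1].copy() for k, v in self.channels.items()},
            sampling_rate=self.sampling_rate,
            zt_start=self.zt_start + start_s / 3600.0,
        )


@dataclass
class Hypnogram:
    """Sequence of vigilance-state labels on a fixed epoch grid."""

    labels: np.ndarray
    epoch_length: float = 4.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.labels.tolist()) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance-state labels: {sorted(bad)}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length

    def slice_epochs(self, start: int, stop: int) -> "Hypnogram":
        return Hypnogram(self.labels[start:stop].copy(), self.epoch_length)

    def sample_labels(self, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Per-sample state labels (repeats each epoch label)."""
        spe = int(round(self.epoch_length * sampling_rate))
        full = np.repeat(self.labels, spe)
        if n_samples > full.size:  # trailing, unscored samples inherit last label
            full = np.concatenate([full, np.full(n_samples - full.size, full[-1])])
        return full[:n_samples]


@dataclass
class ArtifactMask:
    """Boolean per-sample exclusion flags for one EEG channel."""

    flags: np.ndarray
    threshold: float
    channel: str = "eeg_frontal"

    @property
    def excluded_fraction(self) -> float:
        return float(np.mean(self.flags))

    def excluded_seconds(self, sampling_rate: float) -> float:
        return float(np.sum(self.flags)) / sampling_rate


@dataclass(frozen=True)
class PhaseWindow:
    """Light ([ZT0, ZT12)) or dark ([ZT12, ZT23)) analysis window."""

    phase: str
    zt_span: Tuple[float, float]

    @property
    def duration_s(self) -> float:
        return (self.zt_span[1] - self.zt_span[0]) * 3600.0


#: the 23-h analysis window: 12 h light, 11 h dark, final hour omitted
LIGHT_WINDOW = PhaseWindow("light", (0.0, 12.0))
DARK_WINDOW = PhaseWindow("dark", (12.0, 23.0))
PHASE_WINDOWS: Dict[str, PhaseWindow] = {"light": LIGHT_WINDOW, "dark": DARK_WINDOW}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV (metadata comment line + header row)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate!r} zt_start={rec.zt_start!r}\n")
        pd.DataFrame(rec.channels).to_csv(fh, index=False, float_format="%.6g")


def _normalize_channel_name(name: str) -> str:
    key = name.strip().lower().replace("-", "_").replace(".", "_")
    if key in _CHANNEL_ALIASES:
        return _CHANNEL_ALIASES[key]
    raise ValueError(
        f"unknown channel label {name!r}; recognized labels map to "
        f"{CANONICAL_CHANNELS} (found in aliases: {sorted(_CHANNEL_ALIASES)})"
    )


def load_recording(
    path: str | Path,
    format: str = "csv",
    sampling_rate: float | None = None,
) -> Recording:
    """Load a recording from disk.

    Only the CSV dialect written by :func:`save_recording` (and any CSV with
    one column per channel) is supported.  ``sampling_rate`` overrides or
    supplies the rate when the file carries no metadata line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = format.lower()
    if format == "edf":
        raise NotImplementedError(
            "EDF input is not supported; convert to the CSV dialect "
            "(see save_recording) instead"
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'csv'")

    zt_start = 0.0
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first.lstrip("#").split():
            key, _, val = token.partition("=")
            if key == "sampling_rate_hz" and sampling_rate is None:
                sampling_rate = float(val)
            elif key == "zt_start":
                zt_start = float(val)
    if sampling_rate is None:
        raise ValueError(f"{path}: no sampling rate in header and none supplied")

    df = pd.read_csv(path, skiprows=skip)
    channels = {
        _normalize_channel_name(col): df[col].to_numpy(dtype=float) for col in df.columns
    }
    return Recording(channels=channels, sampling_rate=float(sampling_rate), zt_start=zt_start)


def save_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.labels.tolist()) + "\n")


def load_hypnogram(path: str | Path, epoch_length: float = 4.0) -> Hypnogram:
    labels = [ln.strip().upper()[:1] for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Hypnogram(np.array(labels), epoch_length=epoch_length)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def downsample(rec: Recording, target_rate: float) -> Recording:
    """Resample all channels to ``target_rate`` with anti-aliasing.

    Uses rational polyphase resampling (e.g. 125/256 for the standard
    256 -> 125 Hz step) with a zero-phase FIR low-pass.  Requesting the
    current rate is a no-op; upsampling is refused.
    """
    if target_rate > rec.sampling_rate:
        raise ValueError(
            f"upsampling not supported: {rec.sampling_rate} -> {target_rate} Hz"
        )
    if target_rate == rec.sampling_rate:
        return Recording(
            {k: v.copy() for k, v in rec.channels.items()}, rec.sampling_rate, rec.zt_start
        )
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(10000)
    out = {
        name: resample_poly(sig, frac.numerator, frac.denominator)
        for name, sig in rec.channels.items()
    }
    return Recording(out, sampling_rate=float(target_rate), zt_start=rec.zt_start)


def build_artifact_mask(
    rec: Recording,
    hyp: Hypnogram,
    threshold: float,
    channel: str = "eeg_frontal",
) -> ArtifactMask:
    """Flag movement artifacts: samples above ``threshold`` during WAKE.

    Movement artifacts occur only during WAKE, so the amplitude criterion is
    applied exclusively to WAKE-scored samples; NREMS/REMS samples are never
    excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sig = rec.channels[channel]
    wake = hyp.sample_labels(rec.sampling_rate, sig.size) == "W"
    flags = (np.abs(sig) > threshold) & wake
    return ArtifactMask(flags=flags, threshold=float(threshold), channel=channel)


def split_phases(
    rec: Recording | None,
    hyp: Hypnogram,
    mask: ArtifactMask | None = None,
) -> Mapping[str, dict]:
    """Split the 23-h analysis window into light (12 h) and dark (11 h) parts.

    The recording must start at ZT0 and cover at least 23 h; the hour ZT23-24
    (cage maintenance) is discarded.  Returns ``{"light": {...}, "dark": {...}}``
    where each entry carries ``recording``, ``hypnogram``, ``mask`` (sliced,
    mask only when given) and ``window`` (the :class:`PhaseWindow`).
    """
    if hyp.duration_s < 23 * 3600 - 1e-9:
        raise ValueError(
            f"analysis window needs >= 23 h of scored data, got {hyp.duration_s / 3600:.2f} h"
        )
    if rec is not None:
        if abs(rec.zt_start) > 1e-9:
            raise ValueError("recording must start at ZT0 (zt_start == 0)")
        if rec.duration_s < 23 * 3600 - 1e-9:
            raise ValueError("recording shorter than the 23-h analysis window")

    out = {}
    for window in (LIGHT_WINDOW, DARK_WINDOW):
        t0, t1 = (z * 3600.0 for z in window.zt_span)
        e0, e1 = int(round(t0 / hyp.epoch_length)), int(round(t1 / hyp.epoch_length))
        entry = {"window": window, "hypnogram": hyp.slice_epochs(e0, e1), "recording": None, "mask": None}
        if rec is not None:
            entry["recording"] = rec.slice_seconds(t0, t1)
            if mask is not None:
                i0 = int(round(t0 * rec.sampling_rate))
                i1 = int(round(t1 * rec.sampling_rate))
                entry["mask"] = ArtifactMask(
                    mask.flags[i0:i1].copy(), mask.threshold, mask.channel
                )
        out[window.phase] = entry
    return out
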