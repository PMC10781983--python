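"""Unity-normalized power spectral densities per vigilance state and phase.

Spectra are estimated per scored 4-s epoch (500 samples at the 125 Hz
analysis rate) with a Hann taper and a 512-point zero-padded transform,
giving a one-sided axis of 257 bins spaced 125/512 ~ 0.2441 Hz apart.
Epoch periodograms are averaged within a state x phase and the average is
normalized to unit sum, so spectra are scale-free and comparable across
animals; they are reported as percentages.

Group curves are per-bin medians across animals with bootstrap percentile
CIs (animals resampled with replacement), and per-bin AUROC effect sizes
against a comparison group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .architecture import effective_labels
from .io import ArtifactMask, Hypnogram, Recording
from . import stats as _stats

#: frequency bands used to characterize vigilance-state spectra (Hz)
BAND_SCHEME: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 5.0),
    "theta": (6.0, 9.0),
    "alpha": (10.0, 15.0),
    "eta": (16.0, 22.75),
    "beta": (23.0, 31.75),
}

NFFT = 512


@dataclass
class PSDEstimate:
    """One-sided, unit-sum normalized spectrum for one state x phase."""

    freqs: np.ndarray  # Hz, 257 bins at 125 Hz / 512-point transform
    power: np.ndarray  # unitless, sums to 1
    state: str
    phase: str = ""
    mouse_id: str = ""
    n_epochs: int = 0

    @property
    def power_pct(self) -> np.ndarray:
        return 100.0 * self.power


def compute_psd(
    rec: Recording,
    hyp: Hypnogram,
    mask: ArtifactMask | None = None,
    state: str = "N",
    phase: str = "",
    channel: str = "eeg_frontal",
    mouse_id: str = "",
    nfft: int = NFFT,
) -> PSDEstimate:
    """Average per-epoch periodogram for one vigilance state, unit-normalized.

    Epochs are assigned states by the bout-partitioned (sustain-rule) labels;
    epochs containing artifact-masked samples are excluded from spectral
    estimation (their labels are retained for temporal analyses).
    """
    sig = rec.channels[channel]
    spe = int(round(hyp.epoch_length * rec.sampling_rate))
    n_epochs = min(hyp.n_epochs, sig.size // spe)
    eff = effective_labels(hyp)[:n_epochs]
    keep = eff == state
    if mask is not None:
        masked_per_epoch = np.add.reduceat(
            mask.flags[: n_epochs * spe].astype(int), np.arange(0, n_epochs * spe, spe)
        )
        keep &= masked_per_epoch == 0
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(f"no artifact-free {state!r} epochs in phase {phase!r}")

    segs = sig[: n_epochs * spe].reshape(n_epochs, spe)[idx]
    segs = segs - segs.mean(axis=1, keepdims=True)
    window = np.hanning(spe)
    spec = np.abs(np.fft.rfft(segs * window, n=nfft, axis=1)) ** 2
    mean_spec = spec.mean(axis=0)
    power = mean_spec / mean_spec.sum()
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.sampling_rate)
    return PSDEstimate(
        freqs=freqs, power=power, state=state, phase=phase, mouse_id=mouse_id, n_epochs=idx.size
    )


def band_power(
    psd: PSDEstimate, scheme: Dict[str, Tuple[float, float]] = BAND_SCHEME
) -> Dict[str, float]:
    """Fraction of total power per band (closed intervals on bin centers).

    Frequencies between bands (e.g. 5-6 Hz) belong to no band, so the
    fractions sum to less than 1.
    """
    out = {}
    for name, (lo, hi) in scheme.items():
        sel = (psd.freqs >= lo) & (psd.freqs <= hi)
        out[name] = float(psd.power[sel].sum())
    return out


def _bootstrap_median_bands(
    mat: np.ndarray, n_boot: int, rng: np.random.Generator, chunk: int = 32
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column bootstrap 95% CI of the median of ``mat`` (rows = animals)."""
    n_mice, n_bins = mat.shape
    idx = rng.integers(0, n_mice, size=(n_boot, n_mice))
    lo = np.empty(n_bins)
    hi = np.empty(n_bins)
    for c0 in range(0, n_bins, chunk):
        c1 = min(c0 + chunk, n_bins)
        meds = np.median(mat[:, c0:c1][idx], axis=1)  # (n_boot, chunk)
        lo[c0:c1], hi[c0:c1] = np.percentile(meds, [2.5, 97.5], axis=0)
    return lo, hi


def group_spectrum(
    psds: Sequence[PSDEstimate],
    comparison: Sequence[PSDEstimate] | None = None,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Group median spectrum (in %) with bootstrap CIs, plus per-bin AUROC
    effect sizes versus a comparison group when one is given.

    Bootstrap resamples animals, not epochs: the CIs describe across-subject
    variability.  Returns a tidy frame with one row per frequency bin.
    """
    if len(psds) < 2:
        raise ValueError("need at least two animals for a group spectrum")
    rng = _stats._rng(seed)
    freqs = psds[0].freqs
    mat = np.vstack([p.power_pct for p in psds])
    median = np.median(mat, axis=0)
    lo, hi = _bootstrap_median_bands(mat, n_boot, rng)
    lo, hi = np.minimum(lo, median), np.maximum(hi, median)
    df = pd.DataFrame(
        {"freq_hz": freqs, "median_pct": median, "ci_lo": lo, "ci_hi": hi}
    )
    if comparison is not None:
        cmat = np.vstack([p.power_pct for p in comparison])
        aucs, alos, ahis, labels = [], [], [], []
        for j in range(freqs.size):
            eff = _stats.auroc_effect(mat[:, j], cmat[:, j], n_iter=n_boot, seed=rng)
            aucs.append(eff.auc)
            alos.append(eff.ci_lo)
            ahis.append(eff.ci_hi)
            labels.append(eff.label)
        df["auc"] = aucs
        df["auc_ci_lo"] = alos
        df["auc_ci_hi"] = ahis
        df["label"] = labels
    return df


def restrict_display(df: pd.DataFrame, f_lo: float = 1.0, f_hi: float = 30.0) -> pd.DataFrame:
    """Restrict a spectrum table to the conventional 1-30 Hz display range."""
    return df[(df["freq_hz"] >= f_lo) & (df["freq_hz"] <= f_hi)].reset_index(drop=True)
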