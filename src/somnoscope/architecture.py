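"""Vigilance-state architecture: bouts, proportions, transitions, latencies,
and normalized bout-length distribution curves.

A *bout* is a maximal period of one vigilance state after applying the
sustain rule: a state change is recognized only when the new state persists
for at least three consecutive 4-s epochs.  Shorter intrusions are absorbed
into the ongoing bout (they neither split it nor count as transitions), so
bouts partition the hypnogram exactly.  The first bout opens unconditionally
at the first epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import Hypnogram, STATES
from . import stats as _stats

SUSTAIN_EPOCHS = 3  # epochs a new state must persist to open a bout

#: the five physiologically plausible bout transitions; WAKE->REMS is
#: excluded (its occurrence flags narcolepsy/cataplexy-like anomalies)
ALLOWED_TRANSITIONS: Tuple[Tuple[str, str], ...] = (
    ("W", "N"),
    ("N", "R"),
    ("N", "W"),
    ("R", "W"),
    ("R", "N"),
)


@dataclass(frozen=True)
class Bout:
    state: str
    start: float  # seconds from phase start
    duration: float  # seconds

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class TransitionCounts:
    counts: Dict[Tuple[str, str], int]
    anomaly_w_r: int = 0

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def proportions(self) -> Dict[Tuple[str, str], float]:
        tot = self.total
        if tot == 0:
            return {k: float("nan") for k in ALLOWED_TRANSITIONS}
        return {k: v / tot for k, v in self.counts.items()}


@dataclass
class LatencyProfile:
    """Latencies to the onsets of the first five WAKE bouts of a phase.

    ``latencies`` holds the onset times dT1..dT5 (seconds from phase start,
    nondecreasing); ``differential_latencies`` their consecutive differences.
    The combined metric is the sum of the differential latencies (which
    telescopes to dT5 - dT1) plus the median length of the first five WAKE
    bouts.
    """

    latencies: Tuple[float, ...]
    differential_latencies: Tuple[float, ...]
    median_first5_bout_length: float
    combined_metric: float
    complete: bool


def effective_labels(hyp: Hypnogram) -> np.ndarray:
    """Per-epoch labels after the 3-epoch sustain rule.

    Epoch i is assigned the label of the most recent run of three identical
    epochs starting at or before i (the bout opened by that run); epochs
    before any such run inherit the first epoch's label.
    """
    labels = hyp.labels
    n = labels.size
    if n < SUSTAIN_EPOCHS:
        return np.full(n, labels[0])
    hom = (labels[:-2] == labels[1:-1]) & (labels[1:-1] == labels[2:])
    idx = np.where(hom, np.arange(n - 2), -1)
    last = np.maximum.accumulate(idx)
    j = last[np.minimum(np.arange(n), n - SUSTAIN_EPOCHS)]
    return np.where(j >= 0, labels[np.maximum(j, 0)], labels[0])


def detect_bouts(hyp: Hypnogram) -> List[Bout]:
    """Partition a hypnogram into bouts under the 3-epoch sustain rule."""
    eff = effective_labels(hyp)
    change = np.flatnonzero(eff[1:] != eff[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [eff.size]])
    dt = hyp.epoch_length
    return [
        Bout(state=str(eff[s]), start=s * dt, duration=(e - s) * dt)
        for s, e in zip(starts, ends)
    ]


def state_proportions(
    bouts: Sequence[Bout], phase_duration_s: float | None = None
) -> Dict[str, float]:
    """Fraction of a phase spent in each state (bout durations / phase duration)."""
    if not bouts:
        raise ValueError("no bouts supplied")
    if phase_duration_s is None:
        phase_duration_s = sum(b.duration for b in bouts)
    out = {s: 0.0 for s in STATES}
    for b in bouts:
        out[b.state] += b.duration
    return {s: d / phase_duration_s for s, d in out.items()}


def state_time_course(
    hypnograms: Sequence[Hypnogram],
    bin_hours: float = 2.0,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-bin group median state percentages with bootstrap 95% CIs.

    The window is cut into ``bin_hours`` bins (a 23-h window yields eleven
    2-h bins plus a truncated 1-h bin, marked ``truncated``).  Percentages
    use the bout-partitioned (sustain-rule) labels.  Returns a tidy frame
    with one row per (bin, state).
    """
    if not hypnograms:
        raise ValueError("need at least one hypnogram")
    rng = np.random.default_rng(seed)
    dt = hypnograms[0].epoch_length
    n_epochs = min(h.n_epochs for h in hypnograms)
    per_bin = int(round(bin_hours * 3600.0 / dt))
    edges = list(range(0, n_epochs, per_bin)) + [n_epochs]

    effs = [effective_labels(h)[:n_epochs] for h in hypnograms]
    rows = []
    for b, (e0, e1) in enumerate(zip(edges[:-1], edges[1:])):
        truncated = (e1 - e0) < per_bin
        for st in STATES:
            pct = np.array([100.0 * np.mean(eff[e0:e1] == st) for eff in effs])
            if pct.size == 1:  # single animal: degenerate CI
                med = lo = hi = float(pct[0])
            else:
                med, lo, hi = _stats.bootstrap_median_ci(pct, n_iter=n_boot, seed=rng)
            rows.append(
                dict(
                    bin_index=b,
                    bin_start_h=e0 * dt / 3600.0,
                    bin_end_h=e1 * dt / 3600.0,
                    truncated=truncated,
                    state=st,
                    median_pct=med,
                    ci_lo=lo,
                    ci_hi=hi,
                )
            )
    return pd.DataFrame(rows)


def per_bin_percentages(
    hyp: Hypnogram, bin_hours: float = 2.0
) -> pd.DataFrame:
    """Single-mouse per-bin state percentages (sustain-rule labels)."""
    return state_time_course([hyp], n_boot=2, bin_hours=bin_hours)[
        ["bin_index", "bin_start_h", "bin_end_h", "truncated", "state", "median_pct"]
    ].rename(columns={"median_pct": "pct"})


def transition_proportions(bouts: Sequence[Bout]) -> TransitionCounts:
    """Count consecutive bout-state pairs among the five allowed transitions.

    A WAKE->REMS bout pair (possible when a short NREMS intrusion was
    absorbed) is reported as an anomaly and excluded from the denominator.
    """
    if len(bouts) < 2:
        raise ValueError("need at least two bouts to count transitions")
    counts = {k: 0 for k in ALLOWED_TRANSITIONS}
    anomaly = 0
    for a, b in zip(bouts[:-1], bouts[1:]):
        pair = (a.state, b.state)
        if pair in counts:
            counts[pair] += 1
        elif pair == ("W", "R"):
            anomaly += 1
        else:  # same-state pairs cannot occur: bouts are maximal
            raise ValueError(f"invalid bout sequence: consecutive {pair}")
    return TransitionCounts(counts=counts, anomaly_w_r=anomaly)


def wake_latency_profile(bouts: Sequence[Bout], n_bouts: int = 5) -> LatencyProfile:
    """Latencies to the first ``n_bouts`` WAKE-bout onsets of a phase."""
    wake = sorted((b for b in bouts if b.state == "W"), key=lambda b: b.start)[:n_bouts]
    if not wake:
        raise ValueError("no WAKE bouts in phase")
    lat = tuple(b.start for b in wake)
    diffs = tuple(np.diff(lat)) if len(lat) > 1 else ()
    med = float(np.median([b.duration for b in wake]))
    return LatencyProfile(
        latencies=lat,
        differential_latencies=diffs,
        median_first5_bout_length=med,
        combined_metric=float(sum(diffs) + med),
        complete=len(wake) == n_bouts,
    )


def bout_distribution_curve(
    durations: Sequence[float], n_points: int | None = 1000
) -> Tuple[np.ndarray, np.ndarray]:
    """Doubly normalized, sorted bout-duration curve upsampled to ``n_points``.

    Durations are sorted ascending; x = rank / bout count, y = duration /
    cumulative duration, then linearly interpolated onto a uniform grid on
    [0, 1] for cross-animal comparability.  ``n_points=None`` returns the raw
    normalized points without interpolation.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if d.size < 2:
        raise ValueError("need at least two bouts for a distribution curve")
    x = np.arange(1, d.size + 1) / d.size
    y = d / d.sum()
    if n_points is None:
        return x, y
    grid = np.linspace(0.0, 1.0, n_points)
    return grid, np.interp(grid, x, y, left=y[0], right=y[-1])


def group_distribution_curves(
    curves: Iterable[np.ndarray],
) -> Dict[str, np.ndarray]:
    """Pointwise group median curve with first/third-quartile bands."""
    ys = np.vstack(list(curves))
    return {
        "median": np.median(ys, axis=0),
        "q1": np.percentile(ys, 25, axis=0),
        "q3": np.percentile(ys, 75, axis=0),
    }


def bouts_frame(bouts: Sequence[Bout], **meta) -> pd.DataFrame:
    """Tidy table of bouts; ``meta`` columns (mouse, phase, ...) are prepended."""
    df = pd.DataFrame(
        [dict(state=b.state, start_s=b.start, duration_s=b.duration) for b in bouts]
    )
    for k, v in reversed(meta.items()):
        df.insert(0, k, v)
    return df
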