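"""Heartbeat-evoked potentials: R-locked epoching, averaging, group stats."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .recording import Recording
from .rpeak import RPeakTrain

logger = logging.getLogger(__name__)

#: Epoch window relative to the R peak, ms.
EPOCH_WINDOW_MS = (-200.0, 600.0)

#: Time window of interest for group statistics, ms post-R.
TOI_MS = (350.0, 600.0)

#: Low-pass cutoff applied to the continuous EEG before epoching, Hz.
HEP_LOWPASS_HZ = 15.0

#: Per-trial absolute amplitude rejection threshold, µV.
TRIAL_REJECT_UV = 100.0

#: Minimum length of a reported significant window, ms.
MIN_WINDOW_MS = 20.0


@dataclass
class HEPEpochSet:
    """channel × trial × time array of R-locked epochs."""

    data: np.ndarray
    times_ms: np.ndarray
    labels: list[str]
    fs: float
    rejected_trials: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be channel x trial x time")
        if not (self.times_ms[0] <= 0.0 <= self.times_ms[-1]):
            raise ValueError("epoch time axis must include the R peak (t=0)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


@dataclass
class HEPResult:
    """Per-channel trial-averaged waveforms plus significance windows."""

    waveforms: np.ndarray          # channel x time, µV
    times_ms: np.ndarray
    labels: list[str]
    n_trials_used: int
    toi_ms: tuple[float, float] = TOI_MS
    significant_windows: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def epoch_heartbeats(
    eeg: Recording,
    peaks: RPeakTrain,
    *,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    lowpass_hz: float = HEP_LOWPASS_HZ,
    reject_uv: float | None = TRIAL_REJECT_UV,
    min_beats: int = 30,
) -> HEPEpochSet:
    """Cut R-locked epochs from the continuous EEG.

    The continuous data are zero-phase low-pass filtered (15 Hz default)
    *before* epoching.  Epochs run from int(-0.2·fs) to int(0.6·fs) samples
    around each peak (ms -> samples truncated toward zero), both ends
    included: at 256 Hz a peak at sample 1000 spans samples 949..1153, i.e.
    205 samples.  Epochs that would reach
    outside the recording are dropped; overlap with the following beat is
    allowed (unavoidable for RR < 800 ms) and logged.  Trials with any
    sample beyond ±100 µV are rejected and counted.
    """
    if abs(eeg.fs - peaks.fs) > 1e-9:
        raise ValueError("EEG and peak train sampling rates differ")
    if peaks.peak_indices.size and (
        peaks.peak_indices[0] < 0 or peaks.peak_indices[-1] >= eeg.n_times
    ):
        raise ValueError("peaks outside recording")

    data = eeg.samples
    if lowpass_hz:
        sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=eeg.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)

    lo = int(window_ms[0] / 1000.0 * eeg.fs)
    hi = int(window_ms[1] / 1000.0 * eeg.fs)
    n_samp = hi - lo + 1
    times_ms = (np.arange(lo, hi + 1) / eeg.fs) * 1000.0

    rr = np.diff(peaks.peak_indices)
    if rr.size and np.any(rr < int(0.8 * eeg.fs)):
        logger.info(
            "%d epochs overlap the following beat (RR < 800 ms); retained",
            int(np.sum(rr < int(0.8 * eeg.fs))),
        )

    trials = []
    rejected = 0
    for pk in peaks.peak_indices:
        a, b = pk + lo, pk + hi + 1
        if a < 0 or b > eeg.n_times:
            continue
        epoch = data[:, a:b]
        if reject_uv is not None and np.any(np.abs(epoch) > reject_uv):
            rejected += 1
            continue
        trials.append(epoch)
    if len(trials) < min_beats:
        raise ValueError(
            f"only {len(trials)} usable beats (need >= {min_beats})"
        )
    arr = np.stack(trials, axis=1)  # channel x trial x time
    assert arr.shape[2] == n_samp
    return HEPEpochSet(
        data=arr, times_ms=times_ms, labels=list(eeg.labels), fs=eeg.fs,
        rejected_trials=rejected,
    )


def average_hep(
    epochs: HEPEpochSet,
    *,
    baseline_ms: tuple[float, float] | None = None,
    max_trials: int | None = None,
) -> HEPResult:
    """Trial-average the epochs per channel.

    Baseline subtraction (mean over a pre-R window, e.g. (-200, -50) ms) is
    OFF by default: the pre-R interval carries the cardiac field of the P/Q
    waves and subtracting it is contentious for HEP work.  When
    ``max_trials`` is set, the first k accepted trials enter the average.
    """
    data = epochs.data
    if data.shape[1] == 0:
        raise ValueError("zero surviving trials")
    if max_trials is not None:
        data = data[:, :max_trials, :]
    wave = data.mean(axis=1)
    if baseline_ms is not None:
        sel = (epochs.times_ms >= baseline_ms[0]) & (epochs.times_ms <= baseline_ms[1])
        wave = wave - wave[:, sel].mean(axis=1, keepdims=True)
    return HEPResult(
        waveforms=wave,
        times_ms=epochs.times_ms,
        labels=list(epochs.labels),
        n_trials_used=data.shape[1],
        meta={
            "baseline_ms": list(baseline_ms) if baseline_ms else None,
            "rejected_trials": epochs.rejected_trials,
        },
    )


def compare_groups_hep(
    group_a: list[HEPResult],
    group_b: list[HEPResult],
    *,
    toi_ms: tuple[float, float] = TOI_MS,
    alpha: float = 0.05,
    min_window_ms: float = MIN_WINDOW_MS,
) -> dict[str, list[tuple[float, float, float]]]:
    """Detect channels/time-windows with significant group differences.

    At each sample inside the TOI a one-way ANOVA (two groups) is run on the
    per-subject average HEP amplitude; p-values are Bonferroni-corrected by
    the number of tested samples per channel; surviving samples are merged
    into maximal contiguous windows, windows shorter than ``min_window_ms``
    are discarded, and each window reports the minimum corrected p inside it.

    Returns {channel: [(t_start_ms, t_end_ms, p_corrected), ...]}.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 subjects per group")
    times = group_a[0].times_ms
    labels = group_a[0].labels
    for r in group_a + group_b:
        if not np.array_equal(r.times_ms, times):
            raise ValueError("subjects have mismatched time axes")

    a = np.stack([r.waveforms for r in group_a])  # subj x chan x time
    b = np.stack([r.waveforms for r in group_b])
    toi_idx = np.flatnonzero((times >= toi_ms[0]) & (times <= toi_ms[1]))
    m = toi_idx.size

    out: dict[str, list[tuple[float, float, float]]] = {}
    for ci, chan in enumerate(labels):
        pvals = np.ones(m)
        for j, ti in enumerate(toi_idx):
            _, p = stats.f_oneway(a[:, ci, ti], b[:, ci, ti])
            pvals[j] = p
        corrected = np.minimum(pvals * m, 1.0)
        sig = corrected < alpha
        windows = []
        j = 0
        while j < m:
            if sig[j]:
                k = j
                while k + 1 < m and sig[k + 1]:
                    k += 1
                t0 = float(times[toi_idx[j]])
                t1 = float(times[toi_idx[k]])
                if t1 - t0 >= min_window_ms:
                    windows.append((t0, t1, float(corrected[j:k + 1].min())))
                j = k + 1
            else:
                j += 1
        out[chan] = windows
    return out
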