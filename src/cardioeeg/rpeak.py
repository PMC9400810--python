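"""R-peak detection (Pan-Tompkins style) and NN-interval series derivation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording

#: Physiological bounds for a normal-to-normal interval, in ms.
NN_BOUNDS_MS = (300.0, 2000.0)

#: Refractory period after an accepted R peak, in seconds.
REFRACTORY_S = 0.2

#: Maximum relative deviation from the running median tolerated for an NN
#: interval before it is rejected as artifactual.
NN_MEDIAN_DEVIATION = 0.2


class DetectionError(RuntimeError):
    """Raised when no R peaks can be found in an ECG trace."""


class InsufficientDataError(RuntimeError):
    """Raised when too few beats/intervals survive for analysis."""


@dataclass
class RPeakTrain:
    """Detected R-peak sample indices at a given sampling rate."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)


@dataclass
class NNSeries:
    """Normal-to-normal intervals after artifact exclusion.

    ``times_s`` holds the time of each interval's *terminating* beat.
    """

    intervals_ms: np.ndarray
    times_s: np.ndarray
    n_rejected: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.intervals_ms.shape != self.times_s.shape:
            raise ValueError("intervals and times must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("interval times must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def span_s(self) -> float:
        if self.times_s.size < 2:
            return 0.0
        return float(self.times_s[-1] - self.times_s[0])


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(
    ecg: Recording | np.ndarray,
    fs: float | None = None,
    *,
    refine_window_s: float = 0.05,
) -> RPeakTrain:
    """Detect R peaks in a single-lead ECG.

    The detection chain is the classic energy-based one: zero-phase band-pass
    5-15 Hz, differentiation, squaring, 150 ms moving-window integration, then
    adaptive dual-threshold peak picking with a 200 ms refractory period and a
    search-back pass for missed beats.  Each detection is refined to the local
    extremum of the raw (detrended) trace within +/-50 ms, using the absolute
    value so that detection is polarity invariant.

    Parameters
    ----------
    ecg : Recording or 1-D array
        Single ECG channel.  When an array is passed, ``fs`` is required.
    fs : float, optional
        Sampling rate, only used for array input.

    Returns
    -------
    RPeakTrain
    """
    if isinstance(ecg, Recording):
        if ecg.n_channels != 1:
            raise ValueError("detect_r_peaks expects a single-channel recording")
        x = ecg.samples[0]
        fs = ecg.fs
    else:
        x = np.asarray(ecg, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    if fs < 100:
        raise ValueError(f"sampling rate {fs} Hz too low for QRS detection (need >= 100)")
    if x.size < 10 * fs:
        raise ValueError("ECG shorter than 10 s")
    if np.ptp(x) == 0:
        raise DetectionError("flat ECG trace: no peaks")

    # Band-pass 5-15 Hz, zero phase.
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(filt)
    energy = deriv**2
    mwi = _moving_window_integral(energy, max(1, int(round(0.150 * fs))))

    refractory = int(round(REFRACTORY_S * fs))
    # Candidate local maxima of the integrated energy.
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        raise DetectionError("no candidate peaks in energy signal")

    # Adaptive dual thresholds (Pan-Tompkins running estimates).
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5 if mwi[: int(2 * fs)].size else float(mwi.max()) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        c = cand[i]
        if mwi[c] > threshold():
            if accepted and (c - accepted[-1]) < refractory:
                if mwi[c] > mwi[accepted[-1]]:
                    accepted[-1] = int(c)
                i += 1
                continue
            if accepted:
                rr_history.append(float(c - accepted[-1]))
                if len(rr_history) > 8:
                    rr_history.pop(0)
            accepted.append(int(c))
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
            # Search-back: if too long since last beat, take the best
            # candidate above the lower threshold.
            if accepted and rr_history:
                mean_rr = float(np.mean(rr_history))
                if (c - accepted[-1]) > 1.66 * mean_rr and mwi[c] > 0.5 * threshold():
                    if (c - accepted[-1]) >= refractory:
                        rr_history.append(float(c - accepted[-1]))
                        if len(rr_history) > 8:
                            rr_history.pop(0)
                        accepted.append(int(c))
                        spki = 0.25 * mwi[c] + 0.75 * spki
        i += 1

    if not accepted:
        raise DetectionError("no peaks exceeded the adaptive threshold")

    # Refine each detection to the raw-trace extremum within +/-50 ms.
    half = int(round(refine_window_s * fs))
    baseline = np.median(x)
    refined = []
    for c in accepted:
        lo = max(0, c - half)
        hi = min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi] - baseline))))
    refined_arr = np.unique(np.asarray(refined, dtype=int))
    # Enforce refractory after refinement.
    keep = [0]
    for j in range(1, refined_arr.size):
        if refined_arr[j] - refined_arr[keep[-1]] >= refractory:
            keep.append(j)
    return RPeakTrain(peak_indices=refined_arr[keep], fs=fs)


def to_nn_series(peaks: RPeakTrain) -> NNSeries:
    """Derive the NN-interval series from an R-peak train.

    Intervals outside (300, 2000) ms, or deviating more than 20% from the
    running median of the previous 5 accepted intervals, are excluded and
    counted in ``n_rejected``.  Gaps are not interpolated.
    """
    if peaks.n_peaks < 3:
        raise InsufficientDataError(f"need >= 3 peaks, got {peaks.n_peaks}")
    times = peaks.times_s
    rr_ms = np.diff(times) * 1000.0
    end_times = times[1:]

    lo, hi = NN_BOUNDS_MS
    accepted_vals: list[float] = []
    accepted_times: list[float] = []
    n_rejected = 0
    for val, t in zip(rr_ms, end_times):
        if not (lo < val < hi):
            n_rejected += 1
            continue
        if len(accepted_vals) >= 5:
            med = float(np.median(accepted_vals[-5:]))
        elif accepted_vals:
            med = float(np.median(accepted_vals))
        else:
            med = val
        if med > 0 and abs(val - med) / med > NN_MEDIAN_DEVIATION:
            n_rejected += 1
            continue
        accepted_vals.append(float(val))
        accepted_times.append(float(t))

    if len(accepted_vals) < 2:
        raise InsufficientDataError(
            f"only {len(accepted_vals)} NN intervals survived exclusion"
        )
    return NNSeries(
        intervals_ms=np.asarray(accepted_vals),
        times_s=np.asarray(accepted_times),
        n_rejected=n_rejected,
        meta={"rule": "300-2000ms AND <=20% deviation from 5-beat running median"},
    )
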