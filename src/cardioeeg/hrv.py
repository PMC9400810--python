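"""Heart-rate-variability metrics: SDNN, RMSSD, SD1 and HF spectral power.

Conventions (recorded in every output's metadata block):

* SDNN uses the sample standard deviation (denominator N-1).
* SD1 is computed from the Poincare rotated-axis construction and
  cross-checked against the RMSSD/sqrt(2) identity.
* HF power integrates the Welch PSD of the 4 Hz cubic-spline-resampled,
  linearly detrended NN tachogram over 0.15-0.40 Hz, in ms^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .rpeak import InsufficientDataError, NNSeries

#: High-frequency band of the NN tachogram, Hz.
HF_BAND_HZ = (0.15, 0.40)

#: Uniform resampling rate of the tachogram before spectral analysis, Hz.
TACHOGRAM_FS = 4.0

#: Welch segment length for the tachogram PSD, samples (64 s at 4 Hz).
TACHOGRAM_NPERSEG = 256

METADATA = {
    "sdnn_denominator": "N-1",
    "sd1_construction": "poincare rotated axes; equals RMSSD/sqrt(2)",
    "hf_band_hz": list(HF_BAND_HZ),
    "tachogram_resampling": f"cubic spline to {TACHOGRAM_FS} Hz, linear detrend",
    "tachogram_psd": f"Welch, Hamming, {TACHOGRAM_NPERSEG}-point segments, 50% overlap",
}


@dataclass
class HRVSummary:
    """Per-subject HRV parameters."""

    sdnn_ms: float
    rmssd_ms: float
    sd1_ms: float
    hf_ms2: float
    n_intervals: int
    meta: dict = field(default_factory=lambda: dict(METADATA))

    def as_dict(self) -> dict:
        return {
            "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms,
            "sd1_ms": self.sd1_ms,
            "hf_ms2": self.hf_ms2,
            "n_intervals": self.n_intervals,
        }


def compute_time_domain(nn: NNSeries) -> tuple[float, float, float]:
    """Return (SDNN, RMSSD, SD1) in ms.

    SD1 is derived from the Poincare plot: points (NN_k, NN_{k+1}) are
    rotated by 45 degrees and SD1 is the standard deviation along the minor
    axis, which reduces to sqrt(var(successive differences)/2).
    """
    x = np.asarray(nn.intervals_ms, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 NN intervals, got {x.size}")
    sdnn = float(np.std(x, ddof=1))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    # Poincare minor axis: rotate (x1, x2) pairs by 45 deg; SD1 is the SD of
    # (x2 - x1)/sqrt(2) with a population denominator over pairs.
    minor = (x[1:] - x[:-1]) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(minor**2)))
    # Cross-check the SD1 = RMSSD/sqrt(2) identity.
    expected = rmssd / np.sqrt(2.0)
    if expected > 0 and abs(sd1 - expected) / expected > 1e-9:
        raise AssertionError("SD1 != RMSSD/sqrt(2): internal inconsistency")
    return sdnn, rmssd, sd1


def compute_hf_power(nn: NNSeries) -> float:
    """Absolute HF power (0.15-0.40 Hz) of the NN tachogram in ms^2."""
    if nn.n_intervals == 0:
        raise InsufficientDataError("empty NN series")
    if nn.span_s < 60.0:
        raise InsufficientDataError(
            f"recording span {nn.span_s:.1f} s too short for HF analysis (need >= 60 s)"
        )
    t = nn.times_s
    y = nn.intervals_ms
    spline = interpolate.CubicSpline(t, y)
    grid = np.arange(t[0], t[-1], 1.0 / TACHOGRAM_FS)
    resampled = spline(grid)
    resampled = signal.detrend(resampled, type="linear")
    nperseg = min(TACHOGRAM_NPERSEG, resampled.size)
    freqs, psd = signal.welch(
        resampled,
        fs=TACHOGRAM_FS,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    lo, hi = HF_BAND_HZ
    band = (freqs >= lo) & (freqs <= hi)
    if not np.any(band):
        raise InsufficientDataError("no PSD bins inside the HF band")
    return float(np.trapezoid(psd[band], freqs[band]))


def summarize(nn: NNSeries) -> HRVSummary:
    """Compute the full four-parameter HRV summary from an NN series."""
    sdnn, rmssd, sd1 = compute_time_domain(nn)
    hf = compute_hf_power(nn)
    return HRVSummary(
        sdnn_ms=sdnn, rmssd_ms=rmssd, sd1_ms=sd1, hf_ms2=hf,
        n_intervals=nn.n_intervals,
    )
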