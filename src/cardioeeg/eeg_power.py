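"""EEG preprocessing, Welch band power per ROI, and alpha-peak frequency.

The predictor table used by the coupling statistics lives here: per subject,
per frequency band, per (ROI, hemisphere), the mean power in dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import MASTOID_CHANNELS, Recording, canonical_label

logger = logging.getLogger(__name__)

#: Closed-open frequency bands, Hz.
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta": (13.0, 31.0),
}

#: (ROI, hemisphere) -> member channels.
DEFAULT_ROIS = {
    ("F", "L"): ("Fp1", "F3", "F7"),
    ("F", "R"): ("Fp2", "F4", "F8"),
    ("C", "L"): ("C3",),
    ("C", "R"): ("C4",),
    ("T", "L"): ("T3", "T5"),
    ("T", "R"): ("T4", "T6"),
    ("P", "L"): ("P3",),
    ("P", "R"): ("P4",),
    ("O", "L"): ("O1",),
    ("O", "R"): ("O2",),
}

ROI_ORDER = ("F", "C", "T", "P", "O")

#: Welch defaults: 4 s Hamming segments, 0% overlap, density scaling.
WELCH_SEGMENT_S = 4.0

#: Amplitude threshold for 1 s epoch rejection, µV.
REJECT_THRESHOLD_UV = 150.0


@dataclass
class BandScheme:
    """Named, non-overlapping, ascending closed-open frequency ranges."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError(f"degenerate band ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            if lo < hi:
                raise ValueError("bands must not overlap")

    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class ROIMap:
    """(ROI, hemisphere) -> channel tuple; no channel may appear twice."""

    rois: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROIS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chans in self.rois.values():
            for c in chans:
                cc = canonical_label(c)
                if cc in seen:
                    raise ValueError(f"channel {c} assigned to two ROIs")
                seen.add(cc)

    def channels(self) -> list[str]:
        return [c for chans in self.rois.values() for c in chans]


def preprocess(
    eeg: Recording,
    *,
    l_freq: float = 0.5,
    h_freq: float = 100.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    reference: str = "mastoids",
) -> Recording:
    """Filter and re-reference a raw EEG recording.

    Zero-phase 4th-order Butterworth band-pass (0.5-100 Hz), zero-phase notch
    at 50 Hz (Q=30), then re-referencing to the mean of the two mastoids when
    both are present; otherwise a common-average reference is used and the
    downgrade is logged.
    """
    if np.any(~np.isfinite(eeg.samples)):
        raise ValueError("NaN/inf values in EEG input")
    out = eeg.copy()
    nyq = eeg.fs / 2.0
    h = min(h_freq, 0.99 * nyq)
    sos = signal.butter(4, [l_freq, h], btype="bandpass", fs=eeg.fs, output="sos")
    out.samples = signal.sosfiltfilt(sos, out.samples, axis=-1)
    if notch_hz and notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=eeg.fs)
        out.samples = signal.filtfilt(b, a, out.samples, axis=-1)

    labels = [canonical_label(lab) for lab in out.labels]
    if reference == "mastoids" and all(m in labels for m in MASTOID_CHANNELS):
        ref = np.mean(
            [out.samples[labels.index(m)] for m in MASTOID_CHANNELS], axis=0
        )
    elif reference in ("mastoids", "average"):
        if reference == "mastoids":
            logger.warning(
                "mastoid channels %s not found; downgrading to common-average "
                "reference", MASTOID_CHANNELS,
            )
        ref = np.mean(out.samples, axis=0)
    elif reference == "none":
        ref = 0.0
    else:
        raise ValueError(f"unknown reference scheme {reference!r}")
    out.samples = out.samples - ref
    return out


def good_window_mask(eeg: Recording, threshold_uv: float = REJECT_THRESHOLD_UV) -> np.ndarray:
    """Boolean mask over 1 s windows; False where any sample exceeds the
    amplitude threshold on any channel (simple artifact rejection)."""
    win = int(round(eeg.fs))
    n_win = eeg.n_times // win
    mask = np.ones(n_win, dtype=bool)
    for w in range(n_win):
        seg = eeg.samples[:, w * win:(w + 1) * win]
        if np.any(np.abs(seg) > threshold_uv):
            mask[w] = False
    return mask


def welch_psd(
    x: np.ndarray,
    fs: float,
    *,
    segment_s: float = WELCH_SEGMENT_S,
    window: str = "hamming",
    overlap: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged periodogram (Welch) of a single channel.

    Hamming window, 4 s segments, 0% overlap by default; density scaling
    (power per Hz) with the window-power correction applied by
    :func:`scipy.signal.welch`.

    Returns
    -------
    freqs, psd : ndarray
        Frequency grid (Hz) and PSD in input-units²/Hz.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one Welch segment ({nperseg})"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window=window, nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant", scaling="density",
    )
    return freqs, psd


def band_power_db(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float],
    *,
    floor: float = 1e-20,
) -> float:
    """Mean PSD density over a closed-open band, in dB (10·log10)."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    if not np.any(sel):
        raise ValueError(f"no PSD bins inside band [{lo}, {hi}) Hz")
    mean_linear = float(np.mean(psd[sel]))
    return 10.0 * np.log10(max(mean_linear, floor))


def band_roi_power(
    eeg: Recording,
    bands: BandScheme | None = None,
    rois: ROIMap | None = None,
    *,
    average: str = "db",
    segment_s: float = WELCH_SEGMENT_S,
) -> pd.DataFrame:
    """Band × (ROI, hemisphere) mean power table for one subject.

    Per channel the PSD density is averaged over each band's bins and
    converted to dB; the ROI value is the arithmetic mean of its member
    channels' dB values (``average="db"``, default) or the dB of the mean
    linear power (``average="linear"``).

    Returns a tidy DataFrame with columns band, roi, hemisphere, power_db.
    """
    bands = bands or BandScheme()
    rois = rois or ROIMap()
    chan_psd: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chans in rois.rois.values():
        for c in chans:
            if c not in chan_psd:
                chan_psd[c] = welch_psd(eeg.get_channel(c), eeg.fs, segment_s=segment_s)
    rows = []
    for band_name, rng in bands.bands.items():
        for (roi, hemi), chans in rois.rois.items():
            if average == "db":
                vals = [band_power_db(*chan_psd[c], rng) for c in chans]
                power = float(np.mean(vals))
            elif average == "linear":
                lin = []
                for c in chans:
                    freqs, psd = chan_psd[c]
                    sel = (freqs >= rng[0]) & (freqs < rng[1])
                    lin.append(float(np.mean(psd[sel])))
                power = 10.0 * np.log10(max(float(np.mean(lin)), 1e-20))
            else:
                raise ValueError(f"unknown averaging mode {average!r}")
            rows.append(
                {"band": band_name, "roi": roi, "hemisphere": hemi, "power_db": power}
            )
    return pd.DataFrame(rows)


def alpha_peak_frequency(
    freqs: np.ndarray,
    psd: np.ndarray,
    *,
    window_hz: tuple[float, float] = (7.0, 13.0),
    prominence_factor: float = 2.0,
) -> tuple[float, bool]:
    """Alpha-peak frequency of a (typically posterior-averaged) PSD.

    The maximum of the PSD within the search window is refined by a local
    quadratic fit through the peak bin and its neighbours.  The ``no_peak``
    flag is returned True when the maximum sits on a window boundary or is
    not prominent (peak density below ``prominence_factor`` times the median
    density inside the window, as for a flat/white spectrum).

    Returns
    -------
    apf_hz : float
    no_peak : bool
    """
    lo, hi = window_hz
    sel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if sel.size < 3:
        raise ValueError(f"PSD grid does not cover {lo}-{hi} Hz")
    sub = psd[sel]
    k = int(np.argmax(sub))
    if k == 0 or k == sub.size - 1:
        return float(freqs[sel[k]]), True
    if sub[k] < prominence_factor * np.median(sub):
        return float(freqs[sel[k]]), True
    # Quadratic through (f_{k-1}, f_k, f_{k+1}).
    y0, y1, y2 = sub[k - 1], sub[k], sub[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    df = freqs[sel[1]] - freqs[sel[0]]
    return float(freqs[sel[k]] + delta * df), False


def posterior_mean_psd(
    eeg: Recording,
    *,
    channels: tuple[str, ...] = ("O1", "O2", "P3", "P4"),
    segment_s: float = WELCH_SEGMENT_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Welch PSD over the posterior (occipital + parietal) channels."""
    psds = []
    freqs = None
    for c in channels:
        freqs, p = welch_psd(eeg.get_channel(c), eeg.fs, segment_s=segment_s)
        psds.append(p)
    return freqs, np.mean(psds, axis=0)
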