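"""Synthetic two-group EEG+ECG cohort generator.

A single latent "vagal tone" scalar per subject drives both the
high-frequency modulation depth of the RR series and the per-band EEG power,
so downstream HRV <-> band-power coupling has a known, configurable sign and
strength.  An R-locked evoked component with group-dependent amplitude and a
cardiac-field bleed of the ECG into the scalp channels complete the
structure the analysis pipeline is meant to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf
from .eeg_power import BandScheme, ROIMap, band_power_db, welch_psd
from .recording import ECG_CHANNEL, EEG_CHANNELS_1020, Recording

RE_GROUP = "RE-like"
CONTROL_GROUP = "control-like"

#: LF and HF modulation frequencies of the RR series, Hz.
RR_LF_HZ = 0.10
RR_HF_HZ = 0.25

_RR_BOUNDS_MS = (300.0, 2000.0)

#: Default per-band baseline EEG power, dB re µV²/Hz.
DEFAULT_BAND_BASE_DB = {
    "delta": 12.0, "theta": 10.0, "alpha1": 13.0, "alpha2": 10.0, "beta": 6.0,
}

#: Scalp topography of the injected R-locked evoked component (unitless
#: weights).  Fronto-central maximum; deliberately non-uniform so the
#: component survives common-average re-referencing.
DEFAULT_HEP_TOPOGRAPHY = {
    "Fp1": 0.8, "Fp2": 0.8, "F7": 0.6, "F3": 1.0, "Fz": 1.0, "F4": 1.0,
    "F8": 0.6, "T3": 0.4, "C3": 1.0, "Cz": 1.0, "C4": 1.0, "T4": 0.4,
    "T5": 0.5, "P3": 0.6, "Pz": 0.6, "P4": 0.6, "T6": 0.5, "O1": 0.3,
    "O2": 0.3,
}

#: Per-channel weights of the cardiac-field bleed (left-lateralized, as the
#: heart's field is); multiplied by ``cfa_gain``.
DEFAULT_CFA_TOPOGRAPHY = {
    "Fp1": 0.5, "Fp2": 0.5, "F7": 0.8, "F3": 0.6, "Fz": 0.5, "F4": 0.6,
    "F8": 0.7, "T3": 1.2, "C3": 0.9, "Cz": 0.7, "C4": 0.8, "T4": 1.0,
    "T5": 1.1, "P3": 0.9, "Pz": 0.8, "P4": 0.8, "T6": 0.9, "O1": 1.0,
    "O2": 0.9,
}

#: Default coupling slopes, dB per unit tone: positive regime for the
#: "RE-like" group, negative for "control-like".
DEFAULT_SLOPES = {
    RE_GROUP: {"delta": 2.5, "theta": 2.5, "alpha1": 2.5, "alpha2": 2.5, "beta": 2.5},
    CONTROL_GROUP: {"delta": -2.5, "theta": -2.5, "alpha1": -2.5, "alpha2": -2.5, "beta": -2.5},
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``band_coupling_slope`` maps group -> band -> dB per unit tone (a scalar
    per group is broadcast to every band); the slope's sign defines the
    coupling regime injected for that group.
    """

    n_per_group: tuple[int, int] = (11, 7)
    duration_s: float = 600.0
    fs: float = 256.0
    rr_mean_ms: float = 900.0
    rr_lf_amp_ms: float = 30.0
    rr_hf_amp_base_ms: float = 40.0
    rr_jitter_ms: float = 5.0
    tone_coupling_gain: float = 12.0
    band_base_db: dict = field(default_factory=lambda: dict(DEFAULT_BAND_BASE_DB))
    band_coupling_slope: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SLOPES.items()}
    )
    hep_amp_uv: dict = field(
        default_factory=lambda: {RE_GROUP: 5.0, CONTROL_GROUP: 2.0}
    )
    hep_latency_ms: tuple[float, float] = (400.0, 500.0)
    hep_topography: dict = field(default_factory=lambda: dict(DEFAULT_HEP_TOPOGRAPHY))
    cfa_gain: float = 3.0
    cfa_topography: dict = field(default_factory=lambda: dict(DEFAULT_CFA_TOPOGRAPHY))
    noise_sd_uv: float = 10.0
    ecg_noise_sd_mv: float = 0.01
    ecg_wander_mv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = self.duration_s * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration_s x fs must be an integer sample count")
        if self.rr_mean_ms <= self.rr_lf_amp_ms + self.rr_hf_amp_base_ms:
            raise ValueError("rr_mean_ms must exceed the summed modulation amplitudes")
        if not (_RR_BOUNDS_MS[0] < self.rr_mean_ms < _RR_BOUNDS_MS[1]):
            raise ValueError(f"rr_mean_ms outside physiological bounds {_RR_BOUNDS_MS}")

    def slope(self, group: str, band: str, roi: str | None = None) -> float:
        spec = self.band_coupling_slope.get(group, 0.0)
        if isinstance(spec, dict):
            val = spec.get(band, 0.0)
            if isinstance(val, dict):  # optional per-ROI refinement
                return float(val.get(roi, 0.0))
            return float(val)
        return float(spec)


@dataclass
class SyntheticSubject:
    subject_id: str
    group_label: str
    tone_u: float
    recording: Recording
    true_r_peaks: np.ndarray
    true_band_power_db: pd.DataFrame
    true_hrv: dict
    sub_seed: int


def generate_rr_series(
    spec: CohortSpec, tone_u: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the RR interval series and cumulative beat times.

    RR(k) = mean + lf_amp·sin(2π·0.10·t_k) + depth·sin(2π·0.25·t_k) + jitter,
    where depth = rr_hf_amp_base_ms + tone_coupling_gain·tone_u (clamped at
    zero so HF power stays monotone in tone).  Beat times are cumulative sums
    starting 0.5 s into the record, truncated at ``duration_s``.

    Returns
    -------
    rr_ms : ndarray
        Intervals following each beat except the last.
    beat_times_s : ndarray
    """
    if not np.isfinite(tone_u):
        raise ValueError("tone_u must be finite")
    depth = max(0.0, spec.rr_hf_amp_base_ms + spec.tone_coupling_gain * tone_u)
    beats = [0.5]
    rr: list[float] = []
    while True:
        t = beats[-1]
        interval = (
            spec.rr_mean_ms
            + spec.rr_lf_amp_ms * np.sin(2 * np.pi * RR_LF_HZ * t)
            + depth * np.sin(2 * np.pi * RR_HF_HZ * t)
            + (spec.rr_jitter_ms * rng.standard_normal() if spec.rr_jitter_ms else 0.0)
        )
        if not (_RR_BOUNDS_MS[0] < interval < _RR_BOUNDS_MS[1]):
            raise ValueError(
                f"spec produced RR interval {interval:.1f} ms outside {_RR_BOUNDS_MS}"
            )
        nxt = t + interval / 1000.0
        if nxt >= spec.duration_s:
            break
        rr.append(float(interval))
        beats.append(float(nxt))
    return np.asarray(rr), np.asarray(beats)


# PQRST template: (amplitude mV, center offset s, width s) per deflection.
_PQRST = (
    (0.12, -0.200, 0.025),   # P
    (-0.15, -0.025, 0.010),  # Q
    (1.00, 0.000, 0.012),    # R
    (-0.25, 0.030, 0.012),   # S
    (0.30, 0.250, 0.050),    # T
)


def pqrst_template(t: np.ndarray) -> np.ndarray:
    """Fixed sum-of-Gaussians PQRST waveform (mV) centered on the R wave."""
    out = np.zeros_like(t, dtype=float)
    for amp, mu, sd in _PQRST:
        out += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return out


def synthesize_ecg(
    beat_times_s: np.ndarray,
    fs: float,
    duration_s: float,
    rng: np.random.Generator,
    *,
    noise_sd_mv: float = 0.01,
    wander_mv: float = 0.05,
) -> tuple[Recording, np.ndarray]:
    """Render an ECG trace from beat times.

    Each beat contributes one PQRST template; the R wave is the per-beat
    global maximum.  Baseline wander (slow sine) and white noise are added
    on top.

    Returns the single-channel Recording (mV) and the true R-peak sample
    indices.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if beat_times_s.size and np.any(np.diff(beat_times_s) <= 0):
        raise ValueError("beat times must be strictly increasing")
    if beat_times_s.size > 1 and np.any(np.diff(beat_times_s) < 0.3):
        raise ValueError("RR < 300 ms would overlap PQRST templates")
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    half = int(round(0.45 * fs))
    tmpl_t = np.arange(-half, half + 1) / fs
    tmpl = pqrst_template(tmpl_t)
    r_peaks = []
    for bt in beat_times_s:
        center = int(round(bt * fs))
        lo, hi = center - half, center + half + 1
        tlo = max(0, lo)
        thi = min(n, hi)
        if thi <= tlo:
            continue
        trace[tlo:thi] += tmpl[tlo - lo: thi - lo]
        if 0 <= center < n:
            r_peaks.append(center)
    if wander_mv:
        tgrid = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        trace += wander_mv * np.sin(2 * np.pi * 0.2 * tgrid + phase)
    if noise_sd_mv:
        trace += noise_sd_mv * rng.standard_normal(n)
    rec = Recording(samples=trace[np.newaxis, :], fs=fs, labels=[ECG_CHANNEL], units=["mV"])
    return rec, np.asarray(r_peaks, dtype=int)


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi) Hz, synthesized in the
    frequency domain (exact brick-wall band edges)."""
    lo, hi = band
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = np.zeros(freqs.size, dtype=complex)
    sel = (freqs >= lo) & (freqs < hi)
    k = int(np.count_nonzero(sel))
    spectrum[sel] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _hep_waveform(fs: float, latency_ms: tuple[float, float], amp_uv: float) -> tuple[np.ndarray, int]:
    """Half-sine deflection; returns (waveform, onset offset in samples)."""
    lo, hi = latency_ms
    start = int(round(lo / 1000.0 * fs))
    stop = int(round(hi / 1000.0 * fs))
    k = np.arange(stop - start)
    wave = amp_uv * np.sin(np.pi * (k + 0.5) / max(1, stop - start))
    return wave, start


def synthesize_eeg(
    spec: CohortSpec,
    tone_u: float,
    group_label: str,
    true_r_peaks: np.ndarray,
    ecg_trace: np.ndarray,
    rng: np.random.Generator,
    *,
    bands: BandScheme | None = None,
    rois: ROIMap | None = None,
    channels: tuple[str, ...] | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesize the 19-channel EEG with controlled band power.

    Each channel is a sum over bands of band-limited noise whose Welch band
    power (measured with the analysis defaults) is calibrated closed-loop to
    ``base + slope·tone`` dB, plus the R-locked evoked component (half-sine,
    scaled by the channel's topography weight), the cardiac-field bleed
    ``cfa_gain × topography × ecg``, and white sensor noise.

    ``channels`` restricts generation to a subset of the montage (used by
    replicate studies that only measure one ROI); default is all 19.

    Returns the Recording and the ground-truth band × ROI power table.
    """
    bands = bands or BandScheme()
    rois = rois or ROIMap()
    chan_list = tuple(channels) if channels is not None else EEG_CHANNELS_1020
    unknown = [c for c in chan_list if c not in EEG_CHANNELS_1020]
    if unknown:
        raise ValueError(f"unknown channel labels {unknown}")
    n = int(round(spec.duration_s * spec.fs))
    fs = spec.fs

    # channel -> (roi, hemisphere); channels outside every ROI get slope 0.
    chan_roi: dict[str, tuple[str, str]] = {}
    for key, chans in rois.rois.items():
        for c in chans:
            chan_roi[c] = key

    hep_amp = float(spec.hep_amp_uv.get(group_label, 0.0)) if isinstance(
        spec.hep_amp_uv, dict) else float(spec.hep_amp_uv)
    hep_wave, hep_offset = _hep_waveform(fs, spec.hep_latency_ms, hep_amp)

    samples = np.zeros((len(chan_list), n))
    truth_rows = []
    for ci, chan in enumerate(chan_list):
        roi_key = chan_roi.get(chan)
        sig = np.zeros(n)
        for band_name, rng_hz in bands.bands.items():
            base = float(spec.band_base_db.get(band_name, 0.0))
            slope = spec.slope(group_label, band_name, roi_key[0] if roi_key else None) if roi_key else 0.0
            target_db = base + slope * tone_u
            noise = _band_noise(n, fs, rng_hz, rng)
            freqs, psd = welch_psd(noise, fs)
            measured_db = band_power_db(freqs, psd, rng_hz)
            sig += noise * 10.0 ** ((target_db - measured_db) / 20.0)
        if hep_amp and hep_wave.size:
            w = float(spec.hep_topography.get(chan, 1.0))
            for pk in true_r_peaks:
                lo = pk + hep_offset
                hi = lo + hep_wave.size
                if 0 <= lo and hi <= n:
                    sig[lo:hi] += w * hep_wave
        if spec.cfa_gain:
            sig += spec.cfa_gain * float(spec.cfa_topography.get(chan, 1.0)) * ecg_trace
        if spec.noise_sd_uv:
            sig += spec.noise_sd_uv * rng.standard_normal(n)
        samples[ci] = sig

    for band_name in bands.bands:
        base = float(spec.band_base_db.get(band_name, 0.0))
        for (roi, hemi) in rois.rois:
            truth_rows.append({
                "band": band_name, "roi": roi, "hemisphere": hemi,
                "power_db": base + spec.slope(group_label, band_name, roi) * tone_u,
            })
    truth = pd.DataFrame(truth_rows)
    if not np.all(np.isfinite(truth["power_db"])):
        raise ValueError("non-finite ground-truth band power")
    rec = Recording(
        samples=samples, fs=fs, labels=list(chan_list),
        units=["uV"] * len(chan_list),
    )
    return rec, truth


def _true_hrv(rr_ms: np.ndarray, beat_times_s: np.ndarray) -> dict:
    """Ground-truth HRV computed directly from the generated RR series."""
    from .hrv import compute_hf_power, compute_time_domain
    from .rpeak import NNSeries

    nn = NNSeries(intervals_ms=rr_ms, times_s=beat_times_s[1:], n_rejected=0)
    sdnn, rmssd, sd1 = compute_time_domain(nn)
    hf = compute_hf_power(nn)
    return {"sdnn_ms": sdnn, "rmssd_ms": rmssd, "sd1_ms": sd1, "hf_ms2": hf,
            "n_intervals": int(rr_ms.size)}


def generate_subject(
    spec: CohortSpec,
    subject_id: str,
    group_label: str,
    sub_seed: int,
) -> SyntheticSubject:
    """Generate one subject (RR -> ECG -> EEG) from a dedicated sub-seed."""
    rng = np.random.default_rng(sub_seed)
    tone_u = float(rng.standard_normal())
    rr_ms, beat_times = generate_rr_series(spec, tone_u, rng)
    ecg, true_r_peaks = synthesize_ecg(
        beat_times, spec.fs, spec.duration_s, rng,
        noise_sd_mv=spec.ecg_noise_sd_mv, wander_mv=spec.ecg_wander_mv,
    )
    eeg, truth = synthesize_eeg(
        spec, tone_u, group_label, true_r_peaks, ecg.samples[0], rng
    )
    recording = Recording(
        samples=np.vstack([eeg.samples, ecg.samples]),
        fs=spec.fs,
        labels=list(eeg.labels) + [ECG_CHANNEL],
        units=list(eeg.units) + ["mV"],
    )
    if true_r_peaks.size and not (
        np.all(np.diff(true_r_peaks) > 0)
        and true_r_peaks[0] >= 0
        and true_r_peaks[-1] < recording.n_times
    ):
        raise AssertionError("invalid ground-truth R peaks")
    return SyntheticSubject(
        subject_id=subject_id,
        group_label=group_label,
        tone_u=tone_u,
        recording=recording,
        true_r_peaks=true_r_peaks,
        true_band_power_db=truth,
        true_hrv=_true_hrv(rr_ms, beat_times),
        sub_seed=sub_seed,
    )


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSubject], dict]:
    """Generate the full two-group cohort.

    Deterministic given ``spec.seed``: each subject draws from an independent
    sub-seed spawned from the master seed, so the recordings do not depend on
    the output directory or on generation order.

    When ``out_dir`` is given, one EDF per subject plus a JSON manifest and
    ground-truth CSV tables are written there.

    Returns
    -------
    subjects : list of SyntheticSubject
    manifest : dict
    """
    seq = np.random.SeedSequence(spec.seed)
    n_re, n_ctl = spec.n_per_group
    groups = [RE_GROUP] * n_re + [CONTROL_GROUP] * n_ctl
    sub_seeds = [int(s.generate_state(1)[0]) for s in seq.spawn(len(groups))]

    subjects = []
    manifest_subjects = []
    for i, (grp, sseed) in enumerate(zip(groups, sub_seeds)):
        sid = f"sub-{i + 1:02d}"
        subj = generate_subject(spec, sid, grp, sseed)
        subjects.append(subj)
        manifest_subjects.append({
            "subject_id": sid,
            "group": grp,
            "sub_seed": sseed,
            "tone_u": subj.tone_u,
            "n_beats": int(subj.true_r_peaks.size),
            "true_hrv": subj.true_hrv,
            "edf": f"{sid}.edf",
        })

    spec_dict = asdict(spec)
    spec_dict["n_per_group"] = list(spec.n_per_group)
    spec_dict["hep_latency_ms"] = list(spec.hep_latency_ms)
    manifest = {"spec": spec_dict, "subjects": manifest_subjects}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        truth_frames = []
        for subj in subjects:
            write_edf(out_dir / f"{subj.subject_id}.edf", subj.recording,
                      recording_id=subj.subject_id)
            tb = subj.true_band_power_db.copy()
            tb.insert(0, "subject", subj.subject_id)
            tb.insert(1, "group", subj.group_label)
            truth_frames.append(tb)
            np.savetxt(
                out_dir / f"{subj.subject_id}_rpeaks.csv",
                subj.true_r_peaks[:, np.newaxis], fmt="%d",
                header="r_peak_sample", comments="",
            )
        pd.concat(truth_frames, ignore_index=True).to_csv(
            out_dir / "true_band_power.csv", index=False
        )
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return subjects, manifest
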