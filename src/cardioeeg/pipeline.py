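"""End-to-end orchestration: generate/read recordings, run every analysis
stage in dependency order, and write all artifacts with metadata sidecars."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, eeg_power, hep, hrv, rpeak
from .edf import read_edf
from .recording import (
    ECG_CHANNEL,
    EEG_CHANNELS_1020,
    MASTOID_CHANNELS,
    Recording,
    canonical_label,
)
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

EYES_OPEN_S = 540.0  # first 9 min of the 10 min session


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializes losslessly to YAML."""

    output_dir: str = "cardioeeg_out"
    seed: int = 0
    synthetic: bool = True
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    manifest_path: str | None = None                 # real-data mode
    segment: str = "eyes_open"                       # or "full"
    fs_expected: float = 256.0
    reference: str = "mastoids"
    roi_average: str = "db"
    hep_baseline_ms: tuple[float, float] | None = None
    hep_max_trials: int | None = None
    make_plots: bool = False
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("hep_baseline_ms") is not None:
            d["hep_baseline_ms"] = tuple(d["hep_baseline_ms"])
        return cls(**d)


def read_recording(
    path: str | Path,
    *,
    fs: float = 256.0,
    expected_channels: tuple[str, ...] | None = None,
) -> Recording:
    """Read an EDF or plain CSV recording and canonicalize channel labels.

    CSV files carry one column per channel with a header row; ``fs`` applies
    to CSV only (EDF encodes its own rate).  Unknown channel labels raise,
    they are never silently dropped.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = read_edf(path)
    elif path.suffix.lower() in (".csv", ".txt"):
        df = pd.read_csv(path)
        units = ["mV" if canonical_label(c) == ECG_CHANNEL else "uV" for c in df.columns]
        rec = Recording(
            samples=df.to_numpy(dtype=float).T, fs=fs,
            labels=list(df.columns), units=units,
        )
    else:
        raise ValueError(f"unsupported recording format: {path.suffix!r}")

    known = set(EEG_CHANNELS_1020) | set(MASTOID_CHANNELS) | {ECG_CHANNEL}
    mapped = []
    for lab in rec.labels:
        c = canonical_label(lab)
        if c not in known:
            raise ValueError(f"{path.name}: unresolvable channel label {lab!r}")
        mapped.append(c)
    rec.labels = mapped
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in mapped]
        if missing:
            raise ValueError(f"{path.name}: missing channels {missing}")
    return rec


def _crop_segment(rec: Recording, segment: str) -> Recording:
    if segment == "full":
        return rec
    if segment == "eyes_open":
        n = int(min(rec.n_times, round(EYES_OPEN_S * rec.fs)))
        out = rec.copy()
        out.samples = out.samples[:, :n]
        return out
    raise ValueError(f"unknown segment selection {segment!r}")


def _analyze_subject(rec: Recording, config: RunConfig) -> dict:
    """Single-subject chain: R peaks -> NN -> HRV; preprocess -> band power;
    HEP epochs -> average."""
    rec = _crop_segment(rec, config.segment)
    ecg = rec.pick([ECG_CHANNEL])
    eeg_labels = [lab for lab in rec.labels if lab != ECG_CHANNEL]
    eeg = rec.pick(eeg_labels)

    peaks = rpeak.detect_r_peaks(ecg)
    nn = rpeak.to_nn_series(peaks)
    summary = hrv.summarize(nn)

    clean = eeg_power.preprocess(eeg, reference=config.reference)
    powers = eeg_power.band_roi_power(clean, average=config.roi_average)

    epochs = hep.epoch_heartbeats(clean, peaks)
    hep_avg = hep.average_hep(
        epochs, baseline_ms=config.hep_baseline_ms, max_trials=config.hep_max_trials,
    )
    freqs, post_psd = eeg_power.posterior_mean_psd(clean)
    return {
        "nn": nn, "hrv": summary, "band_power": powers, "hep": hep_avg,
        "n_peaks": peaks.n_peaks, "psd": (freqs, post_psd),
    }


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write every artifact under
    ``config.output_dir``.  Per-subject failures are isolated and reported;
    the run fails only when an entire stage comes out empty."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    # --- stage 1: obtain recordings -------------------------------------
    subject_recs: list[tuple[str, str, Recording]] = []
    failures: list[dict] = []
    if config.synthetic:
        spec = CohortSpec(**{**config.cohort, "seed": config.seed})
        rec_dir = out / "recordings"
        subjects, manifest = generate_cohort(spec, rec_dir)
        for s in subjects:
            subject_recs.append((s.subject_id, s.group_label, s.recording))
    else:
        if not config.manifest_path:
            raise ValueError("manifest_path required when synthetic=False")
        with open(config.manifest_path) as fh:
            manifest = json.load(fh)
        base = Path(config.manifest_path).parent
        for entry in manifest["subjects"]:
            sid, grp = entry["subject_id"], entry["group"]
            try:
                rec = read_recording(base / entry["edf"], fs=config.fs_expected)
                subject_recs.append((sid, grp, rec))
            except Exception as exc:  # noqa: BLE001 - isolate per subject
                logger.error("subject %s failed to load: %s", sid, exc)
                failures.append({"subject_id": sid, "stage": "read", "error": str(exc)})
    if not subject_recs:
        raise RuntimeError("no readable recordings: empty stage")

    # --- stage 2: per-subject analysis ----------------------------------
    per_subject: dict[str, dict] = {}
    groups: dict[str, str] = {}
    for sid, grp, rec in subject_recs:
        try:
            per_subject[sid] = _analyze_subject(rec, config)
            groups[sid] = grp
        except Exception as exc:  # noqa: BLE001
            logger.error("subject %s failed: %s", sid, exc)
            failures.append({"subject_id": sid, "stage": "analysis", "error": str(exc)})
    if not per_subject:
        raise RuntimeError("every subject failed analysis: empty stage")

    group_names = sorted(set(groups.values()))

    hrv_rows, power_frames = [], []
    for sid, res in per_subject.items():
        row = {"subject": sid, "group": groups[sid], **res["hrv"].as_dict(),
               "n_rejected": res["nn"].n_rejected}
        hrv_rows.append(row)
        pf = res["band_power"].copy()
        pf.insert(0, "subject", sid)
        pf.insert(1, "group", groups[sid])
        power_frames.append(pf)
    hrv_table = pd.DataFrame(hrv_rows).sort_values("subject").reset_index(drop=True)
    power_table = pd.concat(power_frames, ignore_index=True)
    hrv_table.to_csv(out / "hrv.csv", index=False)
    power_table.to_csv(out / "band_power.csv", index=False)
    _write_json(out / "hrv_meta.json", hrv.METADATA)

    # --- stage 3: group statistics --------------------------------------
    correlograms, regressions = [], []
    for grp in group_names:
        sids = [s for s in per_subject if groups[s] == grp]
        gp = power_table[power_table["group"] == grp].drop(columns=["group"])
        gh = hrv_table[hrv_table["group"] == grp].drop(columns=["group"])
        if len(sids) >= 5:
            cells = coupling.spearman_correlogram(gp, gh, grp)
            correlograms.append(coupling.correlogram_frame(cells))
        else:
            logger.warning("group %s too small for correlogram (n=%d)", grp, len(sids))
        try:
            regressions.extend(coupling.regression_battery(gp, gh, group=grp))
        except ValueError as exc:
            logger.warning("regression battery skipped for %s: %s", grp, exc)

    correlogram_table = (
        pd.concat(correlograms, ignore_index=True) if correlograms else pd.DataFrame()
    )
    if not correlogram_table.empty:
        correlogram_table.to_csv(out / "correlogram.csv", index=False)
        correlogram_table[correlogram_table["passes_report_filter"]].to_csv(
            out / "correlations_reported.csv", index=False
        )
    reg_table = coupling.regression_frame(regressions) if regressions else pd.DataFrame()
    if not reg_table.empty:
        reg_table.to_csv(out / "regression.csv", index=False)

    group_anova = {}
    if len(group_names) == 2:
        a_ids = [s for s in per_subject if groups[s] == group_names[0]]
        b_ids = [s for s in per_subject if groups[s] == group_names[1]]
        if len(a_ids) >= 2 and len(b_ids) >= 2:
            ht = hrv_table.set_index("subject")
            va = {p: ht.loc[a_ids, c].to_numpy()
                  for p, c in zip(("SDNN", "RMSSD", "SD1", "HF"),
                                  ("sdnn_ms", "rmssd_ms", "sd1_ms", "hf_ms2"))}
            vb = {p: ht.loc[b_ids, c].to_numpy()
                  for p, c in zip(("SDNN", "RMSSD", "SD1", "HF"),
                                  ("sdnn_ms", "rmssd_ms", "sd1_ms", "hf_ms2"))}
            group_anova["hrv"] = coupling.group_compare(va, vb, family_size=4)
            pw = power_table.pivot_table(
                index="subject", columns=["band", "roi", "hemisphere"],
                values="power_db",
            )
            va = {"/".join(col): pw.loc[a_ids, col].to_numpy() for col in pw.columns}
            vb = {"/".join(col): pw.loc[b_ids, col].to_numpy() for col in pw.columns}
            group_anova["eeg_power"] = coupling.group_compare(va, vb)
            _write_json(out / "group_anova.json", group_anova)

    # --- stage 4: HEP group comparison ----------------------------------
    hep_windows = {}
    if len(group_names) == 2:
        res_a = [per_subject[s]["hep"] for s in per_subject if groups[s] == group_names[0]]
        res_b = [per_subject[s]["hep"] for s in per_subject if groups[s] == group_names[1]]
        if len(res_a) >= 2 and len(res_b) >= 2:
            hep_windows = hep.compare_groups_hep(res_a, res_b)
            _write_json(out / "hep_windows.json", {
                ch: [{"t_start_ms": w[0], "t_end_ms": w[1], "p_corrected": w[2]}
                     for w in wins]
                for ch, wins in hep_windows.items()
            })
    wave_rows = []
    for sid, res in sorted(per_subject.items()):
        h = res["hep"]
        for ci, ch in enumerate(h.labels):
            for t, v in zip(h.times_ms, h.waveforms[ci]):
                wave_rows.append((sid, ch, t, v))
    pd.DataFrame(
        wave_rows, columns=["subject", "channel", "time_ms", "amplitude_uv"]
    ).to_csv(out / "hep_waveforms.csv", index=False, float_format="%.6f")

    if config.make_plots:
        from . import plots

        spectra = {}
        for grp in group_names:
            sids = [s for s in per_subject if groups[s] == grp]
            freqs = per_subject[sids[0]]["psd"][0]
            spectra[grp] = (freqs, np.stack([per_subject[s]["psd"][1] for s in sids]))
        plots.plot_grand_average_spectrum(spectra, out / "grand_average_spectrum.svg")
        if not correlogram_table.empty:
            plots.plot_correlogram(correlogram_table, out / "correlogram.svg")
        if hep_windows:
            sig_chans = sorted(ch for ch, wins in hep_windows.items() if wins) or \
                list(hep_windows)[:4]
            first = next(iter(per_subject.values()))["hep"]
            idx = [first.labels.index(c) for c in sig_chans]
            gw = {}
            for grp in group_names:
                sids = [s for s in per_subject if groups[s] == grp]
                stackw = np.stack(
                    [per_subject[s]["hep"].waveforms[idx] for s in sids]
                ).mean(axis=0)
                gw[grp] = stackw
            plots.plot_hep_channels(
                first.times_ms, gw, sig_chans,
                {c: hep_windows.get(c, []) for c in sig_chans},
                out / "hep_channels.svg",
            )

    report = {
        "n_subjects": len(per_subject),
        "groups": {g: sum(1 for s in groups.values() if s == g) for g in group_names},
        "failures": failures,
        "seed": config.seed,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        "hep_significant_channels": sorted(
            ch for ch, wins in hep_windows.items() if wins
        ),
    }
    _write_json(out / "report.json", report)
    return report
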