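"""Figure helpers: grand-average spectra, correlogram heatmaps, HEP traces.

All writers pass empty metadata so output files are byte-stable across runs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_SAVE_KW = {"format": "svg", "metadata": {"Date": None}}


def plot_grand_average_spectrum(
    spectra: dict[str, tuple[np.ndarray, np.ndarray]],
    path: str | Path,
    *,
    fmax: float = 40.0,
) -> None:
    """Per-group grand-average PSD (mean ± SD across subjects).

    ``spectra`` maps group -> (freqs, subject × freq PSD array).
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    for group, (freqs, psds) in spectra.items():
        sel = freqs <= fmax
        mean = 10 * np.log10(np.maximum(psds[:, sel].mean(axis=0), 1e-20))
        sd = 10 * np.log10(np.maximum(psds[:, sel], 1e-20)).std(axis=0)
        ax.plot(freqs[sel], mean, label=group)
        ax.fill_between(freqs[sel], mean - sd, mean + sd, alpha=0.25)
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("Power (dB)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def plot_correlogram(frame: pd.DataFrame, path: str | Path) -> None:
    """Heatmap grid of Spearman rho: (ROI, hemisphere) rows x HRV columns,
    one panel per band, mirroring the tidy correlogram table."""
    bands = sorted(frame["band"].unique())
    fig, axes = plt.subplots(1, len(bands), figsize=(3.2 * len(bands), 4),
                             squeeze=False)
    for ax, band in zip(axes[0], bands):
        sub = frame[frame["band"] == band]
        pivot = sub.pivot_table(
            index=["roi", "hemisphere"], columns="hrv_param", values="rho"
        )
        im = ax.imshow(pivot.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45)
        ax.set_yticks(range(len(pivot.index)),
                      [f"{r}_{h}" for r, h in pivot.index])
        ax.set_title(band)
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="Spearman rho")
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def plot_hep_channels(
    times_ms: np.ndarray,
    group_waves: dict[str, np.ndarray],
    channels: list[str],
    windows: dict[str, list[tuple[float, float, float]]],
    path: str | Path,
) -> None:
    """Per-channel group-average HEP traces with significant windows shaded.

    ``group_waves`` maps group -> channel × time mean waveform.
    """
    n = len(channels)
    ncols = min(4, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                             squeeze=False, sharex=True)
    for i, ch in enumerate(channels):
        ax = axes[i // ncols][i % ncols]
        for group, waves in group_waves.items():
            ax.plot(times_ms, waves[i], label=group, lw=1)
        for (t0, t1, _p) in windows.get(ch, []):
            ax.axvspan(t0, t1, color="0.8", zorder=0)
        ax.set_title(ch, fontsize=9)
    axes[0][0].legend(fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("Time (ms)")
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)
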