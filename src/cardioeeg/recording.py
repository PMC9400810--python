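"""Multichannel recording container and 10/20 montage constants."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 scalp electrodes of the reduced 10/20 montage, in conventional order.
EEG_CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Modern (10/10) names accepted as synonyms of the classic temporal labels.
CHANNEL_SYNONYMS = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

#: Mastoid reference channels (optional in a montage).
MASTOID_CHANNELS = ("A1", "A2")

#: Default ECG channel label.
ECG_CHANNEL = "ECG"


def canonical_label(label: str) -> str:
    """Map a channel label to its canonical montage name (case-insensitive,
    T3/T4/T5/T6 synonym table applied).  Unknown labels are returned
    title-cased so the caller can detect them against the montage."""
    stripped = label.strip()
    lut = {c.upper(): c for c in EEG_CHANNELS_1020}
    lut.update({c.upper(): c for c in MASTOID_CHANNELS})
    lut[ECG_CHANNEL.upper()] = ECG_CHANNEL
    lut.update({k.upper(): v for k, v in CHANNEL_SYNONYMS.items()})
    return lut.get(stripped.upper(), stripped)


@dataclass
class Recording:
    """A block of synchronously sampled channels in physical units.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal values; µV for EEG channels, mV for ECG.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    units : list of str, optional
        Physical dimension per channel (``"uV"`` / ``"mV"``).
    start_time : float
        Offset of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    units: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[np.newaxis, :]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.samples.shape[0]} channels but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.units:
            self.units = ["uV"] * len(self.labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def channel_index(self, label: str) -> int:
        want = canonical_label(label)
        for i, lab in enumerate(self.labels):
            if canonical_label(lab) == want:
                return i
        raise KeyError(f"channel {label!r} not present in {self.labels}")

    def get_channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording with the given channels, in the given order."""
        idx = [self.channel_index(lab) for lab in labels]
        return Recording(
            samples=self.samples[idx].copy(),
            fs=self.fs,
            labels=[self.labels[i] for i in idx],
            units=[self.units[i] for i in idx],
            start_time=self.start_time,
        )

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            fs=self.fs,
            labels=list(self.labels),
            units=list(self.units),
            start_time=self.start_time,
        )
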