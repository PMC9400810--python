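"""Minimal EDF (European Data Format) reader/writer.

Implements the plain EDF spec (16-bit samples, fixed-width ASCII headers,
1-second data records) — enough to round-trip multichannel biosignal
recordings.  EDF+ annotations are not supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import Recording

_HEADER_FIXED = 256
_HEADER_PER_SIGNAL = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    """Format a number into a fixed-width ASCII field, preferring precision."""
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    return f"{value:.1e}"[:width].ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    recording: Recording,
    *,
    patient_id: str = "X",
    recording_id: str = "cardioeeg",
    start_date: str = "01.01.00",
    start_time: str = "00.00.00",
) -> None:
    """Write a Recording as an EDF file with 1 s data records.

    The sampling rate must be a positive integer and the recording is
    truncated to a whole number of seconds.  Physical min/max per channel is
    taken from the data (symmetric, padded 1%), giving quantization error of
    about range/2^16 per sample.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_sig = recording.n_channels
    n_records = recording.n_times // fs
    if n_records == 0:
        raise ValueError("recording shorter than one 1 s data record")

    data = recording.samples[:, : n_records * fs]
    phys_min, phys_max, scaled = [], [], []
    for ch in range(n_sig):
        x = data[ch]
        amax = float(np.max(np.abs(x)))
        bound = amax * 1.01 if amax > 0 else 1.0
        phys_min.append(-bound)
        phys_max.append(bound)
        gain = (_DIG_MAX - _DIG_MIN) / (2 * bound)
        dig = np.clip(np.round((x + bound) * gain) + _DIG_MIN, _DIG_MIN, _DIG_MAX)
        scaled.append(dig.astype("<i2"))

    header_bytes = _HEADER_FIXED + _HEADER_PER_SIGNAL * n_sig
    parts = [
        _ascii("0", 8),
        _ascii(patient_id, 80),
        _ascii(recording_id, 80),
        _ascii(start_date, 8),
        _ascii(start_time, 8),
        _ascii(header_bytes, 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(n_sig, 4),
    ]
    labels = [_ascii(lab, 16) for lab in recording.labels]
    transducers = [_ascii("", 80)] * n_sig
    dims = [_ascii(u, 8) for u in recording.units]
    pmins = [_num(v, 8) for v in phys_min]
    pmaxs = [_num(v, 8) for v in phys_max]
    dmins = [_ascii(_DIG_MIN, 8)] * n_sig
    dmaxs = [_ascii(_DIG_MAX, 8)] * n_sig
    prefilter = [_ascii("", 80)] * n_sig
    nsamples = [_ascii(fs, 8)] * n_sig
    reserved = [_ascii("", 32)] * n_sig
    for block in (labels, transducers, dims, pmins, pmaxs, dmins, dmaxs,
                  prefilter, nsamples, reserved):
        parts.extend(block)

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            for ch in range(n_sig):
                fh.write(scaled[ch][sl].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (physical units)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_FIXED:
        raise ValueError(f"{path}: too short to be an EDF file")

    def field(offset: int, width: int) -> str:
        return raw[offset:offset + width].decode("ascii", errors="replace").strip()

    header_bytes = int(field(184, 8))
    n_records = int(field(236, 8))
    record_dur = float(field(244, 8))
    n_sig = int(field(252, 4))
    if header_bytes != _HEADER_FIXED + _HEADER_PER_SIGNAL * n_sig:
        raise ValueError(f"{path}: inconsistent EDF header size")

    # Per-signal header blocks are laid out field-by-field (all labels, then
    # all transducers, ...), so offsets accumulate by field width.
    off = _HEADER_FIXED

    def take(width: int) -> list[str]:
        nonlocal off
        vals = [
            raw[off + i * width: off + (i + 1) * width]
            .decode("ascii", errors="replace").strip()
            for i in range(n_sig)
        ]
        off += width * n_sig
        return vals

    labels = take(16)
    take(80)  # transducer
    dims = take(8)
    pmins = [float(v) for v in take(8)]
    pmaxs = [float(v) for v in take(8)]
    dmins = [int(v) for v in take(8)]
    dmaxs = [int(v) for v in take(8)]
    take(80)  # prefiltering
    ns = [int(v) for v in take(8)]
    take(32)  # reserved

    if len(set(ns)) != 1:
        raise ValueError(f"{path}: heterogeneous per-record sample counts unsupported")
    spr = ns[0]
    fs = spr / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * n_sig * spr
    if body.size < expected:
        raise ValueError(f"{path}: truncated data section")
    body = body[:expected].reshape(n_records, n_sig, spr)

    samples = np.empty((n_sig, n_records * spr), dtype=float)
    for ch in range(n_sig):
        gain = (pmaxs[ch] - pmins[ch]) / (dmaxs[ch] - dmins[ch])
        dig = body[:, ch, :].reshape(-1).astype(float)
        samples[ch] = (dig - dmins[ch]) * gain + pmins[ch]

    return Recording(samples=samples, fs=fs, labels=labels, units=dims)
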