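"""Minimal WFDB (format 16) record writer/reader for the PTB-XL dialect.

Covers exactly what this pipeline needs: a text ``.hea`` header plus a
little-endian int16 ``.dat`` file with sample-interleaved channels, all
channels sharing one gain (adu/mV) and zero baseline.  The header layout
follows the WFDB signal specification closely enough that the fields are
recognizable (record line: name, n_sig, fs, n_samples; one signal line
per lead: file name, format, gain/units, ADC resolution, zero, first
value, checksum, block size, description).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synth import LEAD_NAMES, EcgRecord

DEFAULT_GAIN = 1000.0  # adu per mV; 16-bit range then spans ±32.7 mV

__all__ = ["write_record", "read_record", "DEFAULT_GAIN"]


def write_record(directory, record: EcgRecord, gain: float = DEFAULT_GAIN) -> Path:
    """Write ``<record_id>.hea`` / ``<record_id>.dat``; returns the header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.clip(np.rint(record.signal * gain), -32768, 32767).astype("<i2")
    n_sig, n_samp = adc.shape
    dat_name = f"{record.record_id}.dat"
    lines = [f"{record.record_id} {n_sig} {record.fs} {n_samp}"]
    for ch in range(n_sig):
        checksum = int(adc[ch].astype(np.int64).sum() % 65536)
        lines.append(
            f"{dat_name} 16 {gain:g}/mV 16 0 {int(adc[ch, 0])} "
            f"{checksum} 0 {LEAD_NAMES[ch]}"
        )
    header = directory / f"{record.record_id}.hea"
    header.write_text("\n".join(lines) + "\n")
    # format 16: samples interleaved across signals
    (directory / dat_name).write_bytes(adc.T.tobytes())
    return header


def read_record(directory, record_id: str) -> EcgRecord:
    """Read a record written by :func:`write_record` (or compatible)."""
    directory = Path(directory)
    header = (directory / f"{record_id}.hea").read_text().strip().splitlines()
    name, n_sig, fs, n_samp = header[0].split()[:4]
    n_sig, fs, n_samp = int(n_sig), int(fs), int(n_samp)
    gains = []
    dat_name = None
    for line in header[1 : 1 + n_sig]:
        parts = line.split()
        dat_name = parts[0]
        fmt = parts[1]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB signal format {fmt!r}")
        gains.append(float(parts[2].split("/")[0]))
    raw = np.frombuffer((directory / dat_name).read_bytes(), dtype="<i2")
    adc = raw.reshape(n_samp, n_sig).T
    signal = adc.astype(float) / np.asarray(gains)[:, None]
    return EcgRecord(
        record_id=name,
        patient_id=name,
        signal=signal,
        fs=fs,
        rhythm="SR",
        acquisition_index=0,
    )
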