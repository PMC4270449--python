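"""Recording and table I/O.

Recordings are exchanged in two formats:

* **EDF** (European Data Format, 16-bit): written by a small self-contained
  writer (one data record per second, per-channel physical scaling) and
  read back through :mod:`mne`, which also handles clinical EDF exports.
* **plain matrix**: a two-file text dialect — ``<prefix>.hdr`` with
  ``key<TAB>value`` lines (``fs_hz``, ``n_channels``, ``channels``,
  ``unit``) and ``<prefix>.dat`` holding the channels x samples matrix as
  tab-separated floats.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording, POSTERIOR

_EDF_EPOCH_DATE = "01.01.00"  # fixed header date keeps outputs byte-identical


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path) -> Path:
    """Write a 16-bit EDF file (record duration 1 s, fs samples per record).

    The sampling rate must be an integer; trailing samples beyond the last
    whole second are dropped (EDF stores whole records only).
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = recording.n_channels
    data = recording.samples[:, : n_records * fs]

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    buf = _io.BytesIO()
    header_bytes = 256 * (1 + ns)
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field("X X X X", 80))
    buf.write(_edf_field("Startdate X X X X", 80))
    buf.write(_edf_field(_EDF_EPOCH_DATE, 8))
    buf.write(_edf_field("00.00.00", 8))
    buf.write(_edf_field(header_bytes, 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(n_records, 8))
    buf.write(_edf_field(1, 8))
    buf.write(_edf_field(ns, 4))
    for ch in recording.channel_labels:
        buf.write(_edf_field(ch, 16))
    for _ in range(ns):
        buf.write(_edf_field("AgAgCl electrode", 80))
    for _ in range(ns):
        buf.write(_edf_field("uV", 8))
    for v in phys_min:
        buf.write(_edf_field(f"{v:.6g}"[:8], 8))
    for v in phys_max:
        buf.write(_edf_field(f"{v:.6g}"[:8], 8))
    for _ in range(ns):
        buf.write(_edf_field(dig_min, 8))
    for _ in range(ns):
        buf.write(_edf_field(dig_max, 8))
    for _ in range(ns):
        buf.write(_edf_field("", 80))
    for _ in range(ns):
        buf.write(_edf_field(fs, 8))
    for _ in range(ns):
        buf.write(_edf_field("", 32))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    for rec in range(n_records):
        chunk = data[:, rec * fs : (rec + 1) * fs]
        dig = np.rint(
            (chunk - phys_min[:, None]) * scale[:, None] + dig_min
        ).astype("<i2")
        buf.write(dig.tobytes())
    path.write_bytes(buf.getvalue())
    return path


def read_edf(path) -> EEGRecording:
    """Read an EDF file via mne; samples are returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne uses volts internally
    return EEGRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        meta={"source": str(path), "format": "edf"},
    )


def write_plain(recording: EEGRecording, prefix) -> tuple:
    """Write the two-file plain-matrix dialect; returns (hdr_path, dat_path)."""
    prefix = Path(prefix)
    hdr = prefix.with_suffix(".hdr")
    dat = prefix.with_suffix(".dat")
    hdr.write_text(
        "fs_hz\t{:.10g}\nn_channels\t{}\nchannels\t{}\nunit\tuV\n".format(
            recording.fs, recording.n_channels, ",".join(recording.channel_labels)
        )
    )
    np.savetxt(dat, recording.samples, fmt="%.6g", delimiter="\t")
    return hdr, dat


def read_plain(prefix) -> EEGRecording:
    prefix = Path(prefix)
    hdr = prefix.with_suffix(".hdr")
    dat = prefix.with_suffix(".dat")
    if not hdr.exists() or not dat.exists():
        raise FileNotFoundError(f"plain-matrix pair {hdr} / {dat} not found")
    fields = {}
    for line in hdr.read_text().splitlines():
        if line.strip():
            key, _, value = line.partition("\t")
            fields[key.strip()] = value.strip()
    try:
        fs = float(fields["fs_hz"])
        labels = tuple(fields["channels"].split(","))
    except KeyError as e:
        raise ValueError(f"malformed plain-matrix header: missing {e}") from None
    data = np.loadtxt(dat, delimiter="\t", ndmin=2)
    if data.shape[0] != len(labels):
        raise ValueError(
            f"header lists {len(labels)} channels but matrix has {data.shape[0]} rows"
        )
    return EEGRecording(
        samples=data, fs=fs, channel_labels=labels,
        meta={"source": str(prefix), "format": "plain"},
    )


def read_recording(path, fmt: str | None = None,
                   require_region: tuple | None = POSTERIOR) -> EEGRecording:
    """Read a recording, inferring the format from the extension.

    ``require_region`` (default: the posterior derivations) is checked up
    front so a missing electrode fails with its name rather than deep in
    the pipeline; pass None to skip the check.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "plain"
    if fmt == "edf":
        rec = read_edf(path)
    elif fmt == "plain":
        rec = read_plain(path.with_suffix("") if path.suffix else path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if require_region:
        missing = [ch for ch in require_region if ch not in rec.channel_labels]
        if missing:
            raise KeyError(
                f"recording {path.name} lacks region channels: {', '.join(missing)}"
            )
    return rec


def write_table(df: pd.DataFrame, path) -> Path:
    """Delimited-text table with a header row (tab-separated)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
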