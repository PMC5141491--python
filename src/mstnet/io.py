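"""Recording and manifest I/O.

Recordings travel either as delimited text (one column per channel,
header row of labels — lossless and diff-friendly) or as 16-bit EDF
(European Data Format) with physical units of microvolts. EDF reading
goes through :mod:`mne` (optional dependency); writing uses a small
built-in EDF+C-free writer since the environment provides no EDF export
library. A cohort manifest is a delimited table with one row per
subject: subject_id, group, alsfrs_r, disability, fs, path.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "write_recording_edf",
    "read_recording_edf",
    "read_recording",
    "write_manifest",
    "read_manifest",
]


def write_recording_text(rec: Recording, path: str | Path, sep: str = "\t") -> Path:
    """Write a recording as delimited text: label header, one column per channel."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
    df.to_csv(path, sep=sep, index=False, float_format="%.8g")
    return path


def read_recording_text(path: str | Path, fs: float, sep: str | None = None) -> Recording:
    """Read a delimited-text recording; ``fs`` must be supplied (from the manifest)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return Recording(data=df.to_numpy().T, labels=tuple(df.columns), fs=fs)


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a minimal 16-bit EDF file (physical units microvolts).

    Uses one data record per second when the sample count divides evenly
    by the (integer) sampling rate, otherwise a single record holding the
    whole signal. Values are scaled to the per-file symmetric physical
    range, so the round-trip error is bounded by that range / 2^16.
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    fs = rec.fs
    if fs == int(fs) and n_samp % int(fs) == 0:
        spr = int(fs)  # samples per record
        n_rec = n_samp // spr
        duration = 1.0
    else:
        spr = n_samp
        n_rec = 1
        duration = n_samp / fs
    phys_max = float(np.max(np.abs(rec.data)))
    if phys_max == 0:
        phys_max = 1.0
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(rec.data * scale), dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad(f"{duration:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, lambda lab: lab),  # label
        (80, lambda lab: ""),  # transducer
        (8, lambda lab: "uV"),
        (8, lambda lab: f"{-phys_max:.6g}"[:8]),
        (8, lambda lab: f"{phys_max:.6g}"[:8]),
        (8, lambda lab: str(dig_min)),
        (8, lambda lab: str(dig_max)),
        (80, lambda lab: ""),  # prefiltering
        (8, lambda lab: str(spr)),
        (32, lambda lab: ""),  # reserved
    ]
    sig_header = b"".join(
        b"".join(pad(fn(lab), width) for lab in rec.labels) for width, fn in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())
    return path


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF recording via mne (values returned in microvolts)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data=data, labels=tuple(raw.ch_names), fs=float(raw.info["sfreq"]))


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Dispatch on extension: .edf via mne, anything else as delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path)
    if fs is None:
        raise ValueError("fs is required to read a delimited-text recording")
    return read_recording_text(path, fs=fs)


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a cohort manifest (one row per subject) as delimited text."""
    path = Path(path)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; derives disability from alsfrs_r if absent."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing required columns: {sorted(missing)}")
    if "disability" not in df.columns:
        if "alsfrs_r" not in df.columns:
            raise ValueError("manifest needs a disability or alsfrs_r column")
        df["disability"] = 48 - df["alsfrs_r"].astype(int)
    return df
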