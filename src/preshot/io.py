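"""On-disk formats and the in-memory data model shared by all stages.

Continuous EEG travels as 16-bit EDF (physical units µV), shot events as a
BIDS-events-like tab-separated file (onset in seconds), behavior as CSV,
and ERD/ERS maps as a long-format TSV. The sample-index convention is
``round(onset * fs)`` everywhere (round, not floor).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .montage import positions_for

SCORE_RANGE = (0.0, 10.9)
CONTROL_RANGE = (0.0, 11.0)


@dataclasses.dataclass
class RawRecording:
    """Continuous multichannel EEG in µV.

    data has shape (n_channels, n_samples); channel_labels are 10–20 site
    names (unique); fs in Hz.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def positions(self, extra: dict | None = None) -> np.ndarray:
        """Unit-sphere electrode positions from the built-in montage."""
        return positions_for(self.channel_labels, extra)


def onset_to_sample(onset_s: float | np.ndarray, fs: float) -> int | np.ndarray:
    """Map onset seconds to a sample index by rounding (package-wide rule)."""
    idx = np.rint(np.asarray(onset_s) * fs).astype(np.int64)
    return int(idx) if idx.ndim == 0 else idx


# ---------------------------------------------------------------------------
# EDF (16-bit, one data record per second)

_EDF_HDR = 256
_EDF_SIG = 256


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with physical units µV.

    The record duration is 1 s; the final partial record, if any, is
    zero-padded (recordings produced by the simulator have whole-second
    durations, so the round trip is exact up to quantization).
    """
    if rec.n_channels == 0:
        raise FormatError("cannot write EDF with an empty channel list")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    n_records = math.ceil(rec.n_samples / spr)

    phys_max = np.maximum(np.ceil(np.max(np.abs(rec.data), axis=1) + 1.0), 1.0)
    dig_min, dig_max = -32768, 32767

    with open(Path(path), "wb") as fh:
        ns = rec.n_channels
        fh.write(_pad("0", 8))
        fh.write(_pad(rec.subject_id[:80], 80))
        fh.write(_pad("preshot synthetic EEG", 80))
        fh.write(_pad("01.01.20", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(_EDF_HDR + _EDF_SIG * ns), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        for lab in rec.channel_labels:
            fh.write(_pad(lab, 16))
        fh.write(_pad("", 80) * ns)                       # transducer
        fh.write(_pad("uV", 8) * ns)                      # physical dimension
        for p in phys_max:
            fh.write(_pad(f"{-p:.6g}"[:8], 8))
        for p in phys_max:
            fh.write(_pad(f"{p:.6g}"[:8], 8))
        fh.write(_pad(str(dig_min), 8) * ns)
        fh.write(_pad(str(dig_max), 8) * ns)
        fh.write(_pad("", 80) * ns)                       # prefiltering
        fh.write(_pad(str(spr), 8) * ns)
        fh.write(_pad("", 32) * ns)

        padded = np.zeros((rec.n_channels, n_records * spr))
        padded[:, : rec.n_samples] = rec.data
        scale = (dig_max - dig_min) / (2.0 * phys_max)    # digital per µV
        for r in range(n_records):
            block = padded[:, r * spr : (r + 1) * spr]
            dig = np.rint(block * scale[:, None]).astype("<i2")
            fh.write(dig.tobytes())


def _ascii(raw: bytes, offset: int, what: str) -> str:
    try:
        return raw.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise FormatError(f"EDF header: non-ASCII {what} at byte {offset}") from exc


def read_edf(path: str | Path) -> RawRecording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or compatible).

    Rejects truncated files instead of returning partial data.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _EDF_HDR:
        raise FormatError(f"EDF file shorter than the 256-byte header "
                          f"(got {len(raw)} bytes)")
    hdr_bytes = int(_ascii(raw[184:192], 184, "header length"))
    n_records = int(_ascii(raw[236:244], 236, "record count"))
    rec_dur = float(_ascii(raw[244:252], 244, "record duration"))
    ns = int(_ascii(raw[252:256], 252, "signal count"))
    if ns <= 0:
        raise FormatError("EDF file declares no signals (byte 252)")
    if hdr_bytes != _EDF_HDR + _EDF_SIG * ns:
        raise FormatError(f"EDF header length {hdr_bytes} inconsistent with "
                          f"{ns} signals (byte 184)")
    if len(raw) < hdr_bytes:
        raise FormatError(f"EDF truncated inside the signal header at byte {len(raw)}")

    def field(start: int, width: int, conv=str):
        vals = []
        for i in range(ns):
            off = start + i * width
            vals.append(conv(_ascii(raw[off:off + width], off, "signal field")))
        return vals

    base = _EDF_HDR
    labels = field(base, 16)
    phys_min = field(base + ns * (16 + 80 + 8), 8, float)
    phys_max = field(base + ns * (16 + 80 + 8 + 8), 8, float)
    dig_min = field(base + ns * (16 + 80 + 8 + 8 + 8), 8, float)
    dig_max = field(base + ns * (16 + 80 + 8 + 8 + 8 + 8), 8, float)
    spr = field(base + ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80), 8, int)

    rec_size = sum(spr) * 2
    expect = hdr_bytes + n_records * rec_size
    if len(raw) != expect:
        raise FormatError(f"EDF data truncated: expected {expect} bytes, "
                          f"file ends at byte {len(raw)}")
    if len(set(spr)) != 1:
        raise FormatError("EDF reader requires a common sampling rate across signals")
    fs = spr[0] / rec_dur

    data = np.frombuffer(raw[hdr_bytes:], dtype="<i2").reshape(n_records, ns, spr[0])
    data = data.transpose(1, 0, 2).reshape(ns, -1).astype(np.float64)
    for i in range(ns):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = phys_min[i] + (data[i] - dig_min[i]) * gain
    subject = _ascii(raw[8:88], 8, "patient field") or path.stem
    return RawRecording(data=data, fs=fs, channel_labels=labels, subject_id=subject)


# ---------------------------------------------------------------------------
# Events and behavior tables

EVENT_COLUMNS = ("onset", "trial", "subject")
BEHAVIOR_COLUMNS = ("subject", "trial", "score", "control")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column {col!r}")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated event table (columns onset, trial, subject).

    Onsets are seconds from recording start and must be strictly
    increasing within each subject.
    """
    df = pd.read_csv(path, sep="\t")
    if "onset_s" in df.columns and "onset" not in df.columns:
        df = df.rename(columns={"onset_s": "onset"})
    _require_columns(df, EVENT_COLUMNS, "events")
    df = df[list(EVENT_COLUMNS)].astype({"onset": float, "trial": int, "subject": str})
    for subj, grp in df.groupby("subject"):
        if not np.all(np.diff(grp["onset"].to_numpy()) > 0):
            raise ValidationError(f"event onsets not strictly increasing for "
                                  f"subject {subj}")
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    """Read the per-trial behavior CSV (subject, trial, score, control)."""
    df = pd.read_csv(path)
    _require_columns(df, BEHAVIOR_COLUMNS, "behavior")
    df = df[list(BEHAVIOR_COLUMNS)].astype(
        {"subject": str, "trial": int, "score": float, "control": float})
    validate_behavior(df)
    return df


def validate_behavior(df: pd.DataFrame) -> None:
    bad = df[(df["score"] < SCORE_RANGE[0]) | (df["score"] > SCORE_RANGE[1])]
    if len(bad):
        raise ValidationError(f"shooting score outside [0, 10.9] in {len(bad)} row(s), "
                              f"first value {bad['score'].iloc[0]}")
    bad = df[(df["control"] < CONTROL_RANGE[0]) | (df["control"] > CONTROL_RANGE[1])]
    if len(bad):
        raise ValidationError(f"perceived control outside [0, 11] in {len(bad)} row(s)")
    dup = df.duplicated(subset=["subject", "trial"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["subject", "trial"]].tolist()
        raise ValidationError(f"duplicated (subject, trial) pair {tuple(pair)}")


def write_behavior(df: pd.DataFrame, path: str | Path) -> None:
    df[list(BEHAVIOR_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ERD/ERS long table

ERDERS_COLUMNS = ("subject", "performance_type", "band", "channel",
                  "interval", "erders_pct")


def write_erders_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format ERD/ERS table as TSV; NaN cells become 'NA'."""
    _require_columns(df, ERDERS_COLUMNS, "erders")
    out = df[list(ERDERS_COLUMNS)].copy()
    out["erders_pct"] = out["erders_pct"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_erders_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    _require_columns(df, ERDERS_COLUMNS, "erders")
    return df.astype({"subject": str, "performance_type": int, "band": str,
                      "channel": str, "interval": int, "erders_pct": float})


def erders_is_complete(df: pd.DataFrame, n_types: int = 4,
                       n_intervals: int = 3) -> bool:
    """True when every (subject, type, band, channel) has all intervals
    and all performance types are present for every subject."""
    for (_subj, _band, _ch), grp in df.groupby(["subject", "band", "channel"]):
        have = set(zip(grp["performance_type"], grp["interval"]))
        want = {(t, i) for t in range(1, n_types + 1) for i in range(n_intervals)}
        if have != want:
            return False
    return True


# ---------------------------------------------------------------------------
# JSON helpers (ground truth, stats results, provenance)

def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
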