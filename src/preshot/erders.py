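"""Hilbert-envelope band power and ERD/ERS% maps.

For each analysis band the epoch is band-pass filtered (zero-phase
4th-order Butterworth), the analytic signal is formed with the Hilbert
transform, and instantaneous power is |analytic|² (so a unit-amplitude
sine has envelope power 1.0 µV², not 0.5). The ERD/ERS index compares
mean interval power P_int against the group-averaged baseline power
P_base (window −5…−4 s):

    index% = sign · 100 · (P_int − P_base) / P_base

with sign = −1 by default, so a power *decrease* yields a positive index
(ERD) and an increase a negative one (ERS) — the classical reporting
convention. A 0.5-s guard at each epoch edge is excluded from every
window statistic to avoid filter transients.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, PipelineError
from .preprocess import EpochSet

SIGN_CONVENTIONS = {"erd_positive": -1.0, "raw_percent_change": +1.0}
EDGE_GUARD_S = 0.5


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ConfigurationError(f"invalid band {self.name}: "
                                     f"({self.low}, {self.high})")


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 10.0, 12.0),
)


@dataclasses.dataclass(frozen=True)
class AnalysisWindows:
    """Baseline −5…−4 s; three contiguous 1-s intervals ending at the shot."""

    baseline: tuple[float, float] = (-5.0, -4.0)
    intervals: tuple[tuple[float, float], ...] = ((-3.0, -2.0), (-2.0, -1.0),
                                                  (-1.0, 0.0))

    def __post_init__(self):
        b0, b1 = self.baseline
        if b0 < -5.0:
            raise ConfigurationError(
                "baseline may not start before −5 s (earlier spans are "
                "contaminated by postural adjustments)")
        if not b1 > b0:
            raise ConfigurationError("baseline window must have positive length")
        for (a0, a1) in self.intervals:
            if not a1 > a0:
                raise ConfigurationError("interval must have positive length")
            if max(a0, b0) < min(a1, b1):
                raise ConfigurationError("analysis interval overlaps the baseline")
        for (p, q) in zip(self.intervals, self.intervals[1:]):
            if abs(p[1] - q[0]) > 1e-9:
                raise ConfigurationError("intervals must be contiguous")


@dataclasses.dataclass
class ERDSMap:
    """channels × intervals ERD/ERS% for one (subject, type, band) group."""

    subject: str
    ptype: int
    band: str
    channels: list[str]
    values: np.ndarray        # (n_channels, n_intervals), percent
    p_base: np.ndarray        # (n_channels,), µV²
    n_epochs: int


def band_power(epochs: EpochSet, band: BandDefinition,
               passband: tuple[float, float] = (0.3, 40.0)) -> np.ndarray:
    """Instantaneous band power |analytic|², shape (trials, channels, samples)."""
    if band.low < passband[0] or band.high > passband[1]:
        raise ConfigurationError(
            f"band {band.name} ({band.low}-{band.high} Hz) exceeds the "
            f"broadband passband {passband}")
    if band.high >= epochs.fs / 2:
        raise ConfigurationError(f"band {band.name} reaches the Nyquist rate")
    sos = sps.butter(4, [band.low, band.high], btype="band", fs=epochs.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, epochs.data, axis=2)
    analytic = sps.hilbert(filtered, axis=2)
    return np.abs(analytic) ** 2


def window_slice(epochs: EpochSet, window: tuple[float, float],
                 edge_guard_s: float = EDGE_GUARD_S) -> slice:
    """Sample slice of a half-open window [t0, t1), rejecting windows that
    intrude into the epoch-edge guard."""
    t0, t1 = window
    tmax = epochs.tmin + epochs.data.shape[2] / epochs.fs
    if t0 < epochs.tmin + edge_guard_s or t1 > tmax - edge_guard_s:
        raise ConfigurationError(
            f"window {window} intrudes into the {edge_guard_s}-s epoch-edge guard")
    return slice(epochs.sample_at(t0), epochs.sample_at(t1))


def group_baseline(power: np.ndarray, baseline: slice) -> np.ndarray:
    """P_base per channel: mean over the group's epochs and baseline samples."""
    if power.shape[0] == 0:
        raise PipelineError("empty epoch group has no baseline")
    return power[:, :, baseline].mean(axis=(0, 2))


def erders_index(power: np.ndarray, p_base: np.ndarray,
                 intervals: list[slice],
                 sign_convention: str = "erd_positive") -> np.ndarray:
    """Per-epoch ERD/ERS% per (channel, interval); NaN where P_base = 0."""
    sign = SIGN_CONVENTIONS[sign_convention]
    p_int = np.stack([power[:, :, sl].mean(axis=2) for sl in intervals], axis=2)
    base = p_base[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sign * 100.0 * (p_int - base) / base
    if np.any(p_base == 0):
        warnings.warn("zero baseline power on some channel; index set to NaN")
        out[:, p_base == 0, :] = np.nan
    return out


def compute_subject_maps(epochs: EpochSet, quadrant_by_trial: dict[int, int],
                         bands=DEFAULT_BANDS,
                         windows: AnalysisWindows = AnalysisWindows(),
                         sign_convention: str = "erd_positive",
                         average: str = "per_epoch") -> list[ERDSMap]:
    """ERD/ERS maps for one subject, one per (performance type, band).

    Baseline averaging is done within each (subject × type) group, the
    finest grouping; ``average='per_epoch'`` (default) averages per-epoch
    indices, ``'power_first'`` averages interval power before forming the
    index (exposed for sensitivity checks). Types with no retained epochs
    are skipped with a warning.
    """
    if average not in ("per_epoch", "power_first"):
        raise ConfigurationError(f"unknown averaging mode {average!r}")
    good = epochs.retained()
    ptypes = np.array([quadrant_by_trial[t] for t in good.trials])
    base_sl = window_slice(good, windows.baseline)
    int_sls = [window_slice(good, w) for w in windows.intervals]
    sign = SIGN_CONVENTIONS[sign_convention]
    maps: list[ERDSMap] = []
    for band in bands:
        power = band_power(good, band)
        for ptype in sorted(set(quadrant_by_trial.values())):
            sel = ptypes == ptype
            if not sel.any():
                warnings.warn(f"subject {good.subject_id}: no epochs of "
                              f"type {ptype}; map cell missing")
                continue
            p = power[sel]
            p_base = group_baseline(p, base_sl)
            if average == "per_epoch":
                idx = erders_index(p, p_base, int_sls, sign_convention)
                values = idx.mean(axis=0)
            else:
                p_int = np.stack([p[:, :, sl].mean(axis=(0, 2))
                                  for sl in int_sls], axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    values = sign * 100.0 * (p_int - p_base[:, None]) / p_base[:, None]
            maps.append(ERDSMap(good.subject_id, int(ptype), band.name,
                                list(good.channel_labels), values, p_base,
                                int(sel.sum())))
    return maps


def grand_average(maps: list[ERDSMap]) -> list[ERDSMap]:
    """Across-subject average per (type, band), each subject weighted equally.

    Subjects missing a type are omitted from that type's grand map; the
    contributing-subject count is carried in ``n_epochs``.
    """
    out = []
    keys = sorted({(m.ptype, m.band) for m in maps})
    for ptype, band in keys:
        group = [m for m in maps if m.ptype == ptype and m.band == band]
        channels = group[0].channels
        vals = np.mean([m.values for m in group], axis=0)
        p_base = np.mean([m.p_base for m in group], axis=0)
        out.append(ERDSMap("grand", ptype, band, list(channels), vals, p_base,
                           len(group)))
    return out


def maps_to_long(maps: list[ERDSMap]) -> pd.DataFrame:
    """Flatten maps into the long-format table (one row per cell)."""
    rows = []
    for m in maps:
        for ci, ch in enumerate(m.channels):
            for ii in range(m.values.shape[1]):
                rows.append((m.subject, m.ptype, m.band, ch, ii,
                             m.values[ci, ii]))
    return pd.DataFrame(rows, columns=["subject", "performance_type", "band",
                                       "channel", "interval", "erders_pct"])
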