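"""Broadband filtering, shot-locked epoching, and automated artifact rejection.

The continuous recording is band-pass filtered 0.3–40 Hz (zero-phase),
then cut into 10-s epochs spanning −6…+4 s around each shot release
(half-open window [−6, +4)). Epochs whose pre-shot span [−6, 0] s exceeds
amplitude/gradient thresholds on any channel, or contains a flat channel,
are marked bad; rejection replaces the visual inspection step of the
original protocol with transparent rules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, PipelineError
from .io import RawRecording, onset_to_sample

EPOCH_START_S = -6.0
EPOCH_END_S = 4.0


@dataclasses.dataclass
class EpochSet:
    """Shot-locked epochs for one subject.

    data: (n_trials, n_channels, n_samples) µV, sample 0 at −6 s and the
    shot-release sample at index round(6·fs). ``bad`` marks epochs
    rejected by artifact screening (True = excluded).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str
    trials: np.ndarray                 # trial numbers, aligned with axis 0
    bad: np.ndarray                    # boolean, aligned with axis 0
    tmin: float = EPOCH_START_S

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.bad).sum())

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs

    def sample_at(self, t: float) -> int:
        """Sample index of epoch time t (seconds relative to the shot)."""
        return int(round((t - self.tmin) * self.fs))

    def retained(self) -> "EpochSet":
        keep = ~self.bad
        return EpochSet(self.data[keep], self.fs, self.channel_labels,
                        self.subject_id, self.trials[keep],
                        np.zeros(keep.sum(), bool), self.tmin)


def bandpass_broad(rec: RawRecording, low: float = 0.3, high: float = 40.0
                   ) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass of the continuous data."""
    if not 0 < low < high:
        raise ConfigurationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rec.fs / 2:
        raise ConfigurationError(
            f"high cut-off {high} Hz reaches the Nyquist rate {rec.fs / 2} Hz")
    sos = sps.butter(4, [low, high], btype="band", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return RawRecording(data=out, fs=rec.fs,
                        channel_labels=list(rec.channel_labels),
                        subject_id=rec.subject_id)


def epoch_extract(rec: RawRecording, events: pd.DataFrame
                  ) -> tuple[EpochSet, pd.DataFrame]:
    """Cut −6…+4 s epochs around each shot of this recording's subject.

    Events without ≥6 s of history and ≥4 s of future signal are dropped
    and returned in the second element (columns trial, onset, reason).
    """
    ev = events[events["subject"] == rec.subject_id]
    n_samp = int(round((EPOCH_END_S - EPOCH_START_S) * rec.fs))
    kept, dropped = [], []
    for _, row in ev.iterrows():
        start = onset_to_sample(row["onset"] + EPOCH_START_S, rec.fs)
        if start < 0 or start + n_samp > rec.n_samples:
            dropped.append((int(row["trial"]), float(row["onset"]),
                            "too close to recording edge"))
        else:
            kept.append((int(row["trial"]), start))
    if not kept:
        raise PipelineError(f"no usable events for subject {rec.subject_id}")
    data = np.stack([rec.data[:, s:s + n_samp] for _, s in kept])
    epochs = EpochSet(data=data, fs=rec.fs,
                      channel_labels=list(rec.channel_labels),
                      subject_id=rec.subject_id,
                      trials=np.array([t for t, _ in kept]),
                      bad=np.zeros(len(kept), bool))
    return epochs, pd.DataFrame(dropped, columns=["trial", "onset", "reason"])


def artifact_detect(epochs: EpochSet, amp_thresh: float = 100.0,
                    grad_thresh: float = 50.0, flat_thresh: float = 0.5
                    ) -> EpochSet:
    """Mark epochs bad on the analysis-relevant span [−6, 0] s.

    An epoch is rejected when any channel exceeds ``amp_thresh`` µV
    peak-to-peak, jumps more than ``grad_thresh`` µV between neighboring
    samples, or is flat (peak-to-peak below ``flat_thresh`` µV). The
    decision depends only on the data, so re-running it is idempotent.
    """
    stop = epochs.sample_at(0.0)
    pre = epochs.data[:, :, :stop]
    ptp = pre.max(axis=2) - pre.min(axis=2)            # (trials, channels)
    grad = np.abs(np.diff(pre, axis=2)).max(axis=2)
    bad = ((ptp > amp_thresh) | (grad > grad_thresh)
           | (ptp < flat_thresh)).any(axis=1)
    if bad.all():
        raise PipelineError(
            f"all {epochs.n_epochs} epochs rejected for {epochs.subject_id}; "
            "review amp/grad/flat thresholds")
    return EpochSet(epochs.data, epochs.fs, list(epochs.channel_labels),
                    epochs.subject_id, epochs.trials, bad, epochs.tmin)


def rejection_report(epoch_sets: list[EpochSet]) -> pd.DataFrame:
    """Raw and retained trial counts per subject (study-style bookkeeping)."""
    rows = [(e.subject_id, e.n_epochs, e.n_retained,
             e.n_epochs - e.n_retained) for e in epoch_sets]
    return pd.DataFrame(rows, columns=["subject", "n_raw", "n_retained",
                                       "n_rejected"])
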