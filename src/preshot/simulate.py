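"""Synthetic shooting-session EEG with known injected band-power modulation.

The generator emulates the recording setup of an elite air-pistol session:
a continuous 10–20 multichannel recording per subject, one shot roughly
every minute, per-trial shooting score and perceived control, and
event-locked oscillatory amplitude modulation that differs by MAP
performance quadrant.

Signal model, per channel: a 1/f^alpha Gaussian background plus one
amplitude-modulated narrowband oscillator per analysis band (theta, low
alpha, high alpha). Gains act on oscillation *amplitude*; the ground-truth
ERD/ERS index is expressed in *power*, 100·(1 − g²), so an amplitude gain
g = 0.7 corresponds to a +51% ERD under the ERD-positive sign convention.
Amplitude transitions are smoothed with a 100-ms raised-cosine kernel to
avoid spectral splatter into neighboring bands.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError
from .io import RawRecording, SCORE_RANGE, CONTROL_RANGE
from .montage import DEFAULT_CHANNELS, frontal_weights, is_valid_site

PERFORMANCE_TYPES = (1, 2, 3, 4)
BAND_NAMES = ("theta", "low_alpha", "high_alpha")

#: Pre-shot 1-s analysis windows, seconds relative to shot release.
PRESHOT_WINDOWS = ((-3.0, -2.0), (-2.0, -1.0), (-1.0, 0.0))
BASELINE_WINDOW = (-5.0, -4.0)

#: Reported per-type behavior: type -> ((score mean, sd), (control mean, sd)).
DEFAULT_BEHAVIOR_PARAMS = {
    1: ((10.51, 0.12), (4.59, 0.39)),
    2: ((10.45, 0.12), (6.47, 0.54)),
    3: ((9.90, 0.19), (6.44, 0.46)),
    4: ((9.76, 0.24), (4.39, 0.54)),
}

#: Reported per-type shot counts (238, 350, 212, 348) over 1148 retained shots.
DEFAULT_QUADRANT_MIX = (238 / 1148, 350 / 1148, 212 / 1148, 348 / 1148)

DEFAULT_BAND_CENTERS = {"theta": 6.0, "low_alpha": 9.0, "high_alpha": 11.0}


class GainTable:
    """Amplitude gains per (performance type, band, channel, window).

    Entries may use None as a wildcard for channel and/or window; the most
    specific matching entry wins (channel+window > channel > window > band
    default). Unlisted cells default to gain 1 (no modulation).
    """

    def __init__(self) -> None:
        self._entries: dict[tuple, float] = {}

    def set(self, ptype: int, band: str, gain: float,
            channel: str | None = None, window: int | None = None) -> "GainTable":
        if gain <= 0:
            raise ConfigurationError(f"amplitude gain must be positive, got {gain}")
        if ptype not in PERFORMANCE_TYPES:
            raise ConfigurationError(f"unknown performance type {ptype}")
        if band not in BAND_NAMES:
            raise ConfigurationError(f"unknown band {band!r}")
        self._entries[(ptype, band, channel, window)] = float(gain)
        return self

    def get(self, ptype: int, band: str, channel: str, window: int) -> float:
        for key in ((ptype, band, channel, window), (ptype, band, channel, None),
                    (ptype, band, None, window), (ptype, band, None, None)):
            if key in self._entries:
                return self._entries[key]
        return 1.0

    @classmethod
    def from_type_gains(cls, by_type: dict[int, float]) -> "GainTable":
        """Uniform gain per performance type across all bands/channels/windows."""
        table = cls()
        for ptype, g in by_type.items():
            for band in BAND_NAMES:
                table.set(ptype, band, g)
        return table

    def to_dict(self) -> dict:
        return {"|".join("*" if k is None else str(k) for k in key): g
                for key, g in self._entries.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GainTable":
        table = cls()
        for key, g in d.items():
            pt, band, ch, win = key.split("|")
            table.set(int(pt), band, float(g),
                      None if ch == "*" else ch,
                      None if win == "*" else int(win))
        return table


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition defaults: 10 subjects, 120 shots each, 32-channel
    10–20 cap at 1024 Hz, ~1-min inter-shot spacing."""

    n_subjects: int = 10
    n_trials_per_subject: int = 120
    fs: float = 1024.0
    channel_labels: list[str] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_CHANNELS))
    isi_mean: float = 60.0          # inter-shot interval, s
    isi_jitter: float = 5.0         # uniform +/- jitter, s
    band_centers: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BAND_CENTERS))
    osc_amplitude: dict[str, float] = dataclasses.field(
        default_factory=lambda: {b: 10.0 for b in BAND_NAMES})  # µV
    gains: GainTable = dataclasses.field(default_factory=GainTable)
    noise_exponent: float = 1.0     # 1/f^alpha slope
    noise_std: float = 2.5          # background std, µV
    artifact_rate: float = 0.5      # transients per minute
    quadrant_mix: tuple = DEFAULT_QUADRANT_MIX
    behavior_params: dict = dataclasses.field(
        default_factory=lambda: {k: v for k, v in DEFAULT_BEHAVIOR_PARAMS.items()})
    channel_heterogeneity: float = 0.10  # per-subject channel gain spread
    ramp_s: float = 0.1             # modulation transition ramp
    pre_margin_s: float = 8.0       # quiet span before the first shot
    seed: int = 0

    def validate(self) -> None:
        highest_edge = 12.0  # top of the high-alpha band
        if self.fs <= 2 * highest_edge:
            raise ConfigurationError(
                f"fs = {self.fs} Hz must exceed twice the highest band edge")
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ConfigurationError("need at least one subject and one trial")
        if self.isi_mean - self.isi_jitter < 10.0:
            raise ConfigurationError(
                "inter-shot interval too short for the 10-s epoch span: "
                f"mean {self.isi_mean} - jitter {self.isi_jitter} < 10 s")
        if abs(sum(self.quadrant_mix) - 1.0) > 1e-9 or min(self.quadrant_mix) < 0:
            raise ConfigurationError("quadrant_mix must be a probability vector")
        for lab in self.channel_labels:
            if not is_valid_site(lab):
                raise ConfigurationError(f"{lab!r} is not a known 10–20 site")
        for band, fc in self.band_centers.items():
            if not 0 < fc < self.fs / 2:
                raise ConfigurationError(f"band center {band}={fc} outside (0, fs/2)")


@dataclasses.dataclass
class GroundTruth:
    """What the pipeline should recover: per-trial MAP quadrant and the
    injected modulation expressed as an expected ERD/ERS index."""

    trials: pd.DataFrame        # subject, trial, ptype
    gains: GainTable
    artifact_log: pd.DataFrame  # subject, onset, duration, kind

    def expected_index(self, ptype: int, band: str, channel: str,
                       window: int) -> float:
        """Expected ERD/ERS %, ERD-positive convention: 100·(1 − g²)."""
        g = self.gains.get(ptype, band, channel, window)
        return 100.0 * (1.0 - g * g)

    def to_dict(self) -> dict:
        return {
            "trials": self.trials.to_dict(orient="list"),
            "gains": self.gains.to_dict(),
            "artifact_log": self.artifact_log.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(trials=pd.DataFrame(d["trials"]),
                   gains=GainTable.from_dict(d["gains"]),
                   artifact_log=pd.DataFrame(
                       d["artifact_log"],
                       columns=["subject", "onset", "duration", "kind"]))


def _one_over_f_noise(n: int, alpha: float, std: float,
                      fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian background with a 1/f^alpha amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(freqs)
    f0 = 0.5  # flatten below 0.5 Hz so the variance stays finite
    with np.errstate(divide="ignore"):
        shape = np.where(freqs < f0, f0, freqs) ** (-alpha / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n)
    s = out.std()
    return out * (std / s) if s > 0 else out


#: Transition lead/lag (s) at the edges of a modulated block. The band
#: filters and Hilbert envelope smear an amplitude step over ~±0.2 s;
#: starting the transition slightly before the window (and ending it
#: slightly after) keeps the plateau exact inside the analysis window
#: while the transient lives in the unanalysed −4…−3 s gap / post-shot span.
TRANSITION_LEAD_S = 0.1


def _gain_envelope(n: int, fs: float, onsets: np.ndarray, quadrants: np.ndarray,
                   gains: GainTable, band: str, channel: str,
                   ramp_s: float) -> np.ndarray:
    """Piecewise amplitude envelope (baseline 1) with raised-cosine ramps.

    Transitions from baseline into a modulated window are centred
    TRANSITION_LEAD_S before the window start (and symmetrically after the
    window end when returning to baseline); gain changes between two
    modulated windows are centred on the shared boundary.
    """
    env = np.ones(n)
    lead = TRANSITION_LEAD_S
    for onset, ptype in zip(onsets, quadrants):
        targets = [gains.get(int(ptype), band, channel, w)
                   for w in range(len(PRESHOT_WINDOWS))]
        for w, (t0, t1) in enumerate(PRESHOT_WINDOWS):
            g = targets[w]
            if g == 1.0:
                continue
            prev_g = targets[w - 1] if w > 0 else 1.0
            next_g = targets[w + 1] if w + 1 < len(targets) else 1.0
            a = (onset + t0) - (lead if prev_g == 1.0 else 0.0)
            b = (onset + t1) + (lead if next_g == 1.0 else 0.0)
            env[max(int(round(a * fs)), 0):max(int(round(b * fs)), 0)] = g
    nk = max(int(round(ramp_s * fs)), 1)
    if nk > 1:
        kernel = np.hanning(nk + 2)[1:-1]
        kernel /= kernel.sum()
        env = sps.convolve(env, kernel, mode="same")
    return env


def _synthesize_subject(config: SimulationConfig, subject: str,
                        onsets: np.ndarray, quadrants: np.ndarray,
                        rng: np.random.Generator) -> RawRecording:
    fs = config.fs
    duration = math.ceil(onsets[-1] + config.pre_margin_s)
    n = int(round(duration * fs))
    n_ch = len(config.channel_labels)
    data = np.empty((n_ch, n))
    t = np.arange(n) / fs
    # per-subject channel heterogeneity, shared across time
    het = 1.0 + config.channel_heterogeneity * rng.uniform(-1, 1,
                                                           size=(n_ch, len(BAND_NAMES)))
    for ci, ch in enumerate(config.channel_labels):
        x = _one_over_f_noise(n, config.noise_exponent, config.noise_std, fs, rng)
        for bi, band in enumerate(BAND_NAMES):
            fc = config.band_centers[band]
            # narrowband oscillator: slow random-walk phase, ~0.05 Hz
            # linewidth so Lorentzian tails stay inside the 2-Hz bands
            sigma = math.sqrt(2 * math.pi * 0.05 / fs)
            phase = (2 * math.pi * fc * t
                     + np.cumsum(rng.normal(0.0, sigma, n))
                     + rng.uniform(0, 2 * math.pi))
            env = _gain_envelope(n, fs, onsets, quadrants, config.gains,
                                 band, ch, config.ramp_s)
            amp = config.osc_amplitude[band] * het[ci, bi]
            x += amp * env * np.sin(phase)
        data[ci] = x
    return RawRecording(data=data, fs=fs, channel_labels=list(config.channel_labels),
                        subject_id=subject)


def draw_quadrants(mix, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n true MAP types from the quadrant mixture."""
    mix = np.asarray(mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or mix.min() < 0:
        raise ConfigurationError("quadrant_mix must be a probability vector")
    return rng.choice(PERFORMANCE_TYPES, size=n, p=mix)


def simulate_behavior(config: SimulationConfig, quadrants,
                      seed: int, subjects=None) -> pd.DataFrame:
    """Draw per-trial shooting score and perceived control given true
    quadrant labels, from the per-type Gaussian distributions (clipped to
    the scale bounds)."""
    quadrants = np.asarray(quadrants, dtype=int)
    if quadrants.size == 0:
        raise ValidationError("empty quadrant list")
    rng = np.random.default_rng(seed)
    score = np.empty(quadrants.size)
    control = np.empty(quadrants.size)
    for ptype in PERFORMANCE_TYPES:
        mask = quadrants == ptype
        (sm, ss), (cm, cs) = config.behavior_params[ptype]
        score[mask] = rng.normal(sm, ss, mask.sum())
        control[mask] = rng.normal(cm, cs, mask.sum())
    np.clip(score, *SCORE_RANGE, out=score)
    np.clip(control, *CONTROL_RANGE, out=control)
    if subjects is None:
        subjects = ["S01"] * quadrants.size
    subj = pd.Series(subjects, name="subject")
    return pd.DataFrame({
        "subject": subj,
        "trial": subj.groupby(subj).cumcount() + 1,
        "score": np.round(score, 3),
        "control": np.round(control, 3),
    })


def inject_artifacts(rec: RawRecording, rate: float, seed: int
                     ) -> tuple[RawRecording, pd.DataFrame]:
    """Superimpose ocular and muscular transients at a Poisson rate.

    Ocular events are large slow frontopolar-weighted deflections;
    muscular events are broadband 20–40 Hz bursts. Every event is logged
    (onset, duration, kind) so detectors can be scored against it.
    """
    if rate < 0:
        raise ConfigurationError("artifact rate must be non-negative")
    log_rows = []
    if rate == 0:
        return rec, pd.DataFrame(columns=["subject", "onset", "duration", "kind"])
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    fs = rec.fs
    w_front = frontal_weights(rec.channel_labels)
    t = 0.0
    per_s = rate / 60.0
    while True:
        t += rng.exponential(1.0 / per_s)
        if t >= rec.duration - 2.0:
            break
        kind = "ocular" if rng.random() < 0.5 else "muscular"
        if kind == "ocular":
            dur = rng.uniform(0.5, 1.5)
            amp = rng.uniform(150.0, 300.0)
            n = int(round(dur * fs))
            wave = amp * np.hanning(n)
            weights = w_front
        else:
            dur = rng.uniform(0.3, 0.8)
            amp = rng.uniform(40.0, 60.0)  # std of the burst, µV
            n = int(round(dur * fs))
            sos = sps.butter(4, [20.0, min(40.0, 0.45 * fs)], btype="band",
                             fs=fs, output="sos")
            wave = sps.sosfilt(sos, rng.standard_normal(n))
            wave *= amp / max(wave.std(), 1e-12) * np.hanning(n)
            weights = rng.uniform(0.5, 1.0, rec.n_channels)
        a = int(round(t * fs))
        b = min(a + n, rec.n_samples)
        data[:, a:b] += weights[:, None] * wave[: b - a]
        log_rows.append((rec.subject_id, t, dur, kind))
    log = pd.DataFrame(log_rows, columns=["subject", "onset", "duration", "kind"])
    return (RawRecording(data=data, fs=fs, channel_labels=list(rec.channel_labels),
                         subject_id=rec.subject_id), log)


def simulate_session(config: SimulationConfig, seed: int | None = None
                     ) -> tuple[list[RawRecording], pd.DataFrame,
                                pd.DataFrame, GroundTruth]:
    """Generate a full multi-subject session.

    Returns one continuous recording per subject, the pooled event table,
    the pooled behavior table, and the ground truth (true quadrants,
    injected gains, artifact log). Identical (config, seed) pairs
    reproduce identical outputs.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    subj_seqs = ss.spawn(config.n_subjects + 1)
    beh_seed = ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31)

    recordings: list[RawRecording] = []
    event_rows = []
    all_quadrants = []
    all_subjects = []
    art_logs = []
    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        rng = np.random.default_rng(subj_seqs[si])
        isi = config.isi_mean + rng.uniform(-config.isi_jitter, config.isi_jitter,
                                            config.n_trials_per_subject)
        onsets = config.pre_margin_s + np.cumsum(isi) - isi[0] + 0.0
        onsets = np.round(onsets, 3)
        quadrants = draw_quadrants(config.quadrant_mix,
                                   config.n_trials_per_subject, rng)
        rec = _synthesize_subject(config, subject, onsets, quadrants, rng)
        if config.artifact_rate > 0:
            art_seed = subj_seqs[si].generate_state(2)[1] % (2 ** 31)
            rec, log = inject_artifacts(rec, config.artifact_rate, art_seed)
            art_logs.append(log)
        recordings.append(rec)
        for k, onset in enumerate(onsets):
            event_rows.append((onset, k + 1, subject))
        all_quadrants.append(quadrants)
        all_subjects.extend([subject] * config.n_trials_per_subject)

    events = pd.DataFrame(event_rows, columns=["onset", "trial", "subject"])
    quadrants_all = np.concatenate(all_quadrants)
    behavior = simulate_behavior(config, quadrants_all, beh_seed,
                                 subjects=all_subjects)
    truth = GroundTruth(
        trials=pd.DataFrame({"subject": all_subjects,
                             "trial": behavior["trial"].to_numpy(),
                             "ptype": quadrants_all}),
        gains=config.gains,
        artifact_log=(pd.concat(art_logs, ignore_index=True) if art_logs
                      else pd.DataFrame(columns=["subject", "onset",
                                                 "duration", "kind"])),
    )
    return recordings, events, behavior, truth
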