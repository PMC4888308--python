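"""End-to-end orchestration: simulate/load → preprocess → ERD/ERS →
categorize → statistics → figures, with provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categorize import categorize, derive_thresholds, quadrant_counts
from .erders import (AnalysisWindows, DEFAULT_BANDS, compute_subject_maps,
                     grand_average, maps_to_long)
from .errors import PipelineError
from .io import (read_behavior, read_edf, read_events, write_behavior,
                 write_edf, write_erders_table, write_events, write_json)
from .preprocess import artifact_detect, bandpass_broad, epoch_extract, rejection_report
from .simulate import SimulationConfig, simulate_session
from .stats import run_stats_battery
from .topomap import render_band_figure


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; validated before any computation starts."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    out_dir: str = "preshot_run"
    seed: int = 0
    # input files (simulation is used when edf_paths is None)
    edf_paths: list[str] | None = None
    events_path: str | None = None
    behavior_path: str | None = None
    # stage parameters
    bandpass: tuple[float, float] = (0.3, 40.0)
    amp_thresh: float = 100.0
    grad_thresh: float = 50.0
    flat_thresh: float = 0.5
    windows: AnalysisWindows = dataclasses.field(default_factory=AnalysisWindows)
    sign_convention: str = "erd_positive"
    categorize_mode: str = "median_split"
    stats_policy: str = "mauchly"
    alpha: float = 0.05
    make_figures: bool = True

    def validate(self) -> None:
        if self.edf_paths is not None:
            for name, p in (("events", self.events_path),
                            ("behavior", self.behavior_path)):
                if p is None or not Path(p).exists():
                    raise PipelineError(f"missing {name} file: {p}")
            for p in self.edf_paths:
                if not Path(p).exists():
                    raise PipelineError(f"missing EDF file: {p}")
        else:
            self.simulation.validate()


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write maps, tables, statistics, figures and a
    provenance manifest into ``config.out_dir``. Deterministic for a given
    (config, seed)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    written: list[str] = []

    def save(name: str) -> Path:
        written.append(name)
        return out / name

    truth = None
    if config.edf_paths is None:
        recordings, events, behavior, truth = simulate_session(
            config.simulation, seed=config.seed)
        write_events(events, save("events.tsv"))
        write_behavior(behavior, save("behavior.csv"))
        write_json(truth.to_dict(), save("ground_truth.json"))
    else:
        behavior = read_behavior(config.behavior_path)   # fail early, by name
        events = read_events(config.events_path)
        recordings = [read_edf(p) for p in config.edf_paths]
    counts["n_subjects"] = len(recordings)
    counts["n_trials"] = int(len(events))

    # preprocess
    epoch_sets, dropped_all = [], []
    for rec in recordings:
        filtered = bandpass_broad(rec, *config.bandpass)
        epochs, dropped = epoch_extract(filtered, events)
        epochs = artifact_detect(epochs, config.amp_thresh, config.grad_thresh,
                                 config.flat_thresh)
        epoch_sets.append(epochs)
        if len(dropped):
            dropped.insert(0, "subject", rec.subject_id)
            dropped_all.append(dropped)
    report = rejection_report(epoch_sets)
    report.to_csv(save("rejection_log.tsv"), sep="\t", index=False)
    counts["n_rejected"] = int(report["n_rejected"].sum())
    counts["n_retained"] = int(report["n_retained"].sum())

    # categorize
    rule = derive_thresholds(behavior, config.categorize_mode)
    behavior_cat = categorize(behavior, rule)
    behavior_cat.to_csv(save("quadrants.csv"), index=False)
    counts["per_quadrant_n"] = quadrant_counts(behavior_cat).to_dict()

    # ERD/ERS maps
    all_maps = []
    for epochs in epoch_sets:
        sub_beh = behavior_cat[behavior_cat["subject"] == epochs.subject_id]
        by_trial = dict(zip(sub_beh["trial"], sub_beh["ptype"]))
        all_maps.extend(compute_subject_maps(
            epochs, by_trial, DEFAULT_BANDS, config.windows,
            config.sign_convention))
    long_df = maps_to_long(all_maps)
    write_erders_table(long_df, save("erders.tsv"))
    grand = grand_average(all_maps)
    write_json({f"type{m.ptype}_{m.band}":
                {"channels": m.channels, "values": m.values,
                 "n_subjects": m.n_epochs} for m in grand},
               save("grand_maps.json"))

    # statistics
    battery = run_stats_battery(long_df, policy=config.stats_policy,
                                alpha=config.alpha)
    battery["effects"].to_csv(save("stats_effects.tsv"), sep="\t", index=False)
    battery["significant"].to_csv(save("stats_significant.tsv"), sep="\t",
                                  index=False)
    battery["posthoc"].to_csv(save("stats_posthoc.tsv"), sep="\t", index=False)
    write_json({"effects": battery["effects"].to_dict(orient="records")},
               save("stats.json"))

    if config.make_figures:
        for band in {m.band for m in grand}:
            render_band_figure(grand, band, save(f"topomap_{band}.png"))

    provenance = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "counts": counts,
        "outputs": sorted(written) + ["provenance.json"],
    }
    write_json(provenance, out / "provenance.json")
    return {"out_dir": str(out), "erders": long_df, "grand_maps": grand,
            "stats": battery, "behavior": behavior_cat, "truth": truth,
            "provenance": provenance, "epoch_sets": epoch_sets}


def export_recordings(recordings, out_dir: str | Path) -> list[Path]:
    """Write one EDF per subject (used by the simulate CLI subcommand)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        p = out / f"{rec.subject_id}.edf"
        write_edf(rec, p)
        paths.append(p)
    return paths
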