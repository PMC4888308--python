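"""Generate a small synthetic shooting session and inspect its pieces.

Builds a down-scaled session (2 subjects, 20 shots each, 256 Hz, 8
channels), prints the recording geometry, the first few shot events and
behavior rows, and the injected ground truth. In a full-scale run the
defaults of SimulationConfig reproduce the study conditions: 10 subjects,
120 shots, 32 channels at 1024 Hz, ~1 min between shots.
"""

import preshot as ps

config = ps.SimulationConfig(
    n_subjects=2, n_trials_per_subject=20, fs=256.0,
    channel_labels=["Fpz", "Fz", "Cz", "Pz", "C3", "C4", "O1", "O2"],
    isi_mean=12.0, isi_jitter=1.0, artifact_rate=1.0,
    gains=ps.GainTable.from_type_gains({1: 1.0, 2: 0.8, 3: 0.6, 4: 1.25}))

recordings, events, behavior, truth = ps.simulate_session(config, seed=2016)

rec = recordings[0]
print(f"subject {rec.subject_id}: {rec.n_channels} channels × "
      f"{rec.duration:.0f} s at {rec.fs:.0f} Hz")
print("\nfirst events (onset seconds of each shot):")
print(events.head(3).to_string(index=False))
print("\nbehavior (score 0–10.9, perceived control 0–11):")
print(behavior.head(3).to_string(index=False))
kinds = {k: int(v) for k, v in truth.artifact_log["kind"].value_counts().items()}
print(f"\ninjected artifacts: {len(truth.artifact_log)} ({kinds})")
print("expected ERD/ERS for a Type-3 trial (amplitude gain 0.6):",
      truth.expected_index(3, "low_alpha", "Cz", 0), "%")
# 100·(1−0.6²) = +64%: power drops to 36% of baseline, a strong ERD.
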