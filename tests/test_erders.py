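"""Hilbert-envelope band power and ERD/ERS index computation."""

import numpy as np
import pytest

import preshot as ps
from preshot.erders import ERDSMap, SIGN_CONVENTIONS
from conftest import small_config, TYPE_GAINS


def _epochs_from_array(data, fs=256.0, labels=None):
    n_trials, n_ch, _ = data.shape
    return ps.EpochSet(data=data, fs=fs,
                       channel_labels=labels or [f"C{i}" for i in range(n_ch)],
                       subject_id="S01",
                       trials=np.arange(1, n_trials + 1),
                       bad=np.zeros(n_trials, bool))


def _sine_epochs(freq, fs=256.0, amp=1.0, n_trials=1):
    t = np.arange(round(10 * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return ps.EpochSet(data=np.tile(x, (n_trials, 1, 1)), fs=fs,
                       channel_labels=["Cz"], subject_id="S01",
                       trials=np.arange(1, n_trials + 1),
                       bad=np.zeros(n_trials, bool))


class TestBandPower:
    def test_envelope_power_convention(self):
        """|analytic|² of a unit sine inside the band is A² = 1.0 (not ½A²)."""
        epochs = _sine_epochs(9.0)
        power = ps.band_power(epochs, ps.BandDefinition("low_alpha", 8, 10))
        interior = power[0, 0, int(2 * epochs.fs):-int(2 * epochs.fs)]
        assert interior.mean() == pytest.approx(1.0, rel=0.03)

    def test_white_noise_band_additivity(self, rng):
        """Parseval check: power in disjoint bands sums to the union-band
        power within 10%."""
        data = rng.standard_normal((1, 1, round(10 * 256.0)))
        epochs = _epochs_from_array(data)
        guard = slice(int(256), -int(256))
        p_theta = ps.band_power(epochs, ps.BandDefinition("theta", 4, 8))
        p_la = ps.band_power(epochs, ps.BandDefinition("low_alpha", 8, 10))
        p_union = ps.band_power(epochs, ps.BandDefinition("union", 4, 10))
        lhs = (p_theta + p_la)[0, 0, guard].mean()
        rhs = p_union[0, 0, guard].mean()
        assert lhs == pytest.approx(rhs, rel=0.10)

    def test_zero_signal_zero_power(self):
        epochs = _epochs_from_array(np.zeros((1, 1, round(10 * 256.0))))
        power = ps.band_power(epochs, ps.BandDefinition("theta", 4, 8))
        assert np.allclose(power, 0.0)

    def test_band_outside_passband_rejected(self):
        epochs = _sine_epochs(9.0)
        with pytest.raises(ps.ConfigurationError, match="passband"):
            ps.band_power(epochs, ps.BandDefinition("hf", 30, 45))


class TestGroupBaseline:
    def test_mean_over_epochs(self):
        """Two epochs with baseline powers p and 3p average to 2p, and a
        homogeneous group equals any single epoch."""
        p = np.ones((2, 1, 100))
        p[1] *= 3.0
        assert ps.group_baseline(p, slice(0, 100))[0] == pytest.approx(2.0)
        same = np.full((5, 2, 100), 7.0)
        assert np.allclose(ps.group_baseline(same, slice(0, 100)), 7.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ps.PipelineError, match="empty"):
            ps.group_baseline(np.empty((0, 1, 10)), slice(0, 10))


class TestErdersIndex:
    def test_formula_anchors(self):
        """index = −100·(P_int − P_base)/P_base: ratios 1, 0.5, 2 give
        exactly 0, +50 (ERD), −100 (ERS)."""
        power = np.ones((1, 1, 300))
        power[0, 0, 100:200] = 0.5
        power[0, 0, 200:300] = 2.0
        idx = ps.erders_index(power, np.array([1.0]),
                              [slice(0, 100), slice(100, 200), slice(200, 300)])
        np.testing.assert_allclose(idx[0, 0], [0.0, 50.0, -100.0])

    def test_raw_percent_change_convention(self):
        power = np.ones((1, 1, 100))
        power[0, 0, :] = 0.5
        idx = ps.erders_index(power, np.array([1.0]), [slice(0, 100)],
                              sign_convention="raw_percent_change")
        assert idx[0, 0, 0] == pytest.approx(-50.0)

    def test_zero_baseline_yields_nan_not_blowup(self):
        power = np.ones((1, 2, 100))
        with pytest.warns(UserWarning, match="zero baseline"):
            idx = ps.erders_index(power, np.array([1.0, 0.0]), [slice(0, 100)])
        assert np.isnan(idx[0, 1, 0])
        assert np.isfinite(idx[0, 0, 0])


class TestAnalysisWindows:
    def test_defaults_match_protocol(self):
        w = ps.AnalysisWindows()
        assert w.baseline == (-5.0, -4.0)
        assert w.intervals == ((-3.0, -2.0), (-2.0, -1.0), (-1.0, 0.0))

    @pytest.mark.parametrize("kwargs, message", [
        (dict(baseline=(-5.5, -4.5)), "before −5"),
        (dict(intervals=((-3.0, -2.0), (-1.0, 0.0))), "contiguous"),
        (dict(baseline=(-3.5, -2.5)), "overlaps"),
    ])
    def test_invalid_windows_rejected(self, kwargs, message):
        with pytest.raises(ps.ConfigurationError, match=message):
            ps.AnalysisWindows(**kwargs)

    def test_edge_guard_enforced(self):
        epochs = _sine_epochs(9.0)
        with pytest.raises(ps.ConfigurationError, match="guard"):
            ps.window_slice(epochs, (-6.0, -5.0))


class TestRecovery:
    def test_injected_gains_recovered(self, recovery_session):
        """Indices recover 100·(1−g²) within ±5 points per (type, band,
        channel, window) with ≥50 epochs per quadrant, and sign(index) =
        sign(1−g²) everywhere."""
        cfg, epochs, truth = recovery_session
        by_trial = dict(zip(truth.trials["trial"], truth.trials["ptype"]))
        maps = ps.compute_subject_maps(epochs, by_trial)
        assert min(m.n_epochs for m in maps) >= 40
        for m in maps:
            for ci, ch in enumerate(m.channels):
                for w in range(3):
                    expected = truth.expected_index(m.ptype, m.band, ch, w)
                    got = m.values[ci, w]
                    assert got == pytest.approx(expected, abs=5.0), (
                        m.ptype, m.band, ch, w)
                    if expected != 0.0:
                        assert np.sign(got) == np.sign(expected)

    def test_scale_invariance(self, recovery_session):
        """Rescaling a channel leaves its ERD/ERS index unchanged."""
        _, epochs, truth = recovery_session
        by_trial = dict(zip(truth.trials["trial"], truth.trials["ptype"]))
        sub = epochs.retained()
        sub.data = sub.data[:24].copy()
        sub.trials = sub.trials[:24]
        sub.bad = sub.bad[:24]
        base = ps.compute_subject_maps(sub, by_trial)
        sub2 = ps.EpochSet(sub.data * 3.7, sub.fs, sub.channel_labels,
                           sub.subject_id, sub.trials, sub.bad, sub.tmin)
        scaled = ps.compute_subject_maps(sub2, by_trial)
        for m1, m2 in zip(base, scaled):
            np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)

    def test_band_separation(self):
        """A modulation injected only in 8–10 Hz moves the low-alpha index
        while theta and high-alpha stay within ±8 points of zero."""
        gains = ps.GainTable().set(1, "low_alpha", 0.6)
        cfg = small_config(n_subjects=1, n_trials_per_subject=60,
                           channel_labels=["Cz", "Pz"], gains=gains,
                           quadrant_mix=(1.0, 0.0, 0.0, 0.0))
        recs, events, _, truth = ps.simulate_session(cfg, seed=21)
        epochs, _ = ps.epoch_extract(ps.bandpass_broad(recs[0]), events)
        by_trial = dict(zip(truth.trials["trial"], truth.trials["ptype"]))
        maps = ps.compute_subject_maps(epochs, by_trial)
        for m in maps:
            if m.band == "low_alpha":
                assert np.all(np.abs(m.values - 64.0) < 8.0)
            else:
                assert np.all(np.abs(m.values) < 8.0)


class TestAveraging:
    def _map(self, subject, values, ptype=1, band="theta", n=10):
        values = np.asarray(values, float)
        return ERDSMap(subject, ptype, band, ["Cz", "Pz"], values,
                       np.ones(2), n)

    def test_grand_average_symmetry_and_identity(self):
        m = np.array([[10.0, -5.0, 3.0], [2.0, 0.0, -1.0]])
        grand = ps.grand_average([self._map("S01", m), self._map("S02", -m)])
        np.testing.assert_allclose(grand[0].values, 0.0)
        solo = ps.grand_average([self._map("S01", m)])
        np.testing.assert_allclose(solo[0].values, m)

    def test_equal_subject_weighting(self):
        """Subjects weigh equally regardless of their epoch counts."""
        m1 = self._map("S01", np.full((2, 3), 10.0), n=10)
        m2 = self._map("S02", np.full((2, 3), 30.0), n=100)
        grand = ps.grand_average([m1, m2])
        np.testing.assert_allclose(grand[0].values, 20.0)
        assert grand[0].n_epochs == 2  # contributing subjects

    def test_averaging_orders_agree_on_synthetic_data(self, recovery_session):
        _, epochs, truth = recovery_session
        by_trial = dict(zip(truth.trials["trial"], truth.trials["ptype"]))
        a = ps.compute_subject_maps(epochs, by_trial, average="per_epoch")
        b = ps.compute_subject_maps(epochs, by_trial, average="power_first")
        for m1, m2 in zip(a, b):
            assert np.abs(m1.values - m2.values).max() < 5.0

    def test_long_table_shape(self, recovery_session):
        _, epochs, truth = recovery_session
        by_trial = dict(zip(truth.trials["trial"], truth.trials["ptype"]))
        maps = ps.compute_subject_maps(epochs, by_trial)
        long = ps.maps_to_long(maps)
        # 4 types × 3 bands × 4 channels × 3 intervals
        assert len(long) == 4 * 3 * 4 * 3
        assert set(long.columns) == {"subject", "performance_type", "band",
                                     "channel", "interval", "erders_pct"}
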