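"""Repeated-measures ANOVA, sphericity, effect size and post-hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import preshot as ps
from preshot.stats import _partition


def brute_force_partition(cells: np.ndarray) -> dict:
    """Independent oracle: project the data vector onto the orthogonal
    subspaces built from Kronecker products of centering matrices."""
    n, a, b = cells.shape
    y = cells.reshape(-1)

    def J(k):
        return np.full((k, k), 1.0 / k)

    def C(k):
        return np.eye(k) - J(k)

    def ss(Pn, Pa, Pb):
        proj = np.kron(np.kron(Pn, Pa), Pb)
        v = proj @ y
        return float(v @ v)

    return {
        "S": ss(C(n), J(a), J(b)),
        "A": ss(J(n), C(a), J(b)),
        "B": ss(J(n), J(a), C(b)),
        "AxB": ss(J(n), C(a), C(b)),
        "AxS": ss(C(n), C(a), J(b)),
        "BxS": ss(C(n), J(a), C(b)),
        "AxBxS": ss(C(n), C(a), C(b)),
    }


class TestRmAnova:
    def test_published_design_dfs(self, rng):
        """n = 10 subjects, 4 × 3 within design → dfs (3,27), (2,18), (6,54)."""
        cells = rng.normal(size=(10, 4, 3))
        effects = {e.effect: e for e in ps.rm_anova(cells)}
        assert (effects["A"].df1, effects["A"].df2) == (3, 27)
        assert (effects["B"].df1, effects["B"].df2) == (2, 18)
        assert (effects["AxB"].df1, effects["AxB"].df2) == (6, 54)

    def test_zero_between_level_variation(self, rng):
        subj = rng.normal(size=(6, 1, 1))
        cells = np.broadcast_to(subj, (6, 4, 3)).copy()
        for eff in ps.rm_anova(cells):
            assert eff.F == 0.0

    @pytest.mark.parametrize("shape", [(3, 2, 2), (4, 3, 2), (5, 4, 3),
                                       (10, 4, 3)])
    def test_ss_partition_matches_projection_oracle(self, shape, rng):
        cells = rng.normal(size=shape)
        ours = _partition(cells)
        oracle = brute_force_partition(cells)
        for key, val in oracle.items():
            assert ours[key] == pytest.approx(val, rel=1e-10, abs=1e-12)
        total = sum(oracle.values())
        assert ours["total"] == pytest.approx(total, rel=1e-8)

    def test_f_matches_statsmodels(self, rng):
        """statsmodels AnovaRM as an independent full-model oracle."""
        from statsmodels.stats.anova import AnovaRM
        cells = rng.normal(size=(8, 4, 3))
        rows = [(s, a, b, cells[s, a, b])
                for s in range(8) for a in range(4) for b in range(3)]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "y"])
        ref = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        ours = {e.effect: e for e in ps.rm_anova(cells, policy="never")}
        assert ours["A"].F == pytest.approx(ref.loc["A", "F Value"], rel=1e-8)
        assert ours["B"].F == pytest.approx(ref.loc["B", "F Value"], rel=1e-8)
        assert ours["AxB"].F == pytest.approx(ref.loc["A:B", "F Value"], rel=1e-8)

    def test_missing_cell_named(self, rng):
        cells = rng.normal(size=(4, 4, 3))
        cells[2, 1, 0] = np.nan
        with pytest.raises(ps.DesignError, match=r"\(2, 1, 0\)"):
            ps.rm_anova(cells)
        with pytest.raises(ps.DesignError, match="2 subjects"):
            ps.rm_anova(rng.normal(size=(1, 4, 3)))

    def test_corrected_p_not_smaller_when_nonspherical(self, rng):
        """Shrinking both dfs by ε raises the p of any clearly non-null F
        (near F ≈ 1 the correction can legitimately lower p a hair, so the
        bound is asserted for F ≥ 2, the regime the correction exists for)."""
        checked = 0
        for _ in range(60):
            cells = rng.normal(size=(10, 4, 3))
            cells[:, :, 2] += 3 * rng.normal(size=(10, 1))  # break sphericity
            for eff in ps.rm_anova(cells, policy="always"):
                if eff.epsilon_hf < 1 and eff.F >= 2:
                    assert eff.p_corrected >= eff.p_uncorrected
                    checked += 1
        assert checked >= 5


class TestSphericity:
    def test_compound_symmetry_gives_unit_epsilon(self, rng):
        """Compound-symmetric covariance satisfies sphericity: ε = 1."""
        n, k = 2000, 4
        subj = rng.normal(size=(n, 1))
        y = np.broadcast_to(subj, (n, k)) + rng.normal(size=(n, k))
        cells = y[:, :, None].repeat(3, axis=2) + 0.01 * rng.normal(size=(n, k, 3))
        _, _, gg, hf = ps.sphericity(cells, "A")
        assert gg == pytest.approx(1.0, abs=0.01)
        assert hf == 1.0

    def test_two_levels_trivially_spherical(self, rng):
        cells = rng.normal(size=(6, 2, 3))
        assert ps.sphericity(cells, "A") == (1.0, 1.0, 1.0, 1.0)

    def test_gg_matches_direct_trace_formula(self, rng):
        """ε_GG = (tr M)²/((k−1)·tr M²) on the contrast covariance M."""
        cells = rng.normal(size=(10, 4, 3)) * rng.uniform(0.5, 3, size=3)
        y = cells.mean(axis=1)  # factor B, k = 3
        contrast = linalg.null_space(np.ones((1, 3)))
        m = np.cov(y @ contrast, rowvar=False, ddof=1)
        expected = np.trace(m) ** 2 / (2 * np.trace(m @ m))
        _, _, gg, _ = ps.sphericity(cells, "B")
        assert gg == pytest.approx(expected, rel=1e-10)

    def test_epsilons_match_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = rng.normal(size=(10, 4, 3)) * rng.uniform(0.5, 2, size=(1, 4, 1))
        y = pd.DataFrame(cells.mean(axis=2))
        _, _, gg, hf = ps.sphericity(cells, "A")
        assert gg == pytest.approx(pg.epsilon(y, correction="gg"), rel=1e-8)
        assert hf == pytest.approx(min(1.0, pg.epsilon(y, correction="hf")),
                                   rel=1e-6)
        w_ref = pg.sphericity(y)[1]
        w, _, _, _ = ps.sphericity(cells, "A")
        assert w == pytest.approx(w_ref, rel=1e-8)

    def test_singular_covariance_fallback_warns(self, rng):
        cells = rng.normal(size=(3, 4, 3))  # n−1 = 2 < 6 interaction contrasts
        with pytest.warns(UserWarning, match="singular"):
            _, p, gg, hf = ps.sphericity(cells, "AxB")
        assert np.isnan(p)
        assert 0 < gg <= 1


class TestPartialEtaSquared:
    @pytest.mark.parametrize("F, df1, df2, expected", [
        (5.338, 3, 27, 0.372),   # performance effect, frontal midline theta
        (8.858, 2, 18, 0.496),   # time effect, centro-parietal theta
        (0.0, 3, 27, 0.0),
    ])
    def test_published_identities(self, F, df1, df2, expected):
        assert ps.partial_eta_squared(F, df1, df2) == pytest.approx(expected,
                                                                    abs=5e-4)

    def test_equals_ss_ratio(self, rng):
        cells = rng.normal(size=(6, 4, 3))
        for eff in ps.rm_anova(cells):
            assert eff.eta_p2 == pytest.approx(
                eff.ss_effect / (eff.ss_effect + eff.ss_error), rel=1e-10)


class TestFisherLsd:
    def test_identical_means(self):
        cells = np.random.default_rng(0).normal(size=(6, 1, 3))
        cells = np.broadcast_to(cells, (6, 4, 3)).copy()
        cells += np.random.default_rng(1).normal(size=(6, 4, 3)) * 1e-9
        cells += cells.mean()  # no A-level differences beyond noise
        lsd = ps.fisher_lsd(cells, "A")
        assert np.allclose(lsd["mean_diff"].abs(), 0, atol=1e-8)

    def test_two_level_t_squared_equals_f(self, rng):
        cells = rng.normal(size=(7, 2, 3))
        f = ps.rm_anova(cells)[0]
        lsd = ps.fisher_lsd(cells, "A")
        assert lsd["t"].iloc[0] ** 2 == pytest.approx(f.F, rel=1e-8)

    def test_antisymmetry(self, rng):
        cells = rng.normal(size=(5, 4, 3))
        lsd = ps.fisher_lsd(cells, "A").set_index(["level_i", "level_j"])
        for (i, j) in [(1, 2), (2, 4), (3, 1)]:
            assert lsd.loc[(i, j), "t"] == pytest.approx(
                -lsd.loc[(j, i), "t"], rel=1e-12)


class TestBattery:
    def _long_table(self, rng, n_subjects=5, bands=("theta",),
                    channels=("Cz",), effect=0.0):
        rows = []
        for band in bands:
            for ch in channels:
                for s in range(n_subjects):
                    for a in range(1, 5):
                        for b in range(3):
                            val = rng.normal() + (effect if a == 3 else 0.0)
                            rows.append((f"S{s:02d}", a, band, ch, b, val))
        return pd.DataFrame(rows, columns=["subject", "performance_type",
                                           "band", "channel", "interval",
                                           "erders_pct"])

    def test_one_anova_per_band_electrode(self, rng):
        df = self._long_table(rng, bands=("theta", "low_alpha", "high_alpha"),
                              channels=tuple(ps.DEFAULT_CHANNELS))
        out = ps.run_stats_battery(df)
        assert len(out["effects"]) == 3 * 32 * 3  # bands × electrodes × effects

    def test_incomplete_electrode_skipped(self, rng):
        df = self._long_table(rng, channels=("Cz", "Pz"))
        df = df[~((df["channel"] == "Pz") & (df["performance_type"] == 2))]
        out = ps.run_stats_battery(df)
        assert list(out["skipped"]["channel"]) == ["Pz"]
        assert set(out["effects"]["channel"]) == {"Cz"}

    def test_power_for_strong_injected_effect(self, rng):
        """A large Type-3-only shift is detected by the performance effect
        with power ≥ 0.8 (50 simulated datasets, n = 10 subjects)."""
        hits = 0
        reps = 50
        for _ in range(reps):
            df = self._long_table(rng, n_subjects=10, effect=2.0)
            out = ps.run_stats_battery(df)
            eff = out["effects"]
            row = eff[(eff["effect"] == "performance")]
            hits += int(row["p"].iloc[0] < 0.05)
        assert hits / reps >= 0.8

    def test_posthoc_gated_on_significance(self, rng):
        df = self._long_table(rng, n_subjects=10, effect=3.0)
        out = ps.run_stats_battery(df)
        post = out["posthoc"]
        assert len(post) > 0
        assert set(post["effect"]) <= {"performance", "time"}
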