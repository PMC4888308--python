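"""Two-way repeated-measures ANOVA with sphericity handling and post-hocs.

The design is 4 performance types × 3 pre-shot intervals, both within
subject, applied per (band, electrode) to per-subject mean ERD/ERS
indices. Sums of squares follow the classical balanced partition
(subjects, A, A×S, B, B×S, A×B, A×B×S) with each effect tested against
its own subject-interaction error term. Sphericity is assessed with
Mauchly's test on the orthonormal-contrast covariance; by default the
Huynh–Feldt epsilon rescales the degrees of freedom only when Mauchly's
p < .05 (``policy='mauchly'``; ``'always'`` and ``'never'`` are provided
for sensitivity). Effect size is partial eta squared; post-hoc pairwise
comparisons use Fisher's LSD (unadjusted t on cell means with the
matching ANOVA error term).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats as sst

from .errors import DesignError

EFFECTS = ("A", "B", "AxB")
EFFECT_LABELS = {"A": "performance", "B": "time", "AxB": "performance_x_time"}


@dataclasses.dataclass
class AnovaEffect:
    effect: str               # 'A', 'B' or 'AxB'
    F: float
    df1: int                  # uncorrected, as conventionally printed
    df2: int
    ss_effect: float
    ss_error: float
    epsilon_gg: float
    epsilon_hf: float
    mauchly_w: float
    sphericity_p: float
    p_uncorrected: float
    p_corrected: float
    eta_p2: float

    @property
    def label(self) -> str:
        return EFFECT_LABELS[self.effect]


def cells_from_long(df: pd.DataFrame, n_types: int = 4,
                    n_intervals: int = 3) -> tuple[np.ndarray, list[str]]:
    """(n_subjects, n_types, n_intervals) cell-mean array from long rows
    (columns subject, performance_type, interval, erders_pct).

    Raises DesignError naming the first missing or non-finite cell.
    """
    subjects = sorted(df["subject"].unique())
    cells = np.full((len(subjects), n_types, n_intervals), np.nan)
    g = df.groupby(["subject", "performance_type", "interval"])["erders_pct"].mean()
    for si, s in enumerate(subjects):
        for a in range(1, n_types + 1):
            for b in range(n_intervals):
                try:
                    cells[si, a - 1, b] = g.loc[(s, a, b)]
                except KeyError:
                    raise DesignError(f"missing cell (subject={s}, type={a}, "
                                      f"interval={b})") from None
    if not np.isfinite(cells).all():
        idx = np.argwhere(~np.isfinite(cells))[0]
        raise DesignError(f"non-finite cell (subject={subjects[idx[0]]}, "
                          f"type={idx[1] + 1}, interval={idx[2]})")
    return cells, subjects


def _check_cells(cells: np.ndarray) -> np.ndarray:
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3:
        raise DesignError("cells must be (subjects, A levels, B levels)")
    if cells.shape[0] < 2:
        raise DesignError("repeated-measures ANOVA needs at least 2 subjects")
    if not np.isfinite(cells).all():
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(cells))[0])
        raise DesignError(f"missing cell at (subject, A, B) index {idx}")
    return cells


def _partition(cells: np.ndarray) -> dict[str, float]:
    """Balanced SS partition from marginal means."""
    n, a, b = cells.shape
    g = cells.mean()
    m_s = cells.mean(axis=(1, 2))
    m_a = cells.mean(axis=(0, 2))
    m_b = cells.mean(axis=(0, 1))
    m_ab = cells.mean(axis=0)
    m_as = cells.mean(axis=2)
    m_bs = cells.mean(axis=1)
    ss = {
        "S": a * b * np.sum((m_s - g) ** 2),
        "A": n * b * np.sum((m_a - g) ** 2),
        "B": n * a * np.sum((m_b - g) ** 2),
        "AxB": n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2),
        "AxS": b * np.sum((m_as - m_a[None, :] - m_s[:, None] + g) ** 2),
        "BxS": a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + g) ** 2),
        "total": np.sum((cells - g) ** 2),
    }
    ss["AxBxS"] = ss["total"] - sum(ss[k] for k in
                                    ("S", "A", "B", "AxB", "AxS", "BxS"))
    return ss


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) matrix with orthonormal columns orthogonal to the mean."""
    return linalg.null_space(np.ones((1, k)))


def sphericity(cells: np.ndarray, effect: str
               ) -> tuple[float, float, float, float]:
    """Mauchly's W and p plus Greenhouse–Geisser / Huynh–Feldt epsilons.

    Effects with 2 levels are trivially spherical (W = 1, epsilon = 1).
    When the contrast covariance is singular (too few subjects), the
    epsilons are still computed from its eigenvalues but Mauchly's p is
    returned as NaN with a warning.
    """
    cells = _check_cells(cells)
    n, a, b = cells.shape
    if effect == "A":
        y, levels = cells.mean(axis=2), (a,)
    elif effect == "B":
        y, levels = cells.mean(axis=1), (b,)
    elif effect == "AxB":
        y, levels = cells.reshape(n, a * b), (a, b)
    else:
        raise DesignError(f"unknown effect {effect!r}")
    if len(levels) == 1:
        contrast = _orthonormal_contrasts(levels[0])
    else:
        contrast = np.kron(_orthonormal_contrasts(levels[0]),
                           _orthonormal_contrasts(levels[1]))
    d = contrast.shape[1]
    if d == 1:
        return 1.0, 1.0, 1.0, 1.0
    transformed = y @ contrast
    cov = np.cov(transformed, rowvar=False, ddof=1)
    tr = float(np.trace(cov))
    tr2 = float(np.trace(cov @ cov))
    eps_gg = tr ** 2 / (d * tr2) if tr2 > 0 else 1.0
    eps_gg = min(eps_gg, 1.0)
    denom = d * (n - 1 - d * eps_gg)
    eps_hf = min(1.0, (n * d * eps_gg - 2) / denom) if denom > 0 else 1.0
    det = float(np.linalg.det(cov))
    if n - 1 <= d or det <= 0:
        warnings.warn("contrast covariance singular; Mauchly's test "
                      "unavailable, epsilons from eigenvalues (pseudo-inverse "
                      "fallback)")
        return 0.0, float("nan"), eps_gg, eps_hf
    w = det / (tr / d) ** d
    f_df = d * (d + 1) // 2 - 1
    factor = (2 * d * d + d + 2) / (6.0 * d)
    chi2 = -(n - 1 - factor) * np.log(w)
    p = float(sst.chi2.sf(chi2, f_df))
    return float(w), p, eps_gg, eps_hf


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """η²p = F·df1 / (F·df1 + df2), the SS_effect/(SS_effect+SS_error) identity."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise DesignError("partial eta squared needs F ≥ 0 and positive dfs")
    return F * df1 / (F * df1 + df2)


def rm_anova(cells: np.ndarray, policy: str = "mauchly",
             sphericity_alpha: float = 0.05) -> list[AnovaEffect]:
    """Fit the two-way within-subject ANOVA on a complete balanced table.

    ``policy`` controls when the Huynh–Feldt epsilon rescales dfs for the
    corrected p: 'mauchly' (only when Mauchly's p < sphericity_alpha),
    'always', or 'never'. Printed dfs are always the uncorrected integers.
    """
    if policy not in ("mauchly", "always", "never"):
        raise DesignError(f"unknown sphericity policy {policy!r}")
    cells = _check_cells(cells)
    n, a, b = cells.shape
    ss = _partition(cells)
    spec = {"A": ("A", "AxS", (a - 1), (a - 1) * (n - 1)),
            "B": ("B", "BxS", (b - 1), (b - 1) * (n - 1)),
            "AxB": ("AxB", "AxBxS", (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))}
    out = []
    for effect, (num, err, df1, df2) in spec.items():
        ms_eff = ss[num] / df1
        ms_err = ss[err] / df2
        if ss[num] <= 1e-12 * max(ss["total"], 1.0):  # numerically null effect
            f = 0.0
        elif ms_err <= 0:
            f = float("nan")
        else:
            f = ms_eff / ms_err
        w, sph_p, eps_gg, eps_hf = sphericity(cells, effect)
        p_unc = float(sst.f.sf(f, df1, df2)) if np.isfinite(f) else float("nan")
        apply_eps = (policy == "always"
                     or (policy == "mauchly" and np.isfinite(sph_p)
                         and sph_p < sphericity_alpha))
        if apply_eps and np.isfinite(f):
            p_cor = float(sst.f.sf(f, df1 * eps_hf, df2 * eps_hf))
        else:
            p_cor = p_unc
        eta = (partial_eta_squared(f, df1, df2) if np.isfinite(f)
               else float("nan"))
        out.append(AnovaEffect(effect, f, df1, df2, ss[num], ss[err],
                               eps_gg, eps_hf, w, sph_p, p_unc, p_cor, eta))
    return out


def fisher_lsd(cells: np.ndarray, effect: str = "A") -> pd.DataFrame:
    """Unadjusted pairwise comparisons of the marginal means of one factor.

    Uses the ANOVA error term of that factor: t_ij = (m_i − m_j) /
    sqrt(2·MS_error/n_eff), df = the error term's df, where n_eff is the
    number of observations behind each marginal mean.
    """
    cells = _check_cells(cells)
    n, a, b = cells.shape
    ss = _partition(cells)
    if effect == "A":
        means, ms_err, df_err, n_eff = (cells.mean(axis=(0, 2)),
                                        ss["AxS"] / ((a - 1) * (n - 1)),
                                        (a - 1) * (n - 1), n * b)
    elif effect == "B":
        means, ms_err, df_err, n_eff = (cells.mean(axis=(0, 1)),
                                        ss["BxS"] / ((b - 1) * (n - 1)),
                                        (b - 1) * (n - 1), n * a)
    else:
        raise DesignError("Fisher LSD is defined here for main effects 'A'/'B'")
    if ms_err <= 0:
        raise DesignError("degenerate design: error mean square is zero")
    se = np.sqrt(2.0 * ms_err / n_eff)
    rows = []
    for i in range(len(means)):
        for j in range(len(means)):
            if i == j:
                continue
            diff = means[i] - means[j]
            t = diff / se
            p = 2.0 * float(sst.t.sf(abs(t), df_err))
            rows.append((i + 1, j + 1, diff, t, df_err, p))
    return pd.DataFrame(rows, columns=["level_i", "level_j", "mean_diff",
                                       "t", "df", "p"])


def run_stats_battery(erders_long: pd.DataFrame, policy: str = "mauchly",
                      alpha: float = 0.05, fdr: bool = False
                      ) -> dict[str, pd.DataFrame]:
    """One 4×3 RM-ANOVA per (band, electrode) on subject cell means.

    Trials are first reduced to (subject × type × interval) means (the
    input long table is already at that granularity when produced by the
    map stage). Returns the full effects table, the p < alpha summary in
    the published layout (variable, electrode, dfs, F, p, η²p), and the
    post-hoc LSD tables for significant main effects. Electrodes with
    incomplete designs are skipped and listed under 'skipped'.
    """
    rows, posthoc_rows, skipped = [], [], []
    for (band, channel), sub in erders_long.groupby(["band", "channel"]):
        try:
            cells, _subjects = cells_from_long(sub)
            effects = rm_anova(cells, policy=policy)
        except DesignError as exc:
            skipped.append((band, channel, str(exc)))
            continue
        for eff in effects:
            rows.append((band, channel, eff.label, eff.df1, eff.df2, eff.F,
                         eff.p_uncorrected, eff.p_corrected, eff.epsilon_gg,
                         eff.epsilon_hf, eff.mauchly_w, eff.sphericity_p,
                         eff.eta_p2))
            if (eff.effect in ("A", "B") and np.isfinite(eff.p_corrected)
                    and eff.p_corrected < alpha):
                lsd = fisher_lsd(cells, eff.effect)
                lsd.insert(0, "effect", eff.label)
                lsd.insert(0, "channel", channel)
                lsd.insert(0, "band", band)
                posthoc_rows.append(lsd)
    effects_df = pd.DataFrame(rows, columns=[
        "band", "channel", "effect", "df1", "df2", "F", "p_uncorrected",
        "p", "epsilon_gg", "epsilon_hf", "mauchly_w", "mauchly_p", "eta_p2"])
    if fdr and len(effects_df):
        from scipy.stats import false_discovery_control
        effects_df["p_fdr"] = false_discovery_control(
            effects_df["p"].to_numpy(), method="bh")
    significant = effects_df[effects_df["p"] < alpha][
        ["band", "channel", "effect", "df1", "df2", "F", "p", "eta_p2"]]
    return {
        "effects": effects_df,
        "significant": significant.reset_index(drop=True),
        "posthoc": (pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows
                    else pd.DataFrame(columns=["band", "channel", "effect",
                                               "level_i", "level_j",
                                               "mean_diff", "t", "df", "p"])),
        "skipped": pd.DataFrame(skipped, columns=["band", "channel", "reason"]),
    }
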