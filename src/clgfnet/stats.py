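"""Group statistics: Welch t-tests, Pearson correlations, chi-square.

All tests are two-tailed with alpha fixed at 0.05 and no multiple-testing
correction, matching the analysis surface this package reproduces.  The
two-sample test is Welch's unequal-variance t with Welch-Satterthwaite
degrees of freedom: recomputing the demographic table of the emulated
study from its printed means/SDs reproduces every printed t to two
decimals under Welch, while the pooled-variance form does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "TestResult",
    "welch_t",
    "welch_t_summary",
    "pearson_r",
    "chi2_2x2",
    "group_report",
]

ALPHA = 0.05

#: derived per-subject measures expected by group_report
MEASURES = [
    "beta_power", "gamma_power", "beta_plv", "gamma_plv",
    "switch_duration_ms", "switch_events",
    "n_pos_fb_total", "n_pos_fb_local", "n_pos_fb_global", "n_clgf",
]
PANSS_SCALES = ["panss_positive", "panss_negative", "panss_general", "panss_total"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    family: str  # welch_t | pearson_chi2 | pearson_r
    estimate: float | None = None  # r for correlations

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def welch_t_summary(mean_a: float, sd_a: float, n_a: int,
                    mean_b: float, sd_b: float, n_b: int) -> TestResult:
    """Welch's t from group summary statistics.

    Zero variance in both groups is degenerate: equal means give t = 0
    (p = 1); unequal means give an infinite statistic (p = 0), flagged by
    ``statistic = +/-inf`` rather than an exception.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    diff = mean_a - mean_b
    if va + vb == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(n_a + n_b - 2), 1.0, "welch_t")
        return TestResult(np.copysign(np.inf, diff), float(n_a + n_b - 2),
                          0.0, "welch_t")
    t = diff / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch_t")


def welch_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Welch's t from raw per-subject vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_t_summary(a.mean(), a.std(ddof=1), a.size,
                           b.mean(), b.std(ddof=1), b.size)


def pearson_r(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with the two-tailed p from the t-transform
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must be the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return TestResult(np.copysign(np.inf, r), float(n - 2), 0.0,
                          "pearson_r", estimate=r)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(float(t), float(n - 2), float(p), "pearson_r", estimate=r)


def chi2_2x2(table: np.ndarray) -> TestResult:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return TestResult(chi2, 1.0, float(sps.chi2.sf(chi2, 1)), "pearson_chi2")


def _se(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


def group_report(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    group_col: str = "group",
    groups: tuple[str, str] = ("control", "patient"),
) -> dict:
    """Full statistical surface over a cohort table.

    For every derived measure: per-group mean +/- SE and a two-tailed
    Welch t; plus Pearson correlations of the CLGF count against each
    clinical (PANSS) scale within the patient group.  Raises if a
    requested measure column is missing.
    """
    measures = [m for m in (measures or MEASURES)]
    missing = [m for m in measures if m not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks measure column(s): {missing}")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both groups need at least two subjects")
    out: dict = {"groups": {groups[0]: len(ga), groups[1]: len(gb)},
                 "measures": {}, "correlations": {}}
    for m in measures:
        a, b = ga[m].to_numpy(float), gb[m].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            res = TestResult(0.0, float(len(a) + len(b) - 2), 1.0, "welch_t")
        else:
            res = welch_t(a, b)
        out["measures"][m] = {
            groups[0]: {"mean": float(a.mean()), "se": _se(a)},
            groups[1]: {"mean": float(b.mean()), "se": _se(b)},
            "t": res.statistic, "df": res.df, "p": res.p,
            "significant": res.significant,
        }
    scales = [s for s in PANSS_SCALES if s in table.columns]
    if "n_clgf" in table.columns:
        for s in scales:
            x = gb["n_clgf"].to_numpy(float)
            y = gb[s].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                out["correlations"][s] = {"r": np.nan, "p": np.nan,
                                          "note": "degenerate (constant vector)"}
                continue
            res = pearson_r(x, y)
            out["correlations"][s] = {"r": res.estimate, "p": res.p,
                                      "significant": res.significant}
    return out
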