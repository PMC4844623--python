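"""Group-level statistics: t-tests, Cohen's d with bootstrap CI, RM-ANOVA,
correlations, Bonferroni adjustment, and per-subject learning slopes.

The repeated-measures ANOVA is computed as within-subject *contrast tests*:
for each effect, a normalized contrast over the 3 (training day) x 2
(feedback type) x 2 (regulation direction) cell means yields one score per
subject, and the effect F(1, n-1) is the squared one-sample t statistic of
those scores.  Polynomial (linear/quadratic) contrasts decompose the
three-level training-day factor, so no sphericity correction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

#: polynomial contrasts for the 3-level training-day factor (unit norm)
TD_CONTRASTS = {
    "linear": np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0),
    "quadratic": np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0),
}
#: difference contrast for a 2-level factor (unit norm)
DIFF_CONTRAST = np.array([1.0, -1.0]) / np.sqrt(2.0)

TD_LEVELS = (1, 2, 3)
FEEDBACK_LEVELS = ("CF", "EoBF")
DIRECTION_LEVELS = ("UP", "DOWN")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def t_one_sample(
    x: np.ndarray | list[float], tail: str = "one", mu0: float = 0.0
) -> TTestResult:
    """One-sample t-test of mean(x) against ``mu0``.

    ``tail='one'`` tests the upper-tail alternative mean > mu0 (the
    directional hypotheses UP > DOWN etc.); ``tail='two'`` is two-sided.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance; t statistic undefined")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "greater" if tail == "one" else "two-sided"
    res = sps.ttest_1samp(x, popmean=mu0, alternative=alternative)
    return TTestResult(t=float(res.statistic), df=int(x.size - 1), p=float(res.pvalue))


def cohens_d(x: np.ndarray | list[float]) -> float:
    """Cohen's d for a one-sample design: mean / sample SD (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; Cohen's d undefined")
    return float(x.mean() / sd)


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    n_boot: int


def cohens_d_ci(
    x: np.ndarray | list[float],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> EffectSize:
    """Cohen's d with a percentile bootstrap confidence interval.

    Subjects are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the resampled d values.  Deterministic per seed.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations for a bootstrap CI")
    d = cohens_d(x)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 97]))
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    samples = x[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    good = sds > 0
    boots = means[good] / sds[good]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return EffectSize(d=d, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def _pivot_rm_table(table: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Long-format RM table -> (n_subjects, 3, 2, 2) cell array, complete cases.

    Expected columns: subject, td (1-3), feedback_type (CF/EoBF),
    direction (UP/DOWN), value.
    """
    required = {"subject", "td", "feedback_type", "direction", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"RM table is missing columns: {sorted(missing)}")
    cells = list(product(TD_LEVELS, FEEDBACK_LEVELS, DIRECTION_LEVELS))
    wide = table.pivot_table(
        index="subject",
        columns=["td", "feedback_type", "direction"],
        values="value",
        aggfunc="mean",
    )
    try:
        wide = wide[cells]
    except KeyError as exc:
        raise ValueError(f"RM table lacks cells: {exc}") from exc
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    arr = complete.to_numpy().reshape(len(complete), 3, 2, 2)
    return arr, dropped


@dataclass
class RMAnovaResult:
    """Within-subject contrast tests, one row per effect."""

    effects: pd.DataFrame  # index: effect name; columns: F, df1, df2, p
    n_subjects: int
    dropped_subjects: list

    def effect(self, name: str) -> pd.Series:
        return self.effects.loc[name]


def _contrast_score(cells: np.ndarray, c_td: np.ndarray, c_fb: np.ndarray, c_dir: np.ndarray) -> np.ndarray:
    """Per-subject score: triple tensor contraction of cell means."""
    return np.einsum("stfd,t,f,d->s", cells, c_td, c_fb, c_dir)


def rm_anova_3x2x2(
    table: pd.DataFrame, drop_incomplete: bool = True
) -> RMAnovaResult:
    """3 (TD) x 2 (feedback type) x 2 (direction) repeated-measures ANOVA.

    Long-format input with columns subject, td, feedback_type, direction,
    value; the two CF runs of a day must already be averaged into the CF
    cell.  Each within-subject effect is tested as F(1, n-1) = t^2 of the
    per-subject contrast scores; the TD factor contributes separate linear
    and quadratic rows.  Subjects with incomplete cells are listwise deleted
    (or rejected if ``drop_incomplete`` is False).
    """
    cells, dropped = _pivot_rm_table(table)
    if dropped and not drop_incomplete:
        raise ValueError(f"incomplete RM table rows for subjects: {dropped}")
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete subjects")

    mean_td = np.ones(3) / 3.0
    mean_2 = np.ones(2) / 2.0
    rows = {}

    def add(name: str, c_td: np.ndarray, c_fb: np.ndarray, c_dir: np.ndarray) -> None:
        scores = _contrast_score(cells, c_td, c_fb, c_dir)
        sd = scores.std(ddof=1)
        if sd == 0:
            f = 0.0
            p = 1.0
        else:
            t = scores.mean() / (sd / np.sqrt(n))
            f = float(t**2)
            p = float(sps.f.sf(f, 1, n - 1))
        rows[name] = {"F": f, "df1": 1, "df2": n - 1, "p": p}

    for td_name, c_td in TD_CONTRASTS.items():
        add(f"td_{td_name}", c_td, mean_2, mean_2)
    add("feedback_type", mean_td, DIFF_CONTRAST, mean_2)
    add("direction", mean_td, mean_2, DIFF_CONTRAST)
    for td_name, c_td in TD_CONTRASTS.items():
        add(f"td_{td_name} x feedback_type", c_td, DIFF_CONTRAST, mean_2)
        add(f"td_{td_name} x direction", c_td, mean_2, DIFF_CONTRAST)
    add("feedback_type x direction", mean_td, DIFF_CONTRAST, DIFF_CONTRAST)
    for td_name, c_td in TD_CONTRASTS.items():
        add(f"td_{td_name} x feedback_type x direction", c_td, DIFF_CONTRAST, DIFF_CONTRAST)

    effects = pd.DataFrame.from_dict(rows, orient="index")
    return RMAnovaResult(effects=effects, n_subjects=n, dropped_subjects=dropped)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str


def correlate(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    method: str = "pearson",
    tail: str = "two",
) -> CorrelationResult:
    """Pearson or Spearman correlation with a one- or two-tailed p-value.

    One-tailed tests use the upper-tail alternative r > 0 (test -x for the
    lower tail).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in x or y")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "greater" if tail == "one" else "two-sided"
    if method == "pearson":
        res = sps.pearsonr(x, y, alternative=alternative)
    elif method == "spearman":
        res = sps.spearmanr(x, y, alternative=alternative)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=int(x.size), method=method
    )


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def learning_slope(values: np.ndarray | list[float]) -> float:
    """Least-squares slope of one subject's three session values vs 1..3."""
    y = np.asarray(values, dtype=float)
    if y.size != 3:
        raise ValueError("expected exactly 3 session values")
    if np.any(np.isnan(y)):
        raise ValueError("missing session value; subject must be excluded")
    x = np.array([1.0, 2.0, 3.0])
    return float(np.polyfit(x, y, 1)[0])


def learning_slopes(per_subject: pd.DataFrame) -> pd.Series:
    """Per-subject slopes from a (subject x 3 sessions) table.

    Subjects with any missing session are excluded (listwise) and reported
    via the result's index difference.
    """
    complete = per_subject.dropna()
    return complete.apply(lambda row: learning_slope(row.to_numpy()), axis=1)
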