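"""Scalar statistics: repeated-measures and split-plot ANOVAs with
sphericity handling, paired contrasts with step-down corrections,
within-subject effect sizes, correlation and reliability inference.

Conventions follow standard psychophysics reporting:

* one-way RM-ANOVA with Mauchly's test and the Greenhouse--Geisser
  (GG) epsilon; both the uncorrected and GG-corrected p are always
  reported, with ``p_preferred`` switching to the corrected value when
  Mauchly's test rejects sphericity at .05;
* partial eta squared  eta_p^2 = F * df1 / (F * df1 + df2) on the
  uncorrected degrees of freedom (GG rescales dfs but not F or
  eta_p^2);
* Cohen's d_z = |t| / sqrt(N) for paired contrasts;
* Holm step-down and Bonferroni adjusted p over the declared family;
* Pearson r with two-tailed p from t = r sqrt((n-2)/(1-r^2)) and a 95%
  CI from the Fisher z transform, z +/- 1.96 / sqrt(n-3);
* test--retest reliability as Pearson r across occasions plus the raw
  (covariance-based) two-item Cronbach's alpha
  2 * (1 - (s1^2 + s2^2) / s_total^2).

The ANOVA decompositions are delegated to pingouin; everything else is
scipy / statsmodels with thin result wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "PairedTestResult",
    "CorrelationResult",
    "ReliabilityResult",
    "AccuracyResult",
    "rm_anova_oneway",
    "mixed_anova_2xk",
    "partial_eta_sq",
    "cohens_dz",
    "paired_tests_with_corrections",
    "pearson_with_ci",
    "reliability",
    "accuracy_vs_chance",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: float
    df_error: float
    df_effect_gg: float
    df_error_gg: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float

    @property
    def p_preferred(self) -> float:
        """GG-corrected p when Mauchly's test rejects sphericity."""
        if np.isfinite(self.mauchly_p) and self.mauchly_p < 0.05:
            return self.p_gg
        return self.p_uncorrected

    def to_dict(self) -> dict:
        return {k: (None if v is None or not np.isfinite(v) else float(v))
                for k, v in self.__dict__.items()} | {"p_preferred": float(self.p_preferred)}


@dataclass(frozen=True)
class PairedTestResult:
    name: str
    t: float
    df: int
    p_uncorrected: float
    p_holm: float
    p_bonferroni: float
    cohens_dz: float
    mean_diff: float
    mean_diff_ci95: tuple[float, float]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mean_diff_ci95"] = list(self.mean_diff_ci95)
        return d


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    ci95: tuple[float, float]

    @property
    def df(self) -> int:
        return self.n - 2

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, "df": self.df, "p": self.p, "ci95": list(self.ci95)}


@dataclass(frozen=True)
class ReliabilityResult:
    test_retest_r: float
    cronbach_alpha: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AccuracyResult:
    mean: float
    sem: float
    t: float
    df: int
    p: float
    chance: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return F * df1 / (F * df1 + df2)


def cohens_dz(t: float, n: int) -> float:
    """Within-subject effect size for a paired t: |t| / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return abs(t) / np.sqrt(n)


def _long_format(values: np.ndarray, conditions: Sequence[str]) -> pd.DataFrame:
    n, k = values.shape
    return pd.DataFrame(
        {
            "y": values.ravel(),
            "cond": np.tile(list(conditions), n),
            "subj": np.repeat(np.arange(n), k),
        }
    )


def rm_anova_oneway(
    values: np.ndarray, conditions: Sequence[str] | None = None
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subject x condition
    matrix, with Mauchly's sphericity test and GG correction."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (subjects x conditions)")
    n, k = values.shape
    if k < 2 or n < k:
        raise ValueError("need n >= k >= 2 complete subjects")
    if np.isnan(values).any():
        raise ValueError("missing cells are not supported")
    if conditions is None:
        conditions = [f"c{i}" for i in range(k)]

    # degenerate: no within-subject variation at all -> F defined as 0
    if np.allclose(values, values[:, [0]]):
        eps = 1.0 if k == 2 else 1.0 / (k - 1)
        return AnovaResult(
            F=0.0, df_effect=k - 1, df_error=(k - 1) * (n - 1),
            df_effect_gg=eps * (k - 1), df_error_gg=eps * (k - 1) * (n - 1),
            p_uncorrected=1.0, p_gg=1.0, partial_eta_sq=0.0,
            gg_epsilon=eps, mauchly_w=np.nan, mauchly_p=np.nan,
        )

    df = _long_format(values, conditions)
    res = pg.rm_anova(
        data=df, dv="y", within="cond", subject="subj", correction=True, effsize="np2"
    ).iloc[0]
    eps = 1.0 if k == 2 else float(res["eps"])
    df1, df2 = float(res["ddof1"]), float(res["ddof2"])
    p_gg = float(res["p_GG_corr"]) if "p_GG_corr" in res and np.isfinite(res["p_GG_corr"]) else float(res["p_unc"])
    mauchly_w = float(res["W_spher"]) if "W_spher" in res and np.isfinite(res["W_spher"]) else np.nan
    mauchly_p = float(res["p_spher"]) if "p_spher" in res and np.isfinite(res["p_spher"]) else np.nan
    return AnovaResult(
        F=float(res["F"]),
        df_effect=df1,
        df_error=df2,
        df_effect_gg=eps * df1,
        df_error_gg=eps * df2,
        p_uncorrected=float(res["p_unc"]),
        p_gg=p_gg,
        partial_eta_sq=float(res["np2"]),
        gg_epsilon=eps,
        mauchly_w=mauchly_w,
        mauchly_p=mauchly_p,
    )


def mixed_anova_2xk(values: np.ndarray, groups: Sequence) -> AnovaResult:
    """Split-plot ANOVA: between-subject group x within-subject
    condition; returns the interaction term.

    For two groups of 24 and k = 3 the interaction dfs are (2, 92).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 2 or values.shape[0] != groups.size:
        raise ValueError("values must be (N, k) with one group label per row")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size != 2:
        raise ValueError("exactly two between-subject groups are required")
    if counts.min() < 2:
        raise ValueError("singleton group")
    n, k = values.shape
    df = _long_format(values, [f"c{i}" for i in range(k)])
    df["grp"] = np.repeat(groups.astype(str), k)
    res = pg.mixed_anova(
        data=df, dv="y", within="cond", subject="subj", between="grp", correction=True
    )
    inter = res[res["Source"] == "Interaction"].iloc[0]
    within = res[res["Source"] == "cond"].iloc[0]
    def _get(row, key, default=np.nan):
        val = row.get(key, default)
        return float(val) if np.isfinite(val) else default

    F = _get(inter, "F", 0.0)  # identical cell profiles: no interaction SS
    df1, df2 = float(inter["DF1"]), float(inter["DF2"])
    eps = 1.0 if k == 2 else _get(within, "eps", 1.0)
    p_unc = _get(inter, "p_unc", 1.0)
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if F > 0 else 1.0
    np2 = _get(inter, "np2", 0.0)
    mauchly_w = _get(within, "W_spher")
    mauchly_p = _get(within, "p_spher")
    return AnovaResult(
        F=F,
        df_effect=df1,
        df_error=df2,
        df_effect_gg=eps * df1,
        df_error_gg=eps * df2,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        partial_eta_sq=np2,
        gg_epsilon=eps,
        mauchly_w=mauchly_w,
        mauchly_p=mauchly_p,
    )


def paired_tests_with_corrections(
    values: np.ndarray,
    conditions: Sequence[str],
    comparisons: Sequence[tuple[str, str]],
) -> list[PairedTestResult]:
    """Two-tailed paired t per named condition pair, with Holm and
    Bonferroni adjusted p over the declared family, Cohen's d_z, and a
    95% t-based CI for each mean difference."""
    if len(comparisons) == 0:
        raise ValueError("empty comparison family")
    values = np.asarray(values, dtype=float)
    idx = {c: i for i, c in enumerate(conditions)}
    n = values.shape[0]
    raw: list[tuple[str, float, float, float, float]] = []
    for a, b in comparisons:
        d = values[:, idx[a]] - values[:, idx[b]]
        t, p = stats.ttest_rel(values[:, idx[a]], values[:, idx[b]])
        se = d.std(ddof=1) / np.sqrt(n)
        half = stats.t.ppf(0.975, n - 1) * se
        raw.append((f"{a}-{b}", float(t), float(p), float(d.mean()), float(half)))
    pvals = [r[2] for r in raw]
    p_holm = multipletests(pvals, method="holm")[1]
    p_bonf = multipletests(pvals, method="bonferroni")[1]
    return [
        PairedTestResult(
            name=name,
            t=t,
            df=n - 1,
            p_uncorrected=p,
            p_holm=float(ph),
            p_bonferroni=float(pb),
            cohens_dz=cohens_dz(t, n),
            mean_diff=md,
            mean_diff_ci95=(md - half, md + half),
        )
        for (name, t, p, md, half), ph, pb in zip(raw, p_holm, p_bonf)
    ]


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-tailed p and a Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance")
    n = x.size
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=float(r), n=n, p=float(p), ci95=ci)


def reliability(test1: Sequence[float], test2: Sequence[float]) -> ReliabilityResult:
    """Test--retest Pearson r plus the raw two-occasion Cronbach's alpha
    2 * (1 - (s1^2 + s2^2) / s_total^2); with equal variances this
    reduces to 2r / (1 + r)."""
    a = np.asarray(test1, dtype=float)
    b = np.asarray(test2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    total_var = np.var(a + b, ddof=1)
    if total_var == 0.0:
        raise ValueError("zero total variance")
    r = float(stats.pearsonr(a, b)[0])
    alpha = 2.0 * (1.0 - (np.var(a, ddof=1) + np.var(b, ddof=1)) / total_var)
    return ReliabilityResult(test_retest_r=r, cronbach_alpha=float(alpha))


def accuracy_vs_chance(
    accuracies: Sequence[float], chance: float = 0.5
) -> AccuracyResult:
    """One-sample two-tailed t of per-subject accuracies against chance."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    if acc.std(ddof=1) == 0.0:  # degenerate: all subjects identical
        t = 0.0 if acc[0] == chance else np.sign(acc[0] - chance) * np.inf
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = stats.ttest_1samp(acc, chance)
    return AccuracyResult(
        mean=float(acc.mean()),
        sem=float(acc.std(ddof=1) / np.sqrt(acc.size)),
        t=float(t),
        df=acc.size - 1,
        p=float(p),
        chance=chance,
    )
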