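"""Mixed-model comparison of morphometrics between genotype / age groups.

Cells are not independent: many cells come from each mouse, and mice differ.
All group comparisons therefore use a linear mixed model with a random
intercept per mouse (REML), and report marginal (model-implied) group means.
Two aspects of each metric are tested:

* **mean** — the metric itself, ``metric ~ group + (1 | mouse)``;
* **variance** — a Brown-Forsythe-style dispersion test: each observation is
  replaced by its absolute deviation from the group median and the same
  mixed model is fit to the deviations.  A shift in mean absolute deviation
  is a shift in spread, robustly to non-normality.

Because every metric is assessed twice (raw values and residuals), a
Bonferroni-Dunn factor-2 correction is applied within each metric x contrast
family.  Pairwise contrasts across more than two groups use the studentized
range (Tukey) distribution for family-wise control.

Inference is by the containment (between-mouse) convention: the contrast
standard error and degrees of freedom come from the spread of per-mouse
means around their group means (df = total mice minus the number of
fixed-effect parameters), while the reported effect estimate is the REML
marginal-mean difference.  With a handful of animals per group, cell-level
Wald inference would be badly anti-conservative — in particular for the
dispersion test, where the between-mouse variance of folded residuals is a
small fraction of the cell-level variance and the REML estimate collapses to
the boundary at zero, hiding the mouse-level correlation entirely.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

__all__ = [
    "ComparisonResult",
    "TrendResult",
    "fit_mean_comparison",
    "fit_variance_comparison",
    "bonferroni_dunn_adjust",
    "tukey_pairwise",
    "age_trend",
    "normality_diagnostics",
    "compare_metrics",
]


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison of one metric."""

    metric: str
    group_a: str
    group_b: str
    kind: str                     # "mean" or "variance"
    estimate: float               # marginal-mean difference (b - a)
    se: float
    p: float
    p_adjusted: float = float("nan")
    df: float = float("nan")
    n_cells: tuple[int, int] = (0, 0)
    n_mice: tuple[int, int] = (0, 0)
    converged: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_cells_a"], d["n_cells_b"] = d.pop("n_cells")
        d["n_mice_a"], d["n_mice_b"] = d.pop("n_mice")
        return d


@dataclass
class TrendResult:
    """OLS slope of a per-group summary against age."""

    metric: str
    genotype: str
    slope: float
    ci_low: float
    ci_high: float
    direction: str                # "increasing", "decreasing" or "none"


def _group_key(df: pd.DataFrame, group_cols: Sequence[str]) -> pd.Series:
    key = df[group_cols[0]].astype(str)
    for c in group_cols[1:]:
        key = key + "/" + df[c].astype(str)
    return key


def _fit_mixed(y: np.ndarray, dummies: np.ndarray, mouse: np.ndarray):
    """Random-intercept REML fit; returns (params, cov, n_mice, converged).

    The response is standardized before optimization (the default optimizer
    is unreliable on poorly scaled data) and estimates are mapped back to the
    original scale.  A Nelder-Mead refit backs up the quasi-Newton fit when
    the fixed effects disagree grossly with their OLS counterpart (a cheap
    sanity check: in these balanced designs the GLS and OLS group contrasts
    coincide).
    """
    exog = np.column_stack([np.ones_like(y), dummies])
    loc, scale = float(np.mean(y)), float(np.std(y))
    if scale == 0:
        scale = 1.0
    z = (y - loc) / scale
    ols_beta = np.linalg.lstsq(exog, z, rcond=None)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(z, exog, groups=mouse)
        try:
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=True, method="nm")
            converged = bool(fit.converged)
        k = exog.shape[1]
        if np.abs(np.asarray(fit.params)[:k] - ols_beta).max() > 0.1:
            fit = model.fit(reml=True, method="nm")
            converged = bool(fit.converged)
    if float(np.asarray(fit.cov_re).ravel()[0]) <= 1e-10:
        warnings.warn(
            "mouse-level variance estimated at 0 (singular fit); "
            "contrast df still uses the between-mouse containment rule",
            stacklevel=3,
        )
    params = np.asarray(fit.params)[:k] * scale
    params[0] += loc
    cov = np.asarray(fit.cov_params())[:k, :k] * scale**2
    return params, cov, len(np.unique(mouse)), converged


def _two_group_fit(
    data: pd.DataFrame, metric: str, group_col: str, mouse_col: str, kind: str
) -> ComparisonResult:
    df = data.dropna(subset=[metric])
    levels = sorted(df[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a, b = levels
    if df.groupby(mouse_col)[group_col].nunique().max() > 1:
        raise ValueError("a mouse appears in more than one group")
    n_mice_per = df.groupby(group_col)[mouse_col].nunique()
    if n_mice_per.min() < 2:
        raise ValueError("need >= 2 mice per group")
    y = df[metric].to_numpy(dtype=float)
    dummy = (df[group_col].astype(str) == b).to_numpy(dtype=float)[:, None]
    params, cov, n_mice, converged = _fit_mixed(y, dummy, df[mouse_col].to_numpy())
    est = float(params[1])
    # containment inference: SE and df from the spread of per-mouse means
    mouse_means = df.groupby([group_col, mouse_col], observed=True)[metric].mean()
    ss = 0.0
    inv_m = 0.0
    for g in (a, b):
        mm = mouse_means.loc[g]
        ss += float(((mm - mm.mean()) ** 2).sum())
        inv_m += 1.0 / len(mm)
    dof = n_mice - 2
    sp2 = ss / dof
    se = float(np.sqrt(sp2 * inv_m))
    if se > 0:
        p = float(2.0 * sps.t.sf(abs(est) / se, dof))
    elif abs(est) <= 1e-10:
        # perfectly identical groups: no between-mouse spread, no evidence
        est, p = 0.0, 1.0
    else:
        p = 0.0
    counts = df.groupby(group_col)[metric].size()
    return ComparisonResult(
        metric=metric,
        group_a=a,
        group_b=b,
        kind=kind,
        estimate=est,
        se=se,
        p=p,
        df=dof,
        n_cells=(int(counts[a]), int(counts[b])),
        n_mice=(int(n_mice_per[a]), int(n_mice_per[b])),
        converged=converged,
    )


def fit_mean_comparison(
    data: pd.DataFrame,
    metric: str,
    group_col: str = "genotype",
    mouse_col: str = "mouse",
) -> ComparisonResult:
    """Mixed-model test for a group difference in the mean of ``metric``.

    Fits ``metric ~ group`` with a random intercept per mouse by REML and
    reports the marginal-mean difference (second group minus first, groups in
    sorted order), its standard error, and a t-based p-value with
    between-mouse degrees of freedom.
    """
    return _two_group_fit(data, metric, group_col, mouse_col, kind="mean")


def fit_variance_comparison(
    data: pd.DataFrame,
    metric: str,
    group_col: str = "genotype",
    mouse_col: str = "mouse",
    center: str = "group_median",
    absolute: bool = True,
) -> ComparisonResult:
    """Mixed-model test for a group difference in the *spread* of ``metric``.

    Each observation is transformed to its (absolute, by default) deviation
    from the group median — ``center="global"`` uses the overall median
    instead — and :func:`fit_mean_comparison` is applied to the deviations.
    The estimate is the difference in mean absolute deviation between groups.
    Signed deviations (``absolute=False``) test location, not spread, and are
    provided only for diagnostic use.
    """
    df = data.dropna(subset=[metric]).copy()
    if center == "group_median":
        med = df.groupby(group_col)[metric].transform("median")
    elif center == "global":
        med = df[metric].median()
    else:
        raise ValueError("center must be 'group_median' or 'global'")
    resid = df[metric] - med
    df[metric] = resid.abs() if absolute else resid
    return _two_group_fit(df, metric, group_col, mouse_col, kind="variance")


def bonferroni_dunn_adjust(results: Iterable[ComparisonResult]) -> list[ComparisonResult]:
    """Multiply each p-value by 2 (mean + variance assessments), capped at 1.

    Every metric x contrast is assessed twice — once on the raw values and
    once on the residuals from the median — so the family size is 2.
    """
    out = []
    for r in results:
        r.p_adjusted = min(1.0, 2.0 * r.p)
        out.append(r)
    return out


def tukey_pairwise(
    data: pd.DataFrame,
    metric: str,
    group_cols: Sequence[str] = ("genotype", "age"),
    mouse_col: str = "mouse",
) -> list[ComparisonResult]:
    """All pairwise marginal-mean contrasts with Tukey family-wise adjustment.

    Fits one joint mixed model over all genotype x age cells (random
    intercept per mouse) and compares every pair of groups with the
    studentized-range distribution (q = sqrt(2) |t|, k groups, between-mouse
    df).  With two groups this reduces exactly to the single unadjusted
    contrast.
    """
    df = data.dropna(subset=[metric]).copy()
    df["_group"] = _group_key(df, list(group_cols))
    levels = sorted(df["_group"].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    y = df[metric].to_numpy(dtype=float)
    dummies = np.column_stack(
        [(df["_group"] == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )
    params, cov, n_mice, converged = _fit_mixed(y, dummies, df[mouse_col].to_numpy())
    dof = n_mice - k
    # group means: intercept + dummy coefficient (0 for reference level)
    coef = np.concatenate([[0.0], params[1:]])
    counts = df.groupby("_group")[metric].size()
    mice = df.groupby("_group")[mouse_col].nunique()
    # containment inference: pooled between-mouse variance within groups
    mouse_means = df.groupby(["_group", mouse_col], observed=True)[metric].mean()
    ss = sum(
        float(((mouse_means.loc[g] - mouse_means.loc[g].mean()) ** 2).sum())
        for g in levels
    )
    sp2 = ss / dof if dof > 0 else float("nan")
    out = []
    for i, j in itertools.combinations(range(k), 2):
        est = float(coef[j] - coef[i])
        se = float(np.sqrt(sp2 * (1.0 / mice[levels[i]] + 1.0 / mice[levels[j]])))
        if not np.isfinite(se) or se == 0:
            p = 1.0 if abs(est) <= 1e-10 else 0.0
        elif k == 2:
            p = float(2.0 * sps.t.sf(abs(est) / se, dof))
        else:
            q = abs(est) / se * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, dof))
        out.append(
            ComparisonResult(
                metric=metric,
                group_a=levels[i],
                group_b=levels[j],
                kind="mean",
                estimate=est,
                se=se,
                p=min(p, 1.0),
                df=dof,
                n_cells=(int(counts[levels[i]]), int(counts[levels[j]])),
                n_mice=(int(mice[levels[i]]), int(mice[levels[j]])),
                converged=converged,
            )
        )
    return out


def age_trend(
    summaries: pd.DataFrame,
    metric: str,
    genotype: str | None = None,
    age_col: str = "age",
    alpha: float = 0.05,
) -> TrendResult:
    """OLS slope of a per-mouse (or per-group) summary against age.

    ``summaries`` has one row per mouse or group with columns ``age`` and
    ``metric``.  The slope's normal-approximation CI at level ``alpha``
    determines the direction: the sign of the slope when the CI excludes 0,
    otherwise "none".
    """
    df = summaries.dropna(subset=[metric])
    if genotype is not None:
        df = df[df["genotype"] == genotype]
    ages = df[age_col].to_numpy(dtype=float)
    if len(np.unique(ages)) < 3:
        raise ValueError("need >= 3 distinct ages for a trend")
    y = df[metric].to_numpy(dtype=float)
    X = sm.add_constant(ages)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = slope - z * se, slope + z * se
    if lo > 0:
        direction = "increasing"
    elif hi < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendResult(
        metric=metric,
        genotype=genotype if genotype is not None else "all",
        slope=slope,
        ci_low=lo,
        ci_high=hi,
        direction=direction,
    )


def normality_diagnostics(
    data: pd.DataFrame,
    metric: str,
    group_cols: Sequence[str] = ("genotype", "age"),
) -> pd.DataFrame:
    """Per-group skewness, excess kurtosis and normal q-q pairs.

    Returns one row per group with columns ``n``, ``skewness``, ``kurtosis``,
    ``small_sample`` (flagged below n = 8, where the moment estimates are
    unreliable) and ``qq`` (an (n, 2) array of theoretical vs. sample
    quantiles, ready for plotting).
    """
    rows = []
    df = data.dropna(subset=[metric]).copy()
    df["_group"] = _group_key(df, list(group_cols))
    for group, sub in df.groupby("_group"):
        x = np.sort(sub[metric].to_numpy(dtype=float))
        n = len(x)
        if n < 8:
            warnings.warn(f"group {group}: n={n} < 8, moment estimates unreliable", stacklevel=2)
        probs = (np.arange(1, n + 1) - 0.5) / n  # Hazen plotting positions
        rows.append(
            {
                "group": group,
                "n": n,
                "skewness": float(sps.skew(x)) if n > 2 else float("nan"),
                "kurtosis": float(sps.kurtosis(x)) if n > 3 else float("nan"),
                "small_sample": n < 8,
                "qq": np.column_stack([sps.norm.ppf(probs), x]),
            }
        )
    return pd.DataFrame(rows)


def compare_metrics(
    data: pd.DataFrame,
    metrics: Sequence[str],
    group_col: str = "genotype",
    mouse_col: str = "mouse",
    age_col: str = "age",
    per_age: bool = True,
) -> pd.DataFrame:
    """Run the full mean + variance comparison battery over several metrics.

    By default comparisons are made separately at each age (matching a
    per-timepoint star convention), with the Bonferroni-Dunn factor-2
    adjustment within each metric x age family.  Returns a tidy frame with
    significance markers: ``*`` for an adjusted mean difference at alpha
    0.05, ``#`` for an adjusted variance difference.
    """
    rows = []
    if per_age and age_col in data.columns:
        age_groups = [(a, d) for a, d in data.groupby(age_col)]
    else:
        age_groups = [(float("nan"), data)]
    for age, sub in age_groups:
        for metric in metrics:
            mean_r = fit_mean_comparison(sub, metric, group_col, mouse_col)
            var_r = fit_variance_comparison(sub, metric, group_col, mouse_col)
            bonferroni_dunn_adjust([mean_r, var_r])
            marker = ""
            if mean_r.p_adjusted <= 0.05:
                marker += "*"
            if var_r.p_adjusted <= 0.05:
                marker += "#"
            for r in (mean_r, var_r):
                d = r.to_dict()
                d["age"] = age
                d["significance"] = marker
                rows.append(d)
    return pd.DataFrame(rows)
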