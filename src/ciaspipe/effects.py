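"""Treatment-effect estimation on composite change scores.

ANCOVA (change ~ arm + age + sex + site + baseline composite) with
least-squares means, between-arm contrasts and model-derived Cohen's d
(estimate / sqrt(residual MSE)); one-way ANOVA / chi-squared baseline
comparisons; and simple linear regression of cognitive change on symptom
change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientSampleError,
    SchemaError,
    ZeroVarianceError,
)

ARM_LEVELS = ("active", "placebo")  # placebo is the reference arm
DEFAULT_COVARIATES = ("age", "sex", "site", "baseline_composite")


# ---------------------------------------------------------------------------
# change scores


def compute_changes(scored: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """One row per patient with composite and symptom change scores.

    Positive composite change = improvement; negative symptom change =
    improvement.  Patients missing either endpoint are returned separately
    (second element), never silently dropped.
    """
    base = scored[scored["visit"] == "baseline"].set_index("patient_id")
    week5 = scored[scored["visit"] == "week5"].set_index("patient_id")
    ids = base.index.intersection(week5.index)
    wide = pd.DataFrame(
        {
            "patient_id": ids,
            "arm": base.loc[ids, "arm"].to_numpy(),
            "site": base.loc[ids, "site"].to_numpy(),
            "age": base.loc[ids, "age"].to_numpy(),
            "sex": base.loc[ids, "sex"].to_numpy(),
            "baseline_composite": base.loc[ids, "composite"].to_numpy(),
            "baseline_panss": base.loc[ids, "panss_total"].to_numpy(),
            "d_composite": (
                week5.loc[ids, "composite"].to_numpy()
                - base.loc[ids, "composite"].to_numpy()
            ),
            "d_panss": (
                week5.loc[ids, "panss_total"].to_numpy()
                - base.loc[ids, "panss_total"].to_numpy()
            ),
        }
    ).reset_index(drop=True)
    missing_visit = sorted(set(base.index).symmetric_difference(week5.index))
    incomplete = wide["d_composite"].isna() | wide["d_panss"].isna()
    routed = tuple(missing_visit) + tuple(wide.loc[incomplete, "patient_id"])
    return wide.loc[~incomplete].reset_index(drop=True), routed


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass(frozen=True)
class AncovaFit:
    """A fitted change-score model with the metadata LS means need."""

    params: pd.Series
    cov_params: pd.DataFrame
    mse: float
    df_resid: float
    n_by_arm: Mapping[str, int]
    covariate_means: Mapping[str, float]
    sex_levels: tuple[str, ...]  # reference level first
    site_levels: tuple[str, ...]
    level_weights: Mapping[str, Mapping[str, float]]  # observed proportions
    columns: tuple[str, ...]


def _ordered_levels(series: pd.Series) -> tuple[str, ...]:
    """Observed levels, most frequent first (ties broken by name).

    The most frequent level becomes the reference under treatment coding.
    """
    counts = series.value_counts()
    return tuple(sorted(counts.index, key=lambda lv: (-counts[lv], lv)))


def _build_design(
    data: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, dict]:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["arm"] = (data["arm"] == "active").astype(float)
    meta: dict = {"sex_levels": (), "site_levels": (), "covariate_means": {}, "level_weights": {}}
    for cov in covariates:
        if cov in ("age", "baseline_composite"):
            X[cov] = data[cov].astype(float)
            meta["covariate_means"][cov] = float(data[cov].mean())
        elif cov in ("sex", "site"):
            levels = _ordered_levels(data[cov])
            meta[f"{cov}_levels"] = levels
            n = len(data)
            meta["level_weights"][cov] = {
                lv: float((data[cov] == lv).sum()) / n for lv in levels
            }
            for lv in levels[1:]:
                X[f"{cov}[{lv}]"] = (data[cov] == lv).astype(float)
        else:
            raise SchemaError(f"unknown covariate {cov!r}")
    return X, meta


def fit_ancova(
    data: pd.DataFrame,
    response: str = "d_composite",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AncovaFit:
    """OLS of the change score on arm plus the configured covariates.

    Categorical covariates use treatment (reference) coding with the most
    frequent level as reference; the arm indicator is active=1 so its
    coefficient is the active-minus-placebo adjusted difference.
    """
    n_by_arm = {arm: int((data["arm"] == arm).sum()) for arm in ARM_LEVELS}
    for arm, n_arm in n_by_arm.items():
        if n_arm < 2:
            raise InsufficientSampleError(f"need >= 2 patients in arm {arm!r}, got {n_arm}")
    if data[list({response, "arm", *covariates})].isna().any().any():
        raise SchemaError("response/covariates contain missing values")

    X, meta = _build_design(data, covariates)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(Xv, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        bad += [X.columns[j] for j in piv[Xv.shape[1]:]]
        raise DegenerateDesignError(f"design matrix rank deficient; collinear columns: {bad}")

    fit = sm.OLS(data[response].to_numpy(dtype=float), X).fit()
    return AncovaFit(
        params=fit.params,
        cov_params=fit.cov_params(),
        mse=float(fit.mse_resid),
        df_resid=float(fit.df_resid),
        n_by_arm=n_by_arm,
        covariate_means=meta["covariate_means"],
        sex_levels=meta["sex_levels"],
        site_levels=meta["site_levels"],
        level_weights=meta["level_weights"],
        columns=tuple(X.columns),
    )


# ---------------------------------------------------------------------------
# LS means and effect estimates


@dataclass(frozen=True)
class Effect:
    """One estimated quantity (an LS mean or a contrast) with its tests."""

    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    t: float
    p: float
    cohen_d: float
    n: int | None = None


@dataclass(frozen=True)
class EffectEstimate:
    arms: Mapping[str, Effect]  # per-arm LS mean change from baseline
    contrast: Effect  # active - placebo


def _lsmean_contrast(fit: AncovaFit, arm: str, weighting: str) -> np.ndarray:
    """Contrast vector for one arm's LS mean: continuous covariates at their
    overall means, categorical covariates averaged over observed levels
    (equal weights by default, observed proportions behind config)."""
    c = np.zeros(len(fit.columns))
    cols = {name: i for i, name in enumerate(fit.columns)}
    c[cols["const"]] = 1.0
    c[cols["arm"]] = 1.0 if arm == "active" else 0.0
    for cov, mean in fit.covariate_means.items():
        c[cols[cov]] = mean
    for cov, levels in (("sex", fit.sex_levels), ("site", fit.site_levels)):
        for lv in levels[1:]:
            if weighting == "equal":
                c[cols[f"{cov}[{lv}]"]] = 1.0 / len(levels)
            elif weighting == "observed":
                c[cols[f"{cov}[{lv}]"]] = fit.level_weights[cov][lv]
            else:
                raise SchemaError(f"unknown LS-means weighting {weighting!r}")
    return c


def _effect_from_contrast(
    fit: AncovaFit, c: np.ndarray, alpha: float, n: int | None
) -> Effect:
    est = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov_params.to_numpy() @ c))
    t = est / se if se > 0 else np.nan
    p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    return Effect(
        estimate=est,
        se=se,
        ci_lo=est - tcrit * se,
        ci_hi=est + tcrit * se,
        t=float(t),
        p=p,
        cohen_d=est / np.sqrt(fit.mse),
        n=n,
    )


def estimate_effects(
    fit: AncovaFit, alpha: float = 0.05, weighting: str = "equal"
) -> EffectEstimate:
    """LS mean change per arm (tested against 0), the active-minus-placebo
    contrast, and model-derived Cohen's d = estimate / sqrt(MSE)."""
    contrasts = {arm: _lsmean_contrast(fit, arm, weighting) for arm in ARM_LEVELS}
    arms = {
        arm: _effect_from_contrast(fit, c, alpha, fit.n_by_arm[arm])
        for arm, c in contrasts.items()
    }
    diff = contrasts["active"] - contrasts["placebo"]
    contrast = _effect_from_contrast(fit, diff, alpha, None)
    return EffectEstimate(arms=arms, contrast=contrast)


def effects_to_frame(est: EffectEstimate) -> pd.DataFrame:
    rows = []
    for label, eff in (("active", est.arms["active"]), ("placebo", est.arms["placebo"]), ("active vs placebo", est.contrast)):
        rows.append(
            {
                "treatment": label,
                "n": eff.n,
                "estimate": eff.estimate,
                "se": eff.se,
                "ci_lo": eff.ci_lo,
                "ci_hi": eff.ci_hi,
                "t": eff.t,
                "p": eff.p,
                "cohen_d": eff.cohen_d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline comparisons


def continuous_test(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p; identical groups give F = 0, p = 1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays)
    means = np.array([a.mean() for a in arrays])
    if np.allclose(means, grand.mean()):
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def categorical_test(table: np.ndarray) -> tuple[float, float]:
    """Chi-squared homogeneity test; Yates continuity correction for 2x2."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise InsufficientSampleError("empty contingency table")
    correction = table.shape == (2, 2)
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


@dataclass(frozen=True)
class BaselineComparison:
    characteristic: str
    kind: str  # "continuous" | "categorical"
    summaries: Mapping[str, str]
    statistic: float
    p: float


def baseline_comparisons(
    data: pd.DataFrame,
    group_col: str,
    characteristics: Sequence[tuple[str, str]],
    positive_level: str | None = None,
) -> list[BaselineComparison]:
    """Compare groups characteristic by characteristic.

    ``characteristics`` is a sequence of (column, kind) pairs; kind alone
    decides the test.  Categorical levels observed in only one group are
    retained as zero cells.
    """
    group_levels = _ordered_levels(data[group_col])
    if len(group_levels) < 2:
        raise InsufficientSampleError("need at least two groups to compare")
    out = []
    for col, kind in characteristics:
        if kind == "continuous":
            groups = [
                data.loc[data[group_col] == g, col].dropna().to_numpy()
                for g in group_levels
            ]
            stat, p = continuous_test(groups)
            summaries = {
                g: (
                    f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
                    if len(vals) > 1
                    else f"{vals.mean():.2f} (--)" if len(vals) else "--"
                )
                for g, vals in zip(group_levels, groups)
            }
        elif kind == "categorical":
            table = pd.crosstab(data[group_col], data[col])
            table = table.reindex(group_levels)
            stat, p = categorical_test(table.to_numpy())
            summaries = {}
            for g in group_levels:
                row = table.loc[g]
                if positive_level is not None and positive_level in row.index:
                    n_pos, n_tot = int(row[positive_level]), int(row.sum())
                    summaries[g] = f"{n_pos} ({100.0 * n_pos / n_tot:.1f}%)"
                else:
                    summaries[g] = "/".join(f"{int(v)}" for v in row)
        else:
            raise SchemaError(f"unknown characteristic kind {kind!r}")
        out.append(
            BaselineComparison(
                characteristic=col, kind=kind, summaries=summaries, statistic=stat, p=p
            )
        )
    return out


def comparisons_to_frame(comps: Iterable[BaselineComparison]) -> pd.DataFrame:
    rows = []
    for c in comps:
        row = {"characteristic": c.characteristic, "kind": c.kind}
        row.update(c.summaries)
        row["statistic"] = c.statistic
        row["p"] = c.p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple linear regression


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    std_beta: float
    r2: float
    adj_r2: float
    t: float
    p: float
    n: int


def regress_change(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple OLS of ``y`` on ``x`` with standardised beta and adjusted R^2.

    std_beta = slope * SD(x) / SD(y); adj R^2 = 1 - (1 - R^2)(n-1)/(n-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise SchemaError("x and y must be paired")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise InsufficientSampleError(f"regression needs n >= 3 pairs, got {n}")
    if np.std(x) == 0:
        raise ZeroVarianceError("predictor has zero variance: slope undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    sy = np.std(y, ddof=1)
    std_beta = res.slope * np.std(x, ddof=1) / sy if sy > 0 else np.nan
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        std_beta=float(std_beta),
        r2=float(r2),
        adj_r2=float(1.0 - (1.0 - r2) * (n - 1) / (n - 2)),
        t=float(t),
        p=float(res.pvalue),
        n=n,
    )
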