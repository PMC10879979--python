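"""Cross-sectional analyses: group comparisons, feature→PRO regressions,
and MS-diagnosis moderation.

Three analyses of the pandemic-period data:

* :func:`compare_groups` — per-feature comparison of pwMS vs controls with
  Welch's two-sample t test and a Bonferroni significance flag (family of
  18 features);
* :func:`feature_outcome_regression` — ordinary least squares of a PRO on
  one network feature plus covariates (pwMS models adjust age, disease
  duration, employment, income; control models drop disease duration);
* :func:`moderation_analysis` — joint pwMS+control OLS with an MS ×
  feature interaction; simple slopes per group are derived from the
  coefficients.

Percent-type features enter regressions as 0–1 proportions (see
:func:`persnet.network_metrics.to_regression_scale`), so a coefficient is
the outcome change from a network with none to all members having the
attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from persnet.codebook import Codebook
from persnet.cohort_io import encode_covariates
from persnet.network_metrics import FEATURE_NAMES, features_table, to_regression_scale
from persnet.records import CohortTable

#: Covariates selected by the screening rule, per study arm.
PWMS_COVARIATES = ("age", "disease_duration", "employed", "income")
CONTROL_COVARIATES = ("age", "employed", "income")
OUTCOMES = ("pdds", "msrs_r", "promis_pf")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m for a family of m comparisons."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def printed_threshold(alpha: float, m: int, decimals: int = 5) -> float:
    """The threshold as printed in report footnotes (truncated)."""
    t = bonferroni_threshold(alpha, m)
    factor = 10**decimals
    return math.floor(t * factor) / factor


@dataclass
class GroupComparison:
    feature: str
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    t: float
    p: float
    significant: bool
    m: int  # Bonferroni family size recorded with the flag
    note: str = ""


@dataclass
class AssociationResult:
    feature: str
    outcome: str
    n: int
    beta: float
    ci_low: float
    ci_high: float
    p: float
    covariates: tuple[str, ...] = ()


@dataclass
class ModerationResult:
    feature: str
    outcome: str
    n: int
    interaction_beta: float
    interaction_ci: tuple[float, float]
    interaction_p: float
    slope_pwms: float
    slope_pwms_ci: tuple[float, float]
    slope_pwms_p: float
    slope_control: float
    slope_control_ci: tuple[float, float]
    slope_control_p: float
    percentile_anchors: tuple[float, float, float] = (math.nan,) * 3
    covariates: tuple[str, ...] = ()


def build_analysis_table(
    cohort: CohortTable, codebook: Codebook | None = None
) -> pd.DataFrame:
    """Merged per-entry table of regression-scale features, covariates, PROs."""
    feats = to_regression_scale(features_table(cohort, codebook))
    covs = encode_covariates(cohort, codebook)
    return feats.merge(
        covs.drop(columns=["group"]), on=["participant_id", "timepoint"], how="inner"
    )


def compare_groups(
    features: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("pwMS", "control"),
    feature_names: Sequence[str] = FEATURE_NAMES,
    alpha: float = 0.05,
    m: Optional[int] = None,
) -> list[GroupComparison]:
    """Welch two-sample t test per feature with a Bonferroni family flag.

    ``m`` defaults to the number of features tested.  Features with zero
    variance in both groups get an undefined t and are flagged in ``note``.
    """
    m = m if m is not None else len(feature_names)
    threshold = bonferroni_threshold(alpha, m)
    out = []
    for feat in feature_names:
        x1 = features.loc[features[group_col] == groups[0], feat].dropna()
        x2 = features.loc[features[group_col] == groups[1], feat].dropna()
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError(f"{feat}: need >=2 non-missing values per group")
        note = ""
        if x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0:
            if x1.mean() == x2.mean():
                t, p = 0.0, 1.0
                note = "zero variance in both groups; identical means"
            else:
                t, p = math.nan, math.nan
                note = "zero variance in both groups; t undefined"
        else:
            t, p = stats.ttest_ind(x1, x2, equal_var=False)
        out.append(
            GroupComparison(
                feature=feat,
                mean_1=float(x1.mean()),
                sd_1=float(x1.std(ddof=1)),
                n_1=len(x1),
                mean_2=float(x2.mean()),
                sd_2=float(x2.std(ddof=1)),
                n_2=len(x2),
                t=float(t),
                p=float(p),
                significant=bool(p < threshold) if not math.isnan(p) else False,
                m=m,
                note=note,
            )
        )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns implicated by near-zero R diagonal in a pivoted QR
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _fit_ols(y: pd.Series, X: pd.DataFrame):
    _check_full_rank(X)
    return sm.OLS(np.asarray(y, dtype=float), np.asarray(X, dtype=float)).fit()


def feature_outcome_regression(
    data: pd.DataFrame,
    feature: str,
    outcome: str,
    covariates: Sequence[str] = PWMS_COVARIATES,
) -> AssociationResult:
    """OLS of ``outcome`` on ``feature`` + covariates over complete cases.

    ``data`` is an analysis table (see :func:`build_analysis_table`) with
    features already on regression (0–1) scale.  Returns the feature
    coefficient with a 95% Wald CI and p-value.
    """
    cols = [feature, outcome, *covariates]
    cc = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(cc)
    if n < len(covariates) + 2 + 5:
        raise ValueError(
            f"{feature}->{outcome}: only {n} complete cases for "
            f"{len(covariates) + 2} parameters"
        )
    X = sm.add_constant(cc[[feature, *covariates]])
    res = _fit_ols(cc[outcome], X)
    ci = res.conf_int(alpha=0.05)
    return AssociationResult(
        feature=feature,
        outcome=outcome,
        n=n,
        beta=float(res.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p=float(res.pvalues[1]),
        covariates=tuple(covariates),
    )


def regression_battery(
    data: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    covariates: Sequence[str] = PWMS_COVARIATES,
    feature_names: Sequence[str] = FEATURE_NAMES,
    alpha: float = 0.05,
    m: Optional[int] = None,
) -> pd.DataFrame:
    """One covariate-adjusted regression per (feature, outcome) pair.

    The report mirrors the cross-sectional association table: 18 features ×
    3 PROs with per-cell complete-case n, coefficient, 95% CI, p, and a
    Bonferroni flag for the full family (m defaults to features×outcomes).
    """
    m = m if m is not None else len(feature_names) * len(outcomes)
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for feat in feature_names:
        for out in outcomes:
            r = feature_outcome_regression(data, feat, out, covariates)
            rows.append(
                {
                    "feature": feat,
                    "outcome": out,
                    "n": r.n,
                    "beta": r.beta,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                    "significant": r.p < threshold,
                    "m": m,
                }
            )
    return pd.DataFrame(rows)


def moderation_analysis(
    data: pd.DataFrame,
    feature: str,
    outcome: str = "promis_pf",
    covariates: Sequence[str] = CONTROL_COVARIATES,
    group_col: str = "group",
) -> ModerationResult:
    """Does an MS diagnosis moderate the feature→outcome association?

    Joint OLS over pwMS and controls with an ``MS × feature`` interaction.
    Controls are the reference group, so the control simple slope is the
    feature main effect and the pwMS slope is main + interaction (its CI
    from the coefficient covariance).  The feature's 25th/50th/75th
    percentiles are reported as display anchors.
    """
    present = set(data[group_col].dropna().unique())
    if not {"pwMS", "control"} <= present:
        raise ValueError(f"moderation needs both groups, got {sorted(present)}")
    cols = [feature, outcome, *covariates]
    df = data[[group_col, *cols]].copy()
    df[cols] = df[cols].apply(pd.to_numeric, errors="coerce")
    df = df.dropna()
    df["ms"] = (df[group_col] == "pwMS").astype(float)
    df["feat_x_ms"] = df[feature] * df["ms"]
    for g in (0.0, 1.0):
        if df.loc[df["ms"] == g, feature].nunique() < 2:
            raise ValueError(f"{feature} is constant within one group")
    X = sm.add_constant(df[[feature, "ms", "feat_x_ms", *covariates]])
    res = _fit_ols(df[outcome], X)
    names = list(X.columns)
    i_f, i_i = names.index(feature), names.index("feat_x_ms")
    cov = res.cov_params()
    tcrit = stats.t.ppf(0.975, res.df_resid)

    def lincomb(weights: np.ndarray):
        est = float(weights @ res.params)
        se = float(np.sqrt(weights @ cov @ weights))
        t = est / se
        p = 2 * stats.t.sf(abs(t), res.df_resid)
        return est, (est - tcrit * se, est + tcrit * se), float(p)

    w_ctl = np.zeros(len(names))
    w_ctl[i_f] = 1.0
    w_pwms = w_ctl.copy()
    w_pwms[i_i] = 1.0
    slope_c, ci_c, p_c = lincomb(w_ctl)
    slope_m, ci_m, p_m = lincomb(w_pwms)
    ci_int = res.conf_int(alpha=0.05)
    anchors = tuple(float(q) for q in df[feature].quantile([0.25, 0.5, 0.75]))
    return ModerationResult(
        feature=feature,
        outcome=outcome,
        n=len(df),
        interaction_beta=float(res.params[i_i]),
        interaction_ci=(float(ci_int[i_i, 0]), float(ci_int[i_i, 1])),
        interaction_p=float(res.pvalues[i_i]),
        slope_pwms=slope_m,
        slope_pwms_ci=ci_m,
        slope_pwms_p=p_m,
        slope_control=slope_c,
        slope_control_ci=ci_c,
        slope_control_p=p_c,
        percentile_anchors=anchors,
        covariates=tuple(covariates),
    )


def moderation_battery(
    data: pd.DataFrame,
    outcome: str = "promis_pf",
    covariates: Sequence[str] = CONTROL_COVARIATES,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    rows = []
    for feat in feature_names:
        r = moderation_analysis(data, feat, outcome, covariates)
        rows.append(
            {
                "feature": feat,
                "outcome": outcome,
                "n": r.n,
                "interaction_beta": r.interaction_beta,
                "interaction_ci_low": r.interaction_ci[0],
                "interaction_ci_high": r.interaction_ci[1],
                "interaction_p": r.interaction_p,
                "slope_pwms": r.slope_pwms,
                "slope_pwms_p": r.slope_pwms_p,
                "slope_control": r.slope_control,
                "slope_control_p": r.slope_control_p,
                "anchor_q25": r.percentile_anchors[0],
                "anchor_q50": r.percentile_anchors[1],
                "anchor_q75": r.percentile_anchors[2],
            }
        )
    return pd.DataFrame(rows)
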