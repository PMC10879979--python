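"""Longitudinal analyses: within-subject change tests, change→PRO
regressions, and a permutation-calibrated Fisher omnibus with a Q-Q
confidence envelope.

The longitudinal design pairs each participant's pandemic assessment with
their most proximal prepandemic baseline.  Per-feature change (pandemic
minus baseline) is tested with paired t tests, then related to the latest
available PROs with covariate-adjusted OLS (the cross-sectional covariates
plus elapsed time between assessments and study cohort).

Because a single change→outcome battery yields one p-value per feature, and
the features are correlated, the per-PRO evidence is pooled with Fisher's
combined probability statistic, chi² = −2 Σ ln p, and calibrated against an
*empirical* permutation null: the outcome vector is permuted across
participants (keeping features and covariates aligned with each other), the
whole battery is re-fit per permutation, and the empirical p-value is
``(1 + #{chi²_perm >= chi²_obs}) / (B + 1)``.  The same permutation draws
give per-order-statistic 95% bands for the observed-vs-expected −log10 p
Q-Q plot.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from persnet.codebook import Codebook
from persnet.cohort_io import LongitudinalPair, encode_covariates
from persnet.cross_sectional import AssociationResult, _fit_ols
from persnet.network_metrics import (
    FEATURE_NAMES,
    features_table,
    to_regression_scale,
)
from persnet.records import CohortTable

#: Default covariate set for longitudinal change regressions in pwMS:
#: the screened cross-sectional covariates plus elapsed time and cohort.
PWMS_CHANGE_COVARIATES = ("age", "disease_duration", "employed", "income", "elapsed_years")
CONTROL_CHANGE_COVARIATES = ("age", "employed", "income", "elapsed_years")


@dataclass
class PairedChange:
    feature: str
    n: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    t: float
    p: float
    note: str = ""


@dataclass
class OmnibusResult:
    outcome: str
    k: int
    chi_sq: float
    analytic_p: float
    empirical_p: float
    B: int
    seed: Optional[int]
    observed_p: np.ndarray = field(repr=False, default=None)
    permuted_p: np.ndarray = field(repr=False, default=None)


@dataclass
class QQEnvelope:
    observed_neglog_p: np.ndarray  # sorted ascending
    expected_neglog_p: np.ndarray
    lower_95: np.ndarray
    upper_95: np.ndarray


# ---------------------------------------------------------------------------
# paired change tests


def paired_change_test(pre: Sequence[float], post: Sequence[float], feature: str = "") -> PairedChange:
    """Two-tailed paired t test on (post − pre) over complete pairs."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[ok], post[ok]
    n = len(pre)
    if n < 2:
        raise ValueError(f"{feature}: need >=2 complete pairs, got {n}")
    diff = post - pre
    note = ""
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            t, p = 0.0, 1.0
            note = "all differences zero"
        else:
            t, p = math.inf if diff[0] > 0 else -math.inf, 0.0
            note = "zero variance with nonzero mean difference"
    else:
        t, p = stats.ttest_rel(post, pre)
    return PairedChange(
        feature=feature,
        n=n,
        mean_pre=float(pre.mean()),
        sd_pre=float(pre.std(ddof=1)),
        mean_post=float(post.mean()),
        sd_post=float(post.std(ddof=1)),
        t=float(t),
        p=float(p),
        note=note,
    )


def build_paired_table(
    pairs: list[LongitudinalPair], codebook: Codebook | None = None
) -> pd.DataFrame:
    """Wide per-participant table: features at both timepoints + deltas.

    Columns ``<feature>_pre``, ``<feature>_post``, ``d_<feature>`` (on
    regression scale for the deltas), pandemic covariates/PROs, elapsed
    time, and cohort id.
    """
    pre_cohort = CohortTable([p.prepandemic for p in pairs])
    post_cohort = CohortTable([p.pandemic for p in pairs])
    f_pre = features_table(pre_cohort, codebook).set_index("participant_id")
    f_post = features_table(post_cohort, codebook).set_index("participant_id")
    covs = encode_covariates(post_cohort, codebook).set_index("participant_id")
    rows = []
    for p in pairs:
        pid = p.participant_id
        row = {
            "participant_id": pid,
            "group": p.pandemic.participant.group,
            "cohort_id": p.pandemic.participant.cohort_id,
            "elapsed_years": p.elapsed_years,
        }
        for feat in FEATURE_NAMES:
            row[f"{feat}_pre"] = f_pre.at[pid, feat]
            row[f"{feat}_post"] = f_post.at[pid, feat]
        for col in ("age", "disease_duration", "employed", "income",
                    "pdds", "msrs_r", "promis_pf"):
            row[col] = covs.at[pid, col]
        rows.append(row)
    df = pd.DataFrame(rows)
    # deltas on regression scale: percent-type features as 0-1 proportions
    pre_rs = to_regression_scale(
        df[[f"{f}_pre" for f in FEATURE_NAMES]].rename(
            columns=lambda c: c[:-4]
        )
    )
    post_rs = to_regression_scale(
        df[[f"{f}_post" for f in FEATURE_NAMES]].rename(
            columns=lambda c: c[:-5]
        )
    )
    for feat in FEATURE_NAMES:
        df[f"d_{feat}"] = post_rs[feat] - pre_rs[feat]
    return df


def paired_change_battery(
    paired: pd.DataFrame, feature_names: Sequence[str] = FEATURE_NAMES
) -> pd.DataFrame:
    """Paired t test per feature on report-scale pre/post values."""
    rows = []
    for feat in feature_names:
        r = paired_change_test(paired[f"{feat}_pre"], paired[f"{feat}_post"], feat)
        rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# change -> outcome regressions


def change_regression(
    paired: pd.DataFrame,
    feature: str,
    outcome: str,
    covariates: Sequence[str] = PWMS_CHANGE_COVARIATES,
    cohort_col: Optional[str] = "cohort_id",
) -> AssociationResult:
    """OLS of the pandemic PRO on the feature change + covariates.

    The change covariate set adds elapsed time between assessments and
    study-cohort indicators to the cross-sectional covariates.
    """
    delta = f"d_{feature}"
    cols = [delta, outcome, *covariates]
    df = paired[cols + ([cohort_col] if cohort_col else [])].copy()
    df[cols] = df[cols].apply(pd.to_numeric, errors="coerce")
    df = df.dropna()
    X = df[[delta, *covariates]]
    if cohort_col:
        dummies = pd.get_dummies(df[cohort_col].astype(str), prefix="cohort", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    n = len(df)
    if n < X.shape[1] + 1 + 5:
        raise ValueError(f"{feature}->{outcome}: only {n} complete cases")
    res = _fit_ols(df[outcome], sm.add_constant(X))
    ci = res.conf_int(alpha=0.05)
    return AssociationResult(
        feature=feature,
        outcome=outcome,
        n=n,
        beta=float(res.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p=float(res.pvalues[1]),
        covariates=tuple(X.columns[1:]),
    )


# ---------------------------------------------------------------------------
# Fisher omnibus and permutation calibration


def fisher_omnibus(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability: chi² = −2 Σ ln p, df = 2k.

    Exact zeros are rejected (a permutation-derived p can be floored at
    1/(B+1) instead).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError(
            "p-values must lie in (0, 1]; for permutation p-values use the "
            "floor 1/(B+1) instead of 0"
        )
    chi_sq = float(-2.0 * np.log(p).sum())
    analytic_p = float(stats.chi2.sf(chi_sq, 2 * p.size))
    return chi_sq, analytic_p


def _design_for_feature(
    paired: pd.DataFrame,
    feature: str,
    covariates: Sequence[str],
    cohort_col: Optional[str],
    case_mask: pd.Series,
) -> np.ndarray:
    cols = [f"d_{feature}", *covariates]
    df = paired.loc[case_mask, cols].apply(pd.to_numeric, errors="coerce")
    X = df.to_numpy(dtype=float)
    if cohort_col:
        dummies = pd.get_dummies(
            paired.loc[case_mask, cohort_col].astype(str), prefix="cohort", drop_first=True
        ).to_numpy(dtype=float)
        X = np.hstack([X, dummies])
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _battery_pvalues(designs: list[np.ndarray], Y: np.ndarray) -> np.ndarray:
    """p-value of the feature coefficient for each design, all columns of Y.

    ``Y`` is (n, B); returns (k, B).  Each design has the feature change in
    column 1.  Uses the thin-QR normal equations so the full permutation
    battery is a handful of matrix products per feature.
    """
    k = len(designs)
    B = Y.shape[1]
    out = np.empty((k, B))
    ssy = None
    for j, X in enumerate(designs):
        n, p = X.shape
        Q, R = np.linalg.qr(X)
        QtY = Q.T @ Y  # (p, B)
        coef = np.linalg.solve(R, QtY)
        if ssy is None:
            ssy = np.sum(Y * Y, axis=0)
        rss = ssy - np.sum(QtY * QtY, axis=0)
        dof = n - p
        sigma2 = np.maximum(rss, 0.0) / dof
        Rinv = np.linalg.inv(R)
        xtx_inv_11 = float(np.sum(Rinv[1, :] ** 2))
        se = np.sqrt(sigma2 * xtx_inv_11)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = coef[1, :] / se
        out[j, :] = 2.0 * stats.t.sf(np.abs(tval), dof)
    return out


def permutation_omnibus(
    paired: pd.DataFrame,
    outcome: str,
    feature_names: Sequence[str] = FEATURE_NAMES,
    covariates: Sequence[str] = PWMS_CHANGE_COVARIATES,
    cohort_col: Optional[str] = "cohort_id",
    B: int = 10_000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> OmnibusResult:
    """Permutation-calibrated Fisher omnibus over the change battery.

    The outcome vector is permuted across participants while the
    (feature-change + covariate) block stays intact, preserving the
    inter-feature correlation that Fisher's independence assumption
    ignores — hence the empirical rather than analytic reference
    distribution.  Complete cases are taken jointly over all features so a
    single permutation applies to the whole battery.  With
    ``exhaustive=True`` (tiny cohorts, n ≤ 8) all n! permutations are
    enumerated and the empirical p uses exact counts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not exhaustive and B < 999:
        warnings.warn(f"B={B} gives empirical-p resolution 1/{B + 1}", stacklevel=2)
    if "participant_id" in paired.columns:
        # canonical row order: empirical p invariant to input row shuffles
        paired = paired.sort_values("participant_id", kind="stable").reset_index(drop=True)
    need = [outcome, *covariates] + [f"d_{f}" for f in feature_names]
    numeric = paired[need].apply(pd.to_numeric, errors="coerce")
    case_mask = numeric.notna().all(axis=1)
    if cohort_col:
        case_mask &= paired[cohort_col].notna()
    y = numeric.loc[case_mask, outcome].to_numpy(dtype=float)
    n = len(y)
    designs = [
        _design_for_feature(paired, f, covariates, cohort_col, case_mask)
        for f in feature_names
    ]
    obs_p = _battery_pvalues(designs, y[:, None])[:, 0]
    chi_obs, analytic_p = fisher_omnibus(obs_p)

    rng = np.random.default_rng(seed)
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        B_eff = len(perms)
        Y = y[perms.T]
    else:
        B_eff = B
        Y = np.empty((n, B))
        for b in range(B):
            Y[:, b] = y[rng.permutation(n)]
    perm_p = _battery_pvalues(designs, Y)
    chi_perm = -2.0 * np.log(perm_p).sum(axis=0)
    empirical_p = float((1 + np.sum(chi_perm >= chi_obs - 1e-12)) / (B_eff + 1))
    return OmnibusResult(
        outcome=outcome,
        k=len(feature_names),
        chi_sq=chi_obs,
        analytic_p=analytic_p,
        empirical_p=empirical_p,
        B=B_eff,
        seed=seed,
        observed_p=obs_p,
        permuted_p=perm_p,
    )


def qq_envelope(observed_p: np.ndarray, permuted_p: np.ndarray) -> QQEnvelope:
    """Observed-vs-expected −log10 p with a 95% permutation band.

    ``permuted_p`` is (k, B) — one battery of k p-values per permutation.
    Band = 2.5th/97.5th percentile of the i-th order statistic of −log10 p
    across permutations; expected quantile for rank i (largest first) is
    −log10(i / (k + 1)).
    """
    observed_p = np.asarray(observed_p, dtype=float)
    permuted_p = np.asarray(permuted_p, dtype=float)
    k = observed_p.size
    if permuted_p.shape[0] != k:
        raise ValueError("permuted matrix must have one row per feature")
    B = permuted_p.shape[1]
    if B < 40:
        warnings.warn(f"only {B} permutations; 95% band unreliable", stacklevel=2)
    obs_sorted = np.sort(-np.log10(observed_p))
    perm_sorted = np.sort(-np.log10(permuted_p), axis=0)  # (k, B), ascending
    lower = np.percentile(perm_sorted, 2.5, axis=1)
    upper = np.percentile(perm_sorted, 97.5, axis=1)
    ranks_desc = k - np.arange(k)  # rank of the i-th ascending order stat
    expected = -np.log10(ranks_desc / (k + 1.0))
    return QQEnvelope(
        observed_neglog_p=obs_sorted,
        expected_neglog_p=expected,
        lower_95=lower,
        upper_95=upper,
    )


def qq_to_frame(env: QQEnvelope) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "expected_neglog10_p": env.expected_neglog_p,
            "observed_neglog10_p": env.observed_neglog_p,
            "band_lower_95": env.lower_95,
            "band_upper_95": env.upper_95,
        }
    )
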