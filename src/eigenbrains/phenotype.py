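"""Eigenvalue-phenotype linking and clinical-table statistics.

Per-subject eigenbrain scores are related to clinical, cognitive and
biomarker data with standard models: one-way ANOVA with Tukey HSD post
hocs (post hocs only when the omnibus is significant), Brown-Forsythe
tests for variance inhomogeneity, multivariable OLS with standardized
betas for continuous outcomes and logistic regression with odds ratios
per SD for binary outcomes, plus Pearson chi-squared for contingency
tables.  p-values are reported raw, one model per outcome — no
multiple-comparison correction is applied, mirroring how such exploratory
brain-behaviour tables are usually reported; interpret accordingly.

Predictors (and continuous outcomes) are z-scored inside the link models
so "standardized beta" and "odds ratio per SD" are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, Logit, add_constant
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GROUPS",
    "LinkResult",
    "anova_tukey",
    "brown_forsythe",
    "linear_link",
    "logistic_link",
    "chi_squared_table",
    "compute_composites",
    "classify_ad_biomarkers",
]

#: Fixed diagnostic vocabulary: dysexecutive AD, behavioural-variant FTD,
#: behavioural AD, amnestic AD, cognitively unimpaired.
GROUPS = ("dAD", "bvFTD", "bvAD", "aAD", "CU")

#: Cognitive tests that are never averaged into a domain composite.
SINGLETON_TESTS = ("WCST", "TMT-B")


@dataclass(frozen=True)
class LinkResult:
    outcome: str
    kind: str  # "linear" or "logistic"
    coefficients: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    n: int
    r2: float | None = None
    r2_adj: float | None = None
    omnibus_p: float | None = None
    status: str = "ok"


def _zscore(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("zero-variance column cannot be z-scored")
    return (a - a.mean(axis=0)) / sd


def _check_groups(scores, groups):
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"groups with < 2 subjects: {list(small)}")
    return scores, groups, labels


def anova_tukey(scores, groups, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey HSD post hocs gated on the omnibus test."""
    scores, groups, labels = _check_groups(scores, groups)
    samples = [scores[groups == g] for g in labels]
    f_stat, p = stats.f_oneway(*samples)
    out = {"f": float(f_stat), "p": float(p), "groups": [str(g) for g in labels],
           "tukey": None, "tukey_run": False}
    if p < alpha:
        res = pairwise_tukeyhsd(scores, groups, alpha=alpha)
        table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        out["tukey"] = table
        out["tukey_run"] = True
    return out


def brown_forsythe(scores, groups, center: str = "median") -> dict:
    """Levene test for heteroscedasticity (median-centred by default)."""
    scores, groups, labels = _check_groups(scores, groups)
    samples = [scores[groups == g] for g in labels]
    stat, p = stats.levene(*samples, center=center)
    return {"statistic": float(stat), "p": float(p), "center": center}


def linear_link(scores: np.ndarray, outcome: np.ndarray, outcome_name: str = "outcome",
                terms: list[str] | None = None) -> LinkResult:
    """OLS of a continuous outcome on z-scored eigenbrain scores.

    Reports standardized betas (outcome z-scored as well), t-based 95% CIs
    and p-values, R^2, adjusted R^2 and the omnibus F p-value.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and np.asarray(outcome).size != 1:
        X = X.T
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[mask], y[mask]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} predictors")
    if y.std(ddof=1) <= 0:
        raise ValueError("outcome has zero variance")
    Xz, yz = _zscore(X), _zscore(y)
    if np.linalg.matrix_rank(Xz) < k:
        raise ValueError("rank-deficient predictors")
    fit = OLS(yz, add_constant(Xz)).fit()
    ci = fit.conf_int(alpha=0.05)
    names = terms if terms is not None else [f"EB{i + 1}" for i in range(k)]
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": fit.pvalues[1:],
        }
    )
    return LinkResult(
        outcome=outcome_name, kind="linear", coefficients=coef, n=n,
        r2=float(fit.rsquared), r2_adj=float(fit.rsquared_adj),
        omnibus_p=float(fit.f_pvalue),
    )


def logistic_link(scores: np.ndarray, outcome: np.ndarray, outcome_name: str = "outcome",
                  terms: list[str] | None = None) -> LinkResult:
    """Maximum-likelihood logistic regression; odds ratios per SD of score.

    Non-convergence or (quasi-)separation is reported through ``status``
    rather than as silently unreliable numbers.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and np.asarray(outcome).size != 1:
        X = X.T
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[mask], y[mask]
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class")
    n, k = X.shape
    Xz = _zscore(X)
    names = terms if terms is not None else [f"EB{i + 1}" for i in range(k)]
    status = "ok"
    try:
        fit = Logit(y, add_constant(Xz)).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            status = "non_converged"
        elif np.any(np.abs(fit.params) > 20):
            status = "separation_suspected"
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LinkResult(outcome=outcome_name, kind="logistic",
                          coefficients=pd.DataFrame(), n=n, status="separation")
    ci = fit.conf_int(alpha=0.05)
    # clip log-odds before exponentiating: diverged fits (flagged via
    # status) would otherwise overflow to inf with a warning
    _exp = lambda a: np.exp(np.clip(a, -700, 700))
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": _exp(fit.params[1:]),  # odds ratio per SD
            "ci_low": _exp(ci[1:, 0]),
            "ci_high": _exp(ci[1:, 1]),
            "p": fit.pvalues[1:],
        }
    )
    return LinkResult(outcome=outcome_name, kind="logistic", coefficients=coef,
                      n=n, status=status)


def chi_squared_table(contingency) -> dict:
    """Pearson chi-squared on a counts table, no continuity correction."""
    table = np.asarray(contingency)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency must be at least 2x2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency must hold nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    res = stats.chi2_contingency(table, correction=False)
    low_expected = bool(np.any(res.expected_freq < 5))
    return {"chi2": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue),
            "low_expected_counts": low_expected}


def compute_composites(test_scores: pd.DataFrame, domain_map: dict[str, str]) -> pd.DataFrame:
    """Per-domain cognitive composites: the mean of available scaled scores.

    WCST and TMT-B always pass through as singleton domains.  A domain
    with no available test is missing (NaN), never zero.
    """
    if test_scores.empty:
        raise ValueError("empty test-score table")
    missing = [t for t in test_scores.columns if t not in domain_map]
    if missing:
        raise ValueError(f"tests without a domain: {missing}")
    out = {}
    domains: dict[str, list[str]] = {}
    for test, dom in domain_map.items():
        if test in SINGLETON_TESTS:
            dom = test
        domains.setdefault(dom, []).append(test)
    for dom, tests in domains.items():
        cols = [t for t in tests if t in test_scores.columns]
        if cols:
            out[dom] = test_scores[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=test_scores.index)


# CSF / PET biomarker cut-offs (pg/ml for p-tau; SUVR for PET tracers).
PTAU_LOW, PTAU_HIGH = 54.0, 58.0
ATI_LOW, ATI_HIGH = 0.8, 1.2
PIB_CUTOFF = 1.42
AV1451_CUTOFF = 1.29


def classify_ad_biomarkers(
    ptau: float | None = None,
    ati: float | None = None,
    pib_suvr: float | None = None,
    av1451_suvr: float | None = None,
) -> dict:
    """Band CSF markers and flag PET positivity against fixed cut-offs.

    CSF bands: p-tau < 54 / 54-58 / > 58 pg/ml and ATI > 1.2 / 0.8-1.2 /
    < 0.8 map to not-consistent / borderline / consistent with Alzheimer's
    pathology.  PET positivity uses strict inequalities (amyloid PiB SUVR
    > 1.42, tau AV1451 SUVR > 1.29).  When the two CSF bands disagree the
    combined CSF call is "borderline" with both sub-bands reported.
    """

    def _is_missing(v):
        return v is None or (isinstance(v, float) and np.isnan(v))

    if all(_is_missing(v) for v in (ptau, ati, pib_suvr, av1451_suvr)):
        raise ValueError("all biomarkers missing")

    out: dict = {}
    ptau_band = ati_band = None
    if not _is_missing(ptau):
        ptau_band = ("not_consistent" if ptau < PTAU_LOW
                     else "consistent" if ptau > PTAU_HIGH else "borderline")
        out["ptau_band"] = ptau_band
    if not _is_missing(ati):
        ati_band = ("not_consistent" if ati > ATI_HIGH
                    else "consistent" if ati < ATI_LOW else "borderline")
        out["ati_band"] = ati_band
    if ptau_band and ati_band:
        out["csf_call"] = ptau_band if ptau_band == ati_band else "borderline"
    elif ptau_band or ati_band:
        out["csf_call"] = ptau_band or ati_band
    if not _is_missing(pib_suvr):
        out["amyloid_positive"] = bool(pib_suvr > PIB_CUTOFF)
    if not _is_missing(av1451_suvr):
        out["tau_positive"] = bool(av1451_suvr > AV1451_CUTOFF)
    return out
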