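"""Outcome association: group comparisons, Kaplan–Meier/log-rank, Cox models.

Continuous group comparisons use the Wilcoxon rank-sum test for unpaired
arms (exact for small tie-free samples, tie-corrected normal approximation
otherwise) and the paired t-test for matched samples. Survival curves are
Kaplan–Meier estimates; two-group differences use the log-rank test; hazard
ratios come from Cox proportional-hazards fits with Efron tie handling,
adjusted for age group, sex, and TNM stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .config import ConfigurationError
from .io import require_columns

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_group", "sex", "tnm_stage")
STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


class DegenerateVarianceError(ValueError):
    """Paired differences have no variance; the t statistic is undefined."""


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment across features (off by default everywhere:
    unadjusted per-feature p-values are the primary report)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method=method)[1]
    return out


def compare_groups(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Two-sided comparison of two arms of continuous values.

    Unpaired: Wilcoxon rank-sum (Mann–Whitney U reported as the rank-sum
    statistic of arm a). Paired: t-test on the differences. Identical
    paired arms return (0.0, 1.0); constant non-zero paired differences
    raise :class:`DegenerateVarianceError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs at least two observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length arms")
        diff = a - b
        if np.all(diff == 0):
            return 0.0, 1.0
        if np.ptp(diff) == 0:
            raise DegenerateVarianceError("paired differences are constant; t-test undefined")
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    # standardized statistic (tie-corrected normal scale): antisymmetric under arm swap
    na, nb = len(a), len(b)
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(na * nb / 12.0 * ((n + 1) - tie_term))
    z = (float(res.statistic) - na * nb / 2.0) / sigma
    return float(z), float(res.pvalue)


@dataclass
class KMResult:
    """Median-or-value split survival comparison for one feature."""

    feature: str
    cutpoint: float
    n_low: int
    n_high: int
    chi2: float
    p: float
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def km_logrank(cohort: pd.DataFrame, feature: str, cutpoint_rule="median") -> KMResult:
    """Kaplan–Meier curves and log-rank test for a high/low feature split.

    ``cutpoint_rule`` is ``"median"`` or an explicit numeric cutpoint.
    Ties with the cutpoint go to the low group. Strata with zero events
    are computed with a logged warning, not rejected.
    """
    require_columns(cohort, ("os_time", "event", feature), context="cohort table")
    x = cohort[feature].to_numpy(dtype=float)
    cut = float(np.median(x)) if cutpoint_rule == "median" else float(cutpoint_rule)
    low = x <= cut
    if low.all() or (~low).all():
        raise ValueError(f"cutpoint {cut} leaves an empty stratum for {feature!r}")
    t = cohort["os_time"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)
    curves = {}
    for name, mask in (("low", low), ("high", ~low)):
        if e[mask].sum() == 0:
            logger.warning("stratum %r of %r has zero events", name, feature)
        km = KaplanMeierFitter().fit(t[mask], e[mask], label=name)
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf
    res = logrank_test(t[low], t[~low], event_observed_A=e[low], event_observed_B=e[~low])
    return KMResult(
        feature=feature,
        cutpoint=cut,
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        curves=curves,
    )


def _encode(cohort: pd.DataFrame, columns, stage_encoding: str) -> pd.DataFrame:
    df = pd.DataFrame(index=cohort.index)
    for c in columns:
        col = cohort[c]
        if c == "tnm_stage":
            if stage_encoding == "ordinal":
                df[c] = col.map(STAGE_ORDINAL).astype(float) if col.dtype == object else col.astype(float)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix="stage", drop_first=True)
                df = pd.concat([df, dummies.astype(float)], axis=1)
        elif col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
                df = pd.concat([df, dummies.astype(float)], axis=1)
            else:
                df[c] = (col.astype(str) == levels[-1]).astype(float)
        else:
            df[c] = col.astype(float)
    return df


@dataclass
class CoxResult:
    """Per-term Cox summary; ``converged`` is False on an explicit fit failure."""

    mode: str
    terms: pd.DataFrame | None
    n: int
    n_events: int
    converged: bool
    message: str = ""


def cox_model(
    cohort: pd.DataFrame,
    features,
    covariates=DEFAULT_COVARIATES,
    mode: str = "multivariate",
    stage_encoding: str = "ordinal",
) -> CoxResult:
    """Cox proportional-hazards association of features with overall survival.

    ``mode="multivariate"`` fits all features jointly with the clinical
    covariates; ``mode="univariate"`` fits one model per feature (no
    covariates). Efron tie handling. Non-convergence or separation yields
    an explicit failure result rather than silent numbers.
    """
    features = [features] if isinstance(features, str) else list(features)
    require_columns(cohort, ("os_time", "event", *features), context="cohort table")
    n_events = int(cohort["event"].sum())
    if n_events < 10:
        raise ValueError(f"Cox model requires >= 10 events, got {n_events}")
    if mode == "univariate":
        frames = []
        for f in features:
            r = _fit_cox(cohort, [f], stage_encoding)
            if r.terms is not None:
                frames.append(r.terms)
        terms = pd.concat(frames, ignore_index=True) if frames else None
        return CoxResult("univariate", terms, len(cohort), n_events, terms is not None)
    cov = [c for c in covariates if c in cohort.columns]
    return _fit_cox(cohort, features + cov, stage_encoding)


def _fit_cox(cohort: pd.DataFrame, columns, stage_encoding: str) -> CoxResult:
    X = _encode(cohort, columns, stage_encoding)
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant; drop it before fitting")
    df = pd.concat(
        [cohort[["os_time", "event"]].reset_index(drop=True), X.reset_index(drop=True)], axis=1
    )
    n_events = int(df["event"].sum())
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="event")
    except (ConvergenceError, Exception) as exc:  # lifelines also raises generic errors on separation
        if isinstance(exc, KeyboardInterrupt):
            raise
        logger.error("Cox fit failed: %s", exc)
        return CoxResult("multivariate", None, len(df), n_events, False, message=str(exc))
    s = cph.summary
    terms = pd.DataFrame(
        {
            "term": s.index,
            "coef": s["coef"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "se": s["se(coef)"].to_numpy(),
            "hr_ci_low": np.exp(s["coef"].to_numpy() - 1.959963984540054 * s["se(coef)"].to_numpy()),
            "hr_ci_high": np.exp(s["coef"].to_numpy() + 1.959963984540054 * s["se(coef)"].to_numpy()),
            "p": s["p"].to_numpy(),
        }
    )
    return CoxResult("multivariate", terms, len(df), n_events, True)
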