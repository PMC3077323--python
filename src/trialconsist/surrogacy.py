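"""Trial-level surrogacy screen: country-level effects on two endpoints.

In a multinational trial, the treatment effect can be estimated
separately within each country on a candidate surrogate endpoint (e.g.
leukemia-free survival) and on the true endpoint (overall survival). If
the country-level hazard ratios line up — a weighted linear regression
of HR_true on HR_surrogate with a high coefficient of determination —
the effect observed on the surrogate is a good predictor of the effect
on the true endpoint. This is the trial-level association of surrogate
validation, with countries standing in for trials.

By default the regression is on the hazard-ratio scale, weighted by
country patient counts; inverse-variance and equal weights, and a
log-HR scale, are available. Estimated HRs are treated as fixed
regressors (no errors-in-variables correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, ConfigurationError, EstimationError
from .survival import fit_stratified_cox
from .trial_data import TrialDataset, split_by_covariate

WEIGHT_SCHEMES = ("patients", "inverse-variance", "equal")
SCALES = ("hr", "log-hr")


@dataclass(frozen=True)
class CountryEffect:
    """Treatment effects on both endpoints estimated within one country."""

    country: str
    n: int
    events_a: int
    events_b: int
    hr_a: float
    hr_b: float
    se_log_a: float
    se_log_b: float

    def to_dict(self) -> dict:
        return {
            "country": self.country, "n": self.n,
            "events_a": self.events_a, "events_b": self.events_b,
            "hr_a": self.hr_a, "hr_b": self.hr_b,
            "se_log_a": self.se_log_a, "se_log_b": self.se_log_b,
        }


@dataclass(frozen=True)
class SurrogacyFit:
    slope: float
    intercept: float
    r2: float
    p_slope: float
    weights_used: str
    scale: str
    k: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "r2": self.r2,
            "p_slope": self.p_slope, "weights_used": self.weights_used,
            "scale": self.scale, "k": self.k,
        }


def country_effects(
    dataset: TrialDataset,
    endpoint_a: str = "lfs",
    endpoint_b: str = "os",
    strata: Sequence[str] = ("cr_status",),
    min_patients: int = 5,
) -> tuple[list[CountryEffect], list[tuple[str, str]]]:
    """Per-country treatment effects on both endpoints.

    Stratification defaults to remission status only, since country is
    the unit of analysis. Countries below ``min_patients`` or whose fit
    is degenerate (single-arm, no events) are excluded with a reason.

    Returns ``(effects, excluded)`` where ``excluded`` holds
    ``(country, reason)`` pairs.
    """
    split = split_by_covariate(dataset, "country", min_patients=min_patients)
    effects = []
    excluded = [(s.label, s.reason or "") for s in split.subsets if s.excluded]
    for sub in split.included:
        try:
            fit_a = fit_stratified_cox(sub.data, endpoint=endpoint_a, strata=strata)
            fit_b = fit_stratified_cox(sub.data, endpoint=endpoint_b, strata=strata)
        except EstimationError as exc:
            excluded.append((sub.label, f"not estimable: {exc}"))
            continue
        ea = sum(sub.data.event_counts(endpoint_a))
        eb = sum(sub.data.event_counts(endpoint_b))
        effects.append(
            CountryEffect(
                country=sub.label, n=len(sub.data),
                events_a=ea, events_b=eb,
                hr_a=fit_a.hr, hr_b=fit_b.hr,
                se_log_a=fit_a.se_log_hr, se_log_b=fit_b.se_log_hr,
            )
        )
    if len(effects) < 3:
        raise AnalysisError(
            f"only {len(effects)} usable countries; the country-level "
            "regression needs at least 3"
        )
    return effects, excluded


def _weights(effects: Sequence[CountryEffect], scheme: str, scale: str) -> np.ndarray:
    if scheme == "patients":
        w = np.array([e.n for e in effects], dtype=float)
    elif scheme == "equal":
        w = np.ones(len(effects))
    elif scheme == "inverse-variance":
        # variance of the response (true-endpoint effect); delta method
        # on the HR scale
        if scale == "log-hr":
            w = np.array([1.0 / e.se_log_b**2 for e in effects])
        else:
            w = np.array([1.0 / (e.hr_b * e.se_log_b) ** 2 for e in effects])
    else:
        raise ConfigurationError(
            f"weight_scheme must be one of {WEIGHT_SCHEMES}, got {scheme!r}"
        )
    if not np.all(w > 0) or w.sum() <= 0:
        raise AnalysisError("weights must be positive with positive total")
    return w


def fit_weighted_regression(
    effects: Sequence[CountryEffect],
    weight_scheme: str = "patients",
    scale: str = "hr",
) -> SurrogacyFit:
    """Weighted least-squares regression of HR_b on HR_a across countries.

    ``r2`` is the weighted explained-variance fraction and ``p_slope``
    the two-sided t-test of zero slope on k-2 degrees of freedom. The
    fit is invariant to uniform rescaling of the weights.
    """
    if scale not in SCALES:
        raise ConfigurationError(f"scale must be one of {SCALES}, got {scale!r}")
    if len(effects) < 3:
        raise AnalysisError(f"need >= 3 points, got {len(effects)}")
    import statsmodels.api as sm

    w = _weights(effects, weight_scheme, scale)
    x = np.array([e.hr_a for e in effects], dtype=float)
    y = np.array([e.hr_b for e in effects], dtype=float)
    if scale == "log-hr":
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in the surrogate HRs")

    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = (float(v) for v in res.params)
    r2 = float(res.rsquared)
    p_slope = float(res.pvalues[1])
    if math.isnan(p_slope):  # perfectly collinear points
        p_slope = 0.0 if slope != 0 else 1.0
    return SurrogacyFit(
        slope=slope, intercept=intercept,
        r2=float(min(max(r2, 0.0), 1.0)), p_slope=p_slope,
        weights_used=weight_scheme, scale=scale, k=len(effects),
    )


def predict_effect(fit: SurrogacyFit, hr_a: float) -> float:
    """Predicted true-endpoint HR given a surrogate HR, on the fitted scale."""
    if hr_a <= 0:
        raise ConfigurationError(f"hr_a must be positive, got {hr_a}")
    if fit.scale == "log-hr":
        return math.exp(fit.intercept + fit.slope * math.log(hr_a))
    return fit.intercept + fit.slope * hr_a


def scatter_table(
    effects: Sequence[CountryEffect], weight_scheme: str = "patients",
    scale: str = "hr",
) -> list[dict]:
    """(x, y, weight) rows for plotting the country-level association."""
    w = _weights(effects, weight_scheme, scale)
    rows = []
    for e, wi in zip(effects, w):
        x, y = e.hr_a, e.hr_b
        if scale == "log-hr":
            x, y = math.log(x), math.log(y)
        rows.append({"country": e.country, "x": x, "y": y, "weight": float(wi),
                     "n": e.n})
    return rows
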