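"""Stratified treatment-effect estimation for a two-arm survival trial.

The estimand throughout is the effect of a single binary treatment
indicator on a time-to-event endpoint, with stratification (separate
baseline hazards) for design factors such as country and remission
status. Two routes are provided:

* :func:`fit_stratified_cox` — maximum partial likelihood for the Cox
  model with treatment as the only covariate (Efron tie handling),
  giving the hazard ratio, Wald CI, z and two-sided P;
* :func:`stratified_logrank` — the stratified log-rank test, summing
  observed-minus-expected events and hypergeometric variances over
  strata.

Hazard-ratio orientation
------------------------
By convention here a *beneficial* treatment is reported with HR > 1:
the returned ``hr`` is the control-versus-treatment hazard ratio,
``exp(-beta)`` under 1 = treatment coding. Pass
``orientation="conventional"`` for the usual ``exp(beta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, EstimationError, MonotoneLikelihoodError
from .trial_data import TrialDataset, endpoint_columns

DEFAULT_STRATA = ("country", "cr_status")

#: |beta| beyond which the partial likelihood is treated as monotone
BETA_DIVERGENCE_LIMIT = 15.0
SCORE_TOL = 1e-8
MAX_ITER = 100


@dataclass(frozen=True)
class SurvivalFit:
    """An estimated treatment effect with its uncertainty."""

    hr: float
    log_hr: float
    se_log_hr: float
    ci_low: float
    ci_high: float
    z: float
    p_two_sided: float
    n_treat: int
    n_control: int
    events_treat: int
    events_control: int
    ci_level: float = 0.95
    orientation: str = "benefit"
    strata_used: tuple[str, ...] = ()
    degenerate_strata_dropped: int = 0

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "hr", "log_hr", "se_log_hr", "ci_low", "ci_high", "z",
                "p_two_sided", "n_treat", "n_control", "events_treat",
                "events_control", "ci_level", "orientation",
                "degenerate_strata_dropped",
            )
        }
        d["strata_used"] = list(self.strata_used)
        return d


@dataclass(frozen=True)
class LogrankResult:
    """Stratified log-rank test (1 degree of freedom)."""

    statistic: float
    df: int
    p: float
    direction: int  # sign of observed - expected events in the control arm
    observed_minus_expected_control: float
    variance: float
    strata_used: tuple[str, ...] = ()
    degenerate_strata_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "direction": self.direction,
            "observed_minus_expected_control": self.observed_minus_expected_control,
            "variance": self.variance,
            "strata_used": list(self.strata_used),
            "degenerate_strata_dropped": self.degenerate_strata_dropped,
        }


# ---------------------------------------------------------------------------
# Stratum preparation
# ---------------------------------------------------------------------------


def _stratum_arrays(
    dataset: TrialDataset, endpoint: str, strata: Sequence[str]
) -> tuple[list[tuple[str, np.ndarray, np.ndarray, np.ndarray]], int]:
    """Split the data into analysis strata.

    Returns ``(kept, n_dropped)`` where each kept entry is
    ``(label, times, events, x)`` sorted by time ascending, and
    ``n_dropped`` counts degenerate strata: those with no events or with
    all patients in a single arm (which contribute nothing to either the
    partial likelihood or the log-rank sums).
    """
    time_col, event_col = endpoint_columns(endpoint)
    for s in strata:
        # raises ConfigurationError on unknown names
        dataset.covariate_values(s)

    if strata:
        key_values = list(zip(*(dataset.covariate_values(s) for s in strata)))
    else:
        key_values = [("__all__",)] * len(dataset.records)

    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(key_values):
        groups.setdefault(key, []).append(i)

    kept = []
    dropped = 0
    for key in sorted(groups, key=lambda k: tuple(str(v) for v in k)):
        idx = groups[key]
        recs = [dataset.records[i] for i in idx]
        x = np.array([r.arm for r in recs], dtype=float)
        t = np.array([getattr(r, time_col) for r in recs], dtype=float)
        e = np.array([getattr(r, event_col) for r in recs], dtype=bool)
        if not e.any() or x.min() == x.max():
            dropped += 1
            continue
        order = np.argsort(t, kind="stable")
        label = "/".join(str(v) for v in key)
        kept.append((label, t[order], e[order], x[order]))
    return kept, dropped


def _check_arms_events(dataset: TrialDataset, endpoint: str) -> None:
    nt, nc = dataset.arm_counts()
    if nt == 0 or nc == 0:
        raise EstimationError(
            f"both arms required: n_treat={nt}, n_control={nc}"
        )
    et, ec = dataset.event_counts(endpoint)
    if et + ec == 0:
        raise EstimationError(f"no {endpoint} events observed")


# ---------------------------------------------------------------------------
# Cox partial likelihood (single binary covariate, Efron ties)
# ---------------------------------------------------------------------------


class _CoxStratum:
    """Per-stratum sufficient structure for the partial likelihood.

    With a single binary covariate the weighted risk sums reduce to
    counts of treated/control patients at risk, so each Newton step is a
    handful of vectorized array operations.
    """

    def __init__(self, t: np.ndarray, e: np.ndarray, x: np.ndarray):
        # distinct event times, with death counts per arm
        et = t[e]
        ex = x[e]
        utimes, inv = np.unique(et, return_inverse=True)
        self.d = np.bincount(inv).astype(float)  # deaths at each time
        self.dx = np.bincount(inv, weights=ex)  # treated deaths
        # risk-set counts per arm at each distinct event time
        first_at_risk = np.searchsorted(t, utimes, side="left")
        n_total = len(t)
        cum_x = np.concatenate(([0.0], np.cumsum(x)))
        self.r1 = cum_x[-1] - cum_x[first_at_risk]  # treated at risk
        self.r0 = (n_total - first_at_risk) - self.r1  # control at risk
        self.tied = self.d > 1

    def loglik_score_info(self, beta: float) -> tuple[float, float, float]:
        w = math.exp(beta)
        S0 = self.r0 + w * self.r1
        S1 = w * self.r1
        ll = float(np.sum(beta * self.dx))
        U = float(np.sum(self.dx))
        info = 0.0
        # untied event times: single term j = 0
        single = ~self.tied
        m = S1[single] / S0[single]
        ll -= float(np.sum(np.log(S0[single])))
        U -= float(np.sum(m))
        info += float(np.sum(m - m * m))
        # tied times: Efron correction, j = 0 .. d-1
        for k in np.nonzero(self.tied)[0]:
            d, dx = self.d[k], self.dx[k]
            s0d = (d - dx) + w * dx
            s1d = w * dx
            j = np.arange(d) / d
            z0 = S0[k] - j * s0d
            z1 = S1[k] - j * s1d
            m = z1 / z0
            ll -= float(np.sum(np.log(z0)))
            U -= float(np.sum(m))
            info += float(np.sum(m - m * m))
        return ll, U, info


def _newton_cox(strata_data: list[_CoxStratum]) -> tuple[float, float]:
    """Maximize the summed partial likelihood; return (beta, se)."""
    beta = 0.0
    for _ in range(MAX_ITER):
        U = 0.0
        info = 0.0
        for sd in strata_data:
            _, u_s, i_s = sd.loglik_score_info(beta)
            U += u_s
            info += i_s
        if info <= 0:
            raise EstimationError("partial likelihood carries no information")
        step = U / info
        # dampen huge steps for stability far from the optimum
        step = max(min(step, 2.0), -2.0)
        beta += step
        if abs(beta) > BETA_DIVERGENCE_LIMIT:
            raise MonotoneLikelihoodError(
                "monotone partial likelihood: the treatment log hazard "
                f"diverges towards {'+' if beta > 0 else '-'}infinity",
                direction=1 if beta > 0 else -1,
            )
        if abs(U) < SCORE_TOL:
            break
    else:
        raise EstimationError(
            f"Cox fit did not converge in {MAX_ITER} iterations (|score|={abs(U):.2e})"
        )
    info = sum(sd.loglik_score_info(beta)[2] for sd in strata_data)
    return beta, 1.0 / math.sqrt(info)


def fit_stratified_cox(
    dataset: TrialDataset,
    endpoint: str = "lfs",
    strata: Sequence[str] = DEFAULT_STRATA,
    ci_level: float = 0.95,
    orientation: str = "benefit",
) -> SurvivalFit:
    """Estimate the treatment hazard ratio from a stratified Cox model.

    The model has the treatment indicator as its only covariate and a
    separate baseline hazard per stratum. Ties are handled with the
    Efron approximation. Degenerate strata (no events, or all patients
    in one arm) contribute nothing and are dropped with a count.

    Raises
    ------
    EstimationError
        If an arm is empty or there are no events.
    MonotoneLikelihoodError
        If the likelihood is monotone (e.g. all events in one arm in
        every informative stratum).
    """
    if not 0 < ci_level < 1:
        raise ConfigurationError(f"ci_level must be in (0,1), got {ci_level}")
    if orientation not in ("benefit", "conventional"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    _check_arms_events(dataset, endpoint)
    kept, dropped = _stratum_arrays(dataset, endpoint, strata)
    if not kept:
        raise EstimationError(
            "every stratum is degenerate (no events or single-arm)"
        )
    strata_data = [_CoxStratum(t, e, x) for _, t, e, x in kept]
    beta, se = _newton_cox(strata_data)

    log_hr = -beta if orientation == "benefit" else beta
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    z = log_hr / se
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    if p == 0.0:  # keep p in (0, 1] even when sf underflows
        p = 5e-324
    nt, nc = dataset.arm_counts()
    et, ec = dataset.event_counts(endpoint)
    return SurvivalFit(
        hr=math.exp(log_hr),
        log_hr=log_hr,
        se_log_hr=se,
        ci_low=math.exp(log_hr - zq * se),
        ci_high=math.exp(log_hr + zq * se),
        z=z,
        p_two_sided=p,
        n_treat=nt,
        n_control=nc,
        events_treat=et,
        events_control=ec,
        ci_level=ci_level,
        orientation=orientation,
        strata_used=tuple(label for label, *_ in kept),
        degenerate_strata_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Stratified log-rank test
# ---------------------------------------------------------------------------


def stratified_logrank(
    dataset: TrialDataset,
    endpoint: str = "lfs",
    strata: Sequence[str] = DEFAULT_STRATA,
) -> LogrankResult:
    """Stratified log-rank test of the treatment effect.

    Observed-minus-expected event counts and hypergeometric variances
    are accumulated over every distinct event time within every
    stratum; the statistic is ``(O-E)^2 / V`` on 1 df.
    """
    _check_arms_events(dataset, endpoint)
    kept, dropped = _stratum_arrays(dataset, endpoint, strata)
    if not kept:
        raise EstimationError("every stratum is degenerate (no events or single-arm)")

    ome_treat = 0.0  # observed - expected deaths, treatment arm
    var = 0.0
    for _, t, e, x in kept:
        sd = _CoxStratum(t, e, x)
        n = sd.r0 + sd.r1
        frac1 = sd.r1 / n
        ome_treat += float(np.sum(sd.dx - sd.d * frac1))
        with np.errstate(invalid="ignore", divide="ignore"):
            v = sd.d * frac1 * (1 - frac1) * (n - sd.d) / (n - 1)
        var += float(np.sum(np.where(n > 1, v, 0.0)))
    if var <= 0:
        raise EstimationError("log-rank variance is zero")
    ome_control = -ome_treat
    statistic = ome_treat**2 / var
    return LogrankResult(
        statistic=float(statistic),
        df=1,
        p=float(stats.chi2.sf(statistic, 1)) if statistic > 0 else 1.0,
        direction=int(np.sign(ome_control)),
        observed_minus_expected_control=ome_control,
        variance=var,
        strata_used=tuple(label for label, *_ in kept),
        degenerate_strata_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Summary-level helper
# ---------------------------------------------------------------------------


def z_from_summary(
    hr: float, ci_low: float, ci_high: float, ci_level: float = 0.95
) -> float:
    """Wald z statistic recovered from a published HR and its CI.

    ``se = (ln ci_high - ln ci_low) / (2 * Phi^-1((1+level)/2))`` and
    ``z = ln(hr) / se``. Useful for consistency analyses run from
    published summaries rather than patient-level data.
    """
    if ci_low <= 0 or ci_high <= 0 or hr <= 0:
        raise ConfigurationError("hazard ratio and CI bounds must be positive")
    if not (ci_low <= hr <= ci_high):
        raise ConfigurationError(
            f"hr {hr} must lie within the CI ({ci_low}, {ci_high})"
        )
    if not 0 < ci_level < 1:
        raise ConfigurationError(f"ci_level must be in (0,1), got {ci_level}")
    if ci_high == ci_low:
        raise ConfigurationError("zero-width confidence interval")
    se = (math.log(ci_high) - math.log(ci_low)) / (
        2 * stats.norm.ppf((1 + ci_level) / 2)
    )
    return math.log(hr) / se
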