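"""Consistency of a treatment effect across subsets and countries.

Given per-subset treatment-effect estimates ``tau_i`` (log hazard
ratios) with standard errors ``s_i`` and the overall trial effect
``tau``, the heterogeneity statistic is

    X^2 = sum_i (tau_i - tau)^2 / s_i^2,

chi-square with S-1 degrees of freedom under homogeneity across the S
subsets, and the inconsistency index is

    I^2 = (X^2 - S + 1) / X^2  if X^2 > S - 1, else 0,

the fraction of between-subset variability beyond chance. I^2 below
0.33 is read as little inconsistency, 0.33-0.67 as moderate, above 0.67
as substantial.

A reversal of effect is a subset whose estimated effect has the
opposite sign to the overall effect. For S subsets of equal size (for
survival endpoints, comparable *event* counts), the subset-level test
statistic has standard error sqrt(S) times the overall one, so the
chance of any given subset reversing is approximately
``Phi(-z / sqrt(S))`` where z is the overall (benefit-oriented) Wald
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import AnalysisError, ConfigurationError
from .survival import SurvivalFit, fit_stratified_cox
from .trial_data import TrialDataset, split_by_covariate

#: I^2 interpretation bands
I2_BANDS = ((0.33, "little"), (0.67, "moderate"), (1.0, "substantial"))


@dataclass(frozen=True)
class SubsetEstimate:
    """A treatment effect in one subset, on the log-HR scale."""

    label: str
    tau: float
    se: float
    n: int
    events: int

    def __post_init__(self):
        if self.se <= 0:
            raise ConfigurationError(f"subset {self.label!r}: se must be > 0")
        if self.events > self.n:
            raise ConfigurationError(f"subset {self.label!r}: events exceed n")


@dataclass(frozen=True)
class HeterogeneityResult:
    x2: float
    df: int
    p: float
    i2: float
    s: int

    @property
    def band(self) -> str:
        return i2_band(self.i2)

    def to_dict(self) -> dict:
        return {"x2": self.x2, "df": self.df, "p": self.p, "i2": self.i2,
                "s": self.s, "band": self.band}


def inconsistency_i2(x2: float, s: int) -> float:
    """Inconsistency index: ``(X^2 - S + 1)/X^2`` when X^2 > S-1, else 0."""
    if s < 2:
        raise ConfigurationError(f"need at least 2 subsets, got s={s}")
    if x2 < 0:
        raise ConfigurationError(f"x2 must be non-negative, got {x2}")
    if x2 > s - 1:
        return (x2 - s + 1) / x2
    return 0.0


def i2_band(i2: float) -> str:
    for upper, name in I2_BANDS:
        if i2 < upper:
            return name
    return I2_BANDS[-1][1]


def heterogeneity_x2(
    estimates: Sequence[SubsetEstimate],
    overall_tau: float | None = None,
) -> HeterogeneityResult:
    """Heterogeneity of subset effects around the overall effect.

    ``overall_tau`` is the overall trial estimate on the same log-HR
    scale as the subset ``tau`` values. Passing ``None`` falls back to
    the inverse-variance pooled mean of the subsets, the convention of
    meta-analysis; the default analysis supplies the trial-level
    estimate instead.
    """
    if len(estimates) < 2:
        raise AnalysisError(
            f"heterogeneity needs >= 2 subsets, got {len(estimates)}"
        )
    if overall_tau is None:
        wsum = sum(1 / e.se**2 for e in estimates)
        overall_tau = sum(e.tau / e.se**2 for e in estimates) / wsum
    x2 = sum((e.tau - overall_tau) ** 2 / e.se**2 for e in estimates)
    s = len(estimates)
    df = s - 1
    return HeterogeneityResult(
        x2=float(x2),
        df=df,
        p=float(stats.chi2.sf(x2, df)),
        i2=inconsistency_i2(x2, s),
        s=s,
    )


def reversal_probability(overall_z: float, s: int) -> float:
    """Chance that one of S equal-size subsets reverses the overall effect.

    ``overall_z`` is oriented so that positive means benefit. With the
    subset-level statistic's standard error inflated by sqrt(S), the
    reversal probability is the lower normal tail at ``-z/sqrt(S)``.
    """
    if s < 1:
        raise ConfigurationError(f"need s >= 1 subsets, got {s}")
    return float(stats.norm.cdf(-overall_z / math.sqrt(s)))


# ---------------------------------------------------------------------------
# Forest tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForestRow:
    label: str
    n_treat: int
    n_control: int
    events_treat: int
    events_control: int
    fit: SurvivalFit

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_treat": self.n_treat,
            "n_control": self.n_control,
            "events_treat": self.events_treat,
            "events_control": self.events_control,
            **{f"fit_{k}": v for k, v in self.fit.to_dict().items()},
        }


@dataclass(frozen=True)
class ForestTable:
    """Per-subset effects for one grouping covariate, plus heterogeneity."""

    covariate: str
    endpoint: str
    rows: tuple[ForestRow, ...]
    excluded: tuple[tuple[str, str], ...]  # (label, reason)
    heterogeneity: HeterogeneityResult
    overall: SurvivalFit
    n_missing: int

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "endpoint": self.endpoint,
            "rows": [r.to_dict() for r in self.rows],
            "excluded": [{"label": l, "reason": r} for l, r in self.excluded],
            "heterogeneity": self.heterogeneity.to_dict(),
            "overall": self.overall.to_dict(),
            "n_missing": self.n_missing,
        }

    def render_text(self, width: int = 30) -> str:
        """Monospace forest rendering: one bar per subset on a log scale."""
        lows = [r.fit.ci_low for r in self.rows] + [self.overall.ci_low]
        highs = [r.fit.ci_high for r in self.rows] + [self.overall.ci_high]
        lo, hi = math.log(min(lows)), math.log(max(highs))
        span = hi - lo or 1.0

        def pos(v: float) -> int:
            return int(round((math.log(v) - lo) / span * (width - 1)))

        lines = [f"{self.covariate} ({self.endpoint}), HR>1 = benefit"]
        label_w = max([len(r.label) for r in self.rows] + [len("overall")])
        for r in list(self.rows) + [None]:
            fit = r.fit if r else self.overall
            label = r.label if r else "overall"
            bar = [" "] * width
            for i in range(pos(fit.ci_low), pos(fit.ci_high) + 1):
                bar[i] = "-"
            bar[pos(fit.hr)] = "x"
            if math.log(1.0) >= lo and math.log(1.0) <= hi:
                i1 = pos(1.0)
                if bar[i1] == " ":
                    bar[i1] = "|"
            lines.append(
                f"{label:<{label_w}}  {''.join(bar)}  "
                f"HR {fit.hr:5.2f} ({fit.ci_low:.2f}-{fit.ci_high:.2f})"
            )
        het = self.heterogeneity
        lines.append(
            f"heterogeneity X2={het.x2:.2f} (df={het.df}, P={het.p:.2f}), "
            f"I2={het.i2:.2f} [{het.band}]"
        )
        return "\n".join(lines)


def build_forest(
    dataset: TrialDataset,
    covariate: str,
    endpoint: str = "lfs",
    strata: Sequence[str] = ("country", "cr_status"),
    min_patients: int = 5,
    ci_level: float = 0.95,
) -> ForestTable:
    """Per-subset stratified treatment effects with a heterogeneity test.

    Splits the dataset on ``covariate``, fits the stratified Cox model
    in every subset large enough, and tests heterogeneity of the subset
    log hazard ratios around the overall trial estimate. Subsets that
    are too small or not estimable (one arm, no events) are listed as
    excluded with a reason, never silently dropped.
    """
    if covariate == "arm":
        raise AnalysisError(
            "cannot build a forest over 'arm': subsets would be "
            "confounded with treatment"
        )
    split = split_by_covariate(dataset, covariate, min_patients=min_patients)
    overall = fit_stratified_cox(
        dataset, endpoint=endpoint, strata=strata, ci_level=ci_level
    )
    rows = []
    estimates = []
    excluded = [(s.label, s.reason or "") for s in split.subsets if s.excluded]
    for sub in split.included:
        try:
            fit = fit_stratified_cox(
                sub.data, endpoint=endpoint, strata=strata, ci_level=ci_level
            )
        except AnalysisError as exc:
            excluded.append((sub.label, f"not estimable: {exc}"))
            continue
        et, ec = sub.data.event_counts(endpoint)
        nt, nc = sub.data.arm_counts()
        rows.append(
            ForestRow(
                label=sub.label,
                n_treat=nt,
                n_control=nc,
                events_treat=et,
                events_control=ec,
                fit=fit,
            )
        )
        estimates.append(
            SubsetEstimate(
                label=sub.label,
                tau=fit.log_hr,
                se=fit.se_log_hr,
                n=len(sub.data),
                events=et + ec,
            )
        )
    if len(rows) < 2:
        raise AnalysisError(
            f"covariate {covariate!r} yields {len(rows)} usable subset(s); "
            "need at least 2"
        )
    het = heterogeneity_x2(estimates, overall_tau=overall.log_hr)
    return ForestTable(
        covariate=covariate,
        endpoint=endpoint,
        rows=tuple(rows),
        excluded=tuple(excluded),
        heterogeneity=het,
        overall=overall,
        n_missing=split.n_missing,
    )
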