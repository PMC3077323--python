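"""Robustness of a multicenter treatment effect to individual centers.

Two descriptive cross-validation procedures:

* leave-one-center-out (LOCO): the treatment-effect P-value is
  recomputed after removing each center in turn, and the resulting
  P-values are summarized as a frequency distribution — if no single
  center drives significance, all of them stay in a narrow band;
* sequential elimination: centers are ranked by size (number of
  randomized patients) and removed cumulatively, largest-first or
  smallest-first, until statistical significance is lost; the number of
  eliminations required measures how concentrated the evidence is.

The default per-refit test is the stratified log-rank (the convention
for the primary analysis of a stratified trial); a Wald test from the
stratified Cox fit is available. Both refit the model on the reduced
data with strata re-derived, so strata that become degenerate are
simply dropped by the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, ConfigurationError, EstimationError
from .survival import fit_stratified_cox, stratified_logrank
from .trial_data import TrialDataset

TESTS = ("logrank", "wald")


def _effect_and_p(
    dataset: TrialDataset, endpoint: str, strata: Sequence[str], test: str
) -> tuple[float, float]:
    """(oriented HR, two-sided P) on one dataset, per the chosen test."""
    fit = fit_stratified_cox(dataset, endpoint=endpoint, strata=strata)
    if test == "wald":
        return fit.hr, fit.p_two_sided
    lr = stratified_logrank(dataset, endpoint=endpoint, strata=strata)
    return fit.hr, lr.p


@dataclass(frozen=True)
class LocoRow:
    center_id: str
    n_removed: int
    hr: float | None
    p: float | None
    estimable: bool = True
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "center_id": self.center_id,
            "n_removed": self.n_removed,
            "hr": self.hr,
            "p": self.p,
            "estimable": self.estimable,
            "reason": self.reason,
        }


@dataclass(frozen=True)
class LocoResult:
    rows: tuple[LocoRow, ...]
    endpoint: str
    test: str
    full_data_hr: float
    full_data_p: float

    @property
    def estimable_rows(self) -> tuple[LocoRow, ...]:
        return tuple(r for r in self.rows if r.estimable)

    @property
    def min_p(self) -> float:
        return min(r.p for r in self.estimable_rows)

    @property
    def max_p(self) -> float:
        return max(r.p for r in self.estimable_rows)

    @property
    def mean_p(self) -> float:
        ps = [r.p for r in self.estimable_rows]
        return sum(ps) / len(ps)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "test": self.test,
            "full_data_hr": self.full_data_hr,
            "full_data_p": self.full_data_p,
            "summary": {
                "min_p": self.min_p,
                "max_p": self.max_p,
                "mean_p": self.mean_p,
                "n_centers": len(self.rows),
                "n_estimable": len(self.estimable_rows),
            },
            "rows": [r.to_dict() for r in self.rows],
        }


def leave_one_center_out(
    dataset: TrialDataset,
    endpoint: str = "lfs",
    strata: Sequence[str] = ("country", "cr_status"),
    test: str = "logrank",
) -> LocoResult:
    """Refit the treatment effect once per center, with that center removed.

    Rows whose refit is impossible (an arm emptied, no events left) are
    flagged non-estimable with the failure reason and excluded from the
    min/max/mean summary rather than aborting the whole analysis.
    """
    if test not in TESTS:
        raise ConfigurationError(f"test must be one of {TESTS}, got {test!r}")
    centers = dataset.centers
    if len(centers) < 2:
        raise AnalysisError(f"need >= 2 centers, got {len(centers)}")
    full_hr, full_p = _effect_and_p(dataset, endpoint, strata, test)
    rows = []
    for center in centers:
        reduced = dataset.drop_center(center)
        n_removed = len(dataset) - len(reduced)
        try:
            hr, p = _effect_and_p(reduced, endpoint, strata, test)
            rows.append(LocoRow(center, n_removed, hr, p))
        except EstimationError as exc:
            rows.append(
                LocoRow(center, n_removed, None, None, estimable=False,
                        reason=str(exc))
            )
    if not any(r.estimable for r in rows):
        raise AnalysisError("no leave-one-center-out refit was estimable")
    return LocoResult(
        rows=tuple(rows), endpoint=endpoint, test=test,
        full_data_hr=full_hr, full_data_p=full_p,
    )


def p_histogram(
    loco: LocoResult, bin_width: float = 0.002
) -> list[tuple[float, float, int]]:
    """Frequency distribution of the LOCO P-values.

    Returns ``(lo, hi, count)`` per half-open bin ``[lo, hi)`` covering
    the observed range; counts sum to the number of estimable rows.
    """
    if bin_width <= 0:
        raise ConfigurationError(f"bin_width must be positive, got {bin_width}")
    ps = [r.p for r in loco.estimable_rows]
    if not ps:
        raise AnalysisError("no estimable rows to histogram")
    lo = math.floor(min(ps) / bin_width) * bin_width
    n_bins = max(1, math.ceil((max(ps) - lo) / bin_width + 1e-12))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # half-open [lo, hi) binning
    idx = np.minimum(((np.asarray(ps) - lo) / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i]))
        for i in range(n_bins)
    ]


# ---------------------------------------------------------------------------
# Sequential elimination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EliminationStep:
    step: int
    center_id: str
    center_size: int
    cumulative_removed: int
    hr: float | None
    p: float | None
    estimable: bool = True
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "center_id": self.center_id,
            "center_size": self.center_size,
            "cumulative_removed": self.cumulative_removed,
            "hr": self.hr,
            "p": self.p,
            "estimable": self.estimable,
            "reason": self.reason,
        }


@dataclass(frozen=True)
class EliminationPath:
    ordering: str  # "largest-first" or "smallest-first"
    alpha: float
    steps: tuple[EliminationStep, ...]
    stop_step: int | None  # first step with p > alpha; None if never reached

    def to_dict(self) -> dict:
        return {
            "ordering": self.ordering,
            "alpha": self.alpha,
            "stop_step": self.stop_step,
            "steps": [s.to_dict() for s in self.steps],
        }


ORDERINGS = ("largest-first", "smallest-first")


def rank_centers(
    dataset: TrialDataset, ordering: str, by: str = "patients",
    endpoint: str = "lfs",
) -> list[tuple[str, int]]:
    """Centers ranked for elimination, with deterministic tie-breaks.

    Size is the number of randomized patients by default (``by``
    switches to event counts); ties are broken lexicographically on
    center_id. The ranking is fixed once from the full dataset and is
    not recomputed as centers are removed.
    """
    if ordering not in ORDERINGS:
        raise ConfigurationError(f"ordering must be one of {ORDERINGS}")
    if by not in ("patients", "events"):
        raise ConfigurationError(f"size measure must be patients|events, got {by!r}")
    sizes: dict[str, int] = {}
    for rec in dataset.records:
        if by == "patients":
            sizes[rec.center_id] = sizes.get(rec.center_id, 0) + 1
        else:
            from .trial_data import endpoint_columns

            _, ev = endpoint_columns(endpoint)
            sizes[rec.center_id] = sizes.get(rec.center_id, 0) + int(
                getattr(rec, ev)
            )
    reverse = ordering == "largest-first"
    return sorted(
        sizes.items(), key=lambda kv: ((-kv[1] if reverse else kv[1]), kv[0])
    )


def sequential_elimination(
    dataset: TrialDataset,
    endpoint: str = "lfs",
    strata: Sequence[str] = ("country", "cr_status"),
    ordering: str = "largest-first",
    alpha: float = 0.05,
    test: str = "logrank",
    size_by: str = "patients",
) -> EliminationPath:
    """Cumulatively remove centers in size order until significance is lost.

    The path is recorded step by step until the refit P-value exceeds
    ``alpha`` (recorded as ``stop_step``) or fewer than 2 centers
    remain. Non-estimable refits terminate the path with a flagged step.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError(f"alpha must be in (0,1], got {alpha}")
    if test not in TESTS:
        raise ConfigurationError(f"test must be one of {TESTS}, got {test!r}")
    ranked = rank_centers(dataset, ordering, by=size_by, endpoint=endpoint)
    if len(ranked) < 2:
        raise AnalysisError(f"need >= 2 centers, got {len(ranked)}")
    steps: list[EliminationStep] = []
    current = dataset
    removed = 0
    stop_step = None
    for i, (center, size) in enumerate(ranked, start=1):
        if len(ranked) - i < 1:
            break  # never remove the final center
        current = current.drop_center(center)
        removed += size
        try:
            hr, p = _effect_and_p(current, endpoint, strata, test)
        except EstimationError as exc:
            steps.append(
                EliminationStep(i, center, size, removed, None, None,
                                estimable=False, reason=str(exc))
            )
            break
        steps.append(EliminationStep(i, center, size, removed, hr, p))
        if p > alpha:
            stop_step = i
            break
    return EliminationPath(
        ordering=ordering, alpha=alpha, steps=tuple(steps), stop_step=stop_step
    )
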