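"""Patient-level data model for a two-arm multicenter survival trial.

A trial is a collection of :class:`PatientRecord` objects, one per
randomized patient, each carrying the arm (1 = treatment, 0 = control),
the clinical center and country, the remission stratum (CR1 vs CR>1) and
two time-to-event endpoints:

* ``lfs`` — leukemia-free survival, days from randomization to relapse or
  death, whichever comes first;
* ``os`` — overall survival, days from randomization to death.

Because death is itself an LFS event, every valid record satisfies
``lfs_time <= os_time`` and ``os_event => lfs_event``; these invariants
are enforced on construction and on CSV input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

#: canonical CSV columns, in write order
CORE_COLUMNS = (
    "patient_id",
    "center_id",
    "country",
    "arm",
    "cr_status",
    "lfs_time",
    "lfs_event",
    "os_time",
    "os_event",
)

#: endpoint name -> (time column, event column)
ENDPOINTS = {"lfs": ("lfs_time", "lfs_event"), "os": ("os_time", "os_event")}

#: record fields usable as grouping covariates alongside free-form covariates
STRUCTURAL_COVARIATES = ("arm", "center_id", "country", "cr_status")

CR_LEVELS = ("CR1", "CR>1")


@dataclass(frozen=True)
class PatientRecord:
    """One randomized patient."""

    patient_id: str
    center_id: str
    country: str
    arm: int  # 1 = treatment, 0 = control
    cr_status: str  # "CR1" or "CR>1"
    lfs_time: float
    lfs_event: bool
    os_time: float
    os_event: bool
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        problems = self.problems()
        if problems:
            raise ValidationError(
                f"invalid record {self.patient_id!r}: " + "; ".join(problems)
            )

    def problems(self) -> list[str]:
        """Human-readable invariant violations (empty when valid)."""
        out = []
        if self.arm not in (0, 1):
            out.append(f"arm must be 0 or 1, got {self.arm!r}")
        if self.cr_status not in CR_LEVELS:
            out.append(f"cr_status must be one of {CR_LEVELS}, got {self.cr_status!r}")
        if self.lfs_time < 0 or self.os_time < 0:
            out.append("times must be non-negative")
        if self.lfs_time > self.os_time:
            out.append(f"lfs_time {self.lfs_time} exceeds os_time {self.os_time}")
        if self.os_event and not self.lfs_event:
            out.append("os_event implies lfs_event (death is an LFS event)")
        return out


class TrialDataset:
    """Ordered, validated collection of :class:`PatientRecord`."""

    def __init__(self, records: Iterable[PatientRecord]):
        self.records: tuple[PatientRecord, ...] = tuple(records)
        self._validate()
        self._frame: pd.DataFrame | None = None

    def _validate(self) -> None:
        seen: dict[str, int] = {}
        dupes = []
        center_country: dict[str, str] = {}
        for rec in self.records:
            if rec.patient_id in seen:
                dupes.append(rec.patient_id)
            seen[rec.patient_id] = 1
            prev = center_country.setdefault(rec.center_id, rec.country)
            if prev != rec.country:
                raise ValidationError(
                    f"center {rec.center_id!r} appears in two countries "
                    f"({prev!r} and {rec.country!r})"
                )
        if dupes:
            raise ValidationError(f"duplicate patient_ids: {sorted(set(dupes))}")

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialDataset) and self.records == other.records

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names: dict[str, None] = {}
        for rec in self.records:
            for k in rec.covariates:
                names.setdefault(k)
        return tuple(names)

    @property
    def centers(self) -> tuple[str, ...]:
        return tuple(sorted({r.center_id for r in self.records}))

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted({r.country for r in self.records}))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: core columns plus one column per covariate.

        Missing covariate values appear as NaN. The frame is cached; treat
        it as read-only.
        """
        if self._frame is None:
            rows = []
            for rec in self.records:
                row = {c: getattr(rec, c) for c in CORE_COLUMNS}
                row["arm"] = int(rec.arm)
                row["lfs_event"] = bool(rec.lfs_event)
                row["os_event"] = bool(rec.os_event)
                row.update(rec.covariates)
                rows.append(row)
            self._frame = pd.DataFrame(rows)
        return self._frame

    def covariate_values(self, name: str) -> list[str | None]:
        """Per-record value of a structural field or free-form covariate."""
        if name in STRUCTURAL_COVARIATES:
            return [str(getattr(r, name)) for r in self.records]
        if name not in self.covariate_names:
            raise ConfigurationError(
                f"unknown covariate {name!r}; available: "
                f"{STRUCTURAL_COVARIATES + self.covariate_names}"
            )
        return [r.covariates.get(name) for r in self.records]

    def subset(self, keep: Sequence[bool]) -> "TrialDataset":
        if len(keep) != len(self.records):
            raise ValueError("mask length mismatch")
        return TrialDataset(r for r, k in zip(self.records, keep) if k)

    def drop_center(self, center_id: str) -> "TrialDataset":
        return TrialDataset(r for r in self.records if r.center_id != center_id)

    def arm_counts(self) -> tuple[int, int]:
        """(n_treatment, n_control)."""
        nt = sum(r.arm == 1 for r in self.records)
        return nt, len(self.records) - nt

    def event_counts(self, endpoint: str) -> tuple[int, int]:
        """(events in treatment arm, events in control arm)."""
        _, event_col = endpoint_columns(endpoint)
        et = sum(getattr(r, event_col) for r in self.records if r.arm == 1)
        ec = sum(getattr(r, event_col) for r in self.records if r.arm == 0)
        return et, ec


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    try:
        return ENDPOINTS[endpoint]
    except KeyError:
        raise ConfigurationError(
            f"unknown endpoint {endpoint!r}; expected one of {sorted(ENDPOINTS)}"
        ) from None


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------


def read_trial_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> TrialDataset:
    """Read a patient-level trial CSV into a validated :class:`TrialDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row. Event flags must be coded 0/1 and
        times as non-negative numbers (days).
    column_map:
        Optional mapping from canonical column names (``patient_id``,
        ``arm``, ``lfs_time``, ...) to the file's actual headers, for
        files with nonstandard naming. Unmapped extra columns become
        categorical covariates.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    unknown = set(column_map) - set(CORE_COLUMNS)
    if unknown:
        raise ConfigurationError(f"column_map keys not recognized: {sorted(unknown)}")
    df = df.rename(columns=rename)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing} in {path.name}"
        )
    return _frame_to_dataset(df)


def _parse_time(value: str, column: str, pid: str) -> float:
    try:
        t = float(value)
    except ValueError:
        raise ValidationError(f"patient {pid!r}: {column}={value!r} is not a number")
    if t < 0:
        raise ValidationError(f"patient {pid!r}: {column}={t} is negative")
    return t


def _parse_flag(value: str, column: str, pid: str) -> bool:
    if value not in ("0", "1"):
        raise ValidationError(
            f"patient {pid!r}: {column}={value!r} must be coded 0/1"
        )
    return value == "1"


def _frame_to_dataset(df: pd.DataFrame) -> TrialDataset:
    covariate_cols = [c for c in df.columns if c not in CORE_COLUMNS]
    records = []
    time_order_bad = []
    for _, row in df.iterrows():
        pid = row["patient_id"]
        lfs_time = _parse_time(row["lfs_time"], "lfs_time", pid)
        os_time = _parse_time(row["os_time"], "os_time", pid)
        if lfs_time > os_time:
            time_order_bad.append(pid)
            continue
        covs = {c: row[c] for c in covariate_cols if row[c] != ""}
        records.append(
            PatientRecord(
                patient_id=pid,
                center_id=row["center_id"],
                country=row["country"],
                arm=int(_parse_flag(row["arm"], "arm", pid)),
                cr_status=row["cr_status"],
                lfs_time=lfs_time,
                lfs_event=_parse_flag(row["lfs_event"], "lfs_event", pid),
                os_time=os_time,
                os_event=_parse_flag(row["os_event"], "os_event", pid),
                covariates=covs,
            )
        )
    if time_order_bad:
        raise ValidationError(
            f"lfs_time exceeds os_time for patient(s): {time_order_bad}"
        )
    return TrialDataset(records)


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    """Write a dataset as CSV, re-readable by :func:`read_trial_csv`.

    Times are written in full repr precision so the round trip is the
    identity; event flags are written 0/1; missing covariate values as
    empty fields.
    """
    path = Path(path)
    cov_names = dataset.covariate_names
    rows = []
    for rec in dataset.records:
        row = {
            "patient_id": rec.patient_id,
            "center_id": rec.center_id,
            "country": rec.country,
            "arm": int(rec.arm),
            "cr_status": rec.cr_status,
            "lfs_time": repr(float(rec.lfs_time)),
            "lfs_event": int(rec.lfs_event),
            "os_time": repr(float(rec.os_time)),
            "os_event": int(rec.os_event),
        }
        for c in cov_names:
            row[c] = rec.covariates.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CORE_COLUMNS) + list(cov_names))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subset splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Subset:
    """One level of a grouping covariate."""

    label: str
    data: TrialDataset
    excluded: bool = False
    reason: str | None = None

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CovariateSplit:
    covariate: str
    subsets: tuple[Subset, ...]
    n_missing: int

    @property
    def included(self) -> tuple[Subset, ...]:
        return tuple(s for s in self.subsets if not s.excluded)

    @property
    def excluded(self) -> tuple[Subset, ...]:
        return tuple(s for s in self.subsets if s.excluded)


def split_by_covariate(
    dataset: TrialDataset, covariate: str, min_patients: int = 5
) -> CovariateSplit:
    """Partition a dataset by the levels of a covariate.

    Records with a missing value are excluded from the split (never
    imputed) and counted in ``n_missing``. Subsets with fewer than
    ``min_patients`` patients are returned flagged as excluded rather
    than silently dropped, mirroring the reporting of small-country
    exclusions in multicenter analyses. Labels are ordered
    lexicographically so outputs are byte-stable.
    """
    if min_patients < 0:
        raise ConfigurationError("min_patients must be >= 0")
    values = dataset.covariate_values(covariate)
    labels = sorted({v for v in values if v is not None})
    subsets = []
    for label in labels:
        sub = dataset.subset([v == label for v in values])
        excluded = len(sub) < min_patients
        reason = (
            f"only {len(sub)} patients (< min_patients={min_patients})"
            if excluded
            else None
        )
        subsets.append(Subset(label=label, data=sub, excluded=excluded, reason=reason))
    n_missing = sum(v is None for v in values)
    return CovariateSplit(covariate=covariate, subsets=tuple(subsets), n_missing=n_missing)
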