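"""Shared fixtures: tiny hand-built trials and generated datasets."""

from __future__ import annotations

import dataclasses

import pytest

from trialconsist import (
    PatientRecord,
    TrialDataset,
    default_trial_config,
    generate_trial,
)


def make_patient(
    pid,
    arm,
    lfs_time,
    lfs_event,
    os_time=None,
    os_event=None,
    center="c1",
    country="X",
    cr="CR1",
    covariates=None,
):
    """Terse record builder; OS defaults to the LFS endpoint."""
    return PatientRecord(
        patient_id=str(pid),
        center_id=center,
        country=country,
        arm=arm,
        cr_status=cr,
        lfs_time=float(lfs_time),
        lfs_event=bool(lfs_event),
        os_time=float(lfs_time if os_time is None else os_time),
        os_event=bool(lfs_event if os_event is None else os_event),
        covariates=covariates or {},
    )


@pytest.fixture
def six_patient_dataset():
    """Six patients, one stratum, distinct event/censoring times (no ties)."""
    rows = [
        ("p1", 1, 2.0, 1),
        ("p2", 1, 5.0, 0),
        ("p3", 1, 9.0, 1),
        ("p4", 0, 1.0, 1),
        ("p5", 0, 4.0, 1),
        ("p6", 0, 8.0, 0),
    ]
    return TrialDataset(make_patient(*r) for r in rows)


@pytest.fixture
def two_stratum_dataset():
    """Eight patients in two CR strata, no tied event times."""
    rows = [
        ("q1", 1, 1.5, 1, "CR1"),
        ("q2", 0, 3.0, 1, "CR1"),
        ("q3", 1, 6.0, 0, "CR1"),
        ("q4", 0, 7.5, 1, "CR1"),
        ("q5", 1, 2.5, 1, "CR>1"),
        ("q6", 0, 4.5, 1, "CR>1"),
        ("q7", 1, 8.0, 1, "CR>1"),
        ("q8", 0, 9.0, 0, "CR>1"),
    ]
    return TrialDataset(
        make_patient(pid, arm, t, e, cr=cr) for pid, arm, t, e, cr in rows
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default 320-patient synthetic trial (seed 1)."""
    return generate_trial(default_trial_config(seed=1))


@pytest.fixture(scope="session")
def plain_config():
    """Default structure without prognostic covariates (correctly specified
    stratified proportional-hazards model)."""
    return dataclasses.replace(default_trial_config(seed=0), covariate_spec=())
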