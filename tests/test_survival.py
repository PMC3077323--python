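"""Cox/log-rank engine versus brute-force oracles and exact symmetries."""

import dataclasses
import math

import numpy as np
import pytest

from trialconsist import (
    ConfigurationError,
    EstimationError,
    MonotoneLikelihoodError,
    TrialDataset,
    fit_stratified_cox,
    stratified_logrank,
    z_from_summary,
)
from tests.conftest import make_patient

# ---------------------------------------------------------------------------
# Independent oracles: naive per-event-time implementations
# ---------------------------------------------------------------------------


def naive_partial_loglik(dataset, endpoint, strata, beta):
    """Efron partial log-likelihood computed directly from its definition."""
    groups = {}
    for rec in dataset.records:
        key = tuple(getattr(rec, s) for s in strata)
        groups.setdefault(key, []).append(rec)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    ll = 0.0
    for recs in groups.values():
        times = sorted({getattr(r, tcol) for r in recs if getattr(r, ecol)})
        for t in times:
            deaths = [r for r in recs if getattr(r, tcol) == t and getattr(r, ecol)]
            risk = [r for r in recs if getattr(r, tcol) >= t]
            d = len(deaths)
            s0_risk = sum(math.exp(beta * r.arm) for r in risk)
            s0_dead = sum(math.exp(beta * r.arm) for r in deaths)
            ll += sum(beta * r.arm for r in deaths)
            for j in range(d):
                ll -= math.log(s0_risk - (j / d) * s0_dead)
    return ll


def grid_maximizer(dataset, endpoint, strata, lo=-5.0, hi=5.0):
    """Maximize the naive partial likelihood by successively refined scans."""
    for step in (1e-2, 1e-4, 1e-6, 1e-8):
        grid = np.arange(lo, hi + step, step)
        lls = [naive_partial_loglik(dataset, endpoint, strata, b) for b in grid]
        best = grid[int(np.argmax(lls))]
        lo, hi = best - 2 * step, best + 2 * step
    return best


def naive_logrank(dataset, endpoint, strata):
    """Hand-tabulated stratified log-rank O-E and variance."""
    groups = {}
    for rec in dataset.records:
        key = tuple(getattr(rec, s) for s in strata)
        groups.setdefault(key, []).append(rec)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    ome, var = 0.0, 0.0
    for recs in groups.values():
        for t in sorted({getattr(r, tcol) for r in recs if getattr(r, ecol)}):
            risk = [r for r in recs if getattr(r, tcol) >= t]
            deaths = [r for r in risk if getattr(r, tcol) == t and getattr(r, ecol)]
            n, n1 = len(risk), sum(r.arm for r in risk)
            d, d1 = len(deaths), sum(r.arm for r in deaths)
            ome += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return ome, var


# ---------------------------------------------------------------------------
# Cox fit
# ---------------------------------------------------------------------------


def test_cox_matches_grid_search_oracle(six_patient_dataset):
    fit = fit_stratified_cox(six_patient_dataset, "lfs", strata=[],
                             orientation="conventional")
    beta_oracle = grid_maximizer(six_patient_dataset, "lfs", ())
    assert fit.log_hr == pytest.approx(beta_oracle, abs=1e-6)


def test_cox_matches_oracle_two_strata(two_stratum_dataset):
    fit = fit_stratified_cox(two_stratum_dataset, "lfs", strata=["cr_status"],
                             orientation="conventional")
    beta_oracle = grid_maximizer(two_stratum_dataset, "lfs", ("cr_status",))
    assert fit.log_hr == pytest.approx(beta_oracle, abs=1e-6)


def test_identical_arms_give_null_effect():
    # the two arms are exact copies: same times, same censoring
    recs = []
    for arm in (0, 1):
        for i, (t, e) in enumerate([(1.0, 1), (3.0, 1), (5.0, 0), (7.0, 1)]):
            recs.append(make_patient(f"a{arm}{i}", arm, t, e))
    ds = TrialDataset(recs)
    fit = fit_stratified_cox(ds, "lfs", strata=[])
    assert fit.hr == pytest.approx(1.0, abs=1e-9)
    assert fit.z == pytest.approx(0.0, abs=1e-9)
    lr = stratified_logrank(ds, "lfs", strata=[])
    assert lr.statistic == pytest.approx(0.0, abs=1e-12)
    assert lr.p == 1.0


def test_duplicating_patients_halves_variance(default_dataset):
    """Doubling the data shrinks the SE by 1/sqrt(2); the estimate moves
    only within the Efron tie-correction's small-sample wobble, and the
    duplicated-data fit matches an independent refit exactly."""
    fit1 = fit_stratified_cox(default_dataset)
    doubled = TrialDataset(
        list(default_dataset.records)
        + [
            dataclasses.replace(r, patient_id=r.patient_id + "_dup")
            for r in default_dataset.records
        ]
    )
    fit2 = fit_stratified_cox(doubled)
    assert fit2.se_log_hr == pytest.approx(
        fit1.se_log_hr / math.sqrt(2), rel=1e-3
    )
    assert fit2.hr == pytest.approx(fit1.hr, rel=0.02)
    lifelines = pytest.importorskip("lifelines")
    df = doubled.to_frame().assign(E=lambda d: d.lfs_event.astype(int))
    cph = lifelines.CoxPHFitter().fit(
        df[["arm", "lfs_time", "E", "country", "cr_status"]],
        "lfs_time", "E", strata=["country", "cr_status"], formula="arm",
    )
    assert -fit2.log_hr == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)


def test_arm_relabeling_inverts_hr(default_dataset):
    fit = fit_stratified_cox(default_dataset)
    flipped = TrialDataset(
        dataclasses.replace(r, arm=1 - r.arm) for r in default_dataset.records
    )
    fit_f = fit_stratified_cox(flipped)
    assert fit_f.hr == pytest.approx(1 / fit.hr, rel=1e-9)
    assert fit_f.z == pytest.approx(-fit.z, rel=1e-9)


def test_orientation_flag(default_dataset):
    benefit = fit_stratified_cox(default_dataset)
    conventional = fit_stratified_cox(default_dataset, orientation="conventional")
    assert conventional.hr == pytest.approx(1 / benefit.hr, rel=1e-12)
    assert conventional.se_log_hr == benefit.se_log_hr


def test_single_stratum_equals_unstratified(default_dataset):
    # every patient shares the same cr-independent constant stratum
    ds = TrialDataset(
        dataclasses.replace(r, covariates={**r.covariates, "one": "x"})
        for r in default_dataset.records
    )
    a = fit_stratified_cox(ds, strata=["one"])
    b = fit_stratified_cox(ds, strata=[])
    assert a.hr == pytest.approx(b.hr, rel=1e-12)
    assert a.se_log_hr == pytest.approx(b.se_log_hr, rel=1e-12)


def test_cox_agrees_with_lifelines_on_tied_data(default_dataset):
    lifelines = pytest.importorskip("lifelines")
    df = default_dataset.to_frame()
    df = df.assign(E=df.lfs_event.astype(int))
    cph = lifelines.CoxPHFitter().fit(
        df[["arm", "lfs_time", "E", "country", "cr_status"]],
        "lfs_time", "E", strata=["country", "cr_status"], formula="arm",
    )
    fit = fit_stratified_cox(default_dataset, orientation="conventional")
    assert fit.log_hr == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
    assert fit.se_log_hr == pytest.approx(
        float(cph.standard_errors_.iloc[0]), abs=1e-6
    )


def test_degenerate_strata_dropped_and_counted():
    recs = [make_patient(f"p{i}", i % 2, i + 1.0, 1, cr="CR1") for i in range(6)]
    # a CR>1 stratum holding only control patients: no information
    recs += [make_patient("x1", 0, 2.5, 1, cr="CR>1"),
             make_patient("x2", 0, 3.5, 0, cr="CR>1")]
    with_junk = fit_stratified_cox(TrialDataset(recs), strata=["cr_status"])
    clean = fit_stratified_cox(TrialDataset(recs[:6]), strata=["cr_status"])
    assert with_junk.degenerate_strata_dropped == 1
    assert with_junk.hr == pytest.approx(clean.hr, rel=1e-12)


def test_no_events_is_an_error():
    recs = [make_patient(f"p{i}", i % 2, 5.0 + i, 0) for i in range(4)]
    with pytest.raises(EstimationError, match="no lfs events"):
        fit_stratified_cox(TrialDataset(recs), strata=[])


def test_empty_arm_is_an_error():
    recs = [make_patient(f"p{i}", 1, 1.0 + i, 1) for i in range(4)]
    with pytest.raises(EstimationError, match="both arms"):
        fit_stratified_cox(TrialDataset(recs), strata=[])


def test_monotone_likelihood_detected_with_direction():
    # all events in the treated arm while controls remain at risk
    recs = [make_patient(f"t{i}", 1, 1.0 + i, 1) for i in range(3)]
    recs += [make_patient(f"c{i}", 0, 50.0 + i, 0) for i in range(3)]
    with pytest.raises(MonotoneLikelihoodError) as err:
        fit_stratified_cox(TrialDataset(recs), strata=[])
    assert err.value.direction == 1


# ---------------------------------------------------------------------------
# Stratified log-rank
# ---------------------------------------------------------------------------


def test_logrank_matches_hand_tabulation(two_stratum_dataset):
    lr = stratified_logrank(two_stratum_dataset, "lfs", strata=["cr_status"])
    ome, var = naive_logrank(two_stratum_dataset, "lfs", ("cr_status",))
    assert lr.statistic == pytest.approx(ome**2 / var, abs=1e-9)
    assert lr.observed_minus_expected_control == pytest.approx(-ome, abs=1e-12)
    assert lr.direction == int(np.sign(-ome))


def test_logrank_single_stratum_equals_unstratified(six_patient_dataset):
    a = stratified_logrank(six_patient_dataset, "lfs", strata=["country"])
    b = stratified_logrank(six_patient_dataset, "lfs", strata=[])
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_cox_z2_close_to_logrank_chi2(two_stratum_dataset, default_dataset):
    for ds, strata in [
        (two_stratum_dataset, ["cr_status"]),
        (default_dataset, ["country", "cr_status"]),
    ]:
        fit = fit_stratified_cox(ds, strata=strata)
        lr = stratified_logrank(ds, strata=strata)
        assert fit.z**2 == pytest.approx(lr.statistic, rel=0.10)


# ---------------------------------------------------------------------------
# Summary-level z
# ---------------------------------------------------------------------------


def test_z_from_summary_published_example():
    z = z_from_summary(1.43, 1.10, 1.87, ci_level=0.95)
    assert z == pytest.approx(2.64, abs=0.01)


def test_z_from_summary_null_and_errors():
    assert z_from_summary(1.0, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ConfigurationError, match="zero-width"):
        z_from_summary(2.0, 2.0, 2.0)
    with pytest.raises(ConfigurationError, match="positive"):
        z_from_summary(1.0, -0.1, 2.0)
    with pytest.raises(ConfigurationError, match="within"):
        z_from_summary(3.0, 1.0, 2.0)


def test_z_from_summary_inverts_wald_ci(default_dataset):
    fit = fit_stratified_cox(default_dataset)
    z = z_from_summary(fit.hr, fit.ci_low, fit.ci_high, fit.ci_level)
    assert z == pytest.approx(fit.z, rel=1e-9)
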