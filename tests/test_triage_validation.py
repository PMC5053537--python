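from datetime import date, timedelta

import numpy as np
import pytest

from bdzscreen.me_screening import screen_all
from bdzscreen.synthetic_data import SimConfig, _Builder, generate
from bdzscreen.triage_validation import (
    CLASSIFICATIONS,
    TriagePolicy,
    decisions_frame,
    triage,
    triage_batch,
)


def _interaction_stay(age=50, *, dose_mult=1.0, other_bdz=0,
                      respiratory=False, palliative=False, abuse=False,
                      liver=False):
    """One stay with a standard zolpidem + clarithromycin interaction day."""
    b = _Builder()
    pid = b.new_patient(date(2011, 6, 1) - timedelta(days=age * 366), "male")
    hid = b.new_hosp(pid, date(2011, 6, 1), date(2011, 6, 8),
                     palliative=palliative, abuse=abuse,
                     respiratory=respiratory, liver=liver)
    d = date(2011, 6, 4)
    b.give(pid, hid, d, "zolpidem", "N05CF02", 10.0 * dose_mult)
    b.give(pid, hid, d, "clarithromycin", "J01FA09", 500.0)
    extra = [("lorazepam", "N05BA06", 2.0), ("oxazepam", "N05BA04", 30.0)]
    for name, atc, dose in extra[:other_bdz]:
        b.give(pid, hid, d, name, atc, dose)
    return b.dataset(), hid


def _triage_one(dataset, hid, catalog, policy=None):
    result = screen_all(dataset, catalog)
    flags = [f for f in result.flags if f.hosp_id == hid]
    hosp = dataset.hospitalization(hid)
    return triage(hosp, flags, result.annotations, dataset, catalog,
                  policy or TriagePolicy())


def test_full_aggravated_case_is_validated(catalog):
    # standard dose + strong inhibitor + two other BDZ + respiratory
    # insufficiency, not palliative -> validated ME
    ds, hid = _interaction_stay(other_bdz=2, respiratory=True)
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "VALIDATED_ME"
    assert "multi_bdz" in d.aggravating_rules_fired
    assert "respiratory_insufficiency" in d.aggravating_rules_fired


def test_same_case_in_palliative_situation_is_no_me(catalog):
    ds, hid = _interaction_stay(other_bdz=2, respiratory=True,
                                palliative=True)
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "NO_ME"
    assert d.exclusion_rules_fired == ("palliative",)


def test_half_standard_dose_is_no_me(catalog):
    ds, hid = _interaction_stay(dose_mult=0.5)
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "NO_ME"
    assert "low_dose" in d.exclusion_rules_fired


def test_known_abuse_tolerates_even_massive_doses(catalog):
    ds, hid = _interaction_stay(dose_mult=51.0, abuse=True)  # 510 mg/day
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "NO_ME"
    assert "known_abuse" in d.exclusion_rules_fired


def test_no_exclusion_no_aggravator_needs_review(catalog):
    ds, hid = _interaction_stay()
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "NEEDS_REVIEW"
    assert d.exclusion_rules_fired == ()
    assert d.aggravating_rules_fired == ()


def test_elderly_unreduced_initial_dose_aggravates(catalog):
    ds, hid = _interaction_stay(age=72)
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "VALIDATED_ME"
    assert d.aggravating_rules_fired == ("elderly_unreduced_dose",)
    # reduced initial dose: nothing aggravates
    ds2, hid2 = _interaction_stay(age=72, dose_mult=0.75)
    d2 = _triage_one(ds2, hid2, catalog)
    assert "elderly_unreduced_dose" not in d2.aggravating_rules_fired


def test_exclusion_dominates_any_aggravator_set(catalog):
    ds, hid = _interaction_stay(age=72, other_bdz=2, respiratory=True,
                                liver=True, palliative=True)
    d = _triage_one(ds, hid, catalog)
    assert d.classification == "NO_ME"


def test_triage_without_flags_is_an_error(catalog):
    ds, hid = _interaction_stay()
    result = screen_all(ds, catalog)
    with pytest.raises(ValueError):
        triage(ds.hospitalization(hid), [], result.annotations, ds, catalog)


def test_policy_with_all_aggravators_disabled_validates_nothing(catalog):
    cfg = SimConfig(seed=77, n_patients=50)
    dataset, _ = generate(cfg, catalog)
    result = screen_all(dataset, catalog)
    policy = TriagePolicy(multi_bdz=False, respiratory_insufficiency=False,
                          severe_liver_disease=False,
                          elderly_unreduced_dose=False)
    decisions, _ = triage_batch(result, dataset, catalog, policy)
    assert decisions  # the spike-ins guarantee flagged hospitalizations
    assert all(d.classification != "VALIDATED_ME" for d in decisions)


def test_batch_partition_and_summary_counts(catalog, small_sim):
    (dataset, truth), _ = small_sim
    result = screen_all(dataset, catalog)
    decisions, summary = triage_batch(result, dataset, catalog)
    # exactly one decision per consenting flagged hospitalization
    consent = dict(zip(dataset.patients["patient_id"],
                       dataset.patients["research_consent"]))
    eligible = {
        f.hosp_id for f in result.flags
        if consent[dataset.hospitalization(f.hosp_id)["patient_id"]]
    }
    assert {d.hosp_id for d in decisions} == eligible
    assert len({d.hosp_id for d in decisions}) == len(decisions)
    all_row = summary[summary["mechanism"] == "all"].iloc[0]
    assert all_row["n_hospitalizations"] == len(decisions)
    assert sum(all_row[c] for c in CLASSIFICATIONS) == len(decisions)


def test_consent_withdrawn_excluded_entirely(catalog, vignette_data):
    dataset, ids = vignette_data
    result = screen_all(dataset, catalog)
    no_consent_hid = ids["no_consent_interaction"]
    assert any(f.hosp_id == no_consent_hid for f in result.flags)
    decisions, _ = triage_batch(result, dataset, catalog)
    assert no_consent_hid not in {d.hosp_id for d in decisions}


def test_spiked_truth_classifications_recovered(catalog, small_sim):
    (dataset, truth), _ = small_sim
    result = screen_all(dataset, catalog)
    decisions, _ = triage_batch(result, dataset, catalog)
    decided = {d.hosp_id: d.classification for d in decisions}
    for v in truth.violations:
        if v.intended_triage is None:
            continue  # elderly stream is not triaged
        assert decided[v.hosp_id] == v.intended_triage, v


def test_randomized_policy_fuzz_partition_and_dominance(catalog):
    # randomized policies and fixtures: partition always holds and
    # palliative always forces NO_ME
    rng = np.random.default_rng(2024)
    cfg = SimConfig(seed=909, n_patients=40)
    dataset, _ = generate(cfg, catalog)
    result = screen_all(dataset, catalog)
    for _ in range(10):
        policy = TriagePolicy(
            multi_bdz=bool(rng.integers(2)),
            respiratory_insufficiency=bool(rng.integers(2)),
            severe_liver_disease=bool(rng.integers(2)),
            elderly_unreduced_dose=bool(rng.integers(2)),
            low_dose=bool(rng.integers(2)),
            aggravator_threshold=int(rng.integers(1, 4)),
        )
        decisions, summary = triage_batch(result, dataset, catalog, policy)
        assert all(d.classification in CLASSIFICATIONS for d in decisions)
        for d in decisions:
            hosp = dataset.hospitalization(d.hosp_id)
            if hosp["palliative"]:
                assert d.classification == "NO_ME"
            if d.classification == "VALIDATED_ME":
                assert not d.exclusion_rules_fired
                assert len(d.aggravating_rules_fired) >= \
                    policy.aggravator_threshold


def test_decisions_frame_round_trip_columns(catalog, small_sim):
    (dataset, _), _ = small_sim
    result = screen_all(dataset, catalog)
    decisions, _ = triage_batch(result, dataset, catalog)
    df = decisions_frame(decisions)
    assert list(df["hosp_id"]) == [d.hosp_id for d in decisions]
    assert set(df["classification"]) <= set(CLASSIFICATIONS)
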