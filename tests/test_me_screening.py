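from datetime import date, datetime, time, timedelta

import pandas as pd
import pytest

from bdzscreen.ehr_model import expand_patient_days
from bdzscreen.me_screening import (
    annotate_risks,
    detect_cyp_ddi,
    detect_elderly_zolpidem,
    detect_lorazepam_renal,
    screen_all,
)
from bdzscreen.renal_function import UMOL_PER_L_TO_MG_PER_DL, attach_current_egfr
from bdzscreen.synthetic_data import SimConfig, _Builder, generate, scr_for_egfr
from oracles import brute_force_scan, production_flag_keys


def _stay(age=50, sex="male", days=10, start=date(2011, 6, 1)):
    b = _Builder()
    birth = date(start.year - age, 1, 1)
    pid = b.new_patient(birth, sex)
    hid = b.new_hosp(pid, start, start + timedelta(days=days - 1))
    return b, pid, hid, start


def _screen_parts(b, catalog):
    ds = b.dataset()
    pdays = expand_patient_days(ds)
    pdays = attach_current_egfr(pdays, ds.labs)
    return ds, pdays


class TestCypDdi:
    @pytest.mark.parametrize("offset,expect_flag", [(0, True), (1, True),
                                                    (2, True), (3, False)])
    def test_carryover_window_same_day_to_minus_two(self, catalog, offset,
                                                    expect_flag):
        b, pid, hid, start = _stay()
        day = start + timedelta(days=4)
        b.give(pid, hid, day, "zolpidem", "N05CF02", 10.0)
        b.give(pid, hid, day - timedelta(days=offset),
               "clarithromycin", "J01FA09", 500.0)
        ds, pdays = _screen_parts(b, catalog)
        flags = detect_cyp_ddi(pdays, ds.administrations, catalog)
        assert bool(flags) is expect_flag
        if expect_flag:
            assert flags[0].trigger_drugs == (("J01FA09", -offset),)

    def test_glucuronidation_only_drug_never_fires(self, catalog):
        b, pid, hid, start = _stay()
        day = start + timedelta(days=2)
        b.give(pid, hid, day, "lorazepam", "N05BA06", 2.0)
        b.give(pid, hid, day, "clarithromycin", "J01FA09", 500.0)
        ds, pdays = _screen_parts(b, catalog)
        assert detect_cyp_ddi(pdays, ds.administrations, catalog) == []

    def test_moderate_3a4_inhibitor_never_fires(self, catalog):
        b, pid, hid, start = _stay()
        day = start + timedelta(days=2)
        b.give(pid, hid, day, "zolpidem", "N05CF02", 10.0)
        b.give(pid, hid, day, "fluconazole", "J02AC01", 200.0)
        ds, pdays = _screen_parts(b, catalog)
        assert detect_cyp_ddi(pdays, ds.administrations, catalog) == []

    def test_prazepam_fires_on_moderate_2c19(self, catalog):
        b, pid, hid, start = _stay()
        day = start + timedelta(days=2)
        b.give(pid, hid, day, "prazepam", "N05BA11", 20.0)
        b.give(pid, hid, day, "fluconazole", "J02AC01", 200.0)
        ds, pdays = _screen_parts(b, catalog)
        flags = detect_cyp_ddi(pdays, ds.administrations, catalog)
        assert len(flags) == 1 and flags[0].bdz_atc == "N05BA11"
        # same-day only: moderate entries have no carryover
        b2, pid2, hid2, start2 = _stay()
        b2.give(pid2, hid2, start2 + timedelta(days=3),
                "prazepam", "N05BA11", 20.0)
        b2.give(pid2, hid2, start2 + timedelta(days=2),
                "fluconazole", "J02AC01", 200.0)
        ds2, pdays2 = _screen_parts(b2, catalog)
        assert detect_cyp_ddi(pdays2, ds2.administrations, catalog) == []

    def test_lookback_does_not_cross_hospitalizations(self, catalog):
        b = _Builder()
        pid = b.new_patient(date(1960, 1, 1), "male")
        h1 = b.new_hosp(pid, date(2011, 6, 1), date(2011, 6, 3))
        h2 = b.new_hosp(pid, date(2011, 6, 4), date(2011, 6, 8))
        b.give(pid, h1, date(2011, 6, 3), "clarithromycin", "J01FA09", 500.0)
        b.give(pid, h2, date(2011, 6, 4), "zolpidem", "N05CF02", 10.0)
        ds, pdays = _screen_parts(b, catalog)
        assert detect_cyp_ddi(pdays, ds.administrations, catalog) == []

    def test_one_flag_per_day_bdz_with_all_triggers_listed(self, catalog):
        b, pid, hid, start = _stay()
        day = start + timedelta(days=3)
        b.give(pid, hid, day, "zolpidem", "N05CF02", 10.0)
        b.give(pid, hid, day, "clarithromycin", "J01FA09", 500.0)
        b.give(pid, hid, day - timedelta(days=1), "itraconazole",
               "J02AC02", 200.0)
        ds, pdays = _screen_parts(b, catalog)
        flags = detect_cyp_ddi(pdays, ds.administrations, catalog)
        assert len(flags) == 1
        assert set(flags[0].trigger_drugs) == {("J01FA09", 0),
                                               ("J02AC02", -1)}


class TestLorazepamRenal:
    def _renal_stay(self, egfr_target, age=60, sex="male"):
        b, pid, hid, start = _stay(age=age, sex=sex)
        scr = scr_for_egfr(egfr_target, age, sex)
        b.lab(pid, datetime.combine(start + timedelta(days=2), time(8, 0)),
              scr * UMOL_PER_L_TO_MG_PER_DL)
        return b, pid, hid, start

    def test_consecutive_days_both_flagged(self, catalog):
        b, pid, hid, start = self._renal_stay(18.0)
        d = start + timedelta(days=3)
        for day in (d, d + timedelta(days=1)):
            b.give(pid, hid, day, "lorazepam", "N05BA06", 2.0)
        ds, pdays = _screen_parts(b, catalog)
        flags = detect_lorazepam_renal(pdays, ds.administrations, catalog)
        assert {f.day for f in flags} == {d, d + timedelta(days=1)}
        assert all(f.egfr is not None and f.egfr < 30 for f in flags)

    def test_single_day_without_qualifier_not_flagged(self, catalog):
        b, pid, hid, start = self._renal_stay(25.0)
        b.give(pid, hid, start + timedelta(days=3), "lorazepam",
               "N05BA06", 2.0)
        ds, pdays = _screen_parts(b, catalog)
        assert detect_lorazepam_renal(pdays, ds.administrations,
                                      catalog) == []

    def test_boundary_strictly_below_30_with_other_bdz(self, catalog):
        # eGFR 29.9 qualifies via the multi-BDZ arm; 30.0 does not
        age, sex = 60, "male"
        for target, expect in ((29.8, True), (30.2, False)):
            b, pid, hid, start = self._renal_stay(target, age, sex)
            d = start + timedelta(days=3)
            b.give(pid, hid, d, "lorazepam", "N05BA06", 2.0)
            b.give(pid, hid, d, "midazolam", "N05CD08", 7.5)
            ds, pdays = _screen_parts(b, catalog)
            flags = detect_lorazepam_renal(pdays, ds.administrations, catalog)
            assert bool(flags) is expect, (target, flags)

    def test_no_current_egfr_never_flags(self, catalog):
        b, pid, hid, start = _stay()
        d = start + timedelta(days=3)
        for day in (d, d + timedelta(days=1)):
            b.give(pid, hid, day, "lorazepam", "N05BA06", 2.0)
        ds, pdays = _screen_parts(b, catalog)  # no labs at all
        assert detect_lorazepam_renal(pdays, ds.administrations,
                                      catalog) == []


class TestElderlyZolpidem:
    @pytest.mark.parametrize(
        "age,doses,expect",
        [
            (70, [10.0], True),
            (64, [10.0], False),       # age boundary
            (70, [5.0, 5.0], True),    # daily-sum semantics
            (70, [5.0], False),
            (65, [10.0], True),        # inclusive age threshold
        ],
    )
    def test_dose_and_age_thresholds(self, catalog, age, doses, expect):
        b, pid, hid, start = _stay(age=age)
        day = start + timedelta(days=1)
        for dose in doses:
            b.give(pid, hid, day, "zolpidem", "N05CF02", dose)
        ds, pdays = _screen_parts(b, catalog)
        flags = detect_elderly_zolpidem(pdays, ds.administrations, catalog)
        assert bool(flags) is expect

    def test_kept_out_of_potential_me_stream(self, catalog):
        b, pid, hid, start = _stay(age=80)
        b.give(pid, hid, start, "zolpidem", "N05CF02", 10.0)
        result = screen_all(b.dataset(), catalog)
        assert result.flags == []
        assert len(result.elderly_flags) == 1


class TestAnnotations:
    def test_counting_bdz_opioids_relaxants(self, catalog):
        b, pid, hid, start = _stay()
        d = start + timedelta(days=2)
        b.give(pid, hid, d, "lorazepam", "N05BA06", 2.0)
        b.give(pid, hid, d, "zolpidem", "N05CF02", 10.0)
        b.give(pid, hid, d, "morphine", "N02AA01", 10.0)
        ds, pdays = _screen_parts(b, catalog)
        ann = annotate_risks(pdays, ds.administrations, catalog)
        row = ann[ann["day"] == d].iloc[0]
        assert row["n_distinct_bdz"] == 2
        assert row["n_opioids"] == 1
        assert not row["muscle_relaxant"]
        # drug-free day: all zero
        empty = ann[ann["day"] == start].iloc[0]
        assert empty["n_distinct_bdz"] == 0 and empty["n_opioids"] == 0

    def test_five_distinct_bdz_and_extra_inhibitors(self, catalog):
        b, pid, hid, start = _stay()
        d = start + timedelta(days=2)
        for name, atc in [("lorazepam", "N05BA06"), ("diazepam", "N05BA01"),
                          ("zolpidem", "N05CF02"), ("midazolam", "N05CD08"),
                          ("oxazepam", "N05BA04")]:
            b.give(pid, hid, d, name, atc, 1.0)
        b.give(pid, hid, d, "ciprofloxacin", "J01MA02", 500.0)
        ds, pdays = _screen_parts(b, catalog)
        ann = annotate_risks(pdays, ds.administrations, catalog)
        row = ann[ann["day"] == d].iloc[0]
        assert row["n_distinct_bdz"] == 5
        assert row["extra_inhibitors"] == "CYP1A2"


class TestScreenAll:
    def test_clean_dataset_zero_flags(self, catalog):
        b, pid, hid, start = _stay()
        b.give(pid, hid, start, "lorazepam", "N05BA06", 2.0)
        result = screen_all(b.dataset(), catalog)
        assert result.flags == [] and result.elderly_flags == []

    def test_row_order_permutation_invariant(self, catalog, small_sim):
        (dataset, _), _ = small_sim
        shuffled = dataset.administrations.sample(
            frac=1.0, random_state=99
        ).reset_index(drop=True)
        from bdzscreen.ehr_model import Dataset
        ds2 = Dataset(dataset.patients, dataset.hospitalizations, shuffled,
                      dataset.labs)
        r1 = screen_all(dataset, catalog)
        r2 = screen_all(ds2, catalog)
        assert r1.flags == r2.flags
        assert r1.elderly_flags == r2.elderly_flags

    def test_mechanism_toggle_drops_only_that_stream(self, catalog,
                                                     small_sim):
        (dataset, _), _ = small_sim
        r = screen_all(dataset, catalog,
                       mechanisms=["lorazepam_renal", "flumazenil_surrogate"])
        assert all(f.mechanism != "cyp_ddi" for f in r.flags)
        assert r.elderly_flags == []

    def test_flags_never_reference_undispensed_drugs(self, catalog,
                                                     small_sim):
        (dataset, _), _ = small_sim
        result = screen_all(dataset, catalog)
        given = set(zip(dataset.administrations["hosp_id"],
                        dataset.administrations["day"],
                        dataset.administrations["atc_code"]))
        for f in result.flags:
            for atc, off in f.trigger_drugs:
                day = f.day + timedelta(days=off)
                assert (f.hosp_id, day, atc) in given


class TestOracleEquivalence:
    def test_vignette_fixture_matches_brute_force(self, catalog,
                                                  vignette_data):
        dataset, _ = vignette_data
        assert production_flag_keys(screen_all(dataset, catalog)) == \
            brute_force_scan(dataset, catalog)

    def test_generated_dataset_matches_brute_force(self, catalog):
        cfg = SimConfig(seed=424201, n_patients=200)
        dataset, _ = generate(cfg, catalog)
        assert production_flag_keys(screen_all(dataset, catalog)) == \
            brute_force_scan(dataset, catalog)

    def test_adding_an_inhibitor_is_monotone(self, catalog, tmp_path):
        import yaml
        from bdzscreen.reference_catalog import load_catalog
        cfg = SimConfig(seed=5150, n_patients=40)
        dataset, _ = generate(cfg, catalog)
        base = {(f.hosp_id, f.day, f.mechanism, f.bdz_atc)
                for f in screen_all(dataset, catalog).flags}
        user = tmp_path / "more.yaml"
        # promote a background filler drug to a strong inhibitor
        user.write_text(yaml.safe_dump({"inhibitors": [
            {"drug_name": "pantoprazole", "atc_code": "A02BC02",
             "pathway": "CYP3A4", "strength": "strong", "carryover_days": 2},
        ]}))
        bigger = load_catalog(user)
        extended = {(f.hosp_id, f.day, f.mechanism, f.bdz_atc)
                    for f in screen_all(dataset, bigger).flags}
        assert base <= extended
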