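"""Dataset I/O, the renal covariate formula, screening and toxicity rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lznpk as L
from lznpk.dataio import LLOQ_MG_L


class TestCockcroftGault:
    @pytest.mark.parametrize(
        "age, wt, scr, sex, expected",
        [
            (40.0, 70.0, 88.4, L.Sex.MALE, 97.22),
            (40.0, 70.0, 88.4, L.Sex.FEMALE, 82.64),
            (140.0, 70.0, 88.4, L.Sex.MALE, 0.0),
        ],
    )
    def test_formula(self, age, wt, scr, sex, expected):
        assert L.cockcroft_gault(age, wt, scr, sex) == pytest.approx(
            expected, abs=5e-3)

    @pytest.mark.parametrize("kw", [dict(scr_umol_l=0.0), dict(weight=0.0)])
    def test_nonpositive_inputs_rejected(self, kw):
        args = dict(age=40.0, weight=70.0, scr_umol_l=88.4, sex=L.Sex.MALE)
        args.update(kw)
        with pytest.raises(ValueError):
            L.cockcroft_gault(**args)


class TestReadWrite:
    def test_dose_duration_from_rate(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "ID,TIME,AMT,RATE,DV,EVID,MDV\n"
            "1,0,600,600,.,1,1\n"
            "1,11.8,.,.,4.2,0,0\n"
        )
        cohort = L.read_dataset(path)
        d = cohort.patients[0].doses[0]
        assert d.amount == 600.0
        assert d.duration == pytest.approx(1.0)

    def test_round_trip_identity(self, tmp_path, two_patient_cohort):
        pk, oc = tmp_path / "pk.csv", tmp_path / "oc.csv"
        L.write_dataset(two_patient_cohort, pk, outcomes_path=oc)
        back = L.read_dataset(pk, outcomes_path=oc)
        assert len(back) == 2
        for orig, rt in zip(two_patient_cohort, back):
            assert orig.id == rt.id and orig.sex == rt.sex
            assert rt.crcl == pytest.approx(orig.crcl, rel=1e-5)
            assert len(rt.doses) == len(orig.doses)
            assert len(rt.observations) == len(orig.observations)
            for a, b in zip(orig.observations, rt.observations):
                assert b.time == pytest.approx(a.time, rel=1e-5)
                assert b.concentration == pytest.approx(a.concentration, rel=1e-5)
                assert b.kind == a.kind
            assert rt.outcome == orig.outcome
            assert rt.censored == orig.censored
        # second round trip is bit-identical at the written precision
        pk2 = tmp_path / "pk2.csv"
        L.write_dataset(back, pk2)
        first = pk.read_text().splitlines()
        second = pk2.read_text().splitlines()
        assert first == second

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME,AMT,RATE,EVID,MDV\n1,0,600,600,1,1\n")
        with pytest.raises(ValueError, match="DV"):
            L.read_dataset(path)

    def test_observation_missing_dv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "ID,TIME,AMT,RATE,DV,EVID,MDV\n1,0,600,600,.,1,1\n1,5,.,.,.,0,0\n")
        with pytest.raises(ValueError, match="missing DV"):
            L.read_dataset(path)

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "ID,TIME,AMT,RATE,DV,EVID,MDV\n1,12,600,600,.,1,1\n1,0,600,600,.,1,1\n")
        with pytest.raises(ValueError, match="TIME"):
            L.read_dataset(path)

    def test_bql_flagged(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "ID,TIME,AMT,RATE,DV,EVID,MDV\n"
            "1,0,600,600,.,1,1\n"
            "1,11.8,.,.,0.05,0,0\n"
        )
        cohort = L.read_dataset(path)
        o = cohort.patients[0].observations[0]
        assert o.bql and o.concentration < LLOQ_MG_L
        assert cohort.patients[0].fit_observations() == []


class TestScreening:
    def _record(self, sex=L.Sex.MALE, plt=232.0, hb=99.0, anc=4000.0,
                tbil=1.0, days=8.0):
        doses = [L.DoseEvent(time=12.0 * j, amount=600.0)
                 for j in range(int(days * 2))]
        hema = L.Hematology(baseline_plt=plt, nadir_plt=plt,
                            baseline_hb=hb, nadir_hb=hb,
                            baseline_anc=anc, baseline_tbil_xuln=tbil)
        return L.PatientRecord(id=1, sex=sex, crcl=65.0, doses=doses,
                               hematology=hema)

    def test_all_criteria_pass(self):
        eligible, reasons = L.screen_eligibility(self._record())
        assert eligible and reasons == []

    @pytest.mark.parametrize(
        "kw, reason",
        [
            (dict(plt=74.0), "PLT"),
            (dict(hb=67.0), "Hb"),                       # male floor 6.8 g/dL
            (dict(sex=L.Sex.FEMALE, hb=59.0), "Hb"),     # female floor 6 g/dL
            (dict(anc=499.0), "ANC"),
            (dict(tbil=5.1), "TBIL"),
            (dict(days=2.0), "duration"),
        ],
    )
    def test_each_exclusion(self, kw, reason):
        eligible, reasons = L.screen_eligibility(self._record(**kw))
        assert not eligible and reason in reasons

    def test_female_hb_floor_is_lower(self):
        ok, _ = L.screen_eligibility(self._record(sex=L.Sex.FEMALE, hb=62.0))
        assert ok  # 6.2 g/dL excludes males but not females

    def test_missing_hematology_unassessable(self):
        rec = L.PatientRecord(id=1, crcl=65.0)
        eligible, reasons = L.screen_eligibility(rec)
        assert not eligible and "unassessable" in reasons[0]


class TestClassification:
    @pytest.mark.parametrize(
        "plt0, plt1, hb0, hb1, expected",
        [
            (232.0, 120.0, 99.0, 95.0, L.Outcome.THROMBOCYTOPENIA),
            (150.0, 120.0, 99.0, 95.0, L.Outcome.NONE),   # 20% drop only
            (232.0, 220.0, 99.0, 70.0, L.Outcome.ANEMIA),  # 29.3% Hb drop
            (232.0, 174.0, 99.0, 95.0, L.Outcome.NONE),   # 25% drop, >=125
            (232.0, 120.0, 99.0, 70.0, L.Outcome.BOTH),
            (232.0, 174.1, 99.0, 95.0, L.Outcome.NONE),
        ],
    )
    def test_rules(self, plt0, plt1, hb0, hb1, expected):
        h = L.Hematology(baseline_plt=plt0, nadir_plt=plt1,
                         baseline_hb=hb0, nadir_hb=hb1)
        assert L.classify_myelosuppression(h) == expected

    def test_boundary_25pct_drop_inclusive(self):
        # exactly 25% drop, nadir below 125 -> thrombocytopenia
        h = L.Hematology(baseline_plt=160.0, nadir_plt=120.0,
                         baseline_hb=99.0, nadir_hb=99.0)
        assert L.classify_myelosuppression(h) == L.Outcome.THROMBOCYTOPENIA

    def test_zero_baseline_rejected(self):
        h = L.Hematology(baseline_plt=0.0, nadir_plt=0.0,
                         baseline_hb=99.0, nadir_hb=99.0)
        with pytest.raises(ValueError):
            L.classify_myelosuppression(h)

    @given(
        st.floats(80.0, 600.0), st.floats(10.0, 600.0),
        st.floats(70.0, 170.0), st.floats(30.0, 170.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_literal_rule_oracle(self, plt0, plt1, hb0, hb1):
        plt1, hb1 = min(plt0, plt1), min(hb0, hb1)
        h = L.Hematology(baseline_plt=plt0, nadir_plt=plt1,
                         baseline_hb=hb0, nadir_hb=hb1)
        thrombo = plt1 < 125.0 and (plt0 - plt1) / plt0 >= 0.25
        anemia = (hb0 - hb1) / hb0 >= 0.25
        expected = {(False, False): L.Outcome.NONE,
                    (True, False): L.Outcome.THROMBOCYTOPENIA,
                    (False, True): L.Outcome.ANEMIA,
                    (True, True): L.Outcome.BOTH}[(thrombo, anemia)]
        assert L.classify_myelosuppression(h) == expected

    @given(st.floats(80.0, 600.0), st.floats(10.0, 600.0),
           st.floats(1.0, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_nadir(self, plt0, plt1, lower_by):
        plt1 = min(plt0, plt1)
        h_hi = L.Hematology(baseline_plt=plt0, nadir_plt=plt1,
                            baseline_hb=99.0, nadir_hb=99.0)
        h_lo = L.Hematology(baseline_plt=plt0,
                            nadir_plt=max(plt1 - lower_by, 0.0),
                            baseline_hb=99.0, nadir_hb=99.0)
        if L.classify_myelosuppression(h_hi) == L.Outcome.THROMBOCYTOPENIA:
            assert L.classify_myelosuppression(h_lo) == \
                L.Outcome.THROMBOCYTOPENIA
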