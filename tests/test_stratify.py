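"""Exclusions, radiotherapy subgroup, guidelines risk and integrated tiers."""

import numpy as np
import pandas as pd
import pytest

from cinrisk import (RuleTable, apply_exclusions, assign_guidelines_risk,
                     assign_integrated_risk, assign_radiotherapy_subgroup,
                     default_rule_table, stratify_table)
from conftest import make_record


def _expected_subgroup(histotype, grade, stage_sub, age):
    if histotype != "EEC":
        return "EBRT"
    if grade <= 2:
        if stage_sub == "IA":
            return "OB"
        return "OB" if age < 60 else "VBT"
    return "EBRT" if stage_sub == "IB" else "VBT"


def _expected_guidelines(histotype, grade, stage_sub):
    if histotype != "EEC" or (stage_sub == "IB" and grade == 3):
        return "high"
    if grade == 3:
        return "high-intermediate"
    return "intermediate" if stage_sub == "IB" else "low"


ALL_COMBOS = [(h, g, s, a)
              for h in ("EEC", "non-EEC")
              for g in (1, 2, 3)
              for s in ("IA", "IB")
              for a in (55, 65)]


class TestSubgroupClassifier:
    @pytest.mark.parametrize("histotype,grade,stage_sub,age", ALL_COMBOS)
    def test_exhaustive_truth_table(self, histotype, grade, stage_sub, age):
        rec = make_record(histotype=histotype, grade=grade,
                          stage_sub=stage_sub, age=age)
        assert assign_radiotherapy_subgroup(rec) == _expected_subgroup(
            histotype, grade, stage_sub, age)

    def test_canonical_examples(self):
        assert assign_radiotherapy_subgroup(make_record(grade=1, age=55)) == "OB"
        assert assign_radiotherapy_subgroup(
            make_record(grade=3, stage_sub="IB")) == "EBRT"
        assert assign_radiotherapy_subgroup(make_record(grade=3)) == "VBT"

    def test_age_exactly_60_goes_vbt(self):
        rec = make_record(grade=2, stage_sub="IB", age=60)
        assert assign_radiotherapy_subgroup(rec) == "VBT"

    def test_non_stage_i_rejected(self):
        rec = make_record(figo_stage="III")
        with pytest.raises(ValueError, match="stage I"):
            assign_radiotherapy_subgroup(rec)
        rec2 = make_record(stage_sub="II")
        with pytest.raises(ValueError, match="IA or IB"):
            assign_guidelines_risk(rec2)


class TestGuidelinesRisk:
    @pytest.mark.parametrize("histotype,grade,stage_sub,age", ALL_COMBOS)
    def test_full_mapping(self, histotype, grade, stage_sub, age):
        rec = make_record(histotype=histotype, grade=grade,
                          stage_sub=stage_sub, age=age)
        assert assign_guidelines_risk(rec) == _expected_guidelines(
            histotype, grade, stage_sub)

    def test_structural_zeros_on_synthetic_cohort(self, default_cohort):
        """Low appears only in OB, high-intermediate only in VBT, high only
        in EBRT, on any cohort."""
        clinical, _, _ = default_cohort
        kept, _ = apply_exclusions(clinical)
        sub = [assign_radiotherapy_subgroup(r) for _, r in kept.iterrows()]
        risk = [assign_guidelines_risk(r) for _, r in kept.iterrows()]
        tab = pd.crosstab(pd.Series(risk, name="risk"),
                          pd.Series(sub, name="subgroup"))
        for r, allowed in [("low", {"OB"}), ("high-intermediate", {"VBT"}),
                           ("high", {"EBRT"})]:
            if r in tab.index:
                nonzero = set(tab.columns[tab.loc[r] > 0])
                assert nonzero <= allowed, (r, nonzero)
        # intermediate splits across OB and VBT only
        if "intermediate" in tab.index:
            assert set(tab.columns[tab.loc["intermediate"] > 0]) <= {"OB", "VBT"}


class TestExclusions:
    def test_positive_margins_excluded(self):
        table = pd.DataFrame([make_record(positive_margins=1),
                              make_record()]).reset_index(drop=True)
        kept, audit = apply_exclusions(table)
        assert len(kept) == 1
        assert audit["positive_margins"] == 1

    def test_clean_record_retained(self):
        table = pd.DataFrame([make_record()])
        kept, audit = apply_exclusions(table)
        assert len(kept) == 1
        assert sum(audit.values()) == 0

    def test_missing_grade_counted(self):
        rows = [make_record() for _ in range(7)]
        for i in range(3):
            rows[i] = make_record(grade=np.nan)
        kept, audit = apply_exclusions(pd.DataFrame(rows).reset_index(drop=True))
        assert audit["missing_fields"] == 3
        assert len(kept) == 4

    def test_first_reason_wins(self):
        rec = make_record(grade=np.nan, other_malignancy=1, positive_margins=1)
        _, audit = apply_exclusions(pd.DataFrame([rec]))
        assert audit == {"missing_fields": 1, "other_malignancy": 0,
                         "positive_margins": 0}


CUTOFFS = {"OB": 0.0, "VBT": 0.0, "EBRT": 0.0}


def _scores(cin25=0.0, cin70=0.0):
    return pd.Series({"cin25": cin25, "cin70": cin70})


class TestIntegratedRisk:
    def test_ob_pole_mutant_low_regardless_of_score(self):
        rec = make_record(grade=1, pole=1)
        res = assign_integrated_risk(rec, _scores(cin70=5.0), CUTOFFS)
        assert res.integrated_risk == "low"
        assert res.recommended_treatment == "OB"

    def test_ob_wildtype_dichotomized_by_cin70(self):
        rec = make_record(grade=1)
        low = assign_integrated_risk(rec, _scores(cin70=-0.5), CUTOFFS)
        high = assign_integrated_risk(rec, _scores(cin70=0.5), CUTOFFS)
        assert low.integrated_risk == "low"
        assert high.integrated_risk == "intermediate"
        assert low.signature_used == "CIN70"

    def test_tie_at_cutoff_goes_low(self):
        rec = make_record(grade=1)
        res = assign_integrated_risk(rec, _scores(cin70=0.0), CUTOFFS)
        assert res.signature_level == "Low"

    def test_ob_ctnnb1_mutant_shifted_up(self):
        rec = make_record(grade=1, ctnnb1=1)
        low = assign_integrated_risk(rec, _scores(cin70=-1), CUTOFFS)
        high = assign_integrated_risk(rec, _scores(cin70=1), CUTOFFS)
        assert low.integrated_risk == "intermediate"
        assert high.integrated_risk == "high"

    def test_vbt_uses_cin25(self):
        rec = make_record(grade=3)  # IA G3 -> VBT
        assert assign_radiotherapy_subgroup(rec) == "VBT"
        res = assign_integrated_risk(rec, _scores(cin25=1.0, cin70=-9), CUTOFFS)
        assert res.signature_used == "CIN25"
        assert res.integrated_risk == "high"
        pole = assign_integrated_risk(make_record(grade=3, pole=1),
                                      _scores(cin25=9), CUTOFFS)
        assert pole.integrated_risk == "low"

    def test_ebrt_ctnnb1_mutant_ultrahigh(self):
        rec = make_record(grade=3, stage_sub="IB", ctnnb1=1)
        res = assign_integrated_risk(rec, _scores(cin25=-9), CUTOFFS)
        assert res.integrated_risk == "ultrahigh"
        assert res.recommended_treatment == "EBRT+systemic"

    def test_ebrt_wildtype_levels(self):
        rec = make_record(grade=3, stage_sub="IB")
        low = assign_integrated_risk(rec, _scores(cin25=-1), CUTOFFS)
        high = assign_integrated_risk(rec, _scores(cin25=1), CUTOFFS)
        assert low.integrated_risk == "high"
        assert high.integrated_risk == "ultrahigh"
        pole = assign_integrated_risk(
            make_record(grade=3, stage_sub="IB", pole=1), _scores(cin25=9),
            CUTOFFS)
        assert pole.integrated_risk == "high"

    def test_non_eec_gets_no_tier(self):
        rec = make_record(histotype="non-EEC", grade=3)
        res = assign_integrated_risk(rec, _scores(), CUTOFFS)
        assert res.integrated_risk == ""
        assert res.subgroup == "EBRT"
        assert res.guidelines_risk == "high"

    def test_rule_trace_records_predicates(self):
        res = assign_integrated_risk(make_record(grade=1), _scores(cin70=1),
                                     CUTOFFS)
        assert any("matched" in line for line in res.rule_trace)
        assert any("CIN70" in line for line in res.rule_trace)

    def test_missing_cutoff_raises(self):
        with pytest.raises(KeyError, match="cutoff"):
            assign_integrated_risk(make_record(grade=1), _scores(),
                                   {"OB": None, "VBT": 0, "EBRT": 0})


class TestRuleTable:
    def test_default_validates_and_round_trips(self, tmp_path):
        rt = default_rule_table()
        p = tmp_path / "rules.yaml"
        rt.to_yaml(p)
        rt2 = RuleTable.from_yaml(p)
        assert rt2.rules == rt.rules
        assert rt2.signature_by_subgroup == rt.signature_by_subgroup

    def test_non_exhaustive_table_rejected(self):
        rt = default_rule_table()
        rt.rules["VBT"] = [{"when": {"pole_mut": True}, "tier": "low"}]
        with pytest.raises(ValueError, match="no rule covers"):
            rt.validate()

    def test_unknown_tier_rejected(self):
        rt = default_rule_table()
        rt.rules["OB"][0]["tier"] = "extreme"
        with pytest.raises(ValueError, match="unknown tier"):
            rt.validate()


def test_stratify_table_partition(default_cohort):
    """Every non-excluded stage I record gets exactly one subgroup, one
    guidelines risk, and (for EEC) one tier."""
    clinical, _, _ = default_cohort
    kept, _ = apply_exclusions(clinical)
    kept = kept.head(300)
    scores = pd.DataFrame({"cin25": 0.1, "cin70": -0.1},
                          index=kept.index)
    out = stratify_table(kept, scores, CUTOFFS)
    assert len(out) == len(kept)
    assert set(out["subgroup"]) <= {"OB", "VBT", "EBRT"}
    eec = out.loc[kept["histotype"] == "EEC"]
    assert (eec["integrated_risk"].isin(["low", "intermediate", "high",
                                         "ultrahigh"])).all()
    assert (out.loc[kept["histotype"] != "EEC", "integrated_risk"] == "").all()
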