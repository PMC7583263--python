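"""Rule engines for stage I endometrial-carcinoma risk stratification.

Three deterministic classifiers operate on a cleaned clinical table:

* the five-factor adjuvant-radiotherapy subgroup (observation OB, vaginal
  brachytherapy VBT, external-beam radiotherapy EBRT) from histotype,
  grade, stage IA/IB (myometrial invasion) and age;
* the guidelines risk group (low / intermediate / high-intermediate / high);
* the integrated four-tier model (low / intermediate / high / ultrahigh)
  combining the subgroup, POLE/CTNNB1 mutation status and a dichotomized
  CIN signature score, driven by a configurable, ordered rule table.

Every integrated assignment carries a rule trace listing the predicates
evaluated, and cutoffs are inputs — they are never derived here, so the
engines are pure functions of their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RuleTable",
    "StratificationResult",
    "apply_exclusions",
    "assign_radiotherapy_subgroup",
    "assign_guidelines_risk",
    "assign_integrated_risk",
    "stratify_table",
    "default_rule_table",
    "TREATMENT_BY_TIER",
]

REQUIRED_FIELDS = ("histotype", "grade", "stage_sub", "age",
                   "dfs_time", "dfs_event", "os_time", "os_event")
TIERS = ("low", "intermediate", "high", "ultrahigh")
TREATMENT_BY_TIER = {"low": "OB", "intermediate": "VBT",
                     "high": "EBRT", "ultrahigh": "EBRT+systemic"}


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records unusable for classification or survival analysis.

    Checks fire in a fixed order per record — incomplete/invalid fields,
    then other malignancy, then positive surgical margins — and the first
    failing reason is the one counted in the audit log.
    """
    audit = {"missing_fields": 0, "other_malignancy": 0, "positive_margins": 0}
    keep = []
    for pid, rec in table.iterrows():
        if _incomplete(rec):
            audit["missing_fields"] += 1
        elif bool(rec.get("other_malignancy", 0)):
            audit["other_malignancy"] += 1
        elif bool(rec.get("positive_margins", 0)):
            audit["positive_margins"] += 1
        else:
            keep.append(pid)
    return table.loc[keep], audit


def _incomplete(rec: pd.Series) -> bool:
    for f in REQUIRED_FIELDS:
        if f not in rec or pd.isna(rec[f]):
            return True
    if rec["histotype"] not in ("EEC", "non-EEC"):
        return True
    if int(rec["grade"]) not in (1, 2, 3):
        return True
    if rec["stage_sub"] not in ("IA", "IB"):
        return True
    return False


def _check_stage_i(rec: pd.Series) -> None:
    stage = rec.get("figo_stage")
    if stage is not None and not pd.isna(stage):
        if str(stage).upper() not in ("I", "IA", "IB"):
            raise ValueError(f"only FIGO stage I is classified, got {stage!r}")
    if rec["stage_sub"] not in ("IA", "IB"):
        raise ValueError(f"stage_sub must be IA or IB, got {rec['stage_sub']!r}")


def assign_radiotherapy_subgroup(rec: pd.Series) -> str:
    """Five-factor adjuvant-radiotherapy subgroup for a stage I record.

    OB:   IA endometrioid (EEC) grade 1-2, or IB EEC grade 1-2 under age 60.
    EBRT: IB EEC grade 3, or any stage I non-endometrioid carcinoma.
    VBT:  the remainder — IB EEC grade 1-2 at age >= 60, or IA EEC grade 3.

    Age exactly 60 follows the >= 60 stratum, hence the VBT branch.
    """
    _check_stage_i(rec)
    eec = rec["histotype"] == "EEC"
    grade = int(rec["grade"])
    ib = rec["stage_sub"] == "IB"
    if not eec:
        return "EBRT"
    if grade <= 2:
        if not ib:
            return "OB"
        return "OB" if float(rec["age"]) < 60 else "VBT"
    return "EBRT" if ib else "VBT"


def assign_guidelines_risk(rec: pd.Series) -> str:
    """Guidelines risk group for a stage I record.

    low = IA EEC grade 1-2; intermediate = IB EEC grade 1-2;
    high-intermediate = IA EEC grade 3; high = IB EEC grade 3 or non-EEC.
    """
    _check_stage_i(rec)
    eec = rec["histotype"] == "EEC"
    grade = int(rec["grade"])
    ib = rec["stage_sub"] == "IB"
    if not eec or (ib and grade == 3):
        return "high"
    if grade == 3:
        return "high-intermediate"
    return "intermediate" if ib else "low"


@dataclass
class RuleTable:
    """Ordered predicate -> tier rules per radiotherapy subgroup.

    ``signature_by_subgroup`` names the CIN signature dichotomized in each
    subgroup; each rule is ``{"when": {field: value, ...}, "tier": tier}``
    where fields are ``pole_mut``, ``ctnnb1_mut`` and ``level`` (the
    dichotomized signature level, "Low"/"High").  The first matching rule
    wins; a table must be exhaustive for every (pole, ctnnb1, level) cell.
    """

    signature_by_subgroup: dict[str, str]
    rules: dict[str, list[dict]]

    def validate(self) -> None:
        for sg, sig in self.signature_by_subgroup.items():
            if sig not in ("CIN25", "CIN70"):
                raise ValueError(f"{sg}: unknown signature {sig!r}")
        for sg, rules in self.rules.items():
            for rule in rules:
                if rule["tier"] not in TIERS:
                    raise ValueError(f"{sg}: unknown tier {rule['tier']!r}")
                for k in rule["when"]:
                    if k not in ("pole_mut", "ctnnb1_mut", "level"):
                        raise ValueError(f"{sg}: unknown predicate field {k!r}")
            for pole in (True, False):
                for ct in (True, False):
                    for lv in ("Low", "High"):
                        ctx = {"pole_mut": pole, "ctnnb1_mut": ct, "level": lv}
                        if not any(_matches(r["when"], ctx) for r in rules):
                            raise ValueError(f"{sg}: no rule covers {ctx}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"signature_by_subgroup": self.signature_by_subgroup,
                            "rules": self.rules}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rt = cls(signature_by_subgroup=raw["signature_by_subgroup"],
                 rules=raw["rules"])
        rt.validate()
        return rt


def default_rule_table() -> RuleTable:
    """Default integrated-model rule table.

    CIN70 stratifies the OB subgroup and CIN25 the VBT/EBRT subgroups.
    POLE mutation takes precedence in OB/VBT (these patients had no
    events); CTNNB1 mutation takes precedence in EBRT, where it is the
    dominant adverse factor.
    """
    rt = RuleTable(
        signature_by_subgroup={"OB": "CIN70", "VBT": "CIN25", "EBRT": "CIN25"},
        rules={
            "OB": [
                {"when": {"pole_mut": True}, "tier": "low"},
                {"when": {"ctnnb1_mut": False, "level": "Low"}, "tier": "low"},
                {"when": {"ctnnb1_mut": False, "level": "High"}, "tier": "intermediate"},
                {"when": {"ctnnb1_mut": True, "level": "Low"}, "tier": "intermediate"},
                {"when": {"ctnnb1_mut": True, "level": "High"}, "tier": "high"},
            ],
            "VBT": [
                {"when": {"pole_mut": True}, "tier": "low"},
                {"when": {"level": "Low"}, "tier": "intermediate"},
                {"when": {"level": "High"}, "tier": "high"},
            ],
            "EBRT": [
                {"when": {"ctnnb1_mut": True}, "tier": "ultrahigh"},
                {"when": {"pole_mut": True}, "tier": "high"},
                {"when": {"level": "Low"}, "tier": "high"},
                {"when": {"level": "High"}, "tier": "ultrahigh"},
            ],
        },
    )
    rt.validate()
    return rt


def _matches(when: dict, ctx: dict) -> bool:
    return all(ctx[k] == v for k, v in when.items())


@dataclass
class StratificationResult:
    patient_id: str
    subgroup: str                      # OB | VBT | EBRT | EXCLUDED
    exclusion_reason: str = ""
    guidelines_risk: str = ""
    signature_used: str = ""
    signature_level: str = ""
    integrated_risk: str = ""          # empty for non-EEC / excluded
    recommended_treatment: str = ""
    rule_trace: list[str] = field(default_factory=list)


def assign_integrated_risk(rec: pd.Series, scores: pd.Series,
                           cutoffs: dict[str, float],
                           rules: RuleTable | None = None) -> StratificationResult:
    """Integrated four-tier risk for one stage I record.

    *scores* holds the patient's ``cin25``/``cin70`` values; *cutoffs* maps
    subgroup -> dichotomizing cutoff for that subgroup's signature.  Scores
    strictly above the cutoff are High; ties go Low.  Non-endometrioid
    records receive a subgroup and guidelines risk but no integrated tier.
    """
    rules = rules or default_rule_table()
    pid = str(rec.name) if rec.name is not None else str(rec.get("patient_id", ""))
    subgroup = assign_radiotherapy_subgroup(rec)
    g_risk = assign_guidelines_risk(rec)
    trace = [f"subgroup={subgroup}", f"guidelines_risk={g_risk}"]
    if rec["histotype"] != "EEC":
        trace.append("non-EEC: integrated tier not defined")
        return StratificationResult(patient_id=pid, subgroup=subgroup,
                                    guidelines_risk=g_risk, rule_trace=trace)

    sig = rules.signature_by_subgroup[subgroup]
    score_col = sig.lower()
    if score_col not in scores or pd.isna(scores[score_col]):
        raise KeyError(f"missing {sig} score for patient {pid}")
    if subgroup not in cutoffs or cutoffs[subgroup] is None:
        raise KeyError(f"missing {subgroup} cutoff for signature {sig}")
    cutoff = float(cutoffs[subgroup])
    score = float(scores[score_col])
    level = "High" if score > cutoff else "Low"
    trace.append(f"{sig}={score:.4f} vs cutoff {cutoff:.4f} -> {level}")

    ctx = {"pole_mut": bool(rec.get("pole_mut", 0)),
           "ctnnb1_mut": bool(rec.get("ctnnb1_mut", 0)),
           "level": level}
    tier = ""
    for i, rule in enumerate(rules.rules[subgroup]):
        hit = _matches(rule["when"], ctx)
        cond = " & ".join(f"{k}={v}" for k, v in rule["when"].items())
        trace.append(f"rule {i + 1} [{cond} -> {rule['tier']}]: "
                     f"{'matched' if hit else 'no match'}")
        if hit:
            tier = rule["tier"]
            break
    if not tier:
        raise ValueError(f"rule table for {subgroup} is not exhaustive: {ctx}")
    return StratificationResult(
        patient_id=pid, subgroup=subgroup, guidelines_risk=g_risk,
        signature_used=sig, signature_level=level, integrated_risk=tier,
        recommended_treatment=TREATMENT_BY_TIER[tier], rule_trace=trace,
    )


def stratify_table(clinical: pd.DataFrame, scores: pd.DataFrame,
                   cutoffs: dict[str, float],
                   rules: RuleTable | None = None) -> pd.DataFrame:
    """Apply the integrated model to every row of a cleaned clinical table."""
    rules = rules or default_rule_table()
    rows = []
    for pid, rec in clinical.iterrows():
        res = assign_integrated_risk(rec, scores.loc[pid], cutoffs, rules)
        rows.append({
            "patient_id": pid,
            "subgroup": res.subgroup,
            "guidelines_risk": res.guidelines_risk,
            "signature_used": res.signature_used,
            "signature_level": res.signature_level,
            "integrated_risk": res.integrated_risk,
            "recommended_treatment": res.recommended_treatment,
            "rule_trace": ";".join(res.rule_trace),
        })
    return pd.DataFrame(rows).set_index("patient_id")
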