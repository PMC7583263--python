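"""End-to-end orchestration: data -> scores -> subgroups -> cutoffs -> tiers.

The flow mirrors the intended clinical analysis: score CIN signatures on a
per-dataset Z-scored matrix; classify stage I patients into adjuvant
radiotherapy subgroups; derive each subgroup's dichotomizing cutoff by
time-dependent ROC on a mutation-excluded derivation set (POLE and CTNNB1
mutants out of OB, POLE mutants out of VBT, CTNNB1 mutants out of EBRT);
then tier *every* subgroup member with the integrated rule table, mutants
included — their tier comes from the mutation rules, not the cutoff.

All outputs are TSV/JSON in the output directory plus a run manifest with
the config echo, seed, package versions and row counts at every filter
step; identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .meta import forest_data, pool_fixed, smd_from_samples
from .scoring import (ExpressionMatrix, builtin_signature, load_signature,
                      score_table, zscore_normalize)
from .simulate import DEFAULT_SEED, SimConfig, generate_cohort
from .stratify import (RuleTable, apply_exclusions, assign_radiotherapy_subgroup,
                       default_rule_table, stratify_table)
from .survival import cox_fit, km_estimate, logrank_test, optimal_cutoff, td_roc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "derive_cutoffs", "load_clinical_table"]

#: Mutations dropped from each subgroup's cutoff-derivation set.
DEFAULT_CUTOFF_EXCLUSIONS = {
    "OB": ("pole_mut", "ctnnb1_mut"),
    "VBT": ("pole_mut",),
    "EBRT": ("ctnnb1_mut",),
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (simulate-or-load, never both)."""

    out_dir: str | Path = "cinrisk_out"
    seed: int = DEFAULT_SEED
    simulation: SimConfig | None = None
    clinical_path: str | Path | None = None
    expression_path: str | Path | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    cin25_path: str | Path | None = None
    cin70_path: str | Path | None = None
    rule_table_path: str | Path | None = None
    dfs_horizon: float = 60.0
    os_horizon: float = 120.0
    cutoff_exclusions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFF_EXCLUSIONS))
    min_events_for_cutoff: int = 3

    def validate(self) -> None:
        has_paths = self.clinical_path is not None or self.expression_path is not None
        if (self.simulation is None) == (not has_paths):
            raise ValueError("exactly one of {simulation, input paths} must be given")
        if has_paths and (self.clinical_path is None or self.expression_path is None):
            raise ValueError("both clinical_path and expression_path are required")
        if self.dfs_horizon <= 0 or self.os_horizon <= 0:
            raise ValueError("horizons must be positive")


def load_clinical_table(path: str | Path,
                        column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a clinical TSV, optionally renaming cBioPortal-style columns.

    *column_map* maps source column names to the canonical schema
    (histotype, grade, stage_sub, age, *_mut, dfs_time, dfs_event, ...).
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    idx = "patient_id" if "patient_id" in df.columns else df.columns[0]
    return df.set_index(idx)


def derive_cutoffs(clinical: pd.DataFrame, scores: pd.DataFrame,
                   rules: RuleTable, horizon: float,
                   exclusions: dict[str, tuple[str, ...]] | None = None,
                   min_events: int = 3) -> tuple[dict[str, float], dict]:
    """Per-subgroup optimal cutoffs from mutation-excluded derivation sets.

    Returns ``(cutoffs, report)`` where the report records, per subgroup,
    the derivation-set size, events before the horizon, AUC and cutoff.
    A subgroup with fewer than *min_events* horizon events is skipped
    (cutoff None) with a warning.
    """
    exclusions = DEFAULT_CUTOFF_EXCLUSIONS if exclusions is None else exclusions
    cutoffs: dict[str, float] = {}
    report: dict[str, dict] = {}
    for sg in ("OB", "VBT", "EBRT"):
        members = clinical[clinical["subgroup"] == sg]
        deriv = members
        for mut in exclusions.get(sg, ()):
            deriv = deriv[deriv[mut] == 0]
        sig = rules.signature_by_subgroup[sg].lower()
        entry = {"signature": sig.upper(), "n_subgroup": int(len(members)),
                 "n_derivation": int(len(deriv))}
        ev = int(((deriv["dfs_time"] <= horizon) & (deriv["dfs_event"] == 1)).sum())
        entry["n_events_horizon"] = ev
        if ev < min_events:
            logger.warning("subgroup %s: %d events before %.0f months; cutoff skipped",
                           sg, ev, horizon)
            cutoffs[sg] = None
            entry.update(auc=None, cutoff=None)
        else:
            curve = td_roc(scores.loc[deriv.index, sig],
                           deriv["dfs_time"], deriv["dfs_event"], horizon)
            cut = optimal_cutoff(curve)
            cutoffs[sg] = cut.cutoff
            entry.update(auc=round(curve.auc, 6), cutoff=round(cut.cutoff, 6),
                         youden_j=round(cut.youden_j, 6))
        report[sg] = entry
    return cutoffs, report


def _km_by_group(df: pd.DataFrame, group_col: str, time_col: str,
                 event_col: str, horizon: float) -> pd.DataFrame:
    rows = []
    for g, sub in df.groupby(group_col, sort=True):
        if len(sub) == 0:
            continue
        curve = km_estimate(sub[time_col], sub[event_col])
        rows.append({group_col: g, "n": len(sub),
                     "events": int(sub[event_col].sum()),
                     f"km_surv_{int(horizon)}m": curve.survival_at(horizon)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "cinrisk_version": __version__,
                      "counts": {}, "outputs": []}

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        clinical, matrix, truth = generate_cohort(sim)
        truth.to_json(out / "ground_truth.json")
        manifest["outputs"].append("ground_truth.json")
        manifest["simulation_seed"] = sim.seed
    else:
        clinical = load_clinical_table(config.clinical_path, config.column_map)
        matrix = ExpressionMatrix.from_tsv(config.expression_path)
    manifest["counts"]["rows_in"] = int(len(clinical))

    # --- scoring ----------------------------------------------------------
    cin25 = (load_signature(config.cin25_path) if config.cin25_path
             else builtin_signature("CIN25"))
    cin70 = (load_signature(config.cin70_path) if config.cin70_path
             else builtin_signature("CIN70"))
    z = zscore_normalize(matrix)
    scores = score_table(z, cin25, cin70)
    _write_tsv(scores, out / "scores.tsv", manifest)

    # --- exclusions and subgroups ----------------------------------------
    kept, audit = apply_exclusions(clinical)
    manifest["counts"]["exclusions"] = audit
    manifest["counts"]["rows_after_exclusion"] = int(len(kept))
    assert len(clinical) == len(kept) + sum(audit.values())

    kept = kept.copy()
    kept["subgroup"] = [assign_radiotherapy_subgroup(rec) for _, rec in kept.iterrows()]
    manifest["counts"]["subgroup_sizes"] = kept["subgroup"].value_counts().to_dict()

    # --- cutoffs and integrated tiers ------------------------------------
    rules = (RuleTable.from_yaml(config.rule_table_path)
             if config.rule_table_path else default_rule_table())
    cutoffs, cutoff_report = derive_cutoffs(
        kept, scores, rules, config.dfs_horizon,
        exclusions=config.cutoff_exclusions,
        min_events=config.min_events_for_cutoff)
    manifest["cutoffs"] = cutoff_report
    (out / "cutoffs.json").write_text(json.dumps(cutoff_report, indent=2))
    manifest["outputs"].append("cutoffs.json")

    tierable = kept[[cutoffs.get(sg) is not None for sg in kept["subgroup"]]]
    strat = stratify_table(tierable, scores, cutoffs, rules)
    strat = strat.join(kept[["dfs_time", "dfs_event", "os_time", "os_event"]])
    _write_tsv(strat, out / "stratification.tsv", manifest)
    manifest["counts"]["rows_tiered"] = int((strat["integrated_risk"] != "").sum())

    # --- survival reports -------------------------------------------------
    tiered = strat[strat["integrated_risk"] != ""]
    if len(tiered):
        km = _km_by_group(tiered, "integrated_risk", "dfs_time", "dfs_event",
                          config.dfs_horizon)
        _write_tsv(km.set_index("integrated_risk"), out / "km_dfs_by_tier.tsv",
                   manifest)
        groups = [(sub["dfs_time"].to_numpy(), sub["dfs_event"].to_numpy())
                  for _, sub in tiered.groupby("integrated_risk")
                  if sub["dfs_event"].sum() > 0 or len(sub) > 0]
        if len(groups) >= 2 and sum(g[1].sum() for g in groups) > 0:
            stat, p = logrank_test(*groups)
            manifest["logrank_dfs_by_tier"] = {"statistic": stat, "p": p}

    cox_rows = []
    for sg, sub in tiered.groupby("subgroup"):
        sub = sub.join(kept[["ctnnb1_mut"]])
        cov = pd.DataFrame({
            "cin_high": (sub["signature_level"] == "High").astype(float),
            "ctnnb1_mut": sub["ctnnb1_mut"].astype(float),
        })
        if cov.nunique().min() < 2 or sub["dfs_event"].sum() < cov.shape[1] + 1:
            continue
        try:
            fit = cox_fit(cov, sub["dfs_time"], sub["dfs_event"])
        except ValueError:
            continue
        for term, row in fit.summary.iterrows():
            cox_rows.append({"subgroup": sg, "term": term, **row.to_dict()})
    if cox_rows:
        _write_tsv(pd.DataFrame(cox_rows).set_index("subgroup"),
                   out / "cox_dfs_by_subgroup.tsv", manifest)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_meta(study_files: list[str | Path], out_dir: str | Path,
             correction: str = "none") -> pd.DataFrame:
    """Pool per-sample two-arm score files into a fixed-effects forest table.

    Each TSV needs columns ``value`` and ``arm`` (arm 1 = reference).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    estimates = []
    for f in study_files:
        df = pd.read_csv(f, sep="\t")
        arms = sorted(df["arm"].unique())
        if len(arms) != 2:
            raise ValueError(f"{f}: need exactly two arms, found {arms}")
        estimates.append(smd_from_samples(
            df.loc[df["arm"] == arms[0], "value"],
            df.loc[df["arm"] == arms[1], "value"],
            correction=correction, study_id=Path(f).stem))
    meta = pool_fixed(estimates, correction=correction)
    forest = forest_data(meta)
    forest.to_csv(out / "forest.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "meta.json").write_text(json.dumps({
        "d": meta.d, "se": meta.se, "ci95": list(meta.ci95), "z": meta.z,
        "p": meta.p, "q": meta.q, "i2": meta.i2, "k": len(meta.studies),
        "correction": correction}, indent=2))
    return forest


def _write_tsv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
    manifest["outputs"].append(path.name)
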