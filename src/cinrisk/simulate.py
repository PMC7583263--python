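"""Synthetic endometrial-carcinoma cohorts with known ground truth.

The generator emulates the structure the downstream analysis assumes: a
single latent chromosomal-instability (CIN) factor per patient drives both
the expression of the signature genes and the event hazard; clinical
covariates (grade, histotype, stage, age, molecular subtype) shift the
latent factor; mutation indicators are drawn at configurable marginal
frequencies.  Two deliberately anomalous patterns mirror the biology the
risk model exploits: POLE-mutant tumours get *elevated* CIN yet a strongly
protective hazard, and CTNNB1-mutant tumours get *reduced* CIN yet an
elevated hazard.

Event and censoring times are exponential (months), so closed-form sanity
checks are available, and every generated table row has a matching
ground-truth row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ExpressionMatrix, builtin_signature

__all__ = [
    "HazardSpec",
    "SimConfig",
    "GroundTruth",
    "StudyData",
    "generate_cohort",
    "generate_meta_studies",
    "default_meta_arm_sizes",
    "DEFAULT_SEED",
]

#: Default seed (publication date) used when none is supplied.
DEFAULT_SEED = 20201022

MUTATIONS = ("pole", "ctnnb1", "pten", "pik3ca", "fgfr2", "ppp2r1a")
SUBTYPES = ("POLE-mut", "MSI", "CNV-L", "CNV-H")


@dataclass
class HazardSpec:
    """Exponential proportional-hazards specification for one endpoint.

    ``rate_i = baseline_rate * exp(log_hr_cin * z_i
    + log_hr_pole * pole_i + log_hr_ctnnb1 * ctnnb1_i)`` with time in months.
    """

    baseline_rate: float
    log_hr_cin: float
    log_hr_pole: float
    log_hr_ctnnb1: float

    def validate(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be > 0")

    def rate(self, z: np.ndarray, pole: np.ndarray, ctnnb1: np.ndarray) -> np.ndarray:
        return self.baseline_rate * np.exp(
            self.log_hr_cin * z
            + self.log_hr_pole * pole
            + self.log_hr_ctnnb1 * ctnnb1
        )


def _default_dfs() -> HazardSpec:
    return HazardSpec(baseline_rate=0.004, log_hr_cin=0.8,
                      log_hr_pole=-2.0, log_hr_ctnnb1=0.9)


def _default_os() -> HazardSpec:
    return HazardSpec(baseline_rate=0.002, log_hr_cin=0.7,
                      log_hr_pole=-2.0, log_hr_ctnnb1=1.0)


def _default_mutation_freqs() -> dict[str, float]:
    # Stage I cohort marginal mutation rates.
    return {"pole": 0.10, "ctnnb1": 0.24, "pten": 0.76,
            "pik3ca": 0.50, "fgfr2": 0.20, "ppp2r1a": 0.14}


def _default_subtype_freqs() -> dict[str, float]:
    return {"POLE-mut": 0.10, "MSI": 0.34, "CNV-L": 0.34, "CNV-H": 0.22}


def _default_cin_effects() -> dict[str, float]:
    # Shifts on the latent CIN scale.  Directions follow the observed
    # associations: higher grade, non-endometrioid histology, deeper
    # invasion, older age and CNV-high subtype raise CIN; POLE mutation
    # raises it (despite good prognosis) and CTNNB1 mutation lowers it
    # (despite poor prognosis).
    return {
        "grade2": 0.35,
        "grade3": 0.80,
        "non_eec": 0.60,
        "stage_ib": 0.30,
        "age_per_decade": 0.08,   # per decade above 60
        "cnv_high": 0.50,
        "pole": 0.80,
        "ctnnb1": -0.60,
    }


@dataclass
class SimConfig:
    """Full specification of one simulated cohort."""

    n_patients: int = 500
    seed: int = DEFAULT_SEED
    mutation_freqs: dict[str, float] = field(default_factory=_default_mutation_freqs)
    subtype_freqs: dict[str, float] = field(default_factory=_default_subtype_freqs)
    grade_freqs: tuple[float, float, float] = (0.26, 0.26, 0.48)
    eec_freq: float = 0.85
    stage_ib_freq: float = 0.32
    age_mean: float = 64.0
    age_sd: float = 10.0
    cin_effects: dict[str, float] = field(default_factory=_default_cin_effects)
    dfs: HazardSpec = field(default_factory=_default_dfs)
    os: HazardSpec = field(default_factory=_default_os)
    noise_sd: float = 0.6
    censor_rate: float = 0.012
    gene_loading: float = 1.0
    n_noise_genes: int = 30
    time_unit: str = "months"

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, p in {**self.mutation_freqs,
                        "eec_freq": self.eec_freq,
                        "stage_ib_freq": self.stage_ib_freq}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        for name, p in self.subtype_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if abs(sum(self.subtype_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_freqs must sum to 1")
        if abs(sum(self.grade_freqs) - 1.0) > 1e-9:
            raise ValueError("grade_freqs must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        self.dfs.validate()
        self.os.validate()


@dataclass
class GroundTruth:
    """Generator-side truth recorded for recovery tests."""

    latent_cin: pd.Series                 # indexed by patient_id
    true_log_hr: dict[str, dict[str, float]]
    config_seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_seed": self.config_seed,
            "true_log_hr": self.true_log_hr,
            "latent_cin": {k: float(v) for k, v in self.latent_cin.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, ExpressionMatrix, GroundTruth]:
    """Draw one cohort: clinical table, raw expression matrix, ground truth.

    The latent CIN of patient *i* is ``z_i = sum(covariate shifts) +
    Normal(0, noise_sd)``; each signature gene expresses
    ``e_gi = loading * z_i + Normal(0, 1)``.  Survival times are exponential
    with independent exponential censoring; observed time is the minimum and
    the event flag marks which came first.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pid = np.array([f"P{i:05d}" for i in range(n)])

    grade = rng.choice([1, 2, 3], size=n, p=list(config.grade_freqs))
    eec = rng.random(n) < config.eec_freq
    stage_ib = rng.random(n) < config.stage_ib_freq
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 30, 90)
    subtype = rng.choice(SUBTYPES, size=n,
                         p=[config.subtype_freqs[s] for s in SUBTYPES])

    muts = {m: (rng.random(n) < config.mutation_freqs.get(m, 0.0)).astype(np.int8)
            for m in MUTATIONS}
    # POLE-mut molecular subtype and POLE mutation call are the same biology:
    # force the indicator on where the subtype says so.
    muts["pole"] = np.where(subtype == "POLE-mut", 1, muts["pole"]).astype(np.int8)

    eff = config.cin_effects
    z = (
        np.where(grade == 2, eff.get("grade2", 0.0), 0.0)
        + np.where(grade == 3, eff.get("grade3", 0.0), 0.0)
        + np.where(~eec, eff.get("non_eec", 0.0), 0.0)
        + np.where(stage_ib, eff.get("stage_ib", 0.0), 0.0)
        + eff.get("age_per_decade", 0.0) * (age - 60.0) / 10.0
        + np.where(subtype == "CNV-H", eff.get("cnv_high", 0.0), 0.0)
        + eff.get("pole", 0.0) * muts["pole"]
        + eff.get("ctnnb1", 0.0) * muts["ctnnb1"]
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    genes = list(builtin_signature("CIN70").genes)
    expr = config.gene_loading * z[None, :] + rng.normal(0.0, 1.0, size=(len(genes), n))
    if config.n_noise_genes > 0:
        noise = rng.normal(0.0, 1.0, size=(config.n_noise_genes, n))
        genes = genes + [f"NOISE{i:03d}" for i in range(config.n_noise_genes)]
        expr = np.vstack([expr, noise])
    matrix = ExpressionMatrix(
        values=pd.DataFrame(expr, index=genes, columns=pid),
        dataset_id=f"sim-{config.seed}",
    )

    def _draw_endpoint(spec: HazardSpec) -> tuple[np.ndarray, np.ndarray]:
        rate = spec.rate(z, muts["pole"], muts["ctnnb1"])
        t_event = rng.exponential(1.0 / rate)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(np.int8)
        return time, event

    dfs_time, dfs_event = _draw_endpoint(config.dfs)
    os_time, os_event = _draw_endpoint(config.os)

    clinical = pd.DataFrame(
        {
            "patient_id": pid,
            "histotype": np.where(eec, "EEC", "non-EEC"),
            "grade": grade,
            "stage_sub": np.where(stage_ib, "IB", "IA"),
            "age": np.round(age, 1),
            "tcga_subtype": subtype,
            **{f"{m}_mut": muts[m] for m in MUTATIONS},
            "other_malignancy": np.zeros(n, dtype=np.int8),
            "positive_margins": np.zeros(n, dtype=np.int8),
            "dfs_time": np.round(dfs_time, 3),
            "dfs_event": dfs_event,
            "os_time": np.round(os_time, 3),
            "os_event": os_event,
        }
    ).set_index("patient_id")

    truth = GroundTruth(
        latent_cin=pd.Series(z, index=pid, name="latent_cin"),
        true_log_hr={
            "dfs": {"cin": config.dfs.log_hr_cin, "pole": config.dfs.log_hr_pole,
                    "ctnnb1": config.dfs.log_hr_ctnnb1},
            "os": {"cin": config.os.log_hr_cin, "pole": config.os.log_hr_pole,
                   "ctnnb1": config.os.log_hr_ctnnb1},
        },
        config_seed=config.seed,
    )
    return clinical, matrix, truth


@dataclass
class StudyData:
    """Per-sample values for one simulated two-arm study."""

    study_id: str
    arm1: np.ndarray
    arm2: np.ndarray
    true_smd: float


def default_meta_arm_sizes(k_studies: int = 9,
                           total1: int = 483, total2: int = 478) -> list[tuple[int, int]]:
    """Split two arm totals as evenly as possible over *k_studies* studies.

    Defaults match the grade meta-analysis totals (483 Grade 1 & 2 versus
    478 Grade 3 patients over 9 datasets).
    """
    def split(total: int) -> list[int]:
        base, extra = divmod(total, k_studies)
        return [base + (1 if i < extra else 0) for i in range(k_studies)]

    return list(zip(split(total1), split(total2)))


def generate_meta_studies(k_studies: int, per_arm_ns: list[tuple[int, int]],
                          true_smd: float, seed: int = DEFAULT_SEED) -> list[StudyData]:
    """Simulate *k_studies* two-arm studies on the Z scale.

    Arm 1 is Normal(0, 1), arm 2 Normal(true_smd, 1); per-sample values are
    returned so summary and pooling code is exercised end to end.
    """
    if k_studies < 1:
        raise ValueError("k_studies must be >= 1")
    if len(per_arm_ns) != k_studies:
        raise ValueError("per_arm_ns must have one (n1, n2) pair per study")
    rng = np.random.default_rng(seed)
    out: list[StudyData] = []
    for i, (n1, n2) in enumerate(per_arm_ns):
        if n1 < 1 or n2 < 1:
            raise ValueError(f"study {i}: empty arm")
        out.append(StudyData(
            study_id=f"study{i + 1:02d}",
            arm1=rng.normal(0.0, 1.0, size=n1),
            arm2=rng.normal(true_smd, 1.0, size=n2),
            true_smd=float(true_smd),
        ))
    return out
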