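"""Standardized mean differences and inverse-variance fixed-effects pooling.

Per-study effect: Cohen's d on the (per-dataset Z-scored) signature scale,
``d = (mean2 - mean1) / s_pooled`` with the usual pooled SD, variance
``(n1+n2)/(n1*n2) + d^2 / (2(n1+n2))``, and an optional Hedges small-sample
correction ``J = 1 - 3/(4(n1+n2) - 9)``.  Pooling is inverse-variance fixed
effects; heterogeneity is summarized by Cochran's Q and I-squared.  The
direction convention is d > 0 when the second (unfavourable) arm is higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SMDEstimate", "MetaResult", "study_smd", "smd_from_samples",
           "pool_fixed", "forest_data"]

_Z95 = 1.959963984540054


@dataclass
class SMDEstimate:
    study_id: str
    d: float
    se: float
    n1: int
    n2: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.d - _Z95 * self.se, self.d + _Z95 * self.se)

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass
class MetaResult:
    studies: list[SMDEstimate]
    d: float
    se: float
    z: float
    p: float
    q: float
    i2: float          # percent
    correction: str

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.d - _Z95 * self.se, self.d + _Z95 * self.se)


def study_smd(arm1: tuple[int, float, float], arm2: tuple[int, float, float],
              correction: str = "none", study_id: str = "study") -> SMDEstimate:
    """SMD of arm2 minus arm1 from ``(n, mean, SD)`` summaries."""
    n1, m1, s1 = arm1
    n2, m2, s2 = arm2
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero; SMD undefined")
    d = (m2 - m1) / np.sqrt(sp2)
    if correction == "hedges":
        d *= 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'hedges'")
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return SMDEstimate(study_id=study_id, d=float(d), se=float(se),
                       n1=int(n1), n2=int(n2))


def smd_from_samples(x1, x2, correction: str = "none",
                     study_id: str = "study") -> SMDEstimate:
    """SMD computed from per-sample arm values (sample-SD summaries)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return study_smd((x1.size, x1.mean(), x1.std(ddof=1)),
                     (x2.size, x2.mean(), x2.std(ddof=1)),
                     correction=correction, study_id=study_id)


def pool_fixed(estimates: list[SMDEstimate], correction: str = "none") -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-study SMDs."""
    if not estimates:
        raise ValueError("need at least one study estimate")
    d = np.array([e.d for e in estimates])
    w = np.array([e.weight for e in estimates])
    pooled = float(np.sum(w * d) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (d - pooled) ** 2))
    k = len(estimates)
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(studies=list(estimates), d=pooled, se=se, z=float(z),
                      p=p, q=q, i2=i2, correction=correction)


def forest_data(meta: MetaResult) -> pd.DataFrame:
    """Plot-ready forest table: per-study rows plus an overall row.

    Weights are percentages summing to 100 over the studies.
    """
    total_w = sum(e.weight for e in meta.studies)
    rows = []
    for e in meta.studies:
        lo, hi = e.ci95
        rows.append({"study_id": e.study_id, "d": e.d, "ci_low": lo,
                     "ci_high": hi, "weight_pct": 100.0 * e.weight / total_w,
                     "n1": e.n1, "n2": e.n2})
    lo, hi = meta.ci95
    rows.append({"study_id": "overall", "d": meta.d, "ci_low": lo,
                 "ci_high": hi, "weight_pct": 100.0,
                 "n1": sum(e.n1 for e in meta.studies),
                 "n2": sum(e.n2 for e in meta.studies)})
    return pd.DataFrame(rows)
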