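"""Z-score normalization and CIN25/CIN70 signature scoring.

A CIN signature score for a sample is the unweighted mean of the Z-scored
expression of the signature genes present in the matrix.  Normalization is
strictly within one dataset (one :class:`ExpressionMatrix`): scores computed
on matrices from different platforms are comparable only on the Z scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "zscore_normalize",
    "score_signature",
    "load_signature",
    "builtin_signature",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a dataset identity.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns = sample ids.
    dataset_id
        Label for the originating dataset; normalization never crosses it.
    """

    values: pd.DataFrame
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_id: str | None = None) -> "ExpressionMatrix":
        """Read a genes-x-samples TSV whose first column holds gene symbols."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.astype(float), dataset_id=dataset_id or Path(path).stem)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class GeneSignature:
    """An ordered, deduplicated gene list (e.g. CIN25 or CIN70)."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def zscore_normalize(matrix: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, SD 1 across the samples of one dataset.

    Rows with zero variance cannot be standardized; they are set to all-zero
    (score-neutral) and a warning is logged, so that signature coverage counts
    stay stable.

    Parameters
    ----------
    ddof
        Delta degrees of freedom for the SD; 0 (population convention) by
        default.

    Raises
    ------
    ValueError
        If the matrix has fewer than two samples (SD undefined).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        names = [matrix.gene_ids[i] for i in np.flatnonzero(flat)[:10]]
        logger.warning(
            "%d constant gene row(s) set to zero after z-scoring (e.g. %s)",
            int(flat.sum()), ", ".join(names),
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[flat, :] = 0.0
    out = pd.DataFrame(Z, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, dataset_id=matrix.dataset_id)


def score_signature(matrix: ExpressionMatrix, sig: GeneSignature,
                    coverage_warn: float = 0.8) -> pd.DataFrame:
    """Per-sample signature score = mean over signature genes present.

    The matrix is expected to be Z-scored already (see :func:`zscore_normalize`);
    the function does not re-normalize.  Gene matching is case-insensitive.

    Returns
    -------
    DataFrame indexed by sample id with columns ``score`` and ``genes_found``.

    Raises
    ------
    KeyError
        If none of the signature genes are present.
    """
    lookup = {g.upper(): g for g in matrix.gene_ids}
    present = [lookup[g.upper()] for g in sig.genes if g.upper() in lookup]
    if not present:
        raise KeyError(
            f"no genes of signature {sig.name!r} found in matrix "
            f"{matrix.dataset_id!r}; missing: {sig.genes}"
        )
    coverage = len(present) / len(sig.genes)
    if coverage < coverage_warn:
        logger.warning(
            "signature %s coverage %.0f%% (< %.0f%%) in dataset %s",
            sig.name, 100 * coverage, 100 * coverage_warn, matrix.dataset_id,
        )
    scores = matrix.values.loc[present].mean(axis=0)
    return pd.DataFrame(
        {"score": scores.astype(float), "genes_found": len(present)},
        index=matrix.values.columns,
    )


def score_table(matrix: ExpressionMatrix, cin25: GeneSignature,
                cin70: GeneSignature) -> pd.DataFrame:
    """Convenience wrapper producing the standard two-signature score table.

    Columns: ``cin25``, ``cin70``, ``genes_found_25``, ``genes_found_70``.
    """
    s25 = score_signature(matrix, cin25)
    s70 = score_signature(matrix, cin70)
    return pd.DataFrame(
        {
            "cin25": s25["score"],
            "cin70": s70["score"],
            "genes_found_25": s25["genes_found"],
            "genes_found_70": s70["genes_found"],
        }
    )


def load_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Load a one-symbol-per-line gene list; ``#`` starts a comment.

    Duplicate symbols are kept once (first occurrence, order preserved, logged);
    original case is preserved.
    """
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    dups: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key = line.upper()
        if key in seen:
            dups.append(line)
            continue
        seen.add(key)
        genes.append(line)
    if not genes:
        raise ValueError(f"empty signature file: {path}")
    if dups:
        logger.warning("signature %s: %d duplicate symbol(s) kept once: %s",
                       path.name, len(dups), dups[:5])
    return GeneSignature(name=name or path.stem.upper(), genes=genes)


def builtin_signature(name: str) -> GeneSignature:
    """Return a shipped signature by name: ``CIN25`` or ``CIN70``."""
    key = name.strip().lower()
    if key not in {"cin25", "cin70"}:
        raise KeyError(f"unknown builtin signature {name!r}; choose CIN25 or CIN70")
    ref = _ilres.files("cinrisk.resources") / f"{key}.txt"
    with _ilres.as_file(ref) as p:
        return load_signature(p, name=key.upper())
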