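"""Loading, validation and alignment of multi-study multi-omics matrices.

A *study* bundles V omics matrices (one per omics type: RNA, methylation,
protein, ...), each genes-by-samples, measured on the same samples.  The
per-gene view used by the correlation measures is the transposed slice: an
``Sk x V`` matrix whose rows are samples and whose columns are omics types.

Alignment policy: genes and samples are matched across omics (and, for the
gene list, across studies) by identifier intersection in sorted order.  Rows
containing missing values are dropped with a warning; no imputation is
performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsStudy",
    "GeneSpecificMatrix",
    "load_study",
    "gene_matrix",
    "intersect_genes",
    "subset_study",
]


@dataclass(frozen=True)
class GeneSpecificMatrix:
    """One gene's multi-omics profile: samples in rows, omics types in columns."""

    gene_id: str
    values: np.ndarray  # shape (Sk, V)
    omics_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("gene-specific matrix must be 2-D (samples x omics)")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_omics(self) -> int:
        return self.values.shape[1]


@dataclass
class OmicsStudy:
    """V aligned omics matrices (each G x Sk) sharing genes and samples.

    Invariants enforced at construction: every matrix has the same gene index
    (same order), the same sample columns (same order), and no missing values.
    """

    study_id: str
    omics: list[pd.DataFrame]
    omics_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.omics:
            raise ValueError(f"study {self.study_id!r} has no omics matrices")
        if not self.omics_names:
            self.omics_names = [f"omics{i + 1}" for i in range(len(self.omics))]
        if len(self.omics_names) != len(self.omics):
            raise ValueError("omics_names length does not match number of matrices")
        ref = self.omics[0]
        for name, df in zip(self.omics_names, self.omics):
            if not df.index.equals(ref.index):
                raise ValueError(f"gene index of {name!r} differs from first omics")
            if not df.columns.equals(ref.columns):
                raise ValueError(f"sample columns of {name!r} differ from first omics")
            if df.isna().any().any():
                raise ValueError(f"omics matrix {name!r} contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.omics[0].index)

    @property
    def n_genes(self) -> int:
        return self.omics[0].shape[0]

    @property
    def sample_size(self) -> int:
        return self.omics[0].shape[1]

    @property
    def n_omics(self) -> int:
        return len(self.omics)

    def stacked(self) -> np.ndarray:
        """All omics stacked as one ``Sk x (G*V)`` array, gene-major, omics-minor.

        Column ``g * V + v`` holds omics ``v`` of gene ``g``; this ordering is
        shared with the simulation module's correlation matrix layout.
        """
        G, V = self.n_genes, self.n_omics
        out = np.empty((self.sample_size, G * V))
        for v, df in enumerate(self.omics):
            out[:, v::V] = df.to_numpy().T
        return out


def _read_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cells in matrix") from exc
    return df


def load_study(
    paths: Sequence[str | Path],
    fmt: str | None = None,
    study_id: str = "study",
    omics_names: Sequence[str] | None = None,
) -> OmicsStudy:
    """Load V omics files into one aligned :class:`OmicsStudy`.

    Each file is a labelled numeric matrix (first column = gene identifier,
    header row = sample identifiers).  The study is restricted to the sorted
    intersection of genes and of samples across the V files; gene rows with
    missing values are dropped (in every omics) with a logged warning.
    """
    if not paths:
        raise ValueError("no omics files given")
    mats = [_read_matrix(p, fmt) for p in paths]
    names = list(omics_names) if omics_names else [f"omics{i + 1}" for i in range(len(mats))]

    genes: set[str] = set(mats[0].index)
    samples: set[str] = set(mats[0].columns)
    for df in mats[1:]:
        genes &= set(df.index)
        samples &= set(df.columns)
    if not genes:
        raise ValueError("no genes common to all omics files")
    if not samples:
        raise ValueError("no samples common to all omics files")

    gene_order = sorted(genes)
    sample_order = sorted(samples)
    mats = [df.loc[gene_order, sample_order] for df in mats]

    bad = set()
    for name, df in zip(names, mats):
        na_rows = df.index[df.isna().any(axis=1)]
        if len(na_rows):
            logger.warning(
                "study %s omics %s: dropping %d gene(s) with missing values: %s",
                study_id, name, len(na_rows), ", ".join(na_rows[:10]),
            )
            bad |= set(na_rows)
    if bad:
        keep = [g for g in gene_order if g not in bad]
        if not keep:
            raise ValueError("all genes dropped due to missing values")
        mats = [df.loc[keep] for df in mats]

    return OmicsStudy(study_id=study_id, omics=mats, omics_names=names)


def gene_matrix(study: OmicsStudy, gene_id: str) -> GeneSpecificMatrix:
    """The ``Sk x V`` profile of one gene (samples in rows, omics in columns)."""
    if gene_id not in study.omics[0].index:
        raise KeyError(f"gene {gene_id!r} not in study {study.study_id!r}")
    cols = [df.loc[gene_id].to_numpy() for df in study.omics]
    return GeneSpecificMatrix(
        gene_id=gene_id,
        values=np.column_stack(cols),
        omics_names=tuple(study.omics_names),
    )


def intersect_genes(studies: Sequence[OmicsStudy]) -> list[str]:
    """Sorted intersection of gene identifiers across studies."""
    if not studies:
        raise ValueError("need at least one study")
    common: set[str] = set(studies[0].gene_ids)
    for s in studies[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ValueError("no genes common to all studies")
    return sorted(common)


def subset_study(study: OmicsStudy, gene_ids: Sequence[str]) -> OmicsStudy:
    """Restrict a study to ``gene_ids`` (kept in the given order), bit-exactly."""
    missing = [g for g in gene_ids if g not in study.omics[0].index]
    if missing:
        raise KeyError(f"genes not in study {study.study_id!r}: {missing[:5]}")
    return OmicsStudy(
        study_id=study.study_id,
        omics=[df.loc[list(gene_ids)] for df in study.omics],
        omics_names=list(study.omics_names),
    )
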