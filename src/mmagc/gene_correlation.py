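"""Per-study gene-to-gene correlation under three multi-omics measures.

Given a study with V omics types, the association between two genes is
summarised from their ``Sk x V`` profiles by one of:

* **CC** — first canonical correlation between the two genes' omics column
  spaces, in [0, 1]: the highest correlation achievable between a linear
  combination of one gene's omics and a linear combination of the other's.
* **MOC** (maximum omics correlation) — the Pearson correlation of largest
  magnitude among all V x V omics-column pairs, sign retained, in [-1, 1].
* **MSOC** (maximum same-omics correlation) — as MOC but restricted to the
  V matching-type pairs (RNA-RNA, protein-protein, ...), in [-1, 1].

All three reduce to the ordinary Pearson correlation (its absolute value for
CC) when V = 1.  Pairwise values are stored in the canonical row-major
upper-triangle order (1,2),(1,3),...,(1,G),(2,3),...; every downstream module
uses the same pair index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .omics_data import GeneSpecificMatrix, OmicsStudy

__all__ = [
    "CorrelationVector",
    "canonical_correlation",
    "max_omics_correlation",
    "max_same_omics_correlation",
    "correlation_matrix",
    "pair_indices",
    "vector_to_matrix",
    "matrix_to_vector",
]

Method = Literal["CC", "MOC", "MSOC"]

#: Ridge added to each within-gene covariance (relative to trace/V) before
#: whitening in the CCA; keeps collinear omics profiles from breaking the solve.
CCA_RIDGE = 1e-8


def pair_indices(n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle pair order: (0,1),(0,2),...,(0,G-1),(1,2),..."""
    return np.triu_indices(n_genes, k=1)


def vector_to_matrix(values: np.ndarray, n_genes: int) -> np.ndarray:
    """Expand a length-``G(G-1)/2`` pair vector to a symmetric matrix, diagonal 1."""
    values = np.asarray(values, dtype=float)
    if values.shape != (n_genes * (n_genes - 1) // 2,):
        raise ValueError("pair vector length does not match G(G-1)/2")
    mat = np.eye(n_genes)
    rows, cols = pair_indices(n_genes)
    mat[rows, cols] = values
    mat[cols, rows] = values
    return mat


def matrix_to_vector(mat: np.ndarray) -> np.ndarray:
    """Extract the canonical upper-triangle pair vector from a symmetric matrix."""
    mat = np.asarray(mat, dtype=float)
    rows, cols = pair_indices(mat.shape[0])
    return mat[rows, cols].copy()


@dataclass
class CorrelationVector:
    """All distinct gene-pair correlations of one study under one measure.

    ``values[i]`` is the correlation of the i-th gene pair in row-major
    upper-triangle order over ``gene_ids``.
    """

    study_id: str
    method: Method
    values: np.ndarray
    sample_size: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        G = len(self.gene_ids)
        if self.values.shape != (G * (G - 1) // 2,):
            raise ValueError("correlation vector length does not match G(G-1)/2")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Symmetric G x G view with unit diagonal."""
        return vector_to_matrix(self.values, self.n_genes)


def _safe_corrcoef(X: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns; zero-variance columns correlate as 0."""
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance column(s); their correlations "
            "are set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    C[np.isnan(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def _first_canonical_from_blocks(
    S11: np.ndarray, S22: np.ndarray, S12: np.ndarray, ridge: float = CCA_RIDGE
) -> np.ndarray:
    """First canonical correlation from (stacked) covariance blocks.

    Accepts arrays of shape ``(..., V, V)``; solves the whitened SVD problem
    ``L1^-1 S12 L2^-T`` with a small ridge on the within blocks.
    """
    V = S11.shape[-1]
    eye = np.eye(V)
    r1 = ridge * (np.trace(S11, axis1=-2, axis2=-1) / V)[..., None, None]
    r2 = ridge * (np.trace(S22, axis1=-2, axis2=-1) / V)[..., None, None]
    L1 = np.linalg.cholesky(S11 + r1 * eye)
    L2 = np.linalg.cholesky(S22 + r2 * eye)
    # M = L1^-1 S12 L2^-T via two triangular solves
    M = np.linalg.solve(L1, S12)
    M = np.linalg.solve(L2, np.swapaxes(M, -1, -2))
    s = np.linalg.svd(M, compute_uv=False)
    return np.clip(s[..., 0], 0.0, 1.0)


def canonical_correlation(m1: GeneSpecificMatrix, m2: GeneSpecificMatrix) -> float:
    """First canonical correlation between two genes' omics profiles, in [0, 1]."""
    X, Y = m1.values, m2.values
    if X.shape[0] != Y.shape[0]:
        raise ValueError("genes measured on different numbers of samples")
    n = X.shape[0]
    if n < max(X.shape[1], Y.shape[1]) + 2:
        raise ValueError(f"sample size {n} too small for CCA with V={X.shape[1]}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S11 = Xc.T @ Xc / (n - 1)
    S22 = Yc.T @ Yc / (n - 1)
    S12 = Xc.T @ Yc / (n - 1)
    return float(_first_canonical_from_blocks(S11, S22, S12))


def _pairwise_pearson(m1: GeneSpecificMatrix, m2: GeneSpecificMatrix) -> np.ndarray:
    if m1.values.shape[0] != m2.values.shape[0]:
        raise ValueError("genes measured on different numbers of samples")
    both = np.hstack([m1.values, m2.values])
    C = _safe_corrcoef(both)
    V1 = m1.values.shape[1]
    return C[:V1, V1:]


def _signed_absmax(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Entry of maximum absolute value along ``axis``, sign kept."""
    idx = np.argmax(np.abs(values), axis=axis)
    return np.take_along_axis(values, np.expand_dims(idx, axis), axis=axis).squeeze(axis)


def max_omics_correlation(m1: GeneSpecificMatrix, m2: GeneSpecificMatrix) -> float:
    """Signed Pearson correlation of largest magnitude over all omics pairs."""
    block = _pairwise_pearson(m1, m2)
    return float(_signed_absmax(block.ravel()))


def max_same_omics_correlation(m1: GeneSpecificMatrix, m2: GeneSpecificMatrix) -> float:
    """Signed Pearson correlation of largest magnitude over matching omics types."""
    if m1.values.shape[1] != m2.values.shape[1]:
        raise ValueError("MSOC requires the same ordered omics types for both genes")
    if m1.omics_names and m2.omics_names and m1.omics_names != m2.omics_names:
        raise ValueError("MSOC requires matching omics-type names")
    block = _pairwise_pearson(m1, m2)
    return float(_signed_absmax(np.diagonal(block)))


def correlation_matrix(study: OmicsStudy, method: Method) -> CorrelationVector:
    """All ``G(G-1)/2`` pairwise gene correlations of one study.

    Vectorised over pairs: the full ``(G*V) x (G*V)`` Pearson matrix of the
    stacked omics columns is computed once; MOC/MSOC read their candidate
    correlations from its V x V gene blocks, and CC solves the stacked
    whitened-SVD canonical problem on those same blocks (CCA is invariant to
    per-column scaling, so correlation blocks serve as covariance blocks).
    """
    method = method.upper()  # type: ignore[assignment]
    if method not in ("CC", "MOC", "MSOC"):
        raise ValueError(f"unknown correlation method {method!r}")
    G, V, Sk = study.n_genes, study.n_omics, study.sample_size
    if method == "CC" and Sk < V + 2:
        raise ValueError(f"sample size {Sk} too small for CCA with V={V}")
    X = study.stacked()  # (Sk, G*V), gene-major
    C = _safe_corrcoef(X)
    blocks = C.reshape(G, V, G, V)
    rows, cols = pair_indices(G)

    if method == "CC":
        S11 = blocks[rows, :, rows, :]  # (P, V, V)
        S22 = blocks[cols, :, cols, :]
        S12 = blocks[rows, :, cols, :]
        values = _first_canonical_from_blocks(S11, S22, S12)
    else:
        pair_blocks = blocks[rows, :, cols, :]  # (P, V, V)
        if method == "MOC":
            values = _signed_absmax(pair_blocks.reshape(len(rows), V * V))
        else:  # MSOC
            values = _signed_absmax(np.diagonal(pair_blocks, axis1=-2, axis2=-1))

    return CorrelationVector(
        study_id=study.study_id,
        method=method,
        values=values,
        sample_size=Sk,
        gene_ids=study.gene_ids,
    )
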