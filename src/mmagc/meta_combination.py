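"""Fixed-effects pooling of per-study correlation vectors.

Each study k supplies the vector ``r_k`` of its ``p* = G(G-1)/2`` distinct
gene-pair correlations.  The fixed-effects model ``r_k = rho + e_k`` with
``e_k ~ N(0, T_k)`` is fit by generalized least squares:

    rho_hat = (sum_k T_k^-1)^-1 (sum_k T_k^-1 r_k)

``T_k`` is the sampling covariance of a vector of sample correlations; its
entries come from the classical large-sample (Olkin-Siotani) expression

    Cov(r_ab, r_cd) = [ r_ab r_cd (r_ac^2 + r_ad^2 + r_bc^2 + r_bd^2) / 2
                        + r_ac r_bd + r_ad r_bc
                        - (r_ab r_ac r_ad + r_ba r_bc r_bd
                           + r_ca r_cb r_cd + r_da r_db r_dc) ] / S_k

which for (c,d) = (a,b) collapses to ``Var(r_ab) = (1 - r_ab^2)^2 / S_k``.
The *diagonal* variant keeps only those variances, reducing GLS to the usual
entrywise inverse-variance weighted mean — far cheaper and, in simulations,
at least as accurate.  The *full* variant assembles each ``p* x p*`` T_k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import linalg

from .gene_correlation import CorrelationVector, pair_indices, vector_to_matrix

__all__ = [
    "MetaCorrelation",
    "correlation_variance",
    "correlation_covariance",
    "study_covariance_matrix",
    "combine_diagonal",
    "combine_full",
    "finalize_for_clustering",
]

#: Correlations are clipped to this magnitude before entering variance
#: formulas, so a (simulated) perfect correlation cannot produce an infinite
#: inverse-variance weight.
CLIP = 1.0 - 1e-6

#: Refuse the full-covariance variant above this many genes unless overridden
#: (memory grows as p*^2 per study).
MAX_GENES_FULL = 200


@dataclass
class MetaCorrelation:
    """Pooled gene-pair correlation vector with its effective precision."""

    values: np.ndarray  # length p*, signed (pre-finalize)
    method: str
    variant: Literal["diagonal", "full"]
    weight_sum: np.ndarray  # per-entry pooled precision sum
    gene_ids: list[str]
    n_studies: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def correlation_variance(r_ab: float | np.ndarray, sample_size: int) -> float | np.ndarray:
    """Large-sample variance of a sample correlation: ``(1 - r^2)^2 / S_k``."""
    if sample_size < 2:
        raise ValueError("sample size must be at least 2")
    r = np.clip(np.asarray(r_ab, dtype=float), -CLIP, CLIP)
    out = (1.0 - r**2) ** 2 / sample_size
    return float(out) if np.isscalar(r_ab) else out


def correlation_covariance(
    r: np.ndarray, a: int, b: int, c: int, d: int, sample_size: int
) -> float:
    """Large-sample covariance of two sample correlations, Cov(r_ab, r_cd).

    ``r`` is the study's symmetric correlation matrix (unit diagonal).
    Off-diagonal entries are magnitude-clipped as in
    :func:`correlation_variance`, so the (ab, ab) entry equals that variance.
    """
    if a == b or c == d:
        raise ValueError("correlation indices require a != b and c != d")
    r = np.asarray(r, dtype=float)

    def rr(i: int, j: int) -> float:
        if i == j:
            return 1.0
        return float(np.clip(r[i, j], -CLIP, CLIP))

    r_ab, r_cd = rr(a, b), rr(c, d)
    r_ac, r_ad, r_bc, r_bd = rr(a, c), rr(a, d), rr(b, c), rr(b, d)
    num = (
        0.5 * r_ab * r_cd * (r_ac**2 + r_ad**2 + r_bc**2 + r_bd**2)
        + r_ac * r_bd
        + r_ad * r_bc
        - (
            r_ab * r_ac * r_ad
            + r_ab * r_bc * r_bd
            + r_ac * r_bc * r_cd
            + r_ad * r_bd * r_cd
        )
    )
    return num / sample_size


def study_covariance_matrix(vec: CorrelationVector) -> np.ndarray:
    """Assemble the full ``p* x p*`` sampling covariance T_k of one study.

    Vectorised evaluation of the pairwise covariance expression over all
    pair-of-pairs index combinations.
    """
    G = vec.n_genes
    R = vector_to_matrix(np.clip(vec.values, -CLIP, CLIP), G)
    rows, cols = pair_indices(G)
    a, b = rows[:, None], cols[:, None]
    c, d = rows[None, :], cols[None, :]

    r_ab, r_cd = R[a, b], R[c, d]
    r_ac, r_ad, r_bc, r_bd = R[a, c], R[a, d], R[b, c], R[b, d]
    T = (
        0.5 * r_ab * r_cd * (r_ac**2 + r_ad**2 + r_bc**2 + r_bd**2)
        + r_ac * r_bd
        + r_ad * r_bc
        - (
            r_ab * r_ac * r_ad
            + r_ab * r_bc * r_bd
            + r_ac * r_bc * r_cd
            + r_ad * r_bd * r_cd
        )
    )
    T /= vec.sample_size
    return T


def _check_compatible(rs: Sequence[CorrelationVector]) -> None:
    if not rs:
        raise ValueError("need at least one study to pool")
    ref = rs[0]
    for v in rs[1:]:
        if v.gene_ids != ref.gene_ids:
            raise ValueError("studies do not share the same gene list/order")
        if v.method != ref.method:
            raise ValueError("studies use different correlation methods")


def combine_diagonal(
    rs: Sequence[CorrelationVector], pool_absolute: bool = False
) -> MetaCorrelation:
    """Entrywise inverse-variance weighted mean across studies (diagonal T_k).

    With ``pool_absolute=True`` the absolute values |r_k| are pooled instead
    of the signed estimates.
    """
    _check_compatible(rs)
    values = np.stack([np.abs(v.values) if pool_absolute else v.values for v in rs])
    weights = np.stack(
        [1.0 / correlation_variance(row, v.sample_size) for row, v in zip(values, rs)]
    )
    wsum = weights.sum(axis=0)
    if len(rs) == 1:  # single study: exact identity, no round-off
        pooled = values[0].copy()
    else:
        pooled = (weights * values).sum(axis=0) / wsum
    return MetaCorrelation(
        values=pooled,
        method=rs[0].method,
        variant="diagonal",
        weight_sum=wsum,
        gene_ids=list(rs[0].gene_ids),
        n_studies=len(rs),
    )


def _spd_repair(T: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Shift T by lambda*I so its smallest eigenvalue is at least ``floor``.

    The plug-in covariance is asymptotic and can be indefinite at finite
    samples; a diagonal shift is the minimal repair that keeps GLS solvable.
    """
    Ts = 0.5 * (T + T.T)
    lam_min = linalg.eigh(Ts, eigvals_only=True, subset_by_index=[0, 0])[0]
    lam = max(0.0, floor - lam_min)
    if lam > 0.0:
        Ts = Ts + lam * np.eye(Ts.shape[0])
    return Ts


def combine_full(
    rs: Sequence[CorrelationVector],
    pool_absolute: bool = False,
    max_genes: int = MAX_GENES_FULL,
) -> MetaCorrelation:
    """GLS pooling with the full per-study sampling covariance T_k.

    Memory is O(p*^2) per study (p* = G(G-1)/2); studies above ``max_genes``
    genes are refused unless the guard is raised explicitly.
    """
    _check_compatible(rs)
    G = rs[0].n_genes
    if G > max_genes:
        raise ValueError(
            f"full-covariance pooling refused at G={G} > max_genes={max_genes}; "
            "raise max_genes explicitly or use the diagonal variant"
        )
    p = rs[0].n_pairs
    precision_sum = np.zeros((p, p))
    weighted_sum = np.zeros(p)
    for vec in rs:
        T = _spd_repair(study_covariance_matrix(vec))
        r = np.abs(vec.values) if pool_absolute else vec.values
        cf = linalg.cho_factor(T, check_finite=False)
        precision_sum += linalg.cho_solve(cf, np.eye(p), check_finite=False)
        weighted_sum += linalg.cho_solve(cf, r, check_finite=False)
    S = _spd_repair(precision_sum)
    pooled = linalg.cho_solve(
        linalg.cho_factor(S, check_finite=False), weighted_sum, check_finite=False
    )
    return MetaCorrelation(
        values=pooled,
        method=rs[0].method,
        variant="full",
        weight_sum=np.diag(precision_sum).copy(),
        gene_ids=list(rs[0].gene_ids),
        n_studies=len(rs),
    )


def finalize_for_clustering(meta: MetaCorrelation) -> np.ndarray:
    """Pooled vector -> symmetric nonnegative G x G matrix ready for clustering.

    Absolute value (CC is already nonnegative; MOC/MSOC are folded here, after
    pooling), clipping to [0, 1], unit diagonal.
    """
    vals = np.clip(np.abs(meta.values), 0.0, 1.0)
    return vector_to_matrix(vals, meta.n_genes)
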