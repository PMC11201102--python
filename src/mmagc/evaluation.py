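"""Adjusted Rand index and the simulation benchmarking harness.

Clustering accuracy is scored by the adjusted Rand index (ARI) between the
planted and the recovered partition: chance-corrected, 0 in expectation for a
random partition, 1 for perfect agreement up to relabelling.

:func:`run_scenario` replicates the full pipeline — simulate K studies,
compute per-study correlations, pool, cluster, score — for a roster of
method names:

* ``Meta_<M>_Diag`` / ``Meta_<M>`` — pooled across studies with the diagonal
  or full error covariance, for measure ``<M>`` in {CC, MOC, MSOC}; an
  optional trailing ``_<k>`` restricts pooling to the first k studies
  (``Meta_MSOC_Diag_2``).
* ``<M>-<k>`` — single-study multi-omics clustering on study k (``MSOC-1``).
* ``WGCNA(1)`` / ``WGCNA(2)`` — single-omics clustering on omics type 1 of
  study 1 with the inflection / traditional power rule.
* ``K-M(1)`` / ``K-M(2)`` — K-means comparators on omics type 1 of study 1,
  with the true cluster count / a gap-statistic choice of it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .gene_correlation import CorrelationVector, correlation_matrix
from .meta_combination import combine_diagonal, combine_full, finalize_for_clustering
from .modified_wgcna import (
    DEFAULT_POWER_GRID,
    ClusterAssignment,
    adjacency,
    cluster,
    connectivity_profile,
    select_power_inflection,
    select_power_traditional,
    tom,
)
from .simulation import LabeledStudy, SimulationConfig, simulate_meta

__all__ = [
    "adjusted_rand_index",
    "MethodResult",
    "cluster_correlation_matrix",
    "run_replicate",
    "run_scenario",
    "results_frame",
    "smallest_perfect_study_count",
]

DEFAULT_MIN_CLUSTER_SIZE = 3


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


@dataclass
class MethodResult:
    """Per-replicate ARIs of one method, with their summary."""

    method: str
    aris: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.aris))

    @property
    def sd(self) -> float:
        return float(np.std(self.aris, ddof=1)) if len(self.aris) > 1 else 0.0

    @property
    def n_reps(self) -> int:
        return len(self.aris)


def cluster_correlation_matrix(
    corr: np.ndarray,
    power: str | int = "inflection",
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    grid: tuple[int, ...] = DEFAULT_POWER_GRID,
    gene_ids: list[str] | None = None,
    cut: str | float = "modules",
) -> ClusterAssignment:
    """Modified-WGCNA clustering of a finalized correlation matrix.

    ``power`` is ``"inflection"``, ``"traditional"``, or an explicit integer.
    """
    if isinstance(power, str):
        prof = connectivity_profile(corr, grid)
        if power == "inflection":
            m = select_power_inflection(corr, grid, profile=prof)
        elif power == "traditional":
            m = select_power_traditional(corr, grid, profile=prof)
        else:
            raise ValueError(f"unknown power rule {power!r}")
    else:
        m = int(power)
    t = tom(adjacency(corr, m))
    return cluster(t, min_cluster_size, gene_ids=gene_ids, cut=cut)


_META_RE = re.compile(r"^Meta_(CC|MOC|MSOC)(_Diag)?(?:_(\d+))?$")
_SINGLE_RE = re.compile(r"^(CC|MOC|MSOC)-(\d+)$")
_WGCNA_RE = re.compile(r"^WGCNA\((1|2)\)$")
_KMEANS_RE = re.compile(r"^K-M\((1|2)\)$")


def _single_omics_correlation(study_data: LabeledStudy) -> np.ndarray:
    """|Pearson| gene correlation of omics type 1 (single-omics baselines)."""
    X = study_data.study.omics[0].to_numpy()
    C = np.corrcoef(X)
    C[np.isnan(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.abs(np.clip(C, -1.0, 1.0))


def _gap_statistic_k(X: np.ndarray, k_max: int, rng: np.random.Generator,
                     n_refs: int = 10, n_init: int = 25) -> int:
    """Pick the cluster count by the gap statistic (first-SE rule)."""
    mins, maxs = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int, seed: int) -> float:
        if k == 1:
            return float(np.log(((data - data.mean(axis=0)) ** 2).sum()))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(data)
        return float(np.log(max(km.inertia_, 1e-300)))

    gaps, sks = [], []
    for k in range(1, k_max + 1):
        obs = log_wk(X, k, int(rng.integers(2**31)))
        ref = np.array([
            log_wk(rng.uniform(mins, maxs, size=X.shape), k, int(rng.integers(2**31)))
            for _ in range(n_refs)
        ])
        gaps.append(ref.mean() - obs)
        sks.append(ref.std(ddof=1) * np.sqrt(1 + 1 / n_refs))
    for k in range(1, k_max):
        if gaps[k - 1] >= gaps[k] - sks[k]:
            return k
    return k_max


def run_replicate(
    studies: Sequence[LabeledStudy],
    methods: Sequence[str],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    grid: tuple[int, ...] = DEFAULT_POWER_GRID,
    cut: str | float = "modules",
    kmeans_rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """ARI of every requested method on one simulated set of K studies."""
    truth = studies[0].labels
    gene_ids = studies[0].study.gene_ids
    corr_cache: dict[tuple[str, int], CorrelationVector] = {}

    def study_corr(measure: str, k: int) -> CorrelationVector:
        key = (measure, k)
        if key not in corr_cache:
            corr_cache[key] = correlation_matrix(studies[k].study, measure)
        return corr_cache[key]

    def score(assignment: ClusterAssignment) -> float:
        return adjusted_rand_index(truth, assignment.labels)

    out: dict[str, float] = {}
    for name in methods:
        if m := _META_RE.match(name):
            measure, diag, k_str = m.group(1), m.group(2), m.group(3)
            k = int(k_str) if k_str else len(studies)
            if not 1 <= k <= len(studies):
                raise ValueError(f"{name}: study count {k} out of range")
            vecs = [study_corr(measure, i) for i in range(k)]
            meta = combine_diagonal(vecs) if diag else combine_full(vecs)
            corr = finalize_for_clustering(meta)
            out[name] = score(cluster_correlation_matrix(
                corr, "inflection", min_cluster_size, grid, gene_ids, cut))
        elif m := _SINGLE_RE.match(name):
            measure, k = m.group(1), int(m.group(2)) - 1
            if not 0 <= k < len(studies):
                raise ValueError(f"{name}: study index out of range")
            meta = combine_diagonal([study_corr(measure, k)])
            corr = finalize_for_clustering(meta)
            out[name] = score(cluster_correlation_matrix(
                corr, "inflection", min_cluster_size, grid, gene_ids, cut))
        elif m := _WGCNA_RE.match(name):
            rule = "inflection" if m.group(1) == "1" else "traditional"
            corr = _single_omics_correlation(studies[0])
            out[name] = score(cluster_correlation_matrix(
                corr, rule, min_cluster_size, grid, gene_ids, cut))
        elif m := _KMEANS_RE.match(name):
            rng = kmeans_rng if kmeans_rng is not None else np.random.default_rng(0)
            X = studies[0].study.omics[0].to_numpy()  # genes x samples
            c_true = int(len(set(truth)))
            if m.group(1) == "1":
                c = c_true
            else:
                c = _gap_statistic_k(X, c_true + 10, rng)
            km = KMeans(n_clusters=c, n_init=25,
                        random_state=int(rng.integers(2**31))).fit(X)
            out[name] = adjusted_rand_index(truth, km.labels_)
        else:
            raise ValueError(f"unknown method name {name!r}")
    return out


def run_scenario(
    configs: Sequence[SimulationConfig],
    methods: Sequence[str],
    n_reps: int = 100,
    master_seed: int = 0,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    grid: tuple[int, ...] = DEFAULT_POWER_GRID,
    cut: str | float = "modules",
) -> dict[str, MethodResult]:
    """Replicate the pipeline ``n_reps`` times and aggregate per-method ARIs.

    Fully seeded: replicate r uses the r-th child of ``master_seed``'s seed
    sequence, so results are bit-reproducible and extending the roster of
    methods does not change the simulated data.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results: dict[str, MethodResult] = {m: MethodResult(m, []) for m in methods}
    rep_seeds = np.random.SeedSequence(master_seed).spawn(n_reps)
    for r in range(n_reps):
        state = rep_seeds[r].generate_state(2)
        studies = simulate_meta(configs, master_seed=int(state[0] % 2**31))
        km_rng = np.random.default_rng(int(state[1] % 2**31))
        aris = run_replicate(studies, methods, min_cluster_size, grid, cut, km_rng)
        for m, v in aris.items():
            results[m].aris.append(v)
    return results


def results_frame(results: dict[str, MethodResult]) -> pd.DataFrame:
    """Summary table: one row per method with mean and SD of the ARI."""
    return pd.DataFrame(
        [
            {"method": r.method, "mean_ari": r.mean, "sd_ari": r.sd, "n_reps": r.n_reps}
            for r in results.values()
        ]
    ).set_index("method")


def smallest_perfect_study_count(
    results: dict[str, MethodResult], measure: str, variant: str = "Diag",
    max_k: int = 5, tol: float = 0.0,
) -> int | None:
    """Smallest k with mean ARI of ``Meta_<measure>_<variant>_<k>`` >= 1 - tol.

    Expects the sweep methods (``Meta_MSOC_Diag_1`` ... ``_<max_k>``) to be
    present in ``results``; returns None when no k reaches the target.
    """
    suffix = f"_{variant}" if variant else ""
    for k in range(1, max_k + 1):
        name = f"Meta_{measure}{suffix}_{k}"
        if name not in results:
            raise KeyError(f"{name} not in results")
        if results[name].mean >= 1.0 - tol:
            return k
    return None
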