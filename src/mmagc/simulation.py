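"""Synthetic multi-study multi-omics data with planted gene clusters.

Genes are partitioned into equally sized clusters; every gene carries V
omics profiles.  The joint distribution of all ``G*V`` variables is
multivariate normal with mean 0 and a block correlation matrix parameterised
by five correlations:

* ``tau1`` — between omics of the same gene;
* ``tau2`` — same omics type, different genes, same cluster;
* ``tau3`` — different omics types, different genes, same cluster;
* ``tau4`` — any omics pair between genes of different clusters;
* ``tau5`` — background level used to *perturb* clusters: in each perturbed
  cluster, the omics-type-1 correlations of its first ``n_perturbed_genes``
  genes with omics type 1 of every other gene are rewired to ``tau5``, so
  that omics type 1 alone carries a discordant signal.

A proportion ``p`` of the clusters (the first ``ceil(p * n_clusters)``) is
perturbed.  Variables are ordered gene-major, omics-minor (gene 1 omics
1..V, gene 2 omics 1..V, ...), the same layout
:meth:`mmagc.omics_data.OmicsStudy.stacked` uses.

Defaults mirror the benchmark conditions: 50 genes in 10 clusters of 5,
V = 3 omics, per-study sample size 100, (tau1..tau5) = (0.6, 0.4, 0.3, 0.1,
0.1), p = 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .omics_data import OmicsStudy

__all__ = [
    "SimulationConfig",
    "LabeledStudy",
    "build_correlation_matrix",
    "apply_perturbation",
    "simulate_study",
    "simulate_meta",
    "case_configs",
]

#: Smallest admissible eigenvalue for a simulated correlation matrix; an
#: invalid tau combination fails loudly rather than being repaired.
PD_TOL = 1e-10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study."""

    n_clusters: int = 10
    cluster_size: int = 5
    n_omics: int = 3
    sample_size: int = 100
    tau1: float = 0.6
    tau2: float = 0.4
    tau3: float = 0.3
    tau4: float = 0.1
    tau5: float = 0.1
    p_perturbed: float = 0.3
    n_perturbed_genes: int = 3
    perturb_scope: str = "cluster"  # "cluster" or "global"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau3", "tau4", "tau5"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1)")
        if not 0.0 <= self.p_perturbed <= 1.0:
            raise ValueError("p_perturbed must lie in [0, 1]")
        if self.perturb_scope not in ("cluster", "global"):
            raise ValueError("perturb_scope must be 'cluster' or 'global'")
        if self.n_perturbed_genes > self.cluster_size:
            raise ValueError("n_perturbed_genes cannot exceed cluster_size")

    @property
    def n_genes(self) -> int:
        return self.n_clusters * self.cluster_size

    @property
    def taus(self) -> tuple[float, float, float, float, float]:
        return (self.tau1, self.tau2, self.tau3, self.tau4, self.tau5)

    @property
    def true_labels(self) -> np.ndarray:
        """Planted cluster label (1-based) per gene."""
        return np.repeat(np.arange(1, self.n_clusters + 1), self.cluster_size)

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class LabeledStudy:
    """A simulated study together with its planted cluster labels."""

    study: OmicsStudy
    labels: np.ndarray
    config: SimulationConfig = field(repr=False)


def build_correlation_matrix(cfg: SimulationConfig) -> np.ndarray:
    """The unperturbed ``(G*V) x (G*V)`` block correlation matrix.

    Raises if the tau combination is not positive definite (the offending
    smallest eigenvalue is reported).
    """
    G, V = cfg.n_genes, cfg.n_omics
    n = G * V
    gene_of = np.repeat(np.arange(G), V)
    omics_of = np.tile(np.arange(V), G)
    cluster_of = gene_of // cfg.cluster_size

    same_gene = gene_of[:, None] == gene_of[None, :]
    same_omics = omics_of[:, None] == omics_of[None, :]
    same_cluster = cluster_of[:, None] == cluster_of[None, :]

    M = np.full((n, n), cfg.tau4)
    M[same_cluster & ~same_gene & ~same_omics] = cfg.tau3
    M[same_cluster & ~same_gene & same_omics] = cfg.tau2
    M[same_gene] = cfg.tau1
    np.fill_diagonal(M, 1.0)
    _assert_pd(M, "correlation matrix")
    return M


def _assert_pd(M: np.ndarray, what: str) -> None:
    lam_min = float(np.linalg.eigvalsh(M)[0])
    if lam_min <= PD_TOL:
        raise ValueError(
            f"{what} is not positive definite (smallest eigenvalue {lam_min:.3e}); "
            "adjust the tau parameters"
        )


def perturbed_variable_indices(cfg: SimulationConfig) -> np.ndarray:
    """Stacked-variable indices of omics type 1 of the perturbed genes."""
    n_pert_clusters = math.ceil(cfg.p_perturbed * cfg.n_clusters)
    genes = []
    for c in range(n_pert_clusters):
        start = c * cfg.cluster_size
        genes.extend(range(start, start + cfg.n_perturbed_genes))
    return np.asarray(genes, dtype=int) * cfg.n_omics  # omics 1 sits first


def apply_perturbation(corr: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Rewire omics-1 correlations of the perturbed genes to ``tau5``.

    For each perturbed gene, its omics-type-1 correlation with omics type 1
    of the other genes of its cluster is set to ``tau5``, symmetrically; with
    ``perturb_scope="global"`` the rewiring extends to every other gene.  No
    other entries change.  The perturbed matrix must remain positive definite.

    The cluster-local default is forced by feasibility: when the
    between-cluster correlation ``tau4`` differs from ``tau5``, rewriting the
    cross-cluster omics-1 entries as well makes the matrix lose positive
    definiteness at the benchmark parameter settings (e.g. taus
    (0.4, 0.3, 0.3, 0.2, 0.1)), so those settings could never have been
    simulated under the global reading.  With ``tau4 == tau5`` the two scopes
    coincide.
    """
    out = np.asarray(corr, dtype=float).copy()
    pert = perturbed_variable_indices(cfg)
    if pert.size == 0:
        return out
    omics1 = np.arange(cfg.n_genes) * cfg.n_omics
    for v in pert:
        if cfg.perturb_scope == "global":
            targets = omics1[omics1 != v]
        else:
            g = v // cfg.n_omics
            cl = g // cfg.cluster_size
            mates = np.arange(cl * cfg.cluster_size, (cl + 1) * cfg.cluster_size)
            targets = mates[mates != g] * cfg.n_omics
        out[v, targets] = cfg.tau5
        out[targets, v] = cfg.tau5
    _assert_pd(out, "perturbed correlation matrix")
    return out


def simulate_study(
    cfg: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    study_id: str = "study1",
) -> LabeledStudy:
    """Draw one study: Sk iid samples from the perturbed multivariate normal."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    corr = apply_perturbation(build_correlation_matrix(cfg), cfg)
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((cfg.sample_size, corr.shape[0]))
    X = Z @ L.T  # (Sk, G*V), gene-major omics-minor

    gene_ids = cfg.gene_ids()
    sample_ids = [f"{study_id}_s{j + 1}" for j in range(cfg.sample_size)]
    omics = []
    for v in range(cfg.n_omics):
        omics.append(
            pd.DataFrame(X[:, v::cfg.n_omics].T, index=gene_ids, columns=sample_ids)
        )
    study = OmicsStudy(
        study_id=study_id,
        omics=omics,
        omics_names=[f"omics{v + 1}" for v in range(cfg.n_omics)],
    )
    return LabeledStudy(study=study, labels=cfg.true_labels, config=cfg)


def simulate_meta(
    cfgs: Sequence[SimulationConfig], master_seed: int
) -> list[LabeledStudy]:
    """Draw K independent studies with sub-seeds derived from ``master_seed``.

    All configs must agree on the structural fields (genes, clusters, omics);
    sample sizes and correlation parameters may differ per study.
    """
    if not cfgs:
        raise ValueError("need at least one study config")
    ref = cfgs[0]
    for c in cfgs[1:]:
        if (c.n_clusters, c.cluster_size, c.n_omics) != (
            ref.n_clusters, ref.cluster_size, ref.n_omics,
        ):
            raise ValueError("study configs differ in structural fields")
    children = np.random.SeedSequence(master_seed).spawn(len(cfgs))
    return [
        simulate_study(cfg, seed=np.random.default_rng(ss), study_id=f"study{k + 1}")
        for k, (cfg, ss) in enumerate(zip(cfgs, children))
    ]


def case_configs(
    case: int = 1,
    scenario: int = 1,
    n_studies: int = 5,
    sample_size: int | None = None,
) -> list[SimulationConfig]:
    """Study configurations of the three benchmark cases.

    Case 1: all studies iid.  Case 2: the last two studies have a higher
    perturbed-cluster proportion (p = 0.5).  Case 3: studies differ in
    (tau1, tau2) by +/- 0.1 around the base values.  Scenario 1 uses
    (tau1, tau2) = (0.6, 0.4) at sample size 100; scenario 2 swaps them and
    drops the sample size to 30, where clustering is no longer saturated.
    """
    if scenario == 1:
        base = dict(tau1=0.6, tau2=0.4, sample_size=sample_size or 100)
    elif scenario == 2:
        base = dict(tau1=0.4, tau2=0.6, sample_size=sample_size or 30)
    else:
        raise ValueError("scenario must be 1 or 2")
    mk = lambda **kw: SimulationConfig(**{**base, **kw})  # noqa: E731

    if case == 1:
        return [mk() for _ in range(n_studies)]
    if case == 2:
        if n_studies != 5:
            raise ValueError("case 2 is defined for 5 studies")
        return [mk() for _ in range(3)] + [mk(p_perturbed=0.5) for _ in range(2)]
    if case == 3:
        if n_studies != 5:
            raise ValueError("case 3 is defined for 5 studies")
        tuples = {
            1: [(0.6, 0.4), (0.7, 0.5), (0.5, 0.4), (0.6, 0.5), (0.5, 0.5)],
            2: [(0.4, 0.6), (0.5, 0.7), (0.4, 0.5), (0.5, 0.6), (0.5, 0.5)],
        }[scenario]
        return [mk(tau1=t1, tau2=t2) for t1, t2 in tuples]
    raise ValueError("case must be 1, 2 or 3")
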