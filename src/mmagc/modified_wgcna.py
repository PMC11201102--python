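"""Modified WGCNA clustering stage: power selection, TOM, tree cut, pruning.

The pooled gene-to-gene correlation matrix (entries in [0, 1]) is sharpened
by an elementwise integer power ``a = r^m`` (the adjacency), converted to the
topological overlap measure (TOM), and clustered by average-linkage
hierarchical clustering on ``1 - TOM``.  Two power-selection rules are
provided:

* the **traditional** scale-free criterion — smallest power with at least 60%
  adjusted R^2 of the log-log connectivity fit while the mean connectivity
  drops by at most 1/3 per step;
* the **inflection** rule — the smallest power at which the rate of change of
  the mean-connectivity change rate reaches its first local extremum, i.e.
  the first inflection point of the change-rate curve.  The traditional
  criterion tends to push the power high enough that mean connectivity is
  nearly zero; stopping at the first inflection keeps the network informative.

The change rate of the mean connectivity is measured relatively,
``rho(m) = (k(m-1) - k(m)) / k(m-1)`` — the same quantity the traditional
rule's "at most 1/3 per step" bound refers to.  The raw difference sequence
``k(m+1) - k(m)`` would not do: for any matrix with entries in [0, 1), k(m)
is a positive mixture of geometric sequences, so all its higher-order
differences are strictly monotone and would never show a local extremum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "adjacency",
    "mean_connectivity",
    "scale_free_fit",
    "connectivity_profile",
    "ConnectivityProfile",
    "select_power_traditional",
    "select_power_inflection",
    "tom",
    "cluster",
    "ClusterAssignment",
    "NOT_ASSESSABLE",
    "DEFAULT_POWER_GRID",
]

#: Sentinel returned by :func:`scale_free_fit` when fewer than three nonempty
#: connectivity bins remain (the log-log regression is then undefined).
NOT_ASSESSABLE = float("nan")

DEFAULT_POWER_GRID: tuple[int, ...] = tuple(range(1, 21))


def _check_similarity(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if mat.min() < -1e-12 or mat.max() > 1 + 1e-12:
        raise ValueError(f"{name} entries must lie in [0, 1]")
    return np.clip(mat, 0.0, 1.0)


def adjacency(corr: np.ndarray, power: int) -> np.ndarray:
    """Elementwise ``corr ** power`` with unit diagonal (unsigned network)."""
    if power < 1:
        raise ValueError("power must be a positive integer")
    corr = _check_similarity(corr, "correlation matrix")
    adj = corr**power
    np.fill_diagonal(adj, 1.0)
    return adj


def mean_connectivity(adj: np.ndarray) -> float:
    """Mean over genes of the summed adjacency to all *other* genes."""
    adj = np.asarray(adj, dtype=float)
    return float((adj.sum(axis=1) - np.diag(adj)).mean())


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Adjusted R^2 of the scale-free topology fit.

    Per-gene connectivities are binned into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity) over the
    nonempty bins.  Returns ``nan`` (:data:`NOT_ASSESSABLE`) when fewer than
    three usable bins remain.
    """
    adj = np.asarray(adj, dtype=float)
    k = adj.sum(axis=1) - np.diag(adj)
    if adj.shape[0] < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} genes for {n_bins} bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins)
    mean_k = np.array(
        [k[which == i].mean() if freq[i] else np.nan for i in range(n_bins)]
    )
    usable = (freq > 0) & (mean_k > 0)
    if usable.sum() < 3:
        return NOT_ASSESSABLE
    fit = linregress(np.log10(mean_k[usable]), np.log10(freq[usable]))
    n = int(usable.sum())
    r2 = fit.rvalue**2
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


@dataclass
class ConnectivityProfile:
    """Mean connectivity and scale-free fit across a grid of powers."""

    grid: tuple[int, ...]
    mean_k: np.ndarray  # k(m) per grid power
    fit_r2: np.ndarray  # adjusted R^2 per grid power (may contain nan)
    change_rate: np.ndarray = field(init=False)  # rho(m), nan at the first power

    def __post_init__(self) -> None:
        self.mean_k = np.asarray(self.mean_k, dtype=float)
        self.fit_r2 = np.asarray(self.fit_r2, dtype=float)
        rho = np.full_like(self.mean_k, np.nan)
        prev, cur = self.mean_k[:-1], self.mean_k[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            rho[1:] = (prev - cur) / prev
        self.change_rate = rho


def connectivity_profile(
    corr: np.ndarray, grid: tuple[int, ...] = DEFAULT_POWER_GRID, n_bins: int = 10
) -> ConnectivityProfile:
    """Evaluate mean connectivity and the scale-free fit over a power grid."""
    grid = tuple(int(m) for m in grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("power grid must be strictly ascending")
    corr = _check_similarity(corr, "correlation matrix")
    fit_ok = corr.shape[0] >= 2 * n_bins  # too few genes: fit not assessable
    mean_k, fit_r2 = [], []
    for m in grid:
        adj = adjacency(corr, m)
        mean_k.append(mean_connectivity(adj))
        fit_r2.append(scale_free_fit(adj, n_bins=n_bins) if fit_ok
                      else NOT_ASSESSABLE)
    return ConnectivityProfile(grid=grid, mean_k=np.array(mean_k), fit_r2=np.array(fit_r2))


def select_power_traditional(
    corr: np.ndarray,
    grid: tuple[int, ...] = DEFAULT_POWER_GRID,
    min_fit: float = 0.60,
    max_change_rate: float = 1.0 / 3.0,
    profile: ConnectivityProfile | None = None,
) -> int:
    """Smallest power meeting the scale-free criterion.

    Requires adjusted R^2 >= ``min_fit`` and a relative mean-connectivity drop
    of at most ``max_change_rate`` from the previous grid power (vacuous at
    the first grid point).  Falls back to the R^2-maximising power, with a
    warning, when no power qualifies.
    """
    if len(grid) < 3:
        raise ValueError("power grid needs at least 3 points")
    prof = profile if profile is not None else connectivity_profile(corr, grid)
    for i, m in enumerate(prof.grid):
        if not np.isfinite(prof.fit_r2[i]) or prof.fit_r2[i] < min_fit:
            continue
        if i > 0 and prof.change_rate[i] > max_change_rate:
            continue
        return m
    finite = np.where(np.isfinite(prof.fit_r2))[0]
    fallback = prof.grid[int(finite[np.argmax(prof.fit_r2[finite])])] if len(finite) else prof.grid[0]
    warnings.warn(
        f"no power reaches adjusted R^2 >= {min_fit} with change rate <= "
        f"{max_change_rate:.3g}; falling back to the best-fit power {fallback}",
        stacklevel=2,
    )
    return fallback


def select_power_inflection(
    corr: np.ndarray,
    grid: tuple[int, ...] = DEFAULT_POWER_GRID,
    profile: ConnectivityProfile | None = None,
) -> int:
    """Smallest power at the first inflection of the connectivity change rate.

    With ``rho(m)`` the relative change rate of the mean connectivity and
    ``delta(m) = rho(m+1) - rho(m)`` its discrete rate of change, the rule
    returns the smallest grid power where ``delta`` attains a local extremum:
    a strict sign change of its first difference, or — when ``delta`` is
    monotone, as for a uniform correlation matrix whose connectivity decays
    geometrically — the grid boundary where its extreme value sits, which is
    the second grid power.
    """
    if len(grid) < 5:
        raise ValueError("power grid needs at least 5 points for the inflection rule")
    prof = profile if profile is not None else connectivity_profile(corr, grid)
    # Ignore the flat tail where the network has essentially emptied out:
    # there rho is dominated by round-off and shows spurious wiggles.
    alive = prof.mean_k > max(1e-12, 1e-3 * prof.mean_k[0])
    n_alive = int(alive.sum())
    rho = prof.change_rate[:n_alive]  # rho[i] defined for i >= 1
    delta = rho[2:] - rho[1:-1]  # delta[j] = rho(grid[j+2]) - rho(grid[j+1])
    if len(delta) < 1:
        warnings.warn(
            "connectivity collapses within two powers on this grid; "
            "falling back to the traditional criterion",
            stacklevel=2,
        )
        return select_power_traditional(corr, grid, profile=prof)
    d_delta = np.diff(delta)
    # sign changes below round-off scale (e.g. an exactly geometric k whose
    # delta is 0 up to float error) are not extrema
    tol = 1e-9 * max(float(np.nanmax(np.abs(rho))), 1e-12)
    for j in range(1, len(d_delta)):
        if (d_delta[j - 1] * d_delta[j] < 0
                and abs(d_delta[j - 1]) > tol and abs(d_delta[j]) > tol):
            # delta[j] is a strict interior extremum; it sits at grid index j + 1
            return prof.grid[j + 1]
    # delta is monotone: its extreme values sit at the grid boundary, and the
    # first of them is delta[0] — the change rate bends fastest right away.
    return prof.grid[1]


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a weighted unsigned network.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j with
    ``l_ij = sum_{g != i,j} a_ig a_gj`` and ``k_i = sum_{g != i} a_ig``;
    diagonal 1.  Entries stay in [0, 1] whenever the adjacency's do.
    """
    adj = _check_similarity(adj, "adjacency matrix")
    A = adj.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return np.clip(0.5 * (T + T.T), 0.0, 1.0)


@dataclass
class ClusterAssignment:
    """Gene-to-cluster labels; label 0 marks genes left unassigned by pruning."""

    labels: np.ndarray  # int, aligned with gene_ids
    gene_ids: list[str]
    min_cluster_size: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.gene_ids):
            raise ValueError("labels and gene_ids length mismatch")

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels > 0])))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(x) for x in self.labels)))


def _cut_height(
    Z: np.ndarray, policy: str | float, quantile: float, min_cluster_size: int
) -> float:
    heights = Z[:, 2]
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        return float(policy)
    if policy == "modules":
        # Candidate cuts: midpoints of the gaps between distinct merge
        # heights.  Keep the cut yielding the most clusters of at least the
        # minimum size; among ties prefer the highest cut (coarsest view).
        hs = np.unique(heights)
        cands = 0.5 * (hs[:-1] + hs[1:]) if len(hs) > 1 else hs
        best_h, best_n = float(hs[-1] + 1.0), 1
        for h in cands[::-1]:
            flat = hierarchy.fcluster(Z, t=float(h), criterion="distance")
            n_ok = int((np.bincount(flat)[1:] >= min_cluster_size).sum())
            if n_ok > best_n:
                best_h, best_n = float(h), n_ok
        return best_h
    if policy == "gap":
        order = np.sort(heights)
        gaps = np.diff(order)
        j = int(np.argmax(gaps))
        return float(0.5 * (order[j] + order[j + 1]))
    if policy == "quantile":
        return float(np.quantile(heights, quantile))
    raise ValueError(f"unknown cut policy {policy!r}")


def cluster(
    tom_matrix: np.ndarray,
    min_cluster_size: int,
    gene_ids: list[str] | None = None,
    cut: str | float = "modules",
    quantile: float = 0.99,
) -> ClusterAssignment:
    """Average-linkage clustering on ``1 - TOM`` with minimum-size pruning.

    The dendrogram is cut at a height chosen by ``cut``:

    * ``"modules"`` (default) — the flat cut producing the largest number of
      clusters of at least ``min_cluster_size`` genes, the highest such cut
      when tied; the discrete counterpart of pruning by minimum cluster size;
    * ``"gap"`` — midpoint of the largest gap between consecutive sorted
      merge heights;
    * ``"quantile"`` — the ``quantile``-th quantile of merge heights;
    * a float — that absolute height.

    Clusters smaller than ``min_cluster_size`` are dissolved and each of
    their genes reassigned to the surviving cluster at the smallest average
    ``1 - TOM`` distance, or labelled 0 if no cluster survives.  Labels are
    renumbered 1..C by decreasing size (ties by first member index).
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    T = _check_similarity(tom_matrix, "TOM matrix")
    G = T.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(G)]
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    if G == 1:
        labels = np.array([1 if min_cluster_size <= 1 else 0])
        return ClusterAssignment(labels=labels, gene_ids=list(gene_ids),
                                 min_cluster_size=min_cluster_size)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    h = _cut_height(Z, cut, quantile, min_cluster_size)
    raw = hierarchy.fcluster(Z, t=h, criterion="distance")

    sizes = np.bincount(raw)
    surviving = [c for c in range(1, sizes.shape[0]) if sizes[c] >= min_cluster_size]
    labels = np.zeros(G, dtype=int)
    if surviving:
        keep_mask = np.isin(raw, surviving)
        for c in surviving:
            labels[raw == c] = c
        # dissolve small clusters: reassign by smallest average distance
        for g in np.where(~keep_mask)[0]:
            avg = [D[g, raw == c].mean() for c in surviving]
            labels[g] = surviving[int(np.argmin(avg))]
        # renumber by decreasing size, ties by first member
        final = sorted(
            set(labels[labels > 0]),
            key=lambda c: (-int((labels == c).sum()), int(np.argmax(labels == c))),
        )
        remap = {c: i + 1 for i, c in enumerate(final)}
        labels = np.array([remap.get(c, 0) for c in labels])
    return ClusterAssignment(
        labels=labels, gene_ids=list(gene_ids), min_cluster_size=min_cluster_size
    )
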