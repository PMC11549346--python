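"""Group-level inference: cluster-based permutation tests on time courses
and parcel maps, network-based statistics (NBS) on adjacency matrices,
right-tail Pearson correlation with Bonferroni correction, paired effect
sizes and BIC model comparison.

Both permutation procedures use random sign flips of subject-level paired
differences (the exchangeability scheme for paired designs) with
p = (1 + #{null ≥ observed}) / (1 + n_perm), maxsum of t-values as the
cluster statistic and the size (edge count) of the connected component as
the NBS statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr, t as t_dist

__all__ = [
    "ClusterResult",
    "NBSResult",
    "temporal_adjacency",
    "spatial_adjacency",
    "cluster_permutation_paired",
    "nbs_paired",
    "correlate_bonferroni",
    "cohens_d_paired",
    "bic",
    "paired_t",
]


@dataclass
class ClusterResult:
    clusters: list[np.ndarray]  # member element indices per cluster
    cluster_stats: np.ndarray  # signed maxsum of t-values
    p_values: np.ndarray
    t_obs: np.ndarray
    threshold: float
    alpha: float
    n_perm: int

    def significant(self, level: float = 0.05) -> list[np.ndarray]:
        return [c for c, p in zip(self.clusters, self.p_values) if p < level]


@dataclass
class NBSResult:
    components: list[np.ndarray]  # (m, 2) edge lists per component
    component_sizes: np.ndarray  # edge counts
    p_values: np.ndarray
    t_obs: np.ndarray  # (n, n) edge-wise t matrix
    threshold: float
    n_perm: int


def temporal_adjacency(n: int) -> sparse.csr_matrix:
    """Chain adjacency: consecutive samples are neighbours."""
    i = np.arange(n - 1)
    m = sparse.coo_matrix(
        (np.ones(2 * (n - 1)), (np.r_[i, i + 1], np.r_[i + 1, i])), shape=(n, n)
    )
    return m.tocsr()


def spatial_adjacency(centroids: np.ndarray, quantile: float = 0.10) -> sparse.csr_matrix:
    """Parcel adjacency: pairs closer than a centroid-distance quantile.

    The neighbourhood radius is the given quantile of all pairwise
    distances (default 10th percentile), a configurable stand-in for an
    anatomical neighbourhood definition.
    """
    c = np.asarray(centroids)
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    iu = np.triu_indices(c.shape[0], 1)
    radius = np.quantile(d[iu], quantile)
    adj = (d <= radius) & ~np.eye(c.shape[0], dtype=bool)
    return sparse.csr_matrix(adj.astype(float))


def paired_t(d: np.ndarray) -> np.ndarray:
    """Element-wise paired t from a (subjects × elements) difference array.

    Elements with zero variance get t = 0 (excluded from clusters) with a
    warning.
    """
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} element(s) with zero variance excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t


def _clusters_from_mask(
    mask: np.ndarray, adjacency: sparse.csr_matrix | None
) -> list[np.ndarray]:
    """Connected components of suprathreshold elements."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    if adjacency is None:  # 1-d chain: contiguous runs
        breaks = np.flatnonzero(np.diff(idx) > 1)
        return np.split(idx, breaks + 1)
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _perm_t_chunks(d: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 500):
    """Yield (offset, t-fields) for sign-flip permutations, vectorised.

    The per-element sum of squares is sign-flip invariant, so each
    permutation's t field follows from its flipped mean alone.
    """
    n_sub = d.shape[0]
    ss = (d**2).sum(axis=0)
    sqrt_n = np.sqrt(n_sub)
    for lo in range(0, n_perm, chunk):
        m = min(chunk, n_perm - lo)
        signs = rng.choice([-1.0, 1.0], size=(m, n_sub))
        mean_p = signs @ d / n_sub
        var_p = (ss[None, :] - n_sub * mean_p**2) / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = np.where(var_p > 0, mean_p * sqrt_n / np.sqrt(var_p), 0.0)
        yield lo, t_p


def _max_cluster_stat(
    t: np.ndarray, thr: float, adjacency: sparse.csr_matrix | None
) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        for cl in _clusters_from_mask(sign * t > thr, adjacency):
            best = max(best, abs(float(t[cl].sum())))
    return best


def cluster_permutation_paired(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: sparse.csr_matrix | None = None,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterResult:
    """Mass-univariate cluster-based paired two-tailed permutation test.

    ``a`` and ``b`` are (subjects × elements); elements are time samples
    (adjacency None → chain) or parcels (supply a spatial adjacency).
    The cluster-forming threshold is the parametric two-tailed t critical
    value at ``alpha`` with subjects − 1 df; clusters form separately for
    positive and negative t; the null is the max |maxsum| under random
    sign flips of the paired differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("a and b must be equal-shape (subjects >= 2, elements)")
    d = a - b
    n_sub, n_el = d.shape
    thr = float(t_dist.ppf(1 - alpha / 2, n_sub - 1))
    t_obs = paired_t(d)

    clusters: list[np.ndarray] = []
    stats: list[float] = []
    for sign in (1.0, -1.0):
        for cl in _clusters_from_mask(sign * t_obs > thr, adjacency):
            clusters.append(cl)
            stats.append(float(t_obs[cl].sum()))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for lo, t_chunk in _perm_t_chunks(d, n_perm, rng):
        for i in range(t_chunk.shape[0]):
            null[lo + i] = _max_cluster_stat(t_chunk[i], thr, adjacency)

    p_values = np.array(
        [(1 + np.sum(null >= abs(s))) / (1 + n_perm) for s in stats]
    )
    return ClusterResult(
        clusters, np.asarray(stats), p_values, t_obs, thr, alpha, n_perm
    )


def _edge_components(
    t_edges: np.ndarray, thr: float, iu: tuple[np.ndarray, np.ndarray], n_nodes: int
) -> tuple[list[np.ndarray], list[int]]:
    comps: list[np.ndarray] = []
    sizes: list[int] = []
    for sign in (1.0, -1.0):
        mask = sign * t_edges > thr
        if not mask.any():
            continue
        rows, cols = iu[0][mask], iu[1][mask]
        g = sparse.coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes)
        )
        n_comp, labels = connected_components(g, directed=False)
        edge_label = labels[rows]
        for c in np.unique(edge_label):
            sel = edge_label == c
            comps.append(np.column_stack([rows[sel], cols[sel]]))
            sizes.append(int(sel.sum()))
    return comps, sizes


def nbs_paired(
    a: np.ndarray,
    b: np.ndarray,
    edge_alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> NBSResult:
    """Network-based statistic for paired symmetric adjacency matrices.

    ``a``, ``b``: (subjects × n × n).  Edge-wise paired t thresholded
    two-tailed at ``edge_alpha``; the statistic is the edge count of each
    connected suprathreshold component, compared to the sign-flip null
    of the maximum component size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise ValueError("a and b must be (subjects, n, n)")
    n_sub, n_nodes = a.shape[0], a.shape[1]
    iu = np.triu_indices(n_nodes, 1)
    d = (a - b)[:, iu[0], iu[1]]  # (subjects, n_edges)
    thr = float(t_dist.ppf(1 - edge_alpha / 2, n_sub - 1))
    t_obs_edges = paired_t(d)

    comps, sizes = _edge_components(t_obs_edges, thr, iu, n_nodes)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for lo, t_chunk in _perm_t_chunks(d, n_perm, rng):
        for i in range(t_chunk.shape[0]):
            _, perm_sizes = _edge_components(t_chunk[i], thr, iu, n_nodes)
            null[lo + i] = max(perm_sizes) if perm_sizes else 0
    p_values = np.array([(1 + np.sum(null >= s)) / (1 + n_perm) for s in sizes])

    t_mat = np.zeros((n_nodes, n_nodes))
    t_mat[iu] = t_obs_edges
    t_mat += t_mat.T
    return NBSResult(comps, np.asarray(sizes), p_values, t_mat, thr, n_perm)


def correlate_bonferroni(
    x: np.ndarray, y: np.ndarray, m_tests: int = 1
) -> tuple[float, float]:
    """Right-tail Pearson correlation with Bonferroni-corrected p.

    Returns (r, min(1, p_right · m_tests)).  Zero-variance input yields
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance input; correlation undefined")
        return float("nan"), float("nan")
    res = pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(min(1.0, res.pvalue * m_tests))


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Cohen's d: mean(a − b) / sd(a − b) (sample sd, ddof = 1)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences; Cohen's d undefined")
        return float("nan")
    return float(d.mean() / sd)


def bic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood BIC up to additive constants: n·ln(RSS/n) + k·ln(n)."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k:
        raise ValueError("need n > k")
    return float(n * np.log(rss / n) + k * np.log(n))
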