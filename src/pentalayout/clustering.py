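"""Ward hierarchical clustering, quantum clustering, spectral co-clustering,
and consensus co-occurrence across parameter sweeps.

Quantum clustering forms the Parzen-window wavefunction
``psi(x) = sum_i exp(-||x - x_i||^2 / (2 sigma^2))`` and the potential
``V(x) = E + (sigma^2 / 2) * laplacian(psi) / psi`` with ``E`` chosen so
``min V = 0`` over the data points; each point descends the gradient of
``V`` and points whose terminal positions fall within a merge radius share
a cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import SpectralCoclustering

__all__ = [
    "Dendrogram",
    "Partition",
    "ConsensusMatrix",
    "ClusterSweepConfig",
    "ward_cluster",
    "pca_whiten",
    "quantum_cluster",
    "spectral_cocluster",
    "consensus_cooccurrence",
    "run_sweep",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history: ``(node_a, node_b, height, new_node)``
    with leaves ``0..n-1`` and internal nodes ``n..2n-2``."""

    merges: Tuple[Tuple[int, int, float, int], ...]
    leaf_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves need {n - 1} merges, got {len(self.merges)}")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """SciPy linkage matrix (cluster sizes recomputed)."""
        n = len(self.leaf_labels)
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for row, (a, b, h, new) in enumerate(self.merges):
            sizes[new] = sizes[a] + sizes[b]
            Z[row] = [a, b, h, sizes[new]]
        return Z

    def cut(self, k: int) -> Dict[str, int]:
        """Flat clustering into ``k`` groups."""
        labels = hierarchy.fcluster(self.to_linkage(), k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.leaf_labels, labels)}

    def to_newick(self) -> str:
        n = len(self.leaf_labels)
        children: Dict[int, Tuple[int, int]] = {}
        height: Dict[int, float] = {i: 0.0 for i in range(n)}
        for a, b, h, new in self.merges:
            children[new] = (a, b)
            height[new] = h

        def render(node: int) -> str:
            if node < n:
                return self.leaf_labels[node].replace(" ", "_")
            a, b = children[node]
            la = max(height[node] - height[a], 0.0)
            lb = max(height[node] - height[b], 0.0)
            return f"({render(a)}:{la:.6g},{render(b)}:{lb:.6g})"

        root = n + len(self.merges) - 1
        return render(root) + ";"


@dataclass(frozen=True)
class Partition:
    """Flat assignment of items to clusters, with the parameters that
    produced it."""

    assignment: Dict[str, int]
    method: str = ""
    parameter: float = 0.0
    transform: str = ""

    @property
    def items(self) -> Tuple[str, ...]:
        return tuple(self.assignment)

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, items: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in items])


class ConsensusMatrix:
    """Fraction of sweep runs in which two items share a cluster."""

    def __init__(self, items: Sequence[str], values: np.ndarray, n_runs: int):
        values = np.asarray(values, dtype=float)
        n = len(items)
        if values.shape != (n, n):
            raise ValueError("consensus matrix must be square over the items")
        if not np.allclose(values, values.T):
            raise ValueError("consensus matrix must be symmetric")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(values), 1.0):
            raise ValueError("consensus diagonal must be 1")
        self.items = list(items)
        self.values = values
        self.n_runs = n_runs

    def blocks(self, threshold: float = 0.5) -> Dict[str, int]:
        """Connected components of the thresholded co-occurrence graph."""
        n = len(self.items)
        adj = self.values >= threshold
        label = [-1] * n
        current = 0
        for start in range(n):
            if label[start] >= 0:
                continue
            stack = [start]
            label[start] = current
            while stack:
                u = stack.pop()
                for v in range(n):
                    if adj[u, v] and label[v] < 0:
                        label[v] = current
                        stack.append(v)
            current += 1
        return {item: lab for item, lab in zip(self.items, label)}


@dataclass(frozen=True)
class ClusterSweepConfig:
    """Parameter grids for the secondary (consensus) clustering.

    ``sigma_grid`` entries are multiples of the median pairwise distance of
    the whitened embedding; ``k_grid`` entries are bicluster counts.
    """

    sigma_grid: Tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
    k_grid: Tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10)
    transforms: Tuple[str, ...] = ("log2", "proportional")
    n_components: int = 5

    def __post_init__(self) -> None:
        if not self.sigma_grid or not self.k_grid:
            raise ValueError("parameter grids must be non-empty")
        if any(s <= 0 for s in self.sigma_grid):
            raise ValueError("sigma grid entries must be positive")
        if any(k < 2 for k in self.k_grid):
            raise ValueError("k grid entries must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        bad = set(self.transforms) - {"log2", "proportional"}
        if bad:
            raise ValueError(f"unknown transforms: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Ward


def ward_cluster(
    matrix: np.ndarray, labels: Sequence[str], axis: str = "rows"
) -> Dendrogram:
    """Ward minimum-variance agglomeration with Euclidean base distance."""
    data = np.asarray(matrix, dtype=float)
    if axis == "columns":
        data = data.T
    elif axis != "rows":
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in clustering input")
    if len(labels) != data.shape[0]:
        raise ValueError("label count does not match item count")
    Z = hierarchy.linkage(data, method="ward")
    n = data.shape[0]
    merges = tuple(
        (int(Z[i, 0]), int(Z[i, 1]), float(Z[i, 2]), n + i) for i in range(n - 1)
    )
    return Dendrogram(merges=merges, leaf_labels=tuple(labels))


def ward_from_distance_vector(
    condensed: np.ndarray, labels: Sequence[str]
) -> Dendrogram:
    """Ward agglomeration from a precomputed condensed distance vector."""
    condensed = np.asarray(condensed, dtype=float)
    Z = hierarchy.linkage(condensed, method="ward")
    n = len(labels)
    merges = tuple(
        (int(Z[i, 0]), int(Z[i, 1]), float(Z[i, 2]), n + i) for i in range(n - 1)
    )
    return Dendrogram(merges=merges, leaf_labels=tuple(labels))


# ---------------------------------------------------------------------------
# PCA whitening


def pca_whiten(
    matrix: np.ndarray, n_components: int = 5
) -> Tuple[np.ndarray, np.ndarray]:
    """Project items (rows) on the top singular directions and scale each
    to unit variance.

    Returns ``(embedding, explained variance fractions)``. Components
    beyond the effective rank are dropped with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need more than one item")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
    if k == 0:
        return np.zeros((X.shape[0], 1)), np.zeros(1)
    scores = U[:, :k] * s[:k]
    emb = scores / scores.std(axis=0, ddof=0, keepdims=True)
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return emb, explained


# ---------------------------------------------------------------------------
# quantum clustering


def _qc_potential_and_gradient(
    x: np.ndarray, points: np.ndarray, sigma: float
) -> Tuple[float, np.ndarray]:
    diff = x[None, :] - points  # (n, d)
    r2 = np.einsum("ij,ij->i", diff, diff)
    w = np.exp(-r2 / (2.0 * sigma**2))
    s0 = w.sum()
    if s0 <= 0:
        return 0.0, np.zeros_like(x)
    s2 = float(r2 @ w)
    v = s2 / (2.0 * sigma**2 * s0)
    grad_s2 = (w * (2.0 - r2 / sigma**2)) @ diff
    grad_s0 = -(w @ diff) / sigma**2
    grad_v = (grad_s2 * s0 - s2 * grad_s0) / (2.0 * sigma**2 * s0**2)
    return v, grad_v


def quantum_cluster(
    embedding: np.ndarray,
    sigma: float,
    labels: Optional[Sequence[str]] = None,
    max_iter: int = 200,
    step_fraction: float = 0.1,
    merge_fraction: float = 0.25,
    transform: str = "",
) -> Partition:
    """Assign points to basins of attraction of the quantum potential.

    Each point performs a normalized gradient descent with initial step
    ``step_fraction * sigma``; the step is halved whenever it fails to
    decrease the potential, and descent stops once the step drops below
    ``1e-5 * sigma`` or ``max_iter`` is reached. Non-converged points are
    attached to the nearest converged terminal (logged). Terminals within
    ``merge_fraction * sigma`` of each other share a cluster.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.asarray(embedding, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if n == 1:
        return Partition({labels[0]: 0}, method="qc", parameter=sigma, transform=transform)

    terminals = np.empty_like(pts)
    converged = np.ones(n, dtype=bool)
    for i in range(n):
        x = pts[i].copy()
        step = step_fraction * sigma
        v, g = _qc_potential_and_gradient(x, pts, sigma)
        it = 0
        while step >= 1e-5 * sigma and it < max_iter:
            gn = np.linalg.norm(g)
            if gn == 0:
                break
            candidate = x - step * g / gn
            vc, gc = _qc_potential_and_gradient(candidate, pts, sigma)
            if vc < v:
                x, v, g = candidate, vc, gc
            else:
                step *= 0.5
            it += 1
        if it >= max_iter and step >= 1e-5 * sigma:
            converged[i] = False
        terminals[i] = x
    if not converged.all():
        bad = np.flatnonzero(~converged)
        log.info("%d QC descents hit max_iter; attaching to nearest terminal", len(bad))
        good = np.flatnonzero(converged)
        if good.size:
            for i in bad:
                j = good[np.argmin(np.linalg.norm(terminals[good] - terminals[i], axis=1))]
                terminals[i] = terminals[j]

    # union terminals within the merge radius
    radius = merge_fraction * sigma
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(terminals[i] - terminals[j]) <= radius:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots: Dict[int, int] = {}
    assignment = {}
    for i, lab in enumerate(labels):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        assignment[lab] = roots[r]
    return Partition(assignment, method="qc", parameter=sigma, transform=transform)


# ---------------------------------------------------------------------------
# spectral co-clustering


def spectral_cocluster(
    matrix: np.ndarray,
    k: int,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    random_state: int = 0,
    transform: str = "",
) -> Tuple[Partition, Partition]:
    """Bipartite spectral biclustering into ``k`` row/column groups.

    Real-valued input is shifted by its global minimum to nonnegativity; a
    degenerate (constant) matrix yields an arbitrary but valid partition
    with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(matrix dimensions)={min(X.shape)}")
    lo = X.min()
    if lo < 0:
        X = X - lo
    if np.ptp(X) == 0:
        warnings.warn("constant matrix; spectral co-clustering is degenerate")
        rows = {lab: i % k for i, lab in enumerate(row_labels)}
        cols = {lab: i % k for i, lab in enumerate(col_labels)}
        return (
            Partition(rows, method="scc_rows", parameter=k, transform=transform),
            Partition(cols, method="scc_cols", parameter=k, transform=transform),
        )
    X = X + 1e-9 * X.max()  # keep row/column sums strictly positive
    model = SpectralCoclustering(n_clusters=k, random_state=random_state)
    model.fit(X)
    rows = {lab: int(c) for lab, c in zip(row_labels, model.row_labels_)}
    cols = {lab: int(c) for lab, c in zip(col_labels, model.column_labels_)}
    return (
        Partition(rows, method="scc_rows", parameter=k, transform=transform),
        Partition(cols, method="scc_cols", parameter=k, transform=transform),
    )


# ---------------------------------------------------------------------------
# consensus


def consensus_cooccurrence(partitions: Sequence[Partition]) -> ConsensusMatrix:
    """Entry (i, j) = fraction of partitions in which i and j co-cluster."""
    if not partitions:
        raise ValueError("need at least one partition")
    items = sorted(partitions[0].items)
    for p in partitions[1:]:
        if sorted(p.items) != items:
            extra = set(p.items) ^ set(items)
            raise ValueError(f"partitions cover different items; difference: {sorted(extra)}")
    n = len(items)
    acc = np.zeros((n, n))
    for p in partitions:
        lab = p.labels_for(items)
        acc += (lab[:, None] == lab[None, :]).astype(float)
    vals = acc / len(partitions)
    np.fill_diagonal(vals, 1.0)
    return ConsensusMatrix(items, vals, n_runs=len(partitions))


def run_sweep(
    matrices: Dict[str, Tuple[np.ndarray, Sequence[str], Sequence[str]]],
    config: ClusterSweepConfig,
    axis: str = "rows",
    seed: int = 0,
) -> Tuple[ConsensusMatrix, List[Partition]]:
    """Quantum-clustering sigma sweep plus spectral-co-clustering k sweep,
    pooled into one co-occurrence consensus.

    ``matrices`` maps a transform tag to ``(matrix, row_labels,
    col_labels)``; only transforms listed in the config are used. The QC
    sigma grid is interpreted as multiples of the median pairwise distance
    of the whitened embedding. ``axis`` selects whether the consensus is
    over rows or columns.
    """
    missing = [t for t in config.transforms if t not in matrices]
    if missing:
        raise KeyError(f"transforms not among supplied matrices: {missing}")
    partitions: List[Partition] = []
    for transform in config.transforms:
        matrix, row_labels, col_labels = matrices[transform]
        X = np.asarray(matrix, dtype=float)
        items_matrix = X if axis == "rows" else X.T
        item_labels = row_labels if axis == "rows" else col_labels
        emb, _ = pca_whiten(items_matrix, config.n_components)
        med = float(np.median(pdist(emb))) if emb.shape[0] > 1 else 1.0
        if med == 0:
            med = 1.0
        for mult in config.sigma_grid:
            partitions.append(
                quantum_cluster(
                    emb, mult * med, labels=item_labels, transform=transform
                )
            )
        for k in config.k_grid:
            rp, cp = spectral_cocluster(
                X, k, row_labels, col_labels, random_state=seed, transform=transform
            )
            partitions.append(rp if axis == "rows" else cp)
    return consensus_cooccurrence(partitions), partitions
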