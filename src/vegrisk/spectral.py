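"""Spectral clustering with Calinski–Harabasz model selection.

The classifier follows the normalized spectral clustering recipe of
Ng, Jordan & Weiss:

1. standardize the (pc, hi, moe) features column-wise;
2. build an RBF affinity ``A[u, v] = exp(-gamma * ||z_u - z_v||^2)``;
3. form the symmetric normalized Laplacian
   ``L = I - D^{-1/2} A D^{-1/2}`` (self-affinities excluded) and take the
   eigenvectors of its k smallest eigenvalues, row-normalized to the unit
   sphere;
4. run k-means (Lloyd's algorithm, greedy distance-weighted seeding,
   multiple restarts) in the embedding and map labels back to the rows.

The kernel width gamma and the cluster count k are chosen by maximizing the
Calinski–Harabasz (CH) index over a grid — CH is evaluated in the original
standardized feature space so scores are comparable across k. Everything is
deterministic for a fixed seed.

An ``embedding="affinity"`` mode (eigenvectors of the *largest* eigenvalues
of A itself) is provided for sensitivity checks; the Laplacian mode is the
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_features",
    "rbf_affinity",
    "normalized_laplacian",
    "spectral_embed",
    "kmeans",
    "spectral_cluster",
    "calinski_harabasz",
    "grid_search",
    "ClusterAssignment",
    "GridSearchResult",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """k-means output: per-row labels, cluster count and final inertia."""

    labels: np.ndarray
    k: int
    inertia: float

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise DomainError(
                f"labels must use every cluster id in 0..{self.k - 1}, found {present}"
            )


@dataclass(frozen=True)
class GridSearchResult:
    """CH scores over the (gamma, k) grid plus the selected optimum.

    ``table`` has columns gamma, k, ch_score (NaN where a cell failed);
    ``best`` attains the maximum score, ties broken by smaller k then
    smaller gamma.
    """

    table: pd.DataFrame
    best: tuple[float, int]
    assignment: ClusterAssignment = field(repr=False)


def standardize_features(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Center each column and scale to unit variance (population variance).

    Constant columns are centered only (with a warning): they carry no
    clustering information, and dividing by zero would poison the matrix.
    """
    Z = np.asarray(X, dtype=float)
    if Z.ndim != 2:
        raise DomainError("feature matrix must be 2-D")
    if Z.shape[0] < 2:
        raise DomainError("need at least 2 rows to standardize")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("constant feature column(s) %s pass through centered", np.where(constant)[0])
    sd = np.where(constant, 1.0, sd)
    return (Z - mean) / sd


def rbf_affinity(Z: np.ndarray, parameter: float) -> np.ndarray:
    """Gaussian affinity exp(-parameter * squared Euclidean distance).

    Symmetric with unit diagonal; entries in (0, 1].
    """
    if parameter <= 0:
        raise DomainError(f"kernel parameter must be positive, got {parameter}")
    Z = np.asarray(Z, dtype=float)
    d2 = squareform(pdist(Z, metric="sqeuclidean"))
    A = np.exp(-parameter * d2)
    np.fill_diagonal(A, 1.0)
    return A


def normalized_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetric normalized graph Laplacian L = I - D^{-1/2} A D^{-1/2}.

    Self-affinities (the diagonal) are excluded from the graph, so degrees
    sum affinities to *other* nodes only. Eigenvalues lie in [0, 2] with
    smallest exactly 0.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DomainError("affinity must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise DomainError("affinity must be symmetric")
    W = A.copy()
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise DomainError(f"zero-degree row(s) {np.where(deg <= 0)[0]}: graph is disconnected points")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -W * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, 1.0)
    return (L + L.T) / 2.0


def _row_normalize(U: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(U, axis=1)
    safe = np.where(norms == 0, 1.0, norms)  # all-zero rows pass through
    return U / safe[:, None]


def spectral_embed(L: np.ndarray, k: int) -> np.ndarray:
    """Rows of the k bottom eigenvectors of L, normalized to unit length."""
    n = L.shape[0]
    if not 2 <= k <= n:
        raise DomainError(f"embedding dimension k={k} must satisfy 2 <= k <= n={n}")
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    return _row_normalize(vecs)


def _greedy_seed(E: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++ style) centroid seeding."""
    n = E.shape[0]
    centers = np.empty((k, E.shape[1]))
    centers[0] = E[rng.integers(n)]
    d2 = ((E - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = E[rng.integers(n)]
        else:
            centers[j] = E[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((E - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(E: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, float]:
    """Lloyd iterations until the assignment is stable; inertia is checked
    to be non-increasing at every step."""
    k = centers.shape[0]
    labels = np.full(E.shape[0], -1)
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = ((E[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(E.shape[0]), new_labels].sum())
        assert inertia <= prev_inertia + 1e-9, "k-means inertia increased"
        prev_inertia = inertia
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            if members.any():
                centers[j] = E[members].mean(axis=0)
            else:
                # empty cluster: reseed at the point farthest from its centroid
                dist_to_own = d2[np.arange(E.shape[0]), labels]
                far = int(dist_to_own.argmax())
                centers[j] = E[far]
                labels[far] = j
    d2 = ((E[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(E.shape[0]), labels].sum())
    return labels, inertia


def kmeans(
    E: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Seeded k-means: best inertia over ``n_restarts`` greedy-seeded Lloyd runs.

    Empty clusters arising mid-iteration are reseeded at the point farthest
    from its current centroid. Labels are relabelled by first appearance so
    the output is invariant to restart internals.
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if not 1 <= k <= n:
        raise DomainError(f"k={k} must satisfy 1 <= k <= n={n}")
    if n_restarts < 1:
        raise DomainError("n_restarts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centers = _greedy_seed(E, k, rng)
        labels, inertia = _lloyd(E, centers, max_iter)
        if len(np.unique(labels)) < k:
            continue  # degenerate restart (exact duplicates): try again
        if inertia < best_inertia - 1e-12:
            best_labels, best_inertia = labels, inertia
    if best_labels is None:
        raise DomainError(f"could not find {k} non-empty clusters (too few distinct points?)")
    # canonical relabelling: cluster ids in order of first appearance
    order = {old: new for new, old in enumerate(pd.unique(best_labels))}
    canonical = np.array([order[v] for v in best_labels])
    return ClusterAssignment(labels=canonical, k=k, inertia=best_inertia)


def spectral_cluster(
    X: np.ndarray | pd.DataFrame,
    parameter: float,
    k: int,
    seed: int | np.random.Generator = 0,
    *,
    embedding: str = "laplacian",
    n_restarts: int = 10,
    standardize: bool = True,
) -> ClusterAssignment:
    """Full spectral clustering of a feature matrix at one (gamma, k)."""
    Z = standardize_features(X) if standardize else np.asarray(X, dtype=float)
    A = rbf_affinity(Z, parameter)
    E = _embed(A, k, embedding)
    return kmeans(E, k, seed=seed, n_restarts=n_restarts)


def _embed(A: np.ndarray, k: int, embedding: str) -> np.ndarray:
    if embedding == "laplacian":
        return spectral_embed(normalized_laplacian(A), k)
    if embedding == "affinity":
        n = A.shape[0]
        if not 2 <= k <= n:
            raise DomainError(f"k={k} must satisfy 2 <= k <= n={n}")
        _, vecs = eigh(A, subset_by_index=(n - k, n - 1))
        return _row_normalize(vecs[:, ::-1])
    raise DomainError(f"unknown embedding mode {embedding!r}")


def calinski_harabasz(X: np.ndarray | pd.DataFrame, labels: np.ndarray) -> float:
    """Calinski–Harabasz variance-ratio score.

    ``CH = [B / (k-1)] / [W / (n-k)]`` with B the size-weighted squared
    distance of cluster centroids to the grand mean and W the within-cluster
    sum of squares. Larger means better-separated clusters.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if not 2 <= k < n:
        raise DomainError(f"CH requires 2 <= k < n (k={k}, n={n})")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in uniq:
        members = X[labels == c]
        centroid = members.mean(axis=0)
        between += members.shape[0] * float(((centroid - grand) ** 2).sum())
        within += float(((members - centroid) ** 2).sum())
    if within == 0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def grid_search(
    X: np.ndarray | pd.DataFrame,
    parameters,
    ks,
    seed: int = 0,
    *,
    embedding: str = "laplacian",
    n_restarts: int = 10,
) -> GridSearchResult:
    """Evaluate CH for every (gamma, k) cell and pick the argmax.

    CH is computed on the standardized features, not the spectral embedding,
    so scores are comparable across k. Failing cells (degenerate clustering)
    score NaN, are excluded from the argmax and logged. Ties at the maximum
    are broken toward smaller k, then smaller gamma.
    """
    parameters = sorted(float(g) for g in parameters)
    ks = sorted(int(k) for k in ks)
    if not parameters or not ks:
        raise DomainError("parameter and k grids must be non-empty")
    Z = standardize_features(X)
    rows = []
    assignments: dict[tuple[float, int], ClusterAssignment] = {}
    for gi, gamma in enumerate(parameters):
        A = rbf_affinity(Z, gamma)
        for k in ks:
            cell_seed = np.random.default_rng(np.random.SeedSequence([int(seed), gi, int(k)]))
            try:
                E = _embed(A, k, embedding)
                assignment = kmeans(E, k, seed=cell_seed, n_restarts=n_restarts)
                score = calinski_harabasz(Z, assignment.labels)
            except DomainError as exc:
                logger.warning("grid cell (gamma=%g, k=%d) failed: %s", gamma, k, exc)
                rows.append({"gamma": gamma, "k": k, "ch_score": np.nan})
                continue
            assignments[(gamma, k)] = assignment
            rows.append({"gamma": gamma, "k": k, "ch_score": score})
    table = pd.DataFrame(rows, columns=["gamma", "k", "ch_score"])
    valid = table.dropna(subset=["ch_score"])
    if valid.empty:
        raise DomainError("every grid cell failed; no clustering selected")
    best_score = valid["ch_score"].max()
    contenders = valid[valid["ch_score"] == best_score].sort_values(["k", "gamma"])
    best_gamma = float(contenders.iloc[0]["gamma"])
    best_k = int(contenders.iloc[0]["k"])
    return GridSearchResult(
        table=table, best=(best_gamma, best_k), assignment=assignments[(best_gamma, best_k)]
    )
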