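"""K-means parcellation of connectivity profiles under correlation distance.

Each seed voxel's profile row is centered and scaled to unit norm once, so
the distance between a row and a centroid is 1 minus their Pearson
correlation.  Centroids are the means of their members' standardized rows,
re-standardized after every update — the update that maximizes the summed
correlation for unit-norm centroids — which keeps Lloyd iterations
monotonically non-increasing in inertia.  The best of ``n_restarts``
random initializations (lowest total within-cluster point-to-centroid
distance) is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "Parcellation",
    "CleanedParcellation",
    "kmeans_correlation",
    "remove_isolated_voxels",
    "label_agreement",
    "adjusted_rand",
    "contingency_table",
]

logger = logging.getLogger(__name__)

DEFAULT_N_RESTARTS = 100
MAX_LLOYD_ITER = 300


@dataclass
class Parcellation:
    """Seed-voxel labels 1..K for one K, with the winning restart's inertia."""

    labels: np.ndarray
    K: int
    inertia: float
    n_restarts: int
    rng_seed: int
    restart_inertias: np.ndarray = field(default_factory=lambda: np.array([]))
    n_reseeded: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels).tolist())
        missing = set(range(1, self.K + 1)) - present
        if missing:
            logger.warning("parcellation has empty clusters: %s", sorted(missing))
        if self.inertia < -1e-9:
            raise ValueError("inertia must be >= 0")


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms[:, 0] <= 0):
        raise ValueError("profile rows with zero variance cannot be clustered")
    return Xc / norms


def _restandardize_centroids(C: np.ndarray) -> np.ndarray:
    C = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1, keepdims=True)
    norms[norms[:, 0] <= 0] = 1.0
    return C / norms


def _lloyd_once(
    Xs: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, int]:
    """One restart: sample K distinct rows as seeds, iterate to convergence.

    Returns (labels 0-based, inertia, reseed count).  An empty cluster is
    re-seeded at the point currently farthest from its own centroid.
    """
    V = len(Xs)
    seeds = rng.choice(V, size=K, replace=False)
    C = _restandardize_centroids(Xs[seeds].copy())
    labels = np.full(V, -1)
    n_reseeded = 0
    for _ in range(MAX_LLOYD_ITER):
        corr = Xs @ C.T                      # V x K
        new_labels = np.argmax(corr, axis=1)  # argmax -> ties to lowest index
        dists = 1.0 - corr[np.arange(V), new_labels]
        for k in range(K):
            if not np.any(new_labels == k):
                far = int(np.argmax(dists))
                new_labels[far] = k
                dists[far] = 0.0
                n_reseeded += 1
                logger.debug("re-seeded empty cluster %d at voxel %d", k, far)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        C = _restandardize_centroids(
            np.vstack([Xs[labels == k].mean(axis=0) for k in range(K)])
        )
    corr = Xs @ C.T
    inertia = float(np.sum(1.0 - corr[np.arange(V), labels]))
    return labels, inertia, n_reseeded


def kmeans_correlation(
    profiles,
    K: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    rng_seed: int = 0,
) -> Parcellation:
    """Best-of-``n_restarts`` K-means with 1 - Pearson-r distance.

    ``profiles`` may be a ConnectivityProfiles or a bare V x T matrix.
    Deterministic for a given seed: each restart draws from an independent
    child stream of the master seed.
    """
    X = np.asarray(getattr(profiles, "z_matrix", profiles), dtype=float)
    V = len(X)
    if K < 1 or K > V:
        raise ValueError(f"K={K} must be in 1..{V}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 target features")
    Xs = _standardize(X)
    streams = np.random.SeedSequence(rng_seed).spawn(n_restarts)
    best_labels, best_inertia = None, np.inf
    inertias = np.empty(n_restarts)
    total_reseeded = 0
    for i, ss in enumerate(streams):
        labels, inertia, n_re = _lloyd_once(Xs, K, np.random.default_rng(ss))
        inertias[i] = inertia
        total_reseeded += n_re
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    return Parcellation(
        labels=best_labels + 1,
        K=K,
        inertia=best_inertia,
        n_restarts=n_restarts,
        rng_seed=rng_seed,
        restart_inertias=inertias,
        n_reseeded=total_reseeded,
    )


_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class CleanedParcellation:
    """Labels with small detached components flagged (not relabeled)."""

    labels: np.ndarray
    flagged: np.ndarray  # boolean, True = removed from its cluster's seed mask

    def cluster_mask(self, k: int) -> np.ndarray:
        return (self.labels == k) & ~self.flagged


def remove_isolated_voxels(
    parcellation: Parcellation,
    coords: np.ndarray,
    connectivity: int = 6,
    min_component: int = 3,
) -> CleanedParcellation:
    """Flag, per cluster, face-connected components smaller than ``min_component``.

    Isolated islands of a cluster are physiologically implausible seeds; they
    are excluded from that cluster's mask but keep their label for audit.
    """
    coords = np.asarray(coords, dtype=int)
    labels = parcellation.labels
    if len(coords) != len(labels):
        raise ValueError("coords must align with labels")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    origin = coords.min(axis=0)
    dims = coords.max(axis=0) - origin + 1
    flagged = np.zeros(len(labels), dtype=bool)
    for k in np.unique(labels):
        sel = labels == k
        grid = np.zeros(tuple(dims), dtype=bool)
        c = coords[sel] - origin
        grid[c[:, 0], c[:, 1], c[:, 2]] = True
        comp, n_comp = ndimage.label(grid, structure=structure)
        sizes = np.bincount(comp.ravel())
        comp_of_voxel = comp[c[:, 0], c[:, 1], c[:, 2]]
        flagged[np.flatnonzero(sel)[sizes[comp_of_voxel] < min_component]] = True
    return CleanedParcellation(labels=labels.copy(), flagged=flagged)


def contingency_table(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Joint count matrix over the two labelings' distinct values."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=int)
    np.add.at(table, (ai, bi), 1)
    return table


def label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Percent of voxels agreeing under the best one-to-one label matching.

    The optimal matching is found by solving the assignment problem on the
    contingency table, so the value is invariant to label permutations.
    """
    table = contingency_table(labels_a, labels_b)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return 100.0 * table[rows, cols].sum() / table.sum()


def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected Rand index in (-1, 1]."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    return float(adjusted_rand_score(a, b))
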