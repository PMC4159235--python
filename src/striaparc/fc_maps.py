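"""Seed-to-voxel connectivity maps of the parcels.

Per subject, the mean time series of every (cleaned) parcel enters one
multiple regression per target voxel, so each beta reflects that parcel's
unique variance after fitting the others.  Subject betas feed a
random-effects one-sample t-test; voxelwise thresholding at p < 0.001 is
followed by a sign-flip permutation max-cluster-size correction controlling
familywise error — a distribution-free stand-in for smoothness-based
topological corrections, requiring nothing beyond the subject maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .data_model import SubjectTimeSeries
from .parcellation import CleanedParcellation, Parcellation, _STRUCTURES

__all__ = [
    "FCStatMap",
    "SignificantCluster",
    "cluster_mean_timeseries",
    "seed_glm",
    "group_onesample_t",
    "cluster_extent_correct",
]


@dataclass
class SignificantCluster:
    voxel_indices: np.ndarray
    size: int
    peak_index: int
    peak_t: float
    corrected_p: float
    sign: str  # "positive" | "negative"

    @property
    def significant(self) -> bool:
        return self.corrected_p <= 0.05


@dataclass
class FCStatMap:
    """Group-level voxelwise statistics for one parcel seed."""

    cluster_id: int
    mean_beta: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    clusters: list[SignificantCluster] = field(default_factory=list)

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    seed_cluster=self.cluster_id,
                    sign=c.sign,
                    size=c.size,
                    peak_index=c.peak_index,
                    peak_t=c.peak_t,
                    corrected_p=c.corrected_p,
                    significant=c.significant,
                )
                for c in self.clusters
            ]
        )


def cluster_mean_timeseries(
    subject: SubjectTimeSeries,
    parcellation: Parcellation | CleanedParcellation,
) -> np.ndarray:
    """K x T matrix of mean seed series per parcel, excluding flagged voxels."""
    if isinstance(parcellation, CleanedParcellation):
        labels, flagged = parcellation.labels, parcellation.flagged
    else:
        labels, flagged = parcellation.labels, np.zeros(len(parcellation.labels), bool)
    if len(labels) != len(subject.roi_series):
        raise ValueError("parcellation does not match the subject's seed voxels")
    ks = np.unique(labels)
    out = np.empty((len(ks), subject.n_frames))
    for i, k in enumerate(ks):
        sel = (labels == k) & ~flagged
        if not sel.any():
            raise ValueError(f"cluster {k} has no voxels left after cleanup")
        out[i] = subject.roi_series[sel].mean(axis=0)
    return out


def seed_glm(target_series: np.ndarray, cluster_series: np.ndarray) -> np.ndarray:
    """OLS betas of every target voxel on all parcel series jointly (V x K).

    An intercept is always included; the returned matrix excludes it.  A
    rank-deficient design (collinear parcel series) is an error, reported
    with the offending regressor indices.
    """
    Y = np.asarray(target_series, float)
    S = np.asarray(cluster_series, float)
    K, T = S.shape
    if K >= T:
        raise ValueError(f"{K} regressors for {T} frames: underdetermined")
    D = np.column_stack([np.ones(T), S.T])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify which regressors collapse the rank
        bad = [
            k
            for k in range(K)
            if np.linalg.matrix_rank(np.delete(D, k + 1, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear cluster regressors: {bad}"
        )
    beta, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    return beta[1:].T


def group_onesample_t(subject_betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t (df = N - 1) and two-sided p across subjects.

    Input is N x V.  Voxels with zero between-subject variance get t = nan
    and are excluded from any downstream thresholding.
    """
    B = np.asarray(subject_betas, float)
    N = len(B)
    if N < 3:
        raise ValueError("need at least 3 subjects for a random-effects test")
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(N)), np.nan)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df=N - 1), np.nan)
    return t, p


def _suprathreshold_clusters(
    t_map: np.ndarray,
    coords: np.ndarray,
    t_crit: float,
    structure: np.ndarray,
    origin: np.ndarray,
    dims: np.ndarray,
) -> list[np.ndarray]:
    """Connected components of voxels with t > t_crit (one sign at a time)."""
    sel = np.flatnonzero(np.nan_to_num(t_map, nan=-np.inf) > t_crit)
    if sel.size == 0:
        return []
    grid = np.zeros(tuple(dims), bool)
    c = coords[sel] - origin
    grid[c[:, 0], c[:, 1], c[:, 2]] = True
    comp, n_comp = ndimage.label(grid, structure=structure)
    comp_of = comp[c[:, 0], c[:, 1], c[:, 2]]
    return [sel[comp_of == i] for i in range(1, n_comp + 1)]


def cluster_extent_correct(
    subject_betas: np.ndarray,
    coords: np.ndarray,
    voxel_p: float = 0.001,
    fwe_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 6,
    rng_seed: int = 0,
) -> list[SignificantCluster]:
    """Permutation max-cluster-size familywise correction by subject sign flips.

    The observed t map is thresholded one-sided per sign at ``voxel_p``;
    suprathreshold components are scored against the null distribution of the
    maximum component size (over both signs) under random sign flips of the
    subject maps.  Corrected p = (1 + #{null >= size}) / (1 + n_perm).
    """
    B = np.asarray(subject_betas, float)
    coords = np.asarray(coords, int)
    N, V = B.shape
    if len(coords) != V:
        raise ValueError("coords must align with the voxel axis")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable null tail")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    origin = coords.min(axis=0)
    dims = coords.max(axis=0) - origin + 1
    t_crit = stats.t.isf(voxel_p, df=N - 1) if voxel_p < 1 else -np.inf

    def tmap(M: np.ndarray) -> np.ndarray:
        mean = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, mean / (sd / np.sqrt(N)), np.nan)

    t_obs = tmap(B)
    observed = [
        (comp, sign_name)
        for sign, sign_name in ((1.0, "positive"), (-1.0, "negative"))
        for comp in _suprathreshold_clusters(
            sign * t_obs, coords, t_crit, structure, origin, dims
        )
    ]

    rng = np.random.default_rng(rng_seed)
    null_max = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        flips = rng.choice((-1.0, 1.0), size=N)[:, None]
        t_null = tmap(B * flips)
        biggest = 0
        for sign in (1.0, -1.0):
            for comp in _suprathreshold_clusters(
                sign * t_null, coords, t_crit, structure, origin, dims
            ):
                biggest = max(biggest, len(comp))
        null_max[i] = biggest

    clusters = []
    for comp, sign_name in observed:
        size = len(comp)
        p_corr = (1 + int(np.sum(null_max >= size))) / (1 + n_perm)
        signed_t = t_obs[comp] if sign_name == "positive" else -t_obs[comp]
        peak_local = int(np.argmax(signed_t))
        clusters.append(
            SignificantCluster(
                voxel_indices=comp,
                size=size,
                peak_index=int(comp[peak_local]),
                peak_t=float(t_obs[comp[peak_local]]),
                corrected_p=p_corr,
                sign=sign_name,
            )
        )
    clusters.sort(key=lambda c: c.corrected_p)
    return clusters
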