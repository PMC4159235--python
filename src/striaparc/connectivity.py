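"""Seed-voxel connectivity profiles.

A connectivity profile is, for each seed-ROI voxel, the vector of Fisher
z-transformed Pearson correlations with every target (rest-of-brain) voxel.
Subject-level profile matrices are averaged elementwise into a group matrix;
the z transform makes that average approximately variance-stabilized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityProfiles",
    "voxel_profile_matrix",
    "fisher_z",
    "group_average",
    "subject_profiles",
]

R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityProfiles:
    """V_roi x V_target Fisher-z matrix, at subject or group level."""

    z_matrix: np.ndarray
    level: str = "subject"  # "subject" | "group"
    subject_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.z_matrix = np.asarray(self.z_matrix, dtype=float)
        if self.z_matrix.ndim != 2:
            raise ValueError("profile matrix must be 2D")
        if not np.all(np.isfinite(self.z_matrix)):
            raise ValueError("profile matrix contains non-finite values")
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (rows, zero-variance flags)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    dead = norms[:, 0] <= 1e-12 * max(1.0, float(np.abs(X).max() or 1.0))
    norms[dead] = 1.0
    return Xc / norms, dead


def voxel_profile_matrix(roi_series: np.ndarray, target_series: np.ndarray) -> np.ndarray:
    """Pearson correlation of every seed voxel with every target voxel.

    Zero-variance voxels are flagged with a warning and contribute zero rows
    or columns, keeping the voxel indexing stable.
    """
    X = np.asarray(roi_series, float)
    Y = np.asarray(target_series, float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("roi and target series must share the time axis")
    Xs, dead_x = _standardize_rows(X)
    Ys, dead_y = _standardize_rows(Y)
    n_dead = int(dead_x.sum() + dead_y.sum())
    if n_dead:
        warnings.warn(f"{n_dead} zero-variance voxel(s); their correlations set to 0")
        Xs[dead_x] = 0.0
        Ys[dead_y] = 0.0
    return np.clip(Xs @ Ys.T, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform z = atanh(r), with |r| clamped just
    below 1 so perfect correlations stay finite."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -R_CLAMP, R_CLAMP))
    return float(z) if np.isscalar(r) else z


def subject_profiles(
    roi_series: np.ndarray, target_series: np.ndarray, subject_id: str = ""
) -> ConnectivityProfiles:
    """Subject-level Fisher-z profile matrix from raw series."""
    r = voxel_profile_matrix(roi_series, target_series)
    return ConnectivityProfiles(
        fisher_z(r), level="subject", subject_ids=(subject_id,) if subject_id else ()
    )


def group_average(profiles: list[ConnectivityProfiles]) -> ConnectivityProfiles:
    """Elementwise mean of subject z-matrices; provenance records the ids."""
    if not profiles:
        raise ValueError("no profiles to average")
    shape = profiles[0].z_matrix.shape
    for i, p in enumerate(profiles):
        if p.z_matrix.shape != shape:
            sid = p.subject_ids[0] if p.subject_ids else f"index {i}"
            raise ValueError(f"profile shape mismatch for subject {sid}: "
                             f"{p.z_matrix.shape} vs {shape}")
    mean = np.mean([p.z_matrix for p in profiles], axis=0)
    ids = tuple(sid for p in profiles for sid in p.subject_ids)
    return ConnectivityProfiles(mean, level="group", subject_ids=ids)
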