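"""Temporal preprocessing of voxel time series.

Mirrors the standard resting-state cleanup chain: dropping initial frames,
head-motion screening by framewise displacement (FD), despiking, anatomical
component-based (CompCor-style) nuisance estimation, and simultaneous
band-pass filtering plus nuisance regression.  Filtering both the data and
the nuisance design before regression prevents the regression from
reintroducing variance at frequencies the filter removed.

Defaults are the thresholds commonly used at 3 T with a long-TR EPI
sequence: FD < 0.30 mm mean, 1.5 mm / 1.5 deg maxima, a 0.009-0.1 Hz band,
and a 23-column nuisance design (6 motion + 6 derivatives + 5 white-matter
components + 5 CSF components + linear trend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MotionTrace

__all__ = [
    "NuisanceDesign",
    "ExclusionReport",
    "discard_initial_frames",
    "framewise_displacement",
    "apply_exclusion",
    "compcor_components",
    "despike",
    "build_nuisance_design",
    "bandpass_regress",
]

HEAD_RADIUS_MM = 50.0
N_INITIAL_DISCARD = 4
MAX_TRANSLATION_MM = 1.5
MAX_ROTATION_DEG = 1.5
MAX_MEAN_FD_MM = 0.30
DEFAULT_BAND_HZ = (0.009, 0.1)


@dataclass
class NuisanceDesign:
    """T x 23 named nuisance regressor matrix."""

    matrix: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names must match matrix width")

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.columns))


@dataclass
class ExclusionReport:
    """Per-subject motion screening summary."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def included_ids(self) -> list[str]:
        return self.rows.loc[self.rows["included"], "subject_id"].tolist()


def discard_initial_frames(arr: np.ndarray, n: int = N_INITIAL_DISCARD) -> np.ndarray:
    """Drop the first ``n`` frames along the last (time) axis."""
    if arr.shape[-1] <= n:
        raise ValueError(f"cannot discard {n} frames from series of length {arr.shape[-1]}")
    return arr[..., n:]


def framewise_displacement(
    motion: MotionTrace | np.ndarray, head_radius_mm: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-frame head displacement: sum of absolute backward parameter
    differences, rotations converted to arc length on a sphere of
    ``head_radius_mm``.  First entry is 0 by definition.
    """
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, float)
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    diffs = np.abs(np.diff(params, axis=0))
    diffs[:, 3:] *= head_radius_mm
    fd = np.zeros(len(params))
    fd[1:] = diffs.sum(axis=1)
    return fd


def apply_exclusion(
    traces: dict[str, MotionTrace],
    max_translation_mm: float = MAX_TRANSLATION_MM,
    max_rotation_deg: float = MAX_ROTATION_DEG,
    max_mean_fd: float = MAX_MEAN_FD_MM,
) -> ExclusionReport:
    """Screen subjects on maximum motion and mean FD (all strict thresholds)."""
    records = []
    for sid, trace in traces.items():
        max_trans = float(np.abs(trace.translations).max()) if len(trace.params) else 0.0
        max_rot_deg = float(np.degrees(np.abs(trace.rotations).max())) if len(trace.params) else 0.0
        mean_fd = float(framewise_displacement(trace).mean())
        included = (
            max_trans < max_translation_mm
            and max_rot_deg < max_rotation_deg
            and mean_fd < max_mean_fd
        )
        records.append(
            dict(
                subject_id=sid,
                max_translation_mm=max_trans,
                max_rotation_deg=max_rot_deg,
                mean_fd_mm=mean_fd,
                included=included,
            )
        )
    return ExclusionReport(pd.DataFrame.from_records(records))


def compcor_components(
    noise_voxel_series: np.ndarray, n_components: int = 5
) -> np.ndarray:
    """Principal-component time courses of a noise compartment (V x T in).

    Each voxel series is linearly detrended and scaled to unit variance
    before the SVD; the returned T x n matrix has orthonormal columns ordered
    by explained variance.  If the data support fewer than ``n_components``
    directions, the available ones are returned with a warning.
    """
    X = np.asarray(noise_voxel_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("noise series must be V x T")
    V, T = X.shape
    t = np.arange(T, dtype=float)
    t = (t - t.mean()) / (t.std() or 1.0)
    # per-voxel linear detrend
    slopes = X @ t / (T)
    X = X - X.mean(axis=1, keepdims=True) - np.outer(slopes, t)
    sd = X.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 1e-12
    X = np.where(sd > 0, X / np.where(sd > 0, sd, 1.0), 0.0)
    X = X[keep]
    if len(X) == 0:
        warnings.warn("no variance in noise compartment; returning 0 components")
        return np.zeros((T, 0))
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    avail = min(n_components, rank)
    if avail < n_components:
        warnings.warn(
            f"noise compartment supports {avail} components, {n_components} requested"
        )
    return vt[:avail].T


def despike(series: np.ndarray, mad_threshold: float = 3.0) -> np.ndarray:
    """Winsorize outliers on a robust z scale.

    Samples with |x - median| / (1.4826 * MAD) above ``mad_threshold`` are
    shrunk to the threshold boundary on their own side; everything else is
    untouched.  A constant series (MAD = 0) is returned unchanged with a
    warning.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("despike operates on a single 1D series")
    if len(x) < 5:
        raise ValueError("need at least 5 samples to despike")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale <= 0:
        warnings.warn("MAD is zero; series returned unchanged")
        return x.copy()
    z = (x - med) / scale
    bound = mad_threshold * scale
    return np.where(np.abs(z) > mad_threshold, med + np.sign(z) * bound, x)


def build_nuisance_design(
    motion: MotionTrace,
    wm_series: np.ndarray,
    csf_series: np.ndarray,
    n_compcor: int = 5,
) -> NuisanceDesign:
    """Assemble the 23-regressor design: 6 motion, 6 backward-difference
    motion derivatives (first row 0), 5 WM + 5 CSF component time courses,
    and a strictly increasing linear trend.
    """
    params = motion.params
    T = len(params)
    deriv = np.zeros_like(params)
    deriv[1:] = np.diff(params, axis=0)
    wm = compcor_components(wm_series, n_compcor)
    csf = compcor_components(csf_series, n_compcor)
    for name, comp in (("wm", wm), ("csf", csf)):
        if comp.shape[0] != T:
            raise ValueError(f"{name} components have {comp.shape[0]} frames, motion has {T}")
    trend = np.linspace(-1.0, 1.0, T)
    cols = (
        [f"motion_{i}" for i in range(1, 7)]
        + [f"motion_deriv_{i}" for i in range(1, 7)]
        + [f"wm_comp_{i}" for i in range(1, wm.shape[1] + 1)]
        + [f"csf_comp_{i}" for i in range(1, csf.shape[1] + 1)]
        + ["linear_trend"]
    )
    mat = np.column_stack([params, deriv, wm, csf, trend])
    return NuisanceDesign(mat, tuple(cols))


def _bandlimit(X: np.ndarray, band: tuple[float, float], tr_seconds: float) -> np.ndarray:
    """Zero-phase brick-wall band-pass along the last axis via the real FFT."""
    T = X.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(X, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


def bandpass_regress(
    series_matrix: np.ndarray,
    design: NuisanceDesign | np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    tr_seconds: float = 3.5,
) -> np.ndarray:
    """Simultaneous band-pass + nuisance regression (V x T in, V x T out).

    Both the data and the design are band-limited with the same zero-phase
    frequency-domain filter; the filtered data are then residualized on the
    filtered design by least squares, so the output carries no variance at
    out-of-band frequencies and none along any nuisance direction.
    """
    X = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    D = design.matrix if isinstance(design, NuisanceDesign) else np.asarray(design, float)
    D = np.atleast_2d(D)
    if D.shape[0] != X.shape[1]:
        raise ValueError(f"design has {D.shape[0]} rows, data has {X.shape[1]} frames")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if band[1] >= nyquist:
        raise ValueError(f"band upper edge {band[1]} Hz >= Nyquist {nyquist:.4f} Hz")
    Xf = _bandlimit(X, band, tr_seconds)
    Df = _bandlimit(D.T, band, tr_seconds).T
    # drop filtered columns with no remaining variance (e.g. a pure trend)
    norms = np.linalg.norm(Df, axis=0)
    live = norms > 1e-10 * max(norms.max(), 1.0)
    Dlive = Df[:, live]
    if Dlive.shape[1]:
        beta, *_ = np.linalg.lstsq(Dlive, Xf.T, rcond=None)
        Xf = Xf - (Dlive @ beta).T
    return Xf
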