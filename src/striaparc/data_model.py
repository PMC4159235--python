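"""Core domain types and volume / table I/O.

Volumes and label atlases travel as NIfTI (via nibabel); motion traces as
6-column TSV; region specifications as JSON or YAML.  Voxel indices are
0-based throughout and millimetre coordinates are obtained by applying the
affine to voxel centers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AtlasVolume",
    "SubjectTimeSeries",
    "MotionTrace",
    "RegionSpec",
    "read_volume",
    "write_volume",
    "read_motion_tsv",
    "write_motion_tsv",
    "read_region_spec",
    "build_region_mask",
    "resample_mask",
]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class AtlasVolume:
    """A 3D integer label grid (0 = background) with its affine and label names."""

    labels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas grid must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas grid must have integer dtype")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be >= 0")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    def present_ids(self) -> set[int]:
        ids = set(np.unique(self.labels).tolist())
        ids.discard(0)
        return ids

    def absent_ids(self) -> set[int]:
        """Label-table ids that do not occur in the grid."""
        return set(self.label_table) - self.present_ids()


@dataclass
class SubjectTimeSeries:
    """Per-subject seed-ROI and target voxel time series on a shared ordering.

    ``roi_series`` is V_roi x T, ``target_series`` V_target x T; coordinates
    are integer voxel grid indices aligned row-for-row with the series.
    """

    roi_series: np.ndarray
    target_series: np.ndarray
    roi_coords: np.ndarray
    target_coords: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.roi_series = np.asarray(self.roi_series, dtype=float)
        self.target_series = np.asarray(self.target_series, dtype=float)
        if self.roi_series.ndim != 2 or self.target_series.ndim != 2:
            raise ValueError("series must be 2D (voxels x time)")
        if self.roi_series.shape[1] != self.target_series.shape[1]:
            raise ValueError("roi and target series must share the time axis")
        if self.roi_series.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        self.roi_coords = np.asarray(self.roi_coords, dtype=int)
        self.target_coords = np.asarray(self.target_coords, dtype=int)
        if len(self.roi_coords) != len(self.roi_series):
            raise ValueError("roi_coords must align with roi_series rows")
        if len(self.target_coords) != len(self.target_series):
            raise ValueError("target_coords must align with target_series rows")

    @property
    def n_frames(self) -> int:
        return self.roi_series.shape[1]


@dataclass
class MotionTrace:
    """T x 6 rigid-body motion parameters: translations (mm), rotations (rad)."""

    params: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be T x 6")

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class RegionSpec:
    """A named set of atlas label ids, optionally with a mm box constraint.

    The box is a strict-inequality constraint (lo < coord < hi on each axis);
    voxels whose mm center falls strictly inside are included in addition to
    the labelled voxels.
    """

    name: str
    ids: tuple[int, ...] = ()
    box_mm: tuple[float, float, float, float, float, float] | None = None
    allow_absent: bool = False

    def __post_init__(self) -> None:
        self.ids = tuple(int(i) for i in self.ids)
        if self.box_mm is not None:
            b = tuple(float(v) for v in self.box_mm)
            if len(b) != 6:
                raise ValueError("box_mm must be (x_lo, x_hi, y_lo, y_hi, z_lo, z_hi)")
            for lo, hi in zip(b[0::2], b[1::2]):
                if not lo < hi:
                    raise ValueError(f"box bounds must satisfy lo < hi, got {lo} >= {hi}")
            self.box_mm = b


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D or 4D NIfTI volume, returning (data, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"not a readable NIfTI volume: {path}") from exc
    if data.ndim not in (3, 4):
        raise IOError(f"expected 3D or 4D volume, got ndim={data.ndim}: {path}")
    return data, np.asarray(img.affine, dtype=float)


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    """Write a grid as NIfTI, preserving integer dtypes."""
    path = Path(path)
    data = np.asarray(data)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    img.set_data_dtype(data.dtype)
    nib.save(img, str(path))
    return path


def read_motion_tsv(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"motion TSV {path} lacks columns {missing}")
    return MotionTrace(df[list(MOTION_COLUMNS)].to_numpy(float), subject_id=Path(path).stem)


def write_motion_tsv(path: str | Path, trace: MotionTrace) -> Path:
    pd.DataFrame(trace.params, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_region_spec(path: str | Path) -> RegionSpec:
    """Load a RegionSpec from JSON or YAML (keyed name/ids/box_mm)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RegionSpec(
        name=raw.get("name", path.stem),
        ids=tuple(raw.get("ids", ())),
        box_mm=tuple(raw["box_mm"]) if raw.get("box_mm") else None,
        allow_absent=bool(raw.get("allow_absent", False)),
    )


# ---------------------------------------------------------------------------
# Region-mask construction


def voxel_centers_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """mm coordinates of every voxel center, shape (*grid, 3)."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return (vox @ np.asarray(affine, dtype=float).T)[..., :3]


def build_region_mask(
    atlas: AtlasVolume,
    spec: RegionSpec,
    exclude_ids: tuple[int, ...] = (),
) -> np.ndarray:
    """Boolean mask: union of labelled voxels and the strict mm box, minus exclusions.

    ``exclude_ids`` removes voxels carrying those labels even when they fall
    inside the box — used to carve seed-ROI labels out of a rest-of-brain mask.
    """
    if not spec.allow_absent:
        known = set(atlas.label_table) if atlas.label_table else atlas.present_ids()
        missing = set(spec.ids) - known
        if missing:
            raise ValueError(f"region '{spec.name}': unknown label ids {sorted(missing)}")
    mask = np.isin(atlas.labels, spec.ids) if spec.ids else np.zeros(atlas.labels.shape, bool)
    if spec.box_mm is not None:
        x_lo, x_hi, y_lo, y_hi, z_lo, z_hi = spec.box_mm
        mm = voxel_centers_mm(atlas.labels.shape, atlas.affine)
        in_box = (
            (mm[..., 0] > x_lo) & (mm[..., 0] < x_hi)
            & (mm[..., 1] > y_lo) & (mm[..., 1] < y_hi)
            & (mm[..., 2] > z_lo) & (mm[..., 2] < z_hi)
        )
        mask |= in_box
    if exclude_ids:
        mask &= ~np.isin(atlas.labels, tuple(exclude_ids))
    if not mask.any():
        raise ValueError(f"region '{spec.name}' produced an empty mask")
    return mask


def resample_mask(
    mask: np.ndarray,
    affine_src: np.ndarray,
    affine_dst: np.ndarray,
    dims_dst: tuple[int, int, int],
) -> np.ndarray:
    """Nearest-neighbor resampling of a boolean mask onto a destination grid.

    Each destination voxel center is mapped through ``affine_dst`` to mm, then
    through the inverse source affine to a source voxel, rounded to nearest.
    Centers falling outside the source grid are False.
    """
    affine_src = np.asarray(affine_src, float)
    affine_dst = np.asarray(affine_dst, float)
    for a, which in ((affine_src, "source"), (affine_dst, "destination")):
        if abs(np.linalg.det(a[:3, :3])) < 1e-12:
            raise np.linalg.LinAlgError(f"{which} affine is not invertible")
    mm = voxel_centers_mm(tuple(dims_dst), affine_dst)
    ones = np.ones(mm.shape[:-1] + (1,))
    src_vox = np.concatenate([mm, ones], axis=-1) @ np.linalg.inv(affine_src).T
    idx = np.round(src_vox[..., :3]).astype(int)
    out = np.zeros(tuple(dims_dst), bool)
    inside = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=-1)
    ii, jj, kk = idx[inside].T
    out[inside] = mask[ii, jj, kk]
    return out
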