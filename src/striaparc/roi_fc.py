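"""ROI-to-ROI connectivity between parcels and atlas regions with FDR control.

For every (parcel, region) pair: per-subject Pearson correlation between the
mean time series, Fisher z, a group one-sample t across subjects, and
Benjamini-Hochberg FDR over all pairs in the table (the most conservative
family; per-parcel families are available via ``family``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import fisher_z
from .data_model import AtlasVolume

__all__ = ["ROIFCTable", "roi_timeseries", "roi_roi_fc", "bh_fdr"]

Q_THRESHOLD = 0.05


@dataclass
class ROIFCTable:
    """One row per (parcel, region): mean z, t, p, q, significance flag."""

    rows: pd.DataFrame

    def significant_pairs(self) -> pd.DataFrame:
        return self.rows[self.rows["significant"]]


def roi_timeseries(
    target_series: np.ndarray,
    target_labels: np.ndarray,
    region_ids,
) -> tuple[np.ndarray, list[int]]:
    """Mean series per region (R x T) over a labelled target voxel set.

    ``target_labels`` assigns an atlas id to every row of ``target_series``.
    Regions with no in-mask voxels are skipped with a warning; the returned
    id list records which regions survived, in order.
    """
    Y = np.asarray(target_series, float)
    labels = np.asarray(target_labels)
    if len(labels) != len(Y):
        raise ValueError("target_labels must align with target_series rows")
    out, kept = [], []
    for rid in region_ids:
        sel = labels == rid
        if not sel.any():
            warnings.warn(f"region {rid} has no voxels in the target mask; skipped")
            continue
        out.append(Y[sel].mean(axis=0))
        kept.append(int(rid))
    if not out:
        raise ValueError("no region had any in-mask voxels")
    return np.vstack(out), kept


def roi_timeseries_from_atlas(
    target_series: np.ndarray,
    target_coords: np.ndarray,
    atlas: AtlasVolume,
    region_ids,
) -> tuple[np.ndarray, list[int]]:
    """Convenience wrapper: look up voxel labels from an atlas grid."""
    coords = np.asarray(target_coords, int)
    labels = atlas.labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    return roi_timeseries(target_series, labels, region_ids)


def bh_fdr(
    p_values: np.ndarray, q_threshold: float = Q_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted q values, reject flags)."""
    p = np.asarray(p_values, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    reject, q, *_ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, reject


def roi_roi_fc(
    cluster_series_per_subject: list[np.ndarray],
    region_series_per_subject: list[np.ndarray],
    cluster_ids=None,
    region_ids=None,
    q_threshold: float = Q_THRESHOLD,
    family: str = "all",
) -> ROIFCTable:
    """Group ROI-to-ROI table: Fisher z per subject, one-sample t, BH-FDR.

    ``family='all'`` adjusts across every pair in one family;
    ``family='per_cluster'`` adjusts separately within each parcel's rows.
    Pairs involving a constant series in any subject are excluded with a
    warning.
    """
    n_sub = len(cluster_series_per_subject)
    if n_sub < 3 or n_sub != len(region_series_per_subject):
        raise ValueError("need matched series for at least 3 subjects")
    K = len(cluster_series_per_subject[0])
    R = len(region_series_per_subject[0])
    cluster_ids = list(cluster_ids) if cluster_ids is not None else list(range(1, K + 1))
    region_ids = list(region_ids) if region_ids is not None else list(range(1, R + 1))

    z = np.empty((n_sub, K, R))
    dead = np.zeros((K, R), bool)
    for s, (C, G) in enumerate(
        zip(cluster_series_per_subject, region_series_per_subject)
    ):
        C = np.asarray(C, float)
        G = np.asarray(G, float)
        sd_c = C.std(axis=1)
        sd_g = G.std(axis=1)
        dead |= (sd_c[:, None] == 0) | (sd_g[None, :] == 0)
        Cc = (C - C.mean(axis=1, keepdims=True)) / np.where(sd_c, sd_c, 1.0)[:, None]
        Gc = (G - G.mean(axis=1, keepdims=True)) / np.where(sd_g, sd_g, 1.0)[:, None]
        r = np.clip(Cc @ Gc.T / C.shape[1], -1.0, 1.0)
        z[s] = fisher_z(r)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} pair(s) with a constant series excluded")

    mean_z = z.mean(axis=0)
    sd_z = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd_z > 0, mean_z / (sd_z / np.sqrt(n_sub)), np.nan)
    # a pair identical in every subject has no sampling variance: certain effect
    degenerate = (sd_z == 0) & (mean_z != 0)
    t[degenerate] = np.sign(mean_z[degenerate]) * np.inf
    t[(sd_z == 0) & (mean_z == 0)] = 0.0
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df=n_sub - 1), np.nan)
    p[np.isinf(t)] = 0.0

    records = []
    for i, cid in enumerate(cluster_ids):
        for j, rid in enumerate(region_ids):
            if dead[i, j]:
                continue
            records.append(
                dict(cluster=cid, region=rid, z=mean_z[i, j], t=t[i, j], p=p[i, j])
            )
    df = pd.DataFrame.from_records(records)
    df["q"] = np.nan
    df["significant"] = False
    if family == "all":
        groups = [df.index]
    elif family == "per_cluster":
        groups = [g.index for _, g in df.groupby("cluster")]
    else:
        raise ValueError("family must be 'all' or 'per_cluster'")
    for idx in groups:
        ok = idx[np.isfinite(df.loc[idx, "p"].to_numpy(float))]
        if len(ok) == 0:
            continue
        q, reject = bh_fdr(df.loc[ok, "p"].to_numpy(float), q_threshold)
        df.loc[ok, "q"] = q
        df.loc[ok, "significant"] = reject
    return ROIFCTable(df)
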