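"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
parcellate -> stability -> seed-to-voxel maps -> ROI-to-ROI table.

A single master seed fans out to per-stage seeds through a spawned seed
sequence, so one integer reproduces the whole run.  Every artifact in the
run directory is text (TSV/JSON) and the manifest records a content hash of
each, making reruns bit-for-bit comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .connectivity import ConnectivityProfiles, group_average, subject_profiles
from .fc_maps import cluster_extent_correct, cluster_mean_timeseries, group_onesample_t, seed_glm
from .parcellation import kmeans_correlation, remove_isolated_voxels
from .roi_fc import roi_roi_fc, roi_timeseries
from .stability import split_half_stability
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "connectivity",
    "parcellate",
    "stability",
    "fcmap",
    "roifc",
)


@dataclass
class PipelineConfig:
    """Resolved parameters for one run; defaults are the standard operating
    point of the analysis (K = 2-10, 100 restarts, 100 permutations,
    0.009-0.1 Hz band, voxel p < 0.001, FWE 0.05, FDR q < 0.05)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 100
    n_perm: int = 100
    alpha: float = 0.05
    band_hz: tuple[float, float] = preprocess.DEFAULT_BAND_HZ
    voxel_p: float = 0.001
    fwe_alpha: float = 0.05
    fwe_n_perm: int = 1000
    fdr_q: float = 0.05
    min_component: int = 3
    master_seed: int = 0

    def k_values(self) -> tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        w = d["synthetic"].get("weight_matrix")
        if w is not None:
            d["synthetic"]["weight_matrix"] = np.asarray(w).tolist()
        d["band_hz"] = list(self.band_hz)
        return d


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = SyntheticConfig(**raw.pop("synthetic", {}))
    if "band_hz" in raw:
        raw["band_hz"] = tuple(raw["band_hz"])
    return PipelineConfig(synthetic=syn, **raw)


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    Artifacts: resolved config snapshot, exclusion report, group profile
    matrix, per-K parcellations, VI stability table + K selection, seed-map
    cluster tables, and the ROI-to-ROI FC table — plus ``manifest.json``
    listing every file with its SHA-256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _stage_seeds(config.master_seed, len(STAGES))))
    stage_outputs: dict[str, list[str]] = {}
    current = "setup"
    try:
        current = "simulate"
        syn_cfg = SyntheticConfig(**{**asdict(config.synthetic), "rng_seed": seeds["simulate"]})
        _write_json(out / "config.json", {**config.to_dict(), "stage_seeds": seeds})
        dataset = generate_dataset(syn_cfg)
        truth_df = pd.DataFrame(
            dict(
                voxel=np.arange(len(dataset.ground_truth.true_labels)),
                true_label=dataset.ground_truth.true_labels,
            )
        )
        truth_df.to_csv(out / "simulate_truth.tsv", sep="\t", index=False)
        stage_outputs["simulate"] = ["config.json", "simulate_truth.tsv"]

        current = "preprocess"
        report = preprocess.apply_exclusion(dataset.motion)
        report.rows.to_csv(out / "exclusion_report.tsv", sep="\t", index=False)
        included = set(report.included_ids())
        cleaned = {}
        for subj in dataset.subjects:
            if subj.subject_id not in included:
                logger.info("excluding %s on motion", subj.subject_id)
                continue
            roi = preprocess.discard_initial_frames(subj.roi_series)
            tgt = preprocess.discard_initial_frames(subj.target_series)
            motion = dataset.motion[subj.subject_id].params[preprocess.N_INITIAL_DISCARD:]
            wm = preprocess.discard_initial_frames(dataset.wm_series[subj.subject_id])
            csf = preprocess.discard_initial_frames(dataset.csf_series[subj.subject_id])
            from .data_model import MotionTrace

            design = preprocess.build_nuisance_design(MotionTrace(motion), wm, csf)
            roi = preprocess.bandpass_regress(roi, design, config.band_hz, subj.tr_seconds)
            tgt = preprocess.bandpass_regress(tgt, design, config.band_hz, subj.tr_seconds)
            cleaned[subj.subject_id] = (roi, tgt)
        if len(cleaned) < 4:
            raise RuntimeError(f"only {len(cleaned)} subjects survived motion screening")
        stage_outputs["preprocess"] = ["exclusion_report.tsv"]

        current = "connectivity"
        profiles = [
            subject_profiles(roi, tgt, sid) for sid, (roi, tgt) in cleaned.items()
        ]
        group = group_average(profiles)
        np.savetxt(out / "group_profiles.tsv", group.z_matrix, delimiter="\t", fmt="%.10g")
        stage_outputs["connectivity"] = ["group_profiles.tsv"]

        current = "parcellate"
        coords = dataset.subjects[0].roi_coords
        parcellations = {}
        parc_rows = []
        for k in config.k_values():
            if k > len(group.z_matrix):
                logger.warning("skipping K=%d > %d voxels", k, len(group.z_matrix))
                continue
            parc = kmeans_correlation(
                group, k, n_restarts=config.n_restarts,
                rng_seed=seeds["parcellate"] + k,
            )
            cleaned_parc = remove_isolated_voxels(
                parc, coords, min_component=config.min_component
            )
            parcellations[k] = (parc, cleaned_parc)
            for v in range(len(parc.labels)):
                parc_rows.append(
                    dict(K=k, voxel=v, x=coords[v, 0], y=coords[v, 1], z=coords[v, 2],
                         label=parc.labels[v], flagged=bool(cleaned_parc.flagged[v]))
                )
        pd.DataFrame(parc_rows).to_csv(out / "parcellations.tsv", sep="\t", index=False)
        stage_outputs["parcellate"] = ["parcellations.tsv"]

        current = "stability"
        stab = split_half_stability(
            profiles,
            [k for k in config.k_values() if k in parcellations],
            n_perm=config.n_perm,
            rng_seed=seeds["stability"],
        )
        vi_rows = [
            dict(K=k, permutation=p, vi=stab.vi_samples[k][p])
            for k in stab.k_values
            for p in range(stab.n_perm)
        ]
        pd.DataFrame(vi_rows).to_csv(out / "stability_vi.tsv", sep="\t", index=False)
        _write_json(
            out / "stability_summary.json",
            dict(
                optimal_k=stab.optimal_k,
                mean_vi={str(k): v for k, v in stab.mean_vi().items()},
                transitions={
                    str(k): dict(t=t, p=p) for k, (t, p) in stab.transition_tests.items()
                },
                split_sizes=list(stab.split_sizes),
                n_perm=stab.n_perm,
                note=None if stab.optimal_k else
                "no K had VI indistinguishable from K-1; no stable plateau",
            ),
        )
        stage_outputs["stability"] = ["stability_vi.tsv", "stability_summary.json"]

        current = "fcmap"
        k_report = stab.optimal_k or min(parcellations)
        _, cleaned_parc = parcellations[k_report]
        subj_ids = list(cleaned.keys())
        subj_map = {s.subject_id: s for s in dataset.subjects}
        betas = []
        for sid in subj_ids:
            roi, tgt = cleaned[sid]
            subj = subj_map[sid]
            pseudo = type(subj)(
                roi_series=roi, target_series=tgt,
                roi_coords=subj.roi_coords, target_coords=subj.target_coords,
                tr_seconds=subj.tr_seconds, subject_id=sid,
            )
            series_k = cluster_mean_timeseries(pseudo, cleaned_parc)
            betas.append(seed_glm(tgt, series_k))
        betas = np.stack(betas)  # N x V_target x K
        fc_tables = []
        for ki in range(betas.shape[2]):
            B = betas[:, :, ki]
            t, p = group_onesample_t(B)
            sig = cluster_extent_correct(
                B,
                dataset.subjects[0].target_coords,
                voxel_p=config.voxel_p,
                fwe_alpha=config.fwe_alpha,
                n_perm=config.fwe_n_perm,
                rng_seed=seeds["fcmap"] + ki,
            )
            for c in sig:
                fc_tables.append(
                    dict(seed_cluster=ki + 1, sign=c.sign, size=c.size,
                         peak_index=c.peak_index, peak_t=c.peak_t,
                         corrected_p=c.corrected_p, significant=c.significant)
                )
        pd.DataFrame(fc_tables).to_csv(out / "fcmap_clusters.tsv", sep="\t", index=False)
        stage_outputs["fcmap"] = ["fcmap_clusters.tsv"]

        current = "roifc"
        region_labels = dataset.ground_truth.target_networks + 1
        cluster_series, region_series = [], []
        for sid in subj_ids:
            roi, tgt = cleaned[sid]
            subj = subj_map[sid]
            pseudo = type(subj)(
                roi_series=roi, target_series=tgt,
                roi_coords=subj.roi_coords, target_coords=subj.target_coords,
                tr_seconds=subj.tr_seconds, subject_id=sid,
            )
            cluster_series.append(cluster_mean_timeseries(pseudo, cleaned_parc))
            rs, kept = roi_timeseries(tgt, region_labels, sorted(set(region_labels)))
            region_series.append(rs)
        table = roi_roi_fc(
            cluster_series, region_series,
            region_ids=kept, q_threshold=config.fdr_q,
        )
        table.rows.to_csv(out / "roi_fc_table.tsv", sep="\t", index=False)
        stage_outputs["roifc"] = ["roi_fc_table.tsv"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    manifest = dict(
        master_seed=config.master_seed,
        stage_seeds=seeds,
        stages={
            stage: [
                dict(file=f, sha256=_hash_file(out / f)) for f in files
            ]
            for stage, files in stage_outputs.items()
        },
    )
    _write_json(out / "manifest.json", manifest)
    return manifest
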