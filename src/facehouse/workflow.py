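"""End-to-end orchestration of the synthetic study.

One master seed is expanded into independent per-stage streams (cohort,
task, one per simulated scan, cluster-extent Monte Carlo, permutation
inference), so each stage is independently reproducible.  The chain:

cohort -> RT QC -> behavioral model families
design -> per-subject BOLD simulation -> first-level GLM + motion QC
       -> group t maps -> thresholding -> watershed segments
       -> segment means / ROI means -> brain association families
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bold import ScanConfig, simulate_bold
from .cohort import DEFAULT_EFFECT_PLAN, CohortConfig, effect_plan_to_dicts, generate_cohort
from .config import PipelineConfig
from .firstlevel import (
    CONTRASTS,
    build_design_matrix,
    compute_contrast,
    compute_signal_mask,
    fit_glm,
    framewise_displacement,
    smooth_volume,
)
from .grouplevel import (
    ThresholdSpec,
    compute_overlap_map,
    estimate_cluster_extent_k,
    one_sample_tmap,
    threshold_map,
)
from .pipeline import (
    extract_roi_means,
    qc_reaction_times,
    rectangular_parcellation,
    roi_task_activation,
    run_brain_association_models,
    run_emotion_labeling_models,
    run_social_competence_models,
)
from .task import generate_task_design
from .watershed import extract_segment_means, watershed_segments


def stage_seeds(master_seed: int, n_subjects: int) -> dict:
    """Deterministically expand a master seed into per-stage integer seeds."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(5 + n_subjects)
    names = ["cohort", "task", "mc_k", "behavior", "brain"]
    seeds = {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}
    seeds["scans"] = [
        int(c.generate_state(1)[0] % (2**31)) for c in children[5:]
    ]
    return seeds


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced, keyed for inspection."""

    cohort: pd.DataFrame
    qc_log: pd.DataFrame
    behavioral_reports: dict
    subjects: list
    motion: pd.DataFrame
    group_maps: dict
    cluster_sets: dict
    segmentations: dict
    segment_stats: dict
    overlap_maps: dict
    roi_tables: dict
    roi_activation: dict
    brain_reports: dict
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    seeds = stage_seeds(config.seed, config.n_subjects)

    # --- behavioral arm -------------------------------------------------
    effects = (
        effect_plan_to_dicts(DEFAULT_EFFECT_PLAN)
        if config.plant_default_effects
        else ({}, {})
    )
    cohort, _truth = generate_cohort(
        CohortConfig(
            n_children=config.n_children,
            age_range=config.age_range,
            sex_proportion_girls=config.sex_proportion_girls,
            effect_age=effects[0],
            effect_sex=effects[1],
            seed=seeds["cohort"],
        )
    )
    cohort, qc_log = qc_reaction_times(cohort)
    behavioral_reports = {
        "social_competence": run_social_competence_models(
            cohort, n_perm=config.n_perm, seed=seeds["behavior"], alpha=config.alpha
        ),
        "emotion_labeling": run_emotion_labeling_models(
            cohort, n_perm=config.n_perm, seed=seeds["behavior"] + 1, alpha=config.alpha
        ),
        "emotion_labeling+social_competence": run_emotion_labeling_models(
            cohort,
            include_social_competence=True,
            n_perm=config.n_perm,
            seed=seeds["behavior"] + 2,
            alpha=config.alpha,
        ),
    }

    # --- imaging arm ----------------------------------------------------
    design = generate_task_design(seed=seeds["task"])
    subjects = []
    motion_rows = []
    contrast_maps = {name: {} for name in CONTRASTS}
    contrast_tmaps = {name: {} for name in CONTRASTS}
    for i in range(config.n_subjects):
        sid = cohort["child_id"].iloc[i]
        scan = ScanConfig(
            grid_dims=config.grid_dims,
            voxel_size=config.voxel_size_mm,
            tr=config.tr_s,
            n_volumes=config.n_volumes,
            noise_sd=config.noise_sd,
            ar1_coefficient=config.ar1_coefficient,
            drift_amplitude=config.drift_amplitude,
            motion_profile={"step_mm": 0.01, "step_rad": 1e-4},
            seed=seeds["scans"][i],
        )
        series, truth = simulate_bold(design, scan)
        mask = compute_signal_mask(series, config.mask_fraction)
        motion = framewise_displacement(
            series.realignment,
            radius_mm=config.fd_radius_mm,
            fd_threshold_mm=config.fd_threshold_mm,
            max_high_fraction=1.0 - config.low_motion_fraction,
        )
        motion_rows.append(
            {
                "child_id": sid,
                "frac_high": motion.frac_high,
                "low_motion": motion.low_motion,
                "has_holes": mask.has_holes,
            }
        )
        if mask.has_holes or not motion.low_motion:
            continue  # QC exclusion
        X = build_design_matrix(
            design, series.realignment, config.tr_s, config.n_volumes, config.hp_cutoff_s
        )
        glm = fit_glm(series, X, mask)
        for name, spec in CONTRASTS.items():
            cmap = compute_contrast(glm, spec, subject_id=sid)
            if config.fwhm_mm > 0:
                cmap.values = smooth_volume(
                    cmap.values, config.fwhm_mm, series.voxel_size
                )
                cmap.smoothed, cmap.fwhm_mm = True, config.fwhm_mm
            contrast_maps[name][sid] = cmap.values
            contrast_tmaps[name][sid] = glm.contrast_t(spec)
        subjects.append(sid)

    group_maps, cluster_sets, segmentations = {}, {}, {}
    segment_stats, overlap_maps, roi_tables = {}, {}, {}
    roi_activation, brain_reports = {}, {}
    if config.cluster_extent_k is None:
        fwhm_vox = config.fwhm_mm / config.voxel_size_mm if config.fwhm_mm else 0.0
        k = estimate_cluster_extent_k(
            config.grid_dims,
            fwhm_vox,
            cluster_forming_z=config.cluster_forming_z,
            alpha=config.fwe_alpha,
            n_sim=config.k_n_sim,
            seed=seeds["mc_k"],
        )
    else:
        k = config.cluster_extent_k
    spec = ThresholdSpec(
        voxel_fwe_alpha=config.fwe_alpha,
        cluster_forming_z=config.cluster_forming_z,
        cluster_extent_k=k,
    )
    atlas = rectangular_parcellation(config.grid_dims, config.atlas_splits)
    cohort_idx = cohort.set_index("child_id")
    for name in CONTRASTS:
        maps = contrast_maps[name]
        if len(maps) < 2:
            continue
        gmap = one_sample_tmap(list(maps.values()), contrast=name)
        group_maps[name] = gmap
        cset = threshold_map(gmap, spec)
        cluster_sets[name] = cset
        overlap_maps[name] = compute_overlap_map(
            list(contrast_tmaps[name].values()), config.overlap_threshold_t
        )
        roi = extract_roi_means(atlas, maps)
        roi_tables[name] = roi
        roi_activation[name] = roi_task_activation(roi, alpha=config.alpha)
        if cset.n_clusters == 0:
            continue
        seg = watershed_segments(gmap.t, cset)
        segmentations[name] = seg
        seg_means = extract_segment_means(seg, maps)
        segment_stats[name] = seg_means
        # skip predictor sets the subject count cannot support (too few
        # subjects or a predictor without variance in this subsample)
        brain_reports[name] = {}
        for pset in ("age_sex", "emotion_labeling", "social_competence"):
            try:
                brain_reports[name][pset] = run_brain_association_models(
                    seg_means.means,
                    cohort_idx,
                    contrast=name,
                    predictor_set=pset,
                    alpha=config.alpha,
                    seed=seeds["brain"],
                )
            except ValueError:
                continue

    provenance = {
        "config_digest": config.digest(),
        "master_seed": config.seed,
        "stage_seeds": {k: v for k, v in seeds.items()},
        "cluster_extent_k": int(k),
        "n_subjects_passed_qc": len(subjects),
        "versions": {
            "facehouse": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    return PipelineResult(
        cohort=cohort,
        qc_log=qc_log,
        behavioral_reports=behavioral_reports,
        subjects=subjects,
        motion=pd.DataFrame(motion_rows),
        group_maps=group_maps,
        cluster_sets=cluster_sets,
        segmentations=segmentations,
        segment_stats=segment_stats,
        overlap_maps=overlap_maps,
        roi_tables=roi_tables,
        roi_activation=roi_activation,
        brain_reports=brain_reports,
        provenance=provenance,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Persist the pipeline products as TSV/NIfTI plus a provenance log."""
    from . import io as fio

    out = fio.ensure_dir(outdir)
    fio.save_cohort(out / "cohort.tsv", result.cohort)
    fio.save_table(out / "qc_exclusions.tsv", result.qc_log)
    fio.save_table(out / "motion_summary.tsv", result.motion)
    for name, rep in result.behavioral_reports.items():
        fio.save_table(out / f"behavior_{name.replace('>', '_gt_')}.tsv", rep.table)
    eye = np.eye(4)
    for name, gmap in result.group_maps.items():
        tag = name.replace(">", "_gt_")
        fio.save_volume(out / f"group_t_{tag}.nii.gz", np.nan_to_num(gmap.t), eye)
        if name in result.cluster_sets:
            fio.save_volume(
                out / f"clusters_{tag}.nii.gz",
                result.cluster_sets[name].labels.astype(float),
                eye,
            )
        if name in result.segmentations:
            fio.save_volume(
                out / f"segments_{tag}.nii.gz",
                result.segmentations[name].labels.astype(float),
                eye,
            )
            fio.save_table(
                out / f"segment_means_{tag}.tsv",
                result.segment_stats[name].means.reset_index(names="child_id"),
            )
        fio.save_table(out / f"roi_activation_{tag}.tsv", result.roi_activation[name])
        for pset, rep in result.brain_reports.get(name, {}).items():
            fio.save_table(out / f"association_{tag}_{pset}.tsv", rep.table)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
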