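"""End-to-end orchestration: simulate -> univariate -> MVPA -> permutation.

Every stage is seeded deterministically from the pipeline seed, all
thresholds come from :class:`~fairmirror.config.PipelineConfig`, and a
JSON manifest records seeds, thresholds, stage timings and SHA-256
checksums of every written file, so a manifest suffices to reproduce any
output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from fairmirror import mvpa, permutation, simulate, univariate
from fairmirror.config import PipelineConfig, SimConfig, SignalSpec
from fairmirror.glm import gaussian_smooth
from fairmirror.io import write_cluster_table, write_schedule_tsv, write_volume

logger = logging.getLogger("fairmirror")

STAGES = ("simulate", "univariate", "mvpa", "permute")


def derive_seed(base: int, *tags) -> int:
    """Stable per-purpose seed below 2^31 derived from a base seed."""
    digest = hashlib.sha256(("/".join(map(str, (base,) + tags))).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_roi_masks(config: SimConfig, spec: SignalSpec, n_rois: int, seed: int) -> dict[str, np.ndarray]:
    """Generic anatomical-ROI stand-ins: the planted role region plus
    seeded random boxes of comparable size elsewhere in the volume."""
    rois: dict[str, np.ndarray] = {"roi-role-region": spec.role_pattern_region.copy()}
    rng = np.random.default_rng(seed)
    dims = np.asarray(config.volume_dims)
    side = max(3, int(round(np.cbrt(spec.role_pattern_region.sum()))))
    attempts = 0
    while len(rois) < n_rois and attempts < 200:
        attempts += 1
        lo = np.array([rng.integers(0, max(1, d - side)) for d in dims])
        mask = np.zeros(config.volume_dims, dtype=bool)
        mask[lo[0] : lo[0] + side, lo[1] : lo[1] + side, lo[2] : lo[2] + side] = True
        if any(np.array_equal(mask, m) for m in rois.values()):
            continue
        rois[f"roi-{len(rois):02d}"] = mask
    return rois


def simulate_stage(config: PipelineConfig) -> dict:
    """Generate the full multi-subject dataset."""
    sim = config.sim
    spec = config.signal_spec()
    seed = config.seed
    assignments = simulate.make_counterbalance(sim.n_subjects, derive_seed(seed, "cb"))
    templates = simulate.make_signal_templates(sim, spec, derive_seed(seed, "templates"))
    schedules = []
    betas = []
    for i, assignment in enumerate(assignments):
        sched = simulate.make_block_schedule(sim, assignment, derive_seed(seed, "sched", i))
        schedules.append(sched)
        betas.append(
            simulate.simulate_subject_betas(sched, templates, spec, derive_seed(seed, "betas", i))
        )
    execution = simulate.simulate_execution_maps(
        sim.n_subjects, sim, spec, derive_seed(seed, "exec")
    )
    return {
        "assignments": assignments,
        "schedules": schedules,
        "templates": templates,
        "betas": betas,
        "execution_maps": execution,
        "signal_spec": spec,
    }


def _condition_averages(subject_betas, smooth_fwhm_mm: float, voxel_size) -> dict:
    """Unbalanced per-(modality, type, role) means, optionally smoothed —
    the univariate analogue of per-condition first-level predictors."""
    blocks, volumes = subject_betas.analyzable()
    groups: dict[tuple, list[int]] = {}
    for j, b in enumerate(blocks):
        groups.setdefault(b.cell, []).append(j)
    out = {}
    for key, members in groups.items():
        vol = volumes[members].mean(axis=0)
        if smooth_fwhm_mm > 0:
            vol = gaussian_smooth(vol, smooth_fwhm_mm, voxel_size)
        out[key] = vol
    return out


VISUAL_ACTION_VS_CONTROL = univariate.Contrast(
    name="visual_action_vs_control",
    weights={
        ("visual", "action", "fair"): 0.5,
        ("visual", "action", "unfair"): 0.5,
        ("visual", "control", "fair"): -0.5,
        ("visual", "control", "unfair"): -0.5,
    },
)

ROLE_DOUBLE_DIFFERENCE = univariate.Contrast(
    name="fair_minus_unfair_action_specific",
    weights={
        ("visual", "action", "fair"): 1.0,
        ("visual", "control", "fair"): -1.0,
        ("visual", "action", "unfair"): -1.0,
        ("visual", "control", "unfair"): 1.0,
    },
)


def univariate_stage(config: PipelineConfig, data: dict) -> dict:
    """Second-level mass-univariate analysis on smoothed condition means."""
    sim = config.sim
    geometry = sim.geometry
    voxel_size = sim.voxel_size_mm
    cond_avgs = [
        _condition_averages(b, config.smooth_fwhm_univariate_mm, voxel_size)
        for b in data["betas"]
    ]
    perception_maps = [
        univariate.subject_contrast(av, VISUAL_ACTION_VS_CONTROL) for av in cond_avgs
    ]
    perception_t = univariate.one_sample_t(perception_maps, geometry)
    perception_p = univariate.StatMap(
        values=univariate.p_from_t(perception_t.values, perception_t.df),
        kind="p",
        geometry=geometry,
    )
    execution_t = univariate.one_sample_t(data["execution_maps"], geometry)
    shared = univariate.shared_voxel_mask(
        perception_p,
        execution_t,
        q=config.q_fdr,
        exec_p_unc=config.p_exec,
        min_size=config.min_cluster,
        connectivity=config.connectivity,
    )
    role_maps = [univariate.subject_contrast(av, ROLE_DOUBLE_DIFFERENCE) for av in cond_avgs]
    role_t = univariate.one_sample_t(role_maps, geometry)
    t_cut = univariate.t_threshold(config.p_unc, role_t.df)
    role_clusters = univariate.extract_clusters(
        role_t, t_cut, min_size=config.min_cluster, connectivity=config.connectivity
    )
    return {
        "condition_averages": cond_avgs,
        "perception_t": perception_t,
        "execution_t": execution_t,
        "shared_mask": shared,
        "role_t": role_t,
        "role_t_cutoff": t_cut,
        "role_clusters": role_clusters,
    }


def mvpa_stage(config: PipelineConfig, data: dict) -> dict:
    """Pattern preparation and LOSO role classification (ROI + searchlight)."""
    sim = config.sim
    geometry = sim.geometry
    brain_mask = np.ones(sim.volume_dims, dtype=bool)
    per_subject = {}
    for i, betas in enumerate(data["betas"]):
        averages, _ = mvpa.balance_and_average(
            betas,
            grouping=("modality", "stim_type", "role"),
            seed=derive_seed(config.seed, "balance", i),
            center_mask=brain_mask,
        )
        per_subject[betas.subject_id] = mvpa.role_difference_images(averages)
    examples = mvpa.build_example_set(per_subject, brain_mask, dims=sim.volume_dims)
    folds = mvpa.loso_folds(examples.subject_ids)
    spec = mvpa.SearchlightSpec(radius_voxels=config.searchlight_radius, cost_c=config.cost_c)
    rois = make_roi_masks(
        sim, data["signal_spec"], config.n_rois, derive_seed(config.seed, "rois")
    )
    roi_acc = {
        name: mvpa.roi_accuracy(examples, folds, mask, cost_c=config.cost_c)
        for name, mask in rois.items()
    }
    out = {
        "examples": examples,
        "folds": folds,
        "searchlight_spec": spec,
        "rois": rois,
        "roi_accuracy": roi_acc,
        "brain_mask": brain_mask,
    }
    if config.run_searchlight:
        out["searchlight_accuracy"] = mvpa.searchlight_accuracy_map(
            examples, spec, folds, brain_mask, geometry
        )
    return out


def permute_stage(config: PipelineConfig, data: dict, mv: dict) -> dict:
    """Permutation inference for the ROI and searchlight analyses."""
    examples, folds = mv["examples"], mv["folds"]
    results = {}
    for i, (name, mask) in enumerate(mv["rois"].items()):
        results[name] = permutation.roi_permutation_test(
            examples,
            folds,
            mask,
            m=config.m_permutations,
            seed=derive_seed(config.seed, "perm", name),
            cost_c=config.cost_c,
        )
    p_unc = np.array([results[name].p_value for name in mv["rois"]])
    p_bonf = permutation.bonferroni_adjust(p_unc, max(config.n_rois, p_unc.size))
    out = {
        "roi_results": results,
        "roi_p_bonferroni": dict(zip(mv["rois"], p_bonf)),
    }
    if config.run_searchlight:
        p_map, acc_map = permutation.searchlight_permutation_map(
            examples,
            mv["searchlight_spec"],
            folds,
            mv["brain_mask"],
            m=config.m_permutations,
            seed=derive_seed(config.seed, "perm", "searchlight"),
            geometry=config.sim.geometry,
        )
        sig = np.where(np.isfinite(p_map.values), p_map.values < config.p_searchlight, False)
        clusters = univariate.clusters_from_mask(
            sig,
            acc_map,
            min_size=config.min_cluster_searchlight,
            connectivity=config.connectivity,
        )
        out.update(
            searchlight_p=p_map, searchlight_accuracy=acc_map, searchlight_clusters=clusters
        )
    return out


def simulate_role_examples(
    sim: SimConfig,
    spec: SignalSpec,
    seed: int,
    chunked: bool = False,
    mask: np.ndarray | None = None,
) -> mvpa.ExampleSet:
    """Simulate a dataset and reduce it to role-classification examples.

    Runs the full preparation chain (counterbalance, schedules, per-block
    betas, across-voxel centering, balanced averaging, action-minus-
    control subtraction) and returns one fair and one unfair example per
    subject — or, with ``chunked=True``, one pair per run (for the
    within-subject leakage diagnostic).
    """
    brain = np.ones(sim.volume_dims, dtype=bool) if mask is None else np.asarray(mask, bool)
    assignments = simulate.make_counterbalance(sim.n_subjects, derive_seed(seed, "cb"))
    templates = simulate.make_signal_templates(sim, spec, derive_seed(seed, "templates"))
    grouping = ("run", "modality", "stim_type", "role") if chunked else (
        "modality", "stim_type", "role"
    )
    per_subject: dict = {}
    for i, assignment in enumerate(assignments):
        sched = simulate.make_block_schedule(sim, assignment, derive_seed(seed, "sched", i))
        betas = simulate.simulate_subject_betas(
            sched, templates, spec, derive_seed(seed, "betas", i)
        )
        averages, _ = mvpa.balance_and_average(
            betas, grouping, seed=derive_seed(seed, "balance", i), center_mask=brain
        )
        if chunked:
            diffs: dict[str, list] = {"fair": [], "unfair": []}
            needed = [
                ("visual", s, r) for s in ("action", "control") for r in ("fair", "unfair")
            ]
            for run in sorted({k[0] for k in averages}):
                run_avgs = {k[1:]: v for k, v in averages.items() if k[0] == run}
                if any(key not in run_avgs for key in needed):
                    continue  # a dropped cell empties this run for the diagnostic
                run_diffs = mvpa.role_difference_images(run_avgs)
                for role, vol in run_diffs.items():
                    diffs[role].append(vol)
            per_subject[betas.subject_id] = diffs
        else:
            per_subject[betas.subject_id] = mvpa.role_difference_images(averages)
    return mvpa.build_example_set(per_subject, brain, dims=sim.volume_dims)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
    write_betas: bool = False,
) -> dict:
    """Execute the pipeline through the requested stages and write outputs.

    Returns the report bundle: in-memory stage results plus the manifest
    (also written to ``manifest.json``).
    """
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = config.sim.geometry
    written: list[Path] = []
    timings: dict[str, float] = {}
    bundle: dict = {"config": config}

    def _timed(name, fn, *args):
        t0 = time.perf_counter()
        result = fn(*args)
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", name, timings[name])
        return result

    data = _timed("simulate", simulate_stage, config)
    bundle["simulate"] = data
    import pandas as pd

    schedule_frame = pd.concat([s.to_frame() for s in data["schedules"]], ignore_index=True)
    written.append(write_schedule_tsv(schedule_frame, outdir / "schedules.tsv"))
    if write_betas:
        for b in data["betas"]:
            written.append(
                write_volume(
                    np.moveaxis(b.volumes, 0, -1), geometry, outdir / f"{b.subject_id}_betas.nii"
                )
            )

    if "univariate" in stages:
        uni = _timed("univariate", univariate_stage, config, data)
        bundle["univariate"] = uni
        written.append(write_volume(uni["perception_t"].values, geometry, outdir / "perception_t.nii"))
        written.append(write_volume(uni["role_t"].values, geometry, outdir / "role_t.nii"))
        written.append(
            write_volume(uni["shared_mask"].astype(float), geometry, outdir / "shared_mask.nii")
        )
        write_cluster_table(uni["role_clusters"], uni["role_t"], outdir / "role_clusters.tsv")
        written.append(outdir / "role_clusters.tsv")

    if "mvpa" in stages or "permute" in stages:
        mv = _timed("mvpa", mvpa_stage, config, data)
        bundle["mvpa"] = mv
        if "searchlight_accuracy" in mv:
            written.append(
                write_volume(
                    mv["searchlight_accuracy"].values, geometry, outdir / "searchlight_accuracy.nii"
                )
            )

    if "permute" in stages:
        perm = _timed("permute", permute_stage, config, data, mv)
        bundle["permute"] = perm
        rows = []
        for name in mv["rois"]:
            res = perm["roi_results"][name]
            rows.append(
                {
                    "roi": name,
                    "n_voxels": int(mv["rois"][name].sum()),
                    "accuracy": res.observed,
                    "p": res.p_value,
                    "p_bonferroni": perm["roi_p_bonferroni"][name],
                }
            )
        roi_table = pd.DataFrame(rows, columns=["roi", "n_voxels", "accuracy", "p", "p_bonferroni"])
        roi_table.to_csv(outdir / "roi_accuracy.tsv", sep="\t", index=False)
        written.append(outdir / "roi_accuracy.tsv")
        for name in mv["rois"]:
            np.savetxt(
                outdir / f"null_{name}.tsv", perm["roi_results"][name].null_values, fmt="%.6f"
            )
            written.append(outdir / f"null_{name}.tsv")
        if "searchlight_p" in perm:
            written.append(
                write_volume(perm["searchlight_p"].values, geometry, outdir / "searchlight_p.nii")
            )
            write_cluster_table(
                perm["searchlight_clusters"], perm["searchlight_accuracy"],
                outdir / "searchlight_clusters.tsv",
            )
            written.append(outdir / "searchlight_clusters.tsv")

    manifest = {
        "seed": config.seed,
        "stages": list(stages),
        "config": {
            "sim": asdict(config.sim),
            "thresholds": {
                "q_fdr": config.q_fdr,
                "p_exec": config.p_exec,
                "p_unc": config.p_unc,
                "p_searchlight": config.p_searchlight,
                "min_cluster": config.min_cluster,
                "min_cluster_searchlight": config.min_cluster_searchlight,
                "searchlight_radius": config.searchlight_radius,
                "cost_c": config.cost_c,
                "m_permutations": config.m_permutations,
                "connectivity": config.connectivity,
            },
        },
        "timings_s": timings,
        "checksums": {p.name: _sha256(p) for p in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
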