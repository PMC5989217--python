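"""End-to-end pipeline: simulate -> score -> behavior -> RSA -> SVR.

Every stochastic stage derives its own child seed from the configured root
seed, so a rerun with the same configuration reproduces every table and map.
Stage failures abort with an error naming the stage.  Outputs are written
as TSV/CSV tables and NIfTI maps plus a JSON run log recording the config,
derived seeds, and package versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, io, rsa, scoring, simulate, svr
from .config import AnalysisConfig, SimulationParams, stage_seed
from .errors import PipelineStageError
from .rsa import RoiMask, SearchlightSpec
from .volume import StatMap, ball_region

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory products of one pipeline run."""

    ground_truth: simulate.GroundTruth = None
    logs: list = None
    memtable: pd.DataFrame = None
    n_retained_workers: int = None
    consistency: dict = field(default_factory=dict)
    stimulus_table: pd.DataFrame = None
    trial_tables: dict = field(default_factory=dict)
    pattern_sets: dict = field(default_factory=dict)
    anova_old: behavior.AnovaResult = None
    anova_new: behavior.AnovaResult = None
    group_maps: dict = field(default_factory=dict)
    overlap_results: dict = field(default_factory=dict)
    overlap_sweep: pd.DataFrame = None
    roi_rsa_table: pd.DataFrame = None
    roi_svr_table: pd.DataFrame = None
    recovery: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def region_enrichment(group_t: StatMap, region_coords: np.ndarray, n_top: int) -> dict:
    """How strongly a planted region is recovered by a map's top-N voxels.

    Returns the fraction of top-N voxels inside the region, the chance
    fraction (region size / in-mask size), and their ratio.
    """
    top = rsa.top_n_mask(group_t, n_top)
    region = np.zeros(group_t.grid_shape, dtype=bool)
    region[tuple(np.asarray(region_coords).T)] = True
    n_top_eff = int(top.sum())
    frac_in = float((top & region).sum()) / max(n_top_eff, 1)
    chance = float(region.sum()) / float(group_t.mask.sum())
    return {"fraction_in_region": frac_in, "chance_fraction": chance,
            "enrichment": frac_in / chance if chance else np.nan, "n_top": n_top_eff}


def trial_pr(trial_table: pd.DataFrame, memtable: pd.DataFrame) -> np.ndarray:
    pr = memtable["Pr"].reindex(trial_table["image_id"]).to_numpy()
    if np.isnan(pr).any():
        bad = trial_table["image_id"].iloc[int(np.flatnonzero(np.isnan(pr))[0])]
        raise KeyError(f"no memorability score for image {bad}")
    return pr


def run_pipeline(
    config: AnalysisConfig,
    sim: SimulationParams,
    out_dir,
    write_subject_maps: bool = False,
    run_searchlight_svr: bool = False,
) -> PipelineResult:
    """Execute the full synthetic-study analysis and write all outputs.

    The searchlight-SVR map is optional (it is by far the most expensive
    stage); ROI-level SVR always runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    root = config.rng_seed
    res.seeds = {s: stage_seed(root, s) for s in
                 ("ground_truth", "online", "scanner", "bold", "consistency",
                  "condition", "svr")}
    logger.info("root seed %d; derived stage seeds %s", root, res.seeds)

    _simulate_stage(config, sim, res, out)
    _score_stage(config, res, out)
    _behavior_stage(config, res, out)
    _rsa_stage(config, sim, res, out, write_subject_maps)
    _svr_stage(config, sim, res, out, run_searchlight_svr)

    runlog = {
        "analysis_config": dataclasses.asdict(config),
        "simulation_params": dataclasses.asdict(sim),
        "seeds": res.seeds,
        "versions": _versions(),
    }
    (out / "run_log.json").write_text(json.dumps(runlog, indent=2, default=str))
    return res


@_stage("simulate")
def _simulate_stage(config, sim, res, out):
    res.ground_truth = simulate.make_ground_truth(sim, seed=res.seeds["ground_truth"])
    res.logs = simulate.gen_online_study(sim, res.ground_truth, seed=res.seeds["online"])
    res.stimulus_table, res.trial_tables = simulate.gen_scanner_study(
        sim, res.ground_truth, seed=res.seeds["scanner"]
    )
    for k, (sid, tt) in enumerate(res.trial_tables.items()):
        res.pattern_sets[sid] = simulate.gen_bold_patterns(
            tt, res.ground_truth, sim, seed=res.seeds["bold"] + k
        )
    io.write_response_log(res.logs, out / "response_log.tsv")
    io.write_trial_tables(res.trial_tables, out / "trial_tables.tsv")
    gt = res.ground_truth
    pd.DataFrame({"image_id": gt.image_ids, "theta": gt.theta, "phi": gt.phi}).to_csv(
        out / "ground_truth.csv", index=False
    )


@_stage("score")
def _score_stage(config, res, out):
    kept, report = scoring.apply_vigilance_filter(res.logs)
    res.n_retained_workers = len(kept)
    report.to_csv(out / "vigilance_report.csv", index=False)
    res.memtable = scoring.score_images(kept)
    io.write_memorability_table(res.memtable, out / "memorability_table.csv")
    hits, fas = scoring.worker_image_matrices(kept)
    rows = []
    for metric in scoring.METRICS:
        c = scoring.split_half_consistency(
            hits, fas, metric=metric,
            iters=config.consistency_iters, seed=res.seeds["consistency"],
        )
        res.consistency[metric] = c
        rows.append({"metric": metric, "mean_rho": c.mean_rho,
                     "chance_rho": c.chance_rho, "p_perm": c.p_perm,
                     "iters": c.iters, "n_images": c.n_images})
    pd.DataFrame(rows).to_csv(out / "consistency.csv", index=False)


@_stage("behavior")
def _behavior_stage(config, res, out):
    all_trials = pd.concat(res.trial_tables.values(), ignore_index=True)
    rows = []
    for hist in ("old", "new"):
        aov, means, inclusion = behavior.behavior_analysis(
            all_trials, res.memtable, hist,
            min_trials=config.min_trials_per_category,
            min_subjects=config.min_subjects_per_category,
        )
        setattr(res, f"anova_{hist}", aov)
        means.to_csv(out / f"category_means_{hist}.csv")
        aov.pairwise.to_csv(out / f"pairwise_{hist}.csv", index=False)
        d = dataclasses.asdict(aov)
        d.pop("pairwise")
        d["history"] = hist
        rows.append(d)
    pd.DataFrame(rows).to_csv(out / "anova.csv", index=False)


@_stage("rsa")
def _rsa_stage(config, sim, res, out, write_subject_maps):
    spec = SearchlightSpec.from_diameter(
        config.searchlight_diameter_vox, config.min_searchlight_voxels
    )
    subject_maps = {m: [] for m in ("memorability", "memory", "hits", "correct_rejections")}
    for k, (sid, tt) in enumerate(res.trial_tables.items()):
        pr = trial_pr(tt, res.memtable)
        mem_model = rsa.build_memorability_rsm(pr, image_ids=tt["image_id"].to_numpy())
        old_idx = np.flatnonzero((tt["history"] == "old").to_numpy())
        memory_model = rsa.build_memory_rsm(
            tt["remembered"].to_numpy()[old_idx].astype(float)
        )
        cond = rsa.condition_trial_indices(tt, seed=res.seeds["condition"] + k)
        models = {
            "memorability": (mem_model, None),
            "memory": (memory_model, old_idx),
            "hits": (rsa.build_memorability_rsm(pr[cond["hits"]]), cond["hits"]),
            "correct_rejections": (
                rsa.build_memorability_rsm(pr[cond["correct_rejections"]]),
                cond["correct_rejections"],
            ),
        }
        maps = rsa.searchlight_rsa_multi(res.pattern_sets[sid], models, spec)
        for m, sm in maps.items():
            subject_maps[m].append(sm)
            if write_subject_maps:
                io.write_map(sm, out / f"zmap_{m}_{sid}.nii")
    for m, sms in subject_maps.items():
        res.group_maps[m] = rsa.group_map(sms)
        io.write_map(res.group_maps[m], out / f"group_t_{m}.nii")

    n_top = min(config.n_top_voxels, res.group_maps["memorability"].n_defined)
    if n_top < config.n_top_voxels:
        logger.warning("n_top_voxels capped at %d defined voxels", n_top)
    gt = res.ground_truth
    n_rec = min(sim.region_voxels, n_top)
    res.recovery = {
        "memorability_region_a": region_enrichment(
            res.group_maps["memorability"], gt.region_a_voxels, n_rec),
        "memory_region_b": region_enrichment(
            res.group_maps["memory"], gt.region_b_voxels, n_rec),
        "hits_region_a": region_enrichment(
            res.group_maps["hits"], gt.region_a_voxels, n_rec),
        "correct_rejections_region_a": region_enrichment(
            res.group_maps["correct_rejections"], gt.region_a_voxels, n_rec),
    }
    res.overlap_results["memorability_vs_memory"] = rsa.overlap(
        rsa.top_n_mask(res.group_maps["memorability"], n_rec),
        rsa.top_n_mask(res.group_maps["memory"], n_rec),
    )
    res.overlap_results["hits_vs_correct_rejections"] = rsa.overlap(
        rsa.top_n_mask(res.group_maps["hits"], n_rec),
        rsa.top_n_mask(res.group_maps["correct_rejections"], n_rec),
    )
    ns = sorted({max(10, n_rec // 4), n_rec // 2, n_rec, min(2 * n_rec, n_top)})
    res.overlap_sweep = rsa.overlap_sweep(
        res.group_maps["memorability"], res.group_maps["memory"], ns
    )
    res.overlap_sweep.to_csv(out / "overlap_sweep.csv", index=False)

    rois = _planted_rois(res.ground_truth, config)
    mem_models = {}
    for sid, tt in res.trial_tables.items():
        mem_models[sid] = rsa.build_memorability_rsm(trial_pr(tt, res.memtable))
    # use the shared memorability model per subject (identical trial orders differ)
    res.roi_rsa_table = rsa.roi_rsa(res.pattern_sets, mem_models, rois)
    res.roi_rsa_table.to_csv(out / "roi_rsa.csv", index=False)


def _planted_rois(gt, config) -> list[RoiMask]:
    """ROI set from the planted regions plus a matched-size noise control."""
    rois = []
    for name, coords in (("region_a", gt.region_a_voxels), ("region_b", gt.region_b_voxels)):
        prob = np.zeros(gt.mask.shape)
        prob[tuple(np.asarray(coords).T)] = 1.0
        rois.append(RoiMask(name, prob, threshold=config.roi_prob_threshold))
    planted = {tuple(v) for v in gt.region_a_voxels} | {tuple(v) for v in gt.region_b_voxels}
    free = np.array([v for v in np.argwhere(gt.mask) if tuple(v) not in planted])
    center = free.mean(axis=0)
    noise_coords = ball_region(gt.mask.shape, tuple(center), len(gt.region_a_voxels),
                               within=_coords_mask(free, gt.mask.shape))
    prob = np.zeros(gt.mask.shape)
    prob[tuple(noise_coords.T)] = 1.0
    rois.append(RoiMask("noise_control", prob, threshold=config.roi_prob_threshold))
    return rois


def _coords_mask(coords, shape):
    m = np.zeros(shape, dtype=bool)
    m[tuple(np.asarray(coords).T)] = True
    return m


@_stage("svr")
def _svr_stage(config, sim, res, out, run_searchlight_svr):
    rois = _planted_rois(res.ground_truth, config)
    scores = {
        sid: svr.logit_pr(trial_pr(tt, res.memtable))
        for sid, tt in res.trial_tables.items()
    }
    res.roi_svr_table = svr.roi_svr(
        res.pattern_sets, scores, rois,
        train_frac=config.svr_train_frac, iters=config.svr_iters,
        seed=res.seeds["svr"], c=config.svr_c, epsilon=config.svr_epsilon,
    )
    res.roi_svr_table.to_csv(out / "roi_svr.csv", index=False)
    if run_searchlight_svr:
        spec = SearchlightSpec.from_diameter(
            config.searchlight_diameter_vox, config.min_searchlight_voxels
        )
        maps = []
        for k, (sid, ps) in enumerate(res.pattern_sets.items()):
            m = svr.searchlight_svr(
                ps, scores[sid], spec,
                train_frac=config.svr_train_frac, iters=config.svr_iters,
                seed=res.seeds["svr"] + k, c=config.svr_c, epsilon=config.svr_epsilon,
            )
            maps.append(m)
        res.group_maps["svr"] = rsa.group_map(
            [StatMap(m.grid_shape, m.mask, np.arctanh(np.clip(m.values, -1 + 1e-12, 1 - 1e-12)), "fisher_z")
             for m in maps]
        )
        io.write_map(res.group_maps["svr"], out / "group_t_svr.nii")


def _versions() -> dict:
    import nibabel
    import scipy
    import sklearn

    import memrsa

    return {
        "memrsa": memrsa.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "sklearn": sklearn.__version__,
    }
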