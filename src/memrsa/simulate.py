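"""Synthetic study generator with planted, recoverable ground truth.

Three linked experiments are emulated:

* an online continuous-recognition study in which each worker's probability
  of pressing on an image's long-lag repeat is ``sigmoid(theta_i + skill_w)``
  and on its first presentation ``sigmoid(phi_i + skill_w - criterion)`` —
  ``theta`` is the latent memorability of image i and ``phi`` its latent
  false-recognition propensity, both on the logit scale;
* a scanner recognition study in which each subject rates old and new items
  on a 5-level confidence scale by thresholding the same latents plus
  subject noise against per-subject criteria, so confidence is monotone in
  memorability by construction;
* BOLD-like trial patterns on a voxel grid containing two disjoint planted
  regions: in region A the pattern for trial t is
  ``a_t * u + sqrt(1 - a_t^2) * eps_t`` with ``a_t = sqrt(g * m_t)`` and
  ``m_t`` the trial's memorability min-max scaled to [0, 1], giving expected
  pairwise pattern correlation ``g * sqrt(m_i * m_j)`` — increasing in both
  items' memorability; region B uses the subject's own remembered/forgotten
  indicator as ``m_t``; everywhere else is pure noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import HIT_RESPONSES, RESPONSE_LEVELS, SimulationParams
from .errors import GenerationError, ParameterError
from .prep import BoldRun, TrialPatternSet
from .scoring import WorkerResponseLog
from .volume import ball_region, ellipsoid_mask

logger = logging.getLogger(__name__)

# Response-category cutpoints on the latent-strength scale, calibrated once
# against the study's marginal response proportions (hit rate ~0.67 for old
# items, correct-rejection rate ~0.69 for new items, rare extreme-wrong
# responses).  Strength below the first cut maps to HC_new, above the last
# to R.
OLD_CUTS = (-1.60, -0.49, 0.21, 0.84)
NEW_CUTS = (-2.37, -1.41, -0.29, 0.60)


@dataclass
class GroundTruth:
    """Latent quantities every downstream stage is asked to recover."""

    image_ids: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    worker_skill: np.ndarray
    subject_criterion: np.ndarray
    region_a_voxels: np.ndarray  # (n, 3) voxel coords, memorability-coding
    region_b_voxels: np.ndarray  # (n, 3) voxel coords, memory-coding
    mask: np.ndarray
    signal_gain: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_gain <= 1.0):
            raise ParameterError("signal_gain must lie in [0, 1]")
        a = {tuple(v) for v in self.region_a_voxels}
        b = {tuple(v) for v in self.region_b_voxels}
        if a & b:
            raise ParameterError("region A and region B must be disjoint")
        for coords in (self.region_a_voxels, self.region_b_voxels):
            if not self.mask[tuple(np.asarray(coords).T)].all():
                raise ParameterError("planted regions must lie inside the brain mask")

    def memorability_scaled(self) -> np.ndarray:
        """theta min-max scaled to [0, 1] over the image set."""
        t = self.theta
        rng_ = t.max() - t.min()
        if rng_ == 0:
            return np.full_like(t, 0.5)
        return (t - t.min()) / rng_


def make_ground_truth(params: SimulationParams, seed: int = 0) -> GroundTruth:
    """Draw latents and plant the two signal regions in the brain mask."""
    rng = np.random.default_rng(seed)
    n = params.n_images
    rho = params.theta_phi_rho
    cov = np.array(
        [
            [params.theta_sd**2, rho * params.theta_sd * params.phi_sd],
            [rho * params.theta_sd * params.phi_sd, params.phi_sd**2],
        ]
    )
    latents = rng.multivariate_normal([params.theta_mean, params.phi_mean], cov, size=n)
    mask = ellipsoid_mask(params.grid_shape, params.mask_semiaxes)
    center = (np.asarray(params.grid_shape) - 1) / 2.0
    off = params.mask_semiaxes[0] * 0.55
    region_a = ball_region(params.grid_shape, tuple(center - [off, 0, 0]),
                           params.region_voxels, within=mask)
    region_b = ball_region(params.grid_shape, tuple(center + [off, 0, 0]),
                           params.region_voxels, within=mask)
    return GroundTruth(
        image_ids=np.array([f"img{i:04d}" for i in range(n)]),
        theta=latents[:, 0],
        phi=latents[:, 1],
        worker_skill=rng.normal(0.0, params.worker_skill_sd, size=params.n_workers),
        subject_criterion=rng.normal(0.0, params.subject_criterion_sd, size=params.n_subjects),
        region_a_voxels=region_a,
        region_b_voxels=region_b,
        mask=mask,
        signal_gain=params.signal_gain,
    )


def _build_stream(rng, target_ids, filler_ids, target_lag, filler_lag, repeat_frac):
    """One worker's stream: (image_id, is_repeat, role, lag) tuples.

    Target first presentations are scattered over the early stream and each
    repeat placed at a lag drawn uniformly from the target window (falling
    back to any free slot in the window); fillers fill the remaining slots,
    a fraction of them repeating at short lag as vigilance probes.  Returns
    None when a target repeat cannot be placed, so the caller can retry.
    """
    lag_lo, lag_hi = target_lag
    n_t = len(target_ids)
    n_f_rep = max(1, int(round(len(filler_ids) * repeat_frac)))
    length = 2 * n_t + len(filler_ids) + n_f_rep
    if length <= lag_hi + 1:
        raise GenerationError("stream too short for the target lag window")
    slots = np.full(length, -1, dtype=int)  # event index or -1
    events: list[tuple[str, bool, str, float]] = []

    first_pool = length - lag_hi - 1
    firsts = np.sort(rng.choice(first_pool, size=n_t, replace=False))
    for img, p in zip(target_ids, firsts):
        # nudge to a free slot if a previous repeat landed here
        while slots[p] != -1:
            p += 1
            if p >= length:
                return None
        slots[p] = len(events)
        events.append((img, False, "target", np.nan))
        window = np.arange(p + lag_lo, min(p + lag_hi + 1, length))
        free = window[slots[window] == -1]
        if len(free) == 0:
            return None
        q = int(rng.choice(free))
        slots[q] = len(events)
        events.append((img, True, "target", float(q - p)))

    free_slots = np.flatnonzero(slots == -1)
    f_lo, f_hi = filler_lag
    reps_left = n_f_rep
    fill_iter = iter(filler_ids)
    i = 0
    while i < len(free_slots):
        s = free_slots[i]
        try:
            img = next(fill_iter)
        except StopIteration:
            img = f"fillx{s}"
        slots[s] = len(events)
        events.append((img, False, "filler", np.nan))
        i += 1
        if reps_left > 0:
            window_free = free_slots[i:][np.isin(free_slots[i:], np.arange(s + f_lo, s + f_hi + 1))]
            if len(window_free):
                q = int(window_free[0])
                slots[q] = len(events)
                events.append((img, True, "filler", float(q - s)))
                free_slots = free_slots[free_slots != q]
                reps_left -= 1
    order = slots[slots != -1]
    rows = [(pos,) + events[e] for pos, e in enumerate(order)]
    return pd.DataFrame(rows, columns=["position", "image_id", "is_repeat", "role", "lag"])


def gen_online_study(params: SimulationParams, gt: GroundTruth, seed: int = 0) -> list[WorkerResponseLog]:
    """Simulate the crowd-sourced continuous-recognition experiment.

    Each worker's target set is a rotating block of ``n_images *
    target_frac`` images (counterbalanced so every image is a target for
    roughly the same number of workers); the remaining images serve as
    fillers.  Workers indexed below ``n_inattentive`` press near-randomly
    at a high rate and are meant to fail the vigilance filter.
    """
    rng = np.random.default_rng(seed)
    n_targets = int(round(params.n_images * params.target_frac))
    image_order = rng.permutation(params.n_images)
    theta_by_id = dict(zip(gt.image_ids, gt.theta))
    phi_by_id = dict(zip(gt.image_ids, gt.phi))

    logs = []
    for w in range(params.n_workers):
        start = (w * n_targets) % params.n_images
        rolled = np.roll(image_order, -start)
        target_ids = [gt.image_ids[i] for i in rolled[:n_targets]]
        filler_ids = [gt.image_ids[i] for i in rolled[n_targets:]]
        stream = None
        for attempt in range(25):
            stream = _build_stream(
                np.random.default_rng(rng.integers(2**31 - 1)),
                target_ids, filler_ids,
                params.target_lag_range, params.filler_lag_range,
                params.filler_repeat_frac,
            )
            if stream is not None:
                break
            logger.info("worker %d: infeasible lag schedule, retrying (%d)", w, attempt + 1)
        if stream is None:
            raise GenerationError(f"worker {w}: could not satisfy the target lag schedule")

        skill = gt.worker_skill[w % len(gt.worker_skill)]
        inattentive = w < params.n_inattentive
        p = np.empty(len(stream))
        for k, row in enumerate(stream.itertuples()):
            if inattentive:
                p[k] = 0.9
            elif row.role == "target" and row.is_repeat:
                p[k] = expit(theta_by_id[row.image_id] + skill)
            elif row.role == "target":
                p[k] = expit(phi_by_id[row.image_id] + skill - params.criterion_offset)
            elif row.is_repeat:
                p[k] = expit(params.filler_hit_logit + skill)
            else:
                p[k] = expit(params.filler_fa_logit + skill)
        stream["pressed"] = rng.random(len(stream)) < p
        logs.append(WorkerResponseLog(worker_id=f"w{w:04d}", events=stream))
    return logs


def _categorize(strength: np.ndarray, cuts, criterion: float) -> np.ndarray:
    """Map latent strengths to the 5-level scale; higher strength = more 'old'."""
    shifted = np.asarray(cuts) + criterion
    idx = np.searchsorted(shifted, strength, side="right")  # 0..4, 4 = strongest old
    levels = np.array(RESPONSE_LEVELS[::-1])  # HC_new .. R by increasing strength
    return levels[idx]


def gen_scanner_study(
    params: SimulationParams, gt: GroundTruth, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate the scanner recognition test for every subject.

    Returns ``(stimulus_table, trial_tables)``: the old/new assignment of
    each image (shared across subjects) and one trial table per subject with
    columns subject_id, trial, image_id, history, response, onset_tr and the
    derived remembered flag.  Old items are rated by thresholding
    ``theta + noise``, new items by thresholding ``phi + noise``, both
    against per-subject-shifted criteria, which makes response confidence
    monotone in the latent by construction.
    """
    if params.n_subjects < 2:
        raise ParameterError("group statistics need at least 2 subjects")
    if params.n_old + params.n_new != params.n_images:
        raise ParameterError("n_old + n_new must equal n_images")
    rng = np.random.default_rng(seed)
    order = rng.permutation(params.n_images)
    history = np.where(np.isin(np.arange(params.n_images), order[: params.n_old]), "old", "new")
    stim = pd.DataFrame({"image_id": gt.image_ids, "history": history})

    tables = {}
    for s in range(params.n_subjects):
        sid = f"sub{s:02d}"
        crit = gt.subject_criterion[s]
        trial_order = rng.permutation(params.n_images)
        img = gt.image_ids[trial_order]
        hist = history[trial_order]
        noise = rng.normal(0.0, params.subject_noise_sd, size=params.n_images)
        strength = np.where(hist == "old", gt.theta[trial_order], gt.phi[trial_order]) + noise
        resp = np.empty(params.n_images, dtype=object)
        old_sel = hist == "old"
        resp[old_sel] = _categorize(strength[old_sel], OLD_CUTS, crit)
        resp[~old_sel] = _categorize(strength[~old_sel], NEW_CUTS, crit)
        df = pd.DataFrame(
            {
                "subject_id": sid,
                "trial": np.arange(params.n_images),
                "image_id": img,
                "history": hist,
                "response": resp,
                "onset_tr": 2 + 5 * np.arange(params.n_images),
            }
        )
        df["remembered"] = (df["history"] == "old") & df["response"].isin(HIT_RESPONSES)
        tables[sid] = df
        n_hits = int(df["remembered"].sum())
        logger.info("%s: %d hit trials of %d old items", sid, n_hits, params.n_old)
    return stim, tables


def gen_bold_patterns(
    trial_table: pd.DataFrame,
    gt: GroundTruth,
    params: SimulationParams,
    seed: int = 0,
) -> TrialPatternSet:
    """Trial-by-voxel patterns with planted similarity structure for one subject.

    Region A couples similarity to stimulus memorability (shared template
    weighted by ``sqrt(g * m)`` with m the scaled theta of the trial's
    image), region B to the subject's remembered indicator, and all other
    in-mask voxels are independent noise.
    """
    rng = np.random.default_rng(seed)
    mask = gt.mask
    n_vox = int(mask.sum())
    n_trials = len(trial_table)
    g = gt.signal_gain

    patterns = rng.normal(0.0, params.noise_sd, size=(n_trials, n_vox))
    m_scaled = dict(zip(gt.image_ids, gt.memorability_scaled()))
    m_a = np.array([m_scaled[i] for i in trial_table["image_id"]])
    m_b = trial_table["remembered"].to_numpy(dtype=float)

    flat_all = np.ravel_multi_index(tuple(np.argwhere(mask).T), mask.shape)
    col_of = {f: i for i, f in enumerate(flat_all)}
    for coords, m in ((gt.region_a_voxels, m_a), (gt.region_b_voxels, m_b)):
        cols = np.array(
            [col_of[f] for f in np.ravel_multi_index(tuple(np.asarray(coords).T), mask.shape)]
        )
        u = rng.normal(size=len(cols))
        u = (u - u.mean()) / u.std()
        a = np.sqrt(g * m)[:, None]
        eps = rng.normal(size=(n_trials, len(cols)))
        patterns[:, cols] = a * u[None, :] + np.sqrt(1.0 - a**2) * eps

    return TrialPatternSet(
        patterns=patterns,
        mask=mask,
        grid_shape=mask.shape,
        trial_index=trial_table["trial"].to_numpy(),
    )


def embed_patterns_in_run(
    pattern_set: TrialPatternSet,
    onsets: np.ndarray,
    tr_seconds: float = 2.0,
    baseline_sd: float = 0.05,
    seed: int = 0,
) -> BoldRun:
    """Place trial patterns into a 4-D run at their peak volumes.

    Each trial's pattern is written into the 3rd and 4th volumes after its
    onset on top of low-amplitude baseline noise, so
    :func:`memrsa.prep.extract_trial_patterns` recovers the patterns up to
    that noise.  Intended for end-to-end exercises of the preprocessing
    stage, not as a hemodynamic model.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) != pattern_set.n_trials:
        raise ParameterError("one onset per trial required")
    rng = np.random.default_rng(seed)
    n_vol = int(onsets.max()) + 6
    shape = tuple(pattern_set.grid_shape) + (n_vol,)
    data = rng.normal(0.0, baseline_sd, size=shape)
    mask = pattern_set.mask
    for t, o in enumerate(onsets):
        for dv in (2, 3):
            vol = data[..., o + dv]
            vol[mask] += pattern_set.patterns[t]
    return BoldRun(data=data, mask=mask, tr_seconds=tr_seconds, run_id="synthetic")
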