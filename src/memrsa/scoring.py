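"""Crowd-sourced memorability scoring and split-half consistency.

Workers watch a continuous stream of images and press whenever they believe
an image repeated.  Per image, the hit rate HR is the fraction of workers
pressing on its (long-lag) target repeat, the false-alarm rate FA the
fraction pressing on its first presentation, and memorability is the
corrected recognition score Pr = HR - FA.  Short-lag filler repeats serve
only as vigilance probes: workers with filler false alarms above 50% or
filler misses above 50% are excluded before scoring.

Cross-observer consistency is quantified by a split-half permutation test:
workers are randomly halved, images scored within each half, and the two
rankings compared with Spearman's rho; chance is the same statistic after
shuffling the image assignment of the second half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, ParameterError, VigilanceUndefinedError

logger = logging.getLogger(__name__)

METRICS = ("HR", "FA", "Pr", "dprime")


@dataclass
class WorkerResponseLog:
    """One worker's ordered stream of presentations and key presses.

    ``events`` has one row per presentation with columns ``position``,
    ``image_id``, ``is_repeat``, ``pressed``, ``role`` ('target'/'filler')
    and ``lag`` (images since first presentation; NaN for first showings).
    """

    worker_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = self.events
        required = {"position", "image_id", "is_repeat", "pressed", "role"}
        missing = required - set(ev.columns)
        if missing:
            raise IntegrityError(f"worker {self.worker_id}: missing columns {sorted(missing)}")
        if ev["position"].duplicated().any():
            raise IntegrityError(f"worker {self.worker_id}: duplicate stream positions")
        self.events = ev.sort_values("position").reset_index(drop=True)

    def filler_rates(self) -> tuple[float, float]:
        """(false-alarm rate, miss rate) on filler presentations only."""
        ev = self.events
        fill = ev[ev["role"] == "filler"]
        firsts = fill[~fill["is_repeat"]]
        reps = fill[fill["is_repeat"]]
        if len(firsts) == 0 or len(reps) == 0:
            raise VigilanceUndefinedError(
                f"worker {self.worker_id}: no filler events to assess vigilance"
            )
        fa = float(firsts["pressed"].mean())
        miss = float(1.0 - reps["pressed"].mean())
        return fa, miss


def vigilance_filter(log: WorkerResponseLog) -> tuple[bool, str]:
    """Keep/exclude decision for one worker with a reason string.

    A worker is excluded iff their filler false-alarm rate exceeds 50% or
    they missed more than 50% of filler repeats — strict inequalities, so a
    rate of exactly 0.5 is retained.
    """
    fa, miss = log.filler_rates()
    if fa > 0.5:
        return False, f"filler false-alarm rate {fa:.3f} > 0.5"
    if miss > 0.5:
        return False, f"filler miss rate {miss:.3f} > 0.5"
    return True, "kept"


def apply_vigilance_filter(logs: list[WorkerResponseLog]) -> tuple[list[WorkerResponseLog], pd.DataFrame]:
    """Filter a worker collection; returns (retained logs, per-worker report)."""
    rows, kept = [], []
    for log in logs:
        keep, reason = vigilance_filter(log)
        rows.append({"worker_id": log.worker_id, "kept": keep, "reason": reason})
        if keep:
            kept.append(log)
    report = pd.DataFrame(rows)
    logger.info("vigilance filter: %d of %d workers retained", len(kept), len(logs))
    return kept, report


def dprime(hr: float, fa: float, n_hr: int, n_fa: int) -> float:
    """Signal-detection d' = z(HR) - z(FA) with extreme rates clamped.

    Rates of exactly 0 or 1 are replaced by 1/(2n) and 1 - 1/(2n), n being
    the count of contributing workers for that rate.
    """
    hr_c = float(np.clip(hr, 1.0 / (2 * n_hr), 1.0 - 1.0 / (2 * n_hr)))
    fa_c = float(np.clip(fa, 1.0 / (2 * n_fa), 1.0 - 1.0 / (2 * n_fa)))
    return float(stats.norm.ppf(hr_c) - stats.norm.ppf(fa_c))


def score_images(logs: list[WorkerResponseLog]) -> pd.DataFrame:
    """Aggregate retained worker logs into a memorability table.

    Only target presentations are scored (filler repeats are too recent to
    measure memory).  HR and FA for one image may come from different worker
    subsets, so contributing counts are stored separately as ``n_hr`` and
    ``n_fa``.  Images never shown as a target are absent from the table.

    Returns a DataFrame indexed by ``image_id`` with columns
    ``HR, FA, Pr, dprime, n_hr, n_fa`` satisfying Pr = HR - FA exactly.
    """
    frames = []
    for log in logs:
        tg = log.events[log.events["role"] == "target"]
        if len(tg):
            frames.append(tg[["image_id", "is_repeat", "pressed"]])
    if not frames:
        raise ParameterError("no target presentations in any retained log")
    ev = pd.concat(frames, ignore_index=True)
    grp = ev.groupby(["image_id", "is_repeat"])["pressed"]
    agg = grp.agg(["mean", "count"]).unstack("is_repeat")
    hr = agg[("mean", True)]
    fa = agg[("mean", False)]
    n_hr = agg[("count", True)]
    n_fa = agg[("count", False)]
    table = pd.DataFrame(
        {
            "HR": hr,
            "FA": fa,
            "n_hr": n_hr,
            "n_fa": n_fa,
        }
    ).dropna(subset=["HR", "FA"])
    table["n_hr"] = table["n_hr"].astype(int)
    table["n_fa"] = table["n_fa"].astype(int)
    table["Pr"] = table["HR"] - table["FA"]
    table["dprime"] = [
        dprime(r.HR, r.FA, r.n_hr, r.n_fa) for r in table.itertuples()
    ]
    table = table[["HR", "FA", "Pr", "dprime", "n_hr", "n_fa"]]
    validate_memorability_table(table)
    return table


def validate_memorability_table(table: pd.DataFrame) -> None:
    if not ((table["HR"].between(0, 1)).all() and (table["FA"].between(0, 1)).all()):
        raise IntegrityError("HR/FA outside [0, 1]")
    if not np.allclose(table["Pr"], table["HR"] - table["FA"], rtol=0, atol=0):
        raise IntegrityError("Pr != HR - FA")
    if (table[["n_hr", "n_fa"]] < 1).any().any():
        raise IntegrityError("scored image with no contributing workers")


def worker_image_matrices(logs: list[WorkerResponseLog]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Worker-by-image binary response matrices for target events.

    Returns ``(hits, fas)``: entry (w, i) is 1.0 if worker w pressed on the
    repeat (resp. first presentation) of target image i, 0.0 if shown and
    not pressed, NaN if image i was not a target for worker w.
    """
    hit_rows, fa_rows, ids = {}, {}, []
    for log in logs:
        tg = log.events[log.events["role"] == "target"]
        reps = tg[tg["is_repeat"]]
        firsts = tg[~tg["is_repeat"]]
        hit_rows[log.worker_id] = dict(zip(reps["image_id"], reps["pressed"].astype(float)))
        fa_rows[log.worker_id] = dict(zip(firsts["image_id"], firsts["pressed"].astype(float)))
        ids.append(log.worker_id)
    hits = pd.DataFrame.from_dict(hit_rows, orient="index").loc[ids]
    fas = pd.DataFrame.from_dict(fa_rows, orient="index").loc[ids]
    cols = sorted(set(hits.columns) | set(fas.columns))
    return hits.reindex(columns=cols), fas.reindex(columns=cols)


@dataclass
class ConsistencyResult:
    metric: str
    mean_rho: float
    chance_rho: float
    p_perm: float
    iters: int
    n_images: int
    per_iteration_rho: np.ndarray = field(repr=False, default=None)
    per_iteration_chance: np.ndarray = field(repr=False, default=None)


def _half_scores(metric: str, z: np.ndarray, hit_data, hit_valid, fa_data, fa_valid):
    """Per-image metric for the worker subset selected by indicator ``z``."""
    n_hit = z @ hit_valid
    n_fa = z @ fa_valid
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.where(n_hit > 0, (z @ hit_data) / n_hit, np.nan)
        fa = np.where(n_fa > 0, (z @ fa_data) / n_fa, np.nan)
    if metric == "HR":
        return hr, n_hit > 0
    if metric == "FA":
        return fa, n_fa > 0
    valid = (n_hit > 0) & (n_fa > 0)
    if metric == "Pr":
        return hr - fa, valid
    # dprime with 1/(2n) clamping, vectorized over images
    with np.errstate(invalid="ignore", divide="ignore"):
        hr_c = np.clip(hr, 1.0 / (2 * np.maximum(n_hit, 1)), 1.0 - 1.0 / (2 * np.maximum(n_hit, 1)))
        fa_c = np.clip(fa, 1.0 / (2 * np.maximum(n_fa, 1)), 1.0 - 1.0 / (2 * np.maximum(n_fa, 1)))
        d = stats.norm.ppf(hr_c) - stats.norm.ppf(fa_c)
    return d, valid


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    den = np.sqrt((xm @ xm) * (ym @ ym))
    if den == 0:
        return np.nan
    return float((xm @ ym) / den)


def split_half_consistency(
    hits: pd.DataFrame,
    fas: pd.DataFrame,
    metric: str = "Pr",
    iters: int = 10_000,
    seed: int = 0,
    n_null: int = 200,
    keep_iterations: bool = False,
) -> ConsistencyResult:
    """Split-half Spearman consistency of per-image scores, with permutation null.

    Each iteration randomly splits workers into halves (an odd worker joins
    half 1), scores every image within each half, and correlates the two
    score vectors with Spearman's rho; ``mean_rho`` averages over
    iterations.  The chance distribution shuffles half 2's image assignment
    before correlating: each of the ``n_null`` chance draws applies one
    fixed image permutation across all split iterations and averages, so
    chance values are means over the same splits as the observed statistic
    and the one-sided permutation test is calibrated (images are
    exchangeable under the no-consistency null).  The add-one rule
    p = (1 + #{chance >= observed}) / (1 + n_null) keeps p strictly
    positive.

    Images that cannot be scored in both halves (fewer than 2 contributing
    workers for a needed rate) are dropped up front and logged; splits that
    still leave an image unscored are redrawn.

    Parameters
    ----------
    hits, fas : DataFrame
        Worker-by-image matrices from :func:`worker_image_matrices`.
    metric : {"HR", "FA", "Pr", "dprime"}
    """
    if metric not in METRICS:
        raise ParameterError(f"metric must be one of {METRICS}")
    if iters < 1 or n_null < 1:
        raise ParameterError("iters and n_null must be >= 1")
    cols = hits.columns
    if not cols.equals(fas.columns):
        raise IntegrityError("hits and fas matrices have different image sets")
    n_w = len(hits)
    if n_w < 4:
        raise ParameterError("need at least 4 workers (2 per half)")
    rng = np.random.default_rng(seed)

    hit_arr = hits.to_numpy(dtype=float)
    fa_arr = fas.to_numpy(dtype=float)
    # images scorable in both halves under any split
    need_hit = metric in ("HR", "Pr", "dprime")
    need_fa = metric in ("FA", "Pr", "dprime")
    ok_img = np.ones(hit_arr.shape[1], dtype=bool)
    if need_hit:
        ok_img &= (~np.isnan(hit_arr)).sum(axis=0) >= 2
    if need_fa:
        ok_img &= (~np.isnan(fa_arr)).sum(axis=0) >= 2
    if not ok_img.all():
        logger.warning("split-half: dropping %d images with <2 contributing workers",
                       int((~ok_img).sum()))
    hit_arr = hit_arr[:, ok_img]
    fa_arr = fa_arr[:, ok_img]
    n_img = hit_arr.shape[1]
    if n_img < 3:
        raise ParameterError("fewer than 3 images scorable in both halves")
    hit_valid = (~np.isnan(hit_arr)).astype(float)
    fa_valid = (~np.isnan(fa_arr)).astype(float)
    hit_data = np.nan_to_num(hit_arr)
    fa_data = np.nan_to_num(fa_arr)

    perms = np.stack([rng.permutation(n_img) for _ in range(n_null)])
    n_half1 = (n_w + 1) // 2
    rhos = np.empty(iters)
    null_sums = np.zeros(n_null)
    for it in range(iters):
        for attempt in range(50):
            sel = rng.permutation(n_w)
            z1 = np.zeros(n_w)
            z1[sel[:n_half1]] = 1.0
            z2 = 1.0 - z1
            x, vx = _half_scores(metric, z1, hit_data, hit_valid, fa_data, fa_valid)
            y, vy = _half_scores(metric, z2, hit_data, hit_valid, fa_data, fa_valid)
            if (vx & vy & np.isfinite(x) & np.isfinite(y)).all():
                break
        else:
            raise ParameterError("could not draw a split scoring every image in both halves")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rhos[it] = _pearson(rx, ry)
        # chance, all fixed permutations at once: same split, shuffled images
        if np.isfinite(rhos[it]):
            rxc = rx - rx.mean()
            ryc = ry - ry.mean()
            den = np.sqrt((rxc @ rxc) * (ryc @ ryc))
            null_sums += (ryc[perms] @ rxc) / den

    ok = np.isfinite(rhos)
    if not ok.any():
        raise ParameterError("every split produced a constant half (rho undefined)")
    if not ok.all():
        logger.warning("split-half: %d/%d iterations undefined (constant half scores)",
                       int((~ok).sum()), iters)
    mean_rho = float(np.mean(rhos[ok]))
    null_means = null_sums / int(ok.sum())
    chance_rho = float(np.mean(null_means))
    p_perm = float((1 + np.sum(null_means >= mean_rho)) / (1 + n_null))
    return ConsistencyResult(
        metric=metric,
        mean_rho=mean_rho,
        chance_rho=chance_rho,
        p_perm=p_perm,
        iters=int(ok.sum()),
        n_images=n_img,
        per_iteration_rho=rhos[ok] if keep_iterations else None,
        per_iteration_chance=null_means if keep_iterations else None,
    )
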