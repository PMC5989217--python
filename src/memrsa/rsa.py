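"""Representational similarity analysis: model/data RSMs, searchlights, ROIs.

Two hypothesis models are compared against local BOLD pattern similarity:

* the *memorability* model — pairwise similarity of two trials is the mean
  corrected-recognition score (Pr_i + Pr_j) / 2 of their images, identical
  across subjects;
* the *memory* model — for previously studied items only, similarity is the
  mean of the two binary remembered flags (1/0), so both-remembered pairs
  code 1, mixed pairs 0.5, both-forgotten pairs 0; one matrix per subject.

Data RSMs are Pearson correlations of trial voxel vectors.  Model and data
RSMs are compared with Spearman's rho over the lower off-diagonal triangle
(the diagonal never enters any analysis), Fisher z-transformed, and carried
to the group as one-sample t-maps.  Map pairs are characterized by the
overlap of their top-N voxels by t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CR_RESPONSES, HIT_RESPONSES
from .errors import InsufficientTrialsError, ParameterError, ShapeError
from .prep import TrialPatternSet
from .volume import StatMap, sphere_offsets

logger = logging.getLogger(__name__)

#: Fisher z of |r| = 1 is infinite; correlations are clipped here first so
#: group t statistics stay finite.
Z_CAP_R = 1.0 - 1e-12

RSM_KINDS = ("model_memorability", "model_memory", "data")


@dataclass
class RSM:
    """Symmetric trial-by-trial similarity matrix; the diagonal is never used."""

    values: np.ndarray
    kind: str = "data"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError("RSM must be square")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-12,
        ) and (finite == finite.T).all()
        if not sym_ok:
            raise ShapeError("RSM must be symmetric")
        if self.kind not in RSM_KINDS:
            raise ValueError(f"unknown RSM kind {self.kind!r}")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.size, k=-1)
        return self.values[i, j]

    def subset(self, idx: np.ndarray) -> "RSM":
        idx = np.asarray(idx, dtype=int)
        return RSM(self.values[np.ix_(idx, idx)], kind=self.kind)


@dataclass
class SearchlightSpec:
    radius_vox: int = 3
    min_voxels: int = 10

    def __post_init__(self) -> None:
        if self.radius_vox < 0:
            raise ParameterError("radius must be >= 0")

    @classmethod
    def from_diameter(cls, diameter: int, min_voxels: int = 10) -> "SearchlightSpec":
        if diameter < 1 or diameter % 2 == 0:
            raise ParameterError("searchlight diameter must be odd and >= 1")
        return cls(radius_vox=(diameter - 1) // 2, min_voxels=min_voxels)


@dataclass
class RoiMask:
    """Probabilistic ROI thresholded into a binary mask.

    The binary mask keeps voxels whose probability (fraction of a reference
    cohort sharing the voxel) is at least the threshold, default 25%.
    """

    name: str
    probability: np.ndarray
    threshold: float = 0.25

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        if not ((self.probability >= 0) & (self.probability <= 1)).all():
            raise ParameterError(f"ROI {self.name}: probabilities must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return self.probability >= self.threshold


def build_memorability_rsm(pr_per_trial: np.ndarray, image_ids=None) -> RSM:
    """Model RSM with entry (i, j) = (Pr_i + Pr_j) / 2.

    Includes every trial regardless of item history or response; identical
    across subjects for identical trial sets.  A missing (NaN) Pr raises an
    error naming the offending image.
    """
    pr = np.asarray(pr_per_trial, dtype=float)
    bad = ~np.isfinite(pr)
    if bad.any():
        name = image_ids[int(np.flatnonzero(bad)[0])] if image_ids is not None else f"trial {int(np.flatnonzero(bad)[0])}"
        raise ParameterError(f"missing memorability score for {name}")
    vals = (pr[:, None] + pr[None, :]) / 2.0
    if np.ptp(pr) == 0:
        logger.warning("memorability RSM is degenerate (all Pr equal)")
    return RSM(vals, kind="model_memorability")


def build_memory_rsm(remembered_flags: np.ndarray, history=None) -> RSM:
    """Subject-specific model RSM from binary remembered/forgotten flags.

    Defined only for previously studied (old) trials; entry (i, j) is the
    mean of the two flags, i.e. 1 when both were remembered, 0.5 when one
    was, 0 when neither.
    """
    if history is not None and not all(h == "old" for h in np.asarray(history)):
        raise ParameterError("memory RSM accepts old-history trials only")
    flags = np.asarray(remembered_flags, dtype=float)
    if not np.isin(flags, (0.0, 1.0)).all():
        raise ParameterError("remembered flags must be binary")
    vals = (flags[:, None] + flags[None, :]) / 2.0
    if np.ptp(flags) == 0:
        logger.warning("memory RSM is degenerate (all flags equal)")
    return RSM(vals, kind="model_memory")


def data_rsm(patterns, voxel_subset: np.ndarray | None = None) -> RSM:
    """Pearson-correlation RSM of trial voxel vectors.

    ``patterns`` is a TrialPatternSet or a trials-by-voxels array;
    ``voxel_subset`` selects columns.  A zero-variance trial vector yields
    NaN entries for every pair involving it (excluded pairwise downstream).
    """
    mat = patterns.patterns if isinstance(patterns, TrialPatternSet) else np.asarray(patterns, float)
    if voxel_subset is not None:
        mat = mat[:, np.asarray(voxel_subset, dtype=int)]
    if mat.shape[1] < 2:
        raise ParameterError("data RSM needs at least 2 voxels")
    if mat.shape[0] < 3:
        raise ParameterError("data RSM needs at least 3 trials")
    r = _corr_rows(mat)
    return RSM(r, kind="data")


def _corr_rows(mat: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation; zero-variance rows propagate NaN."""
    a = mat - mat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(a, axis=1)
    dead = norm == 0
    if dead.any():
        logger.warning("data RSM: %d zero-variance trial vectors", int(dead.sum()))
    norm_safe = np.where(dead, 1.0, norm)
    a = a / norm_safe[:, None]
    r = np.clip(a @ a.T, -1.0, 1.0)
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    return r


def compare_rsms(model: RSM, data: RSM) -> tuple[float, float]:
    """Spearman rho between two RSMs over the lower off-diagonal triangle,
    plus its Fisher z = atanh(rho).

    NaN data cells are excluded pairwise; a constant model triangle makes
    the correlation undefined and (NaN, NaN) is returned.
    """
    if model.size != data.size:
        raise ShapeError("model and data RSMs differ in size")
    x = model.lower_triangle()
    y = data.lower_triangle()
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan, np.nan
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("compare_rsms: degenerate RSM triangle, correlation undefined")
        return np.nan, np.nan
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, fisher_z(rho)


def fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -Z_CAP_R, Z_CAP_R)))


# ---------------------------------------------------------------------------
# searchlight


def _sphere_columns(pattern_set: TrialPatternSet, spec: SearchlightSpec):
    """Yield (center_index, column indices) for every in-mask center voxel."""
    mask = pattern_set.mask
    grid = np.full(mask.shape, -1, dtype=int)
    grid[mask] = np.arange(int(mask.sum()))
    offs = sphere_offsets(spec.radius_vox)
    centers = pattern_set.voxel_coords
    shape = np.asarray(mask.shape)
    for c_idx in range(len(centers)):
        pts = centers[c_idx] + offs
        inside = ((pts >= 0) & (pts < shape)).all(axis=1)
        cols = grid[tuple(pts[inside].T)]
        yield c_idx, cols[cols >= 0]


def _rank_no_ties(x: np.ndarray) -> np.ndarray:
    # ordinal ranks; ties (measure-zero for correlation data) break by sort
    # order, which only perturbs rho at O(1/n_pairs)
    order = np.argsort(x)
    ranks = np.empty(len(x))
    ranks[order] = np.arange(1, len(x) + 1)
    return ranks


def searchlight_rsa_multi(
    pattern_set: TrialPatternSet,
    models: dict[str, tuple[RSM, np.ndarray | None]],
    spec: SearchlightSpec,
) -> dict[str, StatMap]:
    """Run several model comparisons in one searchlight pass.

    ``models`` maps a name to ``(model_rsm, trial_subset)``; the model RSM
    is sized to the subset (or to all trials when the subset is None).  For
    every in-mask center voxel the sphere's trial-correlation matrix is
    computed once and each model's Spearman/Fisher-z read off its own trial
    subset, which is what makes joint memorability/memory/hit/CR maps cheap.

    Returns one Fisher-z StatMap per model; centers whose sphere holds fewer
    than ``spec.min_voxels`` in-mask voxels (or fewer than 2) are NaN.
    """
    if pattern_set.n_trials < 3:
        raise ParameterError("searchlight needs at least 3 trials")
    if int(pattern_set.mask.sum()) == 0:
        raise ParameterError("empty mask")
    n_all = pattern_set.n_trials

    prepared = {}
    for name, (model, subset) in models.items():
        idx = np.arange(n_all) if subset is None else np.asarray(subset, dtype=int)
        if model.size != len(idx):
            raise ShapeError(f"model {name!r} sized {model.size} but subset has {len(idx)} trials")
        ti, tj = np.tril_indices(len(idx), k=-1)
        mvals = model.values[ti, tj]
        if np.ptp(mvals[np.isfinite(mvals)]) == 0:
            logger.warning("model %r has a constant triangle; its map is undefined", name)
            prepared[name] = None
            continue
        mr = stats.rankdata(mvals)
        mr_c = mr - mr.mean()
        prepared[name] = {
            "gi": idx[ti],
            "gj": idx[tj],
            "mr_c": mr_c,
            "mr_norm2": float(mr_c @ mr_c),
        }

    X = pattern_set.patterns
    out = {name: np.full(len(pattern_set.voxel_coords), np.nan) for name in models}
    min_vox = max(spec.min_voxels, 2)
    for c_idx, cols in _sphere_columns(pattern_set, spec):
        if len(cols) < min_vox:
            continue
        R = _corr_rows(X[:, cols])
        for name, prep in prepared.items():
            if prep is None:
                continue
            dvals = R[prep["gi"], prep["gj"]]
            ok = np.isfinite(dvals)
            if ok.sum() < 3:
                continue
            if ok.all():
                dr = _rank_no_ties(dvals)
                mr_c, mr_norm2 = prep["mr_c"], prep["mr_norm2"]
            else:
                dr = _rank_no_ties(dvals[ok])
                mr_sub = stats.rankdata(prep["mr_c"][ok])
                mr_c = mr_sub - mr_sub.mean()
                mr_norm2 = float(mr_c @ mr_c)
            dr_c = dr - dr.mean()
            den = np.sqrt(mr_norm2 * (dr_c @ dr_c))
            if den == 0:
                continue
            rho = float((mr_c @ dr_c) / den)
            out[name][c_idx] = fisher_z(rho)

    return {
        name: StatMap(pattern_set.grid_shape, pattern_set.mask, vals, "fisher_z")
        for name, vals in out.items()
    }


def searchlight_rsa(pattern_set: TrialPatternSet, model: RSM, spec: SearchlightSpec,
                    trial_subset: np.ndarray | None = None) -> StatMap:
    """Single-model searchlight RSA; see :func:`searchlight_rsa_multi`."""
    return searchlight_rsa_multi(pattern_set, {"m": (model, trial_subset)}, spec)["m"]


# ---------------------------------------------------------------------------
# group statistics, top-N maps, overlap


def group_map(z_maps: list[StatMap]) -> StatMap:
    """Per-voxel one-sample t of subject Fisher-z maps against 0.

    Voxels undefined in a subject are handled pairwise-complete; voxels
    defined in fewer than 2 subjects, or with zero variance across
    subjects, are undefined (NaN) rather than infinite.
    """
    if len(z_maps) < 2:
        raise ParameterError("group map needs at least 2 subjects")
    ref = z_maps[0]
    for m in z_maps[1:]:
        if m.grid_shape != ref.grid_shape or not np.array_equal(m.mask, ref.mask):
            raise ShapeError("subject maps are not on a common grid/mask")
    stack = np.stack([m.values for m in z_maps], axis=0)
    n = np.isfinite(stack).sum(axis=0)
    mean = np.nanmean(np.where(np.isfinite(stack), stack, np.nan), axis=0)
    sd = np.full_like(mean, np.nan)
    enough = n >= 2
    with np.errstate(invalid="ignore"):
        sd[enough] = np.nanstd(np.where(np.isfinite(stack), stack, np.nan), axis=0, ddof=1)[enough]
    t = np.full_like(mean, np.nan)
    good = enough & np.isfinite(sd) & (sd > 0)
    t[good] = mean[good] / (sd[good] / np.sqrt(n[good]))
    return StatMap(ref.grid_shape, ref.mask, t, "group_t")


def top_n_mask(stat_map: StatMap, n: int) -> np.ndarray:
    """Binary volume of the n largest defined values; ties at the cutoff are
    broken by voxel index order (deterministic)."""
    defined = np.flatnonzero(np.isfinite(stat_map.values))
    if n > len(defined):
        logger.warning("top_n_mask: n=%d capped to %d defined voxels", n, len(defined))
        n = len(defined)
    order = defined[np.argsort(-stat_map.values[defined], kind="stable")]
    chosen = order[:n]
    out = np.zeros(stat_map.grid_shape, dtype=bool)
    coords = np.argwhere(stat_map.mask)[chosen]
    out[tuple(coords.T)] = True
    return out


@dataclass
class OverlapResult:
    count: int
    percent: float


def overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> OverlapResult:
    """Shared voxel count between two binary maps, as count and percent of
    the (smaller) map size."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ShapeError("overlap masks differ in shape")
    shared = int((a & b).sum())
    denom = min(int(a.sum()), int(b.sum()))
    pct = 100.0 * shared / denom if denom else 0.0
    return OverlapResult(count=shared, percent=pct)


def overlap_sweep(map_a: StatMap, map_b: StatMap, ns: list[int]) -> pd.DataFrame:
    """Overlap of the two maps' top-N voxels across a grid of N."""
    rows = []
    for n in ns:
        res = overlap(top_n_mask(map_a, n), top_n_mask(map_b, n))
        rows.append({"n_voxels": n, "shared": res.count, "percent": res.percent})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# condition-specific (hit / correct-rejection) RSA


def condition_trial_indices(trial_table: pd.DataFrame, seed: int = 0,
                            min_trials: int = 10) -> dict[str, np.ndarray]:
    """Balanced hit / correct-rejection trial indices for one subject.

    Hits are old trials with any correct old response; correct rejections
    are new trials with a correct new response.  The larger set is
    subsampled without replacement to the smaller set's size m (seeded), so
    condition maps are not confounded by trial counts.  Raises when
    m < ``min_trials``.
    """
    hist = trial_table["history"].to_numpy()
    resp = trial_table["response"].to_numpy()
    hits = np.flatnonzero((hist == "old") & np.isin(resp, HIT_RESPONSES))
    crs = np.flatnonzero((hist == "new") & np.isin(resp, CR_RESPONSES))
    if len(hits) == 0 or len(crs) == 0:
        raise InsufficientTrialsError("a condition has no trials")
    m = min(len(hits), len(crs))
    if m < min_trials:
        raise InsufficientTrialsError(f"insufficient trials: min condition count {m} < {min_trials}")
    rng = np.random.default_rng(seed)
    if len(hits) > m:
        hits = np.sort(rng.choice(hits, size=m, replace=False))
    if len(crs) > m:
        crs = np.sort(rng.choice(crs, size=m, replace=False))
    return {"hits": hits, "correct_rejections": crs}


def condition_rsa(
    trial_table: pd.DataFrame,
    pattern_set: TrialPatternSet,
    pr_per_trial: np.ndarray,
    condition: str,
    spec: SearchlightSpec,
    seed: int = 0,
) -> StatMap:
    """Memorability searchlight restricted to one balanced condition."""
    if condition not in ("hits", "correct_rejections"):
        raise ParameterError("condition must be 'hits' or 'correct_rejections'")
    idx = condition_trial_indices(trial_table, seed=seed)[condition]
    model = build_memorability_rsm(np.asarray(pr_per_trial, float)[idx])
    return searchlight_rsa(pattern_set, model, spec, trial_subset=idx)


# ---------------------------------------------------------------------------
# ROI analyses


def roi_rsa(
    pattern_sets: dict[str, TrialPatternSet],
    models: dict[str, RSM] | RSM,
    rois: list[RoiMask],
    trial_subsets: dict[str, np.ndarray] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Group RSA within probabilistic ROIs, BH-FDR corrected across the family.

    ``models`` may be one RSM shared by all subjects (memorability model) or
    a per-subject dict (memory model).  Per subject and ROI the data RSM is
    computed over the ROI's in-mask voxels and compared to the model; the
    group statistic is a one-sample t of the Fisher-z values against 0.

    Returns a DataFrame with one row per analyzed ROI: mean_r, t, p,
    p_fdr, significant, n_voxels, n_subjects.
    """
    rows = []
    for roi in rois:
        zs, rs = [], []
        n_vox = None
        skip = False
        for sid, ps in pattern_sets.items():
            roi_mask = roi.mask & ps.mask
            coords = np.argwhere(roi_mask)
            if len(coords) < 2:
                logger.warning("ROI %s: <2 in-mask voxels, skipped", roi.name)
                skip = True
                break
            cols = ps.columns_for(coords)
            n_vox = len(cols)
            model = models[sid] if isinstance(models, dict) else models
            subset = None if trial_subsets is None else trial_subsets.get(sid)
            if subset is not None:
                d = data_rsm(ps.patterns[np.asarray(subset, int)], cols)
            else:
                d = data_rsm(ps, cols)
            r, z = compare_rsms(model, d)
            if np.isfinite(z):
                rs.append(r)
                zs.append(z)
        if skip or len(zs) < 2:
            continue
        t_res = stats.ttest_1samp(zs, 0.0)
        rows.append(
            {
                "roi": roi.name,
                "n_voxels": n_vox,
                "n_subjects": len(zs),
                "mean_r": float(np.mean(rs)),
                "t": float(t_res.statistic),
                "p": float(t_res.pvalue),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        rej, p_adj, _, _ = multipletests(df["p"], alpha=q, method="fdr_bh")
        df["p_fdr"] = p_adj
        df["significant"] = rej
    return df
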