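"""Support-vector-regression decoding of continuous memorability.

Memorability scores are logit-transformed (with clamping, since observed
Pr can be <= 0) and predicted from multivoxel patterns by a linear-kernel
SVR.  Accuracy is the mean Pearson correlation between predicted and actual
scores over repeated random 80/20 train/test partitions drawn without
replacement (default 100 iterations).  The same decoder runs per
searchlight sphere or per probabilistic ROI, and per-subject accuracies
are carried to the group as one-sample t statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVR
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ShapeError
from .prep import TrialPatternSet
from .rsa import RoiMask, SearchlightSpec, _sphere_columns, fisher_z
from .volume import StatMap

logger = logging.getLogger(__name__)

LOGIT_EPS = 1e-3

#: liblinear iteration cap for the epsilon-SVR solver; signal-bearing fits
#: converge well below this, and capping keeps pure-noise fits (which have
#: no stable solution to converge to) from dominating run time
MAX_SOLVER_ITER = 200


def logit_pr(pr) -> np.ndarray | float:
    """log(p / (1-p)) with p clamped to [1e-3, 1 - 1e-3].

    Corrected recognition can be 0 or negative (FA above HR), where the raw
    logit is undefined; clamping makes the transform total while preserving
    order on (eps, 1-eps).
    """
    p = np.clip(np.asarray(pr, dtype=float), LOGIT_EPS, 1.0 - LOGIT_EPS)
    out = np.log(p / (1.0 - p))
    return float(out) if np.isscalar(pr) or out.ndim == 0 else out


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy for one voxel set."""

    mean_r: float
    per_iteration_r: np.ndarray = field(repr=False)
    n_train: int
    n_test: int
    seed: int


def svr_cv(
    patterns: np.ndarray,
    scores: np.ndarray,
    train_frac: float = 0.8,
    iters: int = 100,
    seed: int = 0,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> DecodingResult:
    """Repeated random-split linear SVR with Pearson-correlation accuracy.

    Each iteration draws a fresh train/test partition without replacement
    (every trial in exactly one side), standardizes features with
    training-set statistics only, fits a linear epsilon-insensitive SVR,
    and correlates predictions with actual scores on the test set.
    Iterations whose test scores are constant have undefined r and are
    excluded from the mean.
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(scores, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ShapeError("patterns must be trials x voxels aligned with scores")
    n = X.shape[0]
    if n < 10:
        raise ParameterError("SVR cross-validation needs at least 10 trials")
    if X.shape[1] < 1:
        raise ParameterError("need at least 1 voxel")
    if not np.all(np.isfinite(y)):
        raise ParameterError("scores must be finite")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    rs = np.full(iters, np.nan)
    for it in range(iters):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if np.ptp(y[te]) == 0:
            logger.warning("svr_cv: iteration %d has constant test scores, skipped", it)
            continue
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        model = LinearSVR(C=c, epsilon=epsilon, max_iter=MAX_SOLVER_ITER,
                          random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit((X[tr] - mu) / sd, y[tr])
        pred = model.predict((X[te] - mu) / sd)
        if np.ptp(pred) == 0:
            rs[it] = 0.0
            continue
        rs[it] = stats.pearsonr(pred, y[te]).statistic
    ok = np.isfinite(rs)
    if not ok.any():
        raise ParameterError("no SVR iteration produced a defined correlation")
    return DecodingResult(
        mean_r=float(np.mean(rs[ok])),
        per_iteration_r=rs,
        n_train=n_train,
        n_test=n - n_train,
        seed=seed,
    )


def searchlight_svr(
    pattern_set: TrialPatternSet,
    scores: np.ndarray,
    spec: SearchlightSpec,
    train_frac: float = 0.8,
    iters: int = 100,
    seed: int = 0,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> StatMap:
    """Per-voxel SVR decoding accuracy map (mean test-set r per sphere).

    Spheres below ``spec.min_voxels`` in-mask voxels are undefined.  All
    spheres share the same iteration partitions (derived from ``seed``), so
    spatial differences reflect the voxels, not the splits.
    """
    y = np.asarray(scores, dtype=float)
    out = np.full(len(pattern_set.voxel_coords), np.nan)
    for c_idx, cols in _sphere_columns(pattern_set, spec):
        if len(cols) < spec.min_voxels:
            continue
        res = svr_cv(pattern_set.patterns[:, cols], y, train_frac, iters, seed, c, epsilon)
        out[c_idx] = res.mean_r
    return StatMap(pattern_set.grid_shape, pattern_set.mask, out, "svr_r")


def roi_svr(
    pattern_sets: dict[str, TrialPatternSet],
    scores: dict[str, np.ndarray],
    rois: list[RoiMask],
    train_frac: float = 0.8,
    iters: int = 100,
    seed: int = 0,
    q: float = 0.05,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Group SVR decoding within probabilistic ROIs, BH-FDR corrected.

    Per subject and ROI, :func:`svr_cv` yields a mean accuracy; the group
    statistic is a one-sample t of the per-subject mean r (Fisher-z) vs 0.
    """
    rows = []
    for roi in rois:
        per_subj = []
        n_vox = None
        for k, (sid, ps) in enumerate(pattern_sets.items()):
            roi_mask = roi.mask & ps.mask
            coords = np.argwhere(roi_mask)
            if len(coords) < 1:
                logger.warning("ROI %s: no in-mask voxels, skipped", roi.name)
                per_subj = []
                break
            cols = ps.columns_for(coords)
            n_vox = len(cols)
            res = svr_cv(ps.patterns[:, cols], np.asarray(scores[sid], float),
                         train_frac, iters, seed + k, c, epsilon)
            per_subj.append(res.mean_r)
        if len(per_subj) < 2:
            continue
        zs = [fisher_z(r) for r in per_subj]
        t_res = stats.ttest_1samp(zs, 0.0)
        rows.append(
            {
                "roi": roi.name,
                "n_voxels": n_vox,
                "n_subjects": len(per_subj),
                "mean_r": float(np.mean(per_subj)),
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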