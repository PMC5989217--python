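"""BOLD preprocessing and trial-pattern extraction.

Each run's voxel time courses are high-pass filtered (discrete-cosine basis
regression, default cutoff 128 s), linearly detrended, and z-scored over
time, in that order.  A trial's multivoxel pattern is the average of the
3rd and 4th volumes after stimulus onset (the onset volume counting as the
1st), i.e. BOLD measured 4-8 s post-stimulus at TR = 2 s.  No spatial
smoothing exists anywhere in this module, by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ShapeError

logger = logging.getLogger(__name__)


@dataclass
class BoldRun:
    """A 4-D (x, y, z, time) functional run with its brain mask."""

    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float = 2.0
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ShapeError(f"run data must be 4-D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ShapeError(
                f"mask shape {self.mask.shape} != spatial dims {self.data.shape[:3]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class TrialPatternSet:
    """Trials-by-voxels pattern matrix tied to a voxel grid.

    ``patterns[t, v]`` is trial t's value at the in-mask voxel
    ``voxel_coords[v]``; the column order is the C-order scan of the mask.
    """

    patterns: np.ndarray
    mask: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_coords: np.ndarray = field(default=None)
    trial_index: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid_shape):
            raise ShapeError("mask shape != grid_shape")
        if self.voxel_coords is None:
            self.voxel_coords = np.argwhere(self.mask)
        if self.patterns.shape[1] != len(self.voxel_coords):
            raise ShapeError(
                f"{self.patterns.shape[1]} pattern columns vs {len(self.voxel_coords)} in-mask voxels"
            )
        if self.trial_index is None:
            self.trial_index = np.arange(self.patterns.shape[0])

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    def columns_for(self, coords: np.ndarray) -> np.ndarray:
        """Column indices of the given voxel coordinate triples (must be in-mask)."""
        flat_all = np.ravel_multi_index(tuple(self.voxel_coords.T), self.grid_shape)
        lookup = {f: i for i, f in enumerate(flat_all)}
        flat = np.ravel_multi_index(tuple(np.asarray(coords).T), self.grid_shape)
        try:
            return np.array([lookup[f] for f in flat], dtype=int)
        except KeyError as exc:
            raise ShapeError("requested voxel outside the pattern mask") from exc


def dct_highpass_basis(n_volumes: int, tr_seconds: float, cutoff_s: float) -> np.ndarray:
    """Unit-norm DCT-II drift regressors with period above the cutoff.

    The number of retained low-frequency components is
    ``floor(2 * n_volumes * TR / cutoff)``; regressing them out removes
    fluctuations slower than the cutoff period.
    """
    k_max = int(np.floor(2.0 * n_volumes * tr_seconds / cutoff_s))
    t = np.arange(n_volumes)
    cols = [np.cos(np.pi * (t + 0.5) * k / n_volumes) for k in range(1, k_max + 1)]
    if not cols:
        return np.zeros((n_volumes, 0))
    basis = np.stack(cols, axis=1)
    return basis / np.linalg.norm(basis, axis=0)


def preprocess_run(run: BoldRun, highpass_cutoff_s: float = 128.0) -> BoldRun:
    """High-pass filter, linearly detrend, then z-score each in-mask voxel.

    The three steps run in that fixed order on every voxel time course.
    Voxels whose time course is constant after filtering (z-score undefined)
    are zeroed and counted in the log.
    """
    data = run.data
    if not np.all(np.isfinite(data)):
        raise ShapeError("run contains non-finite values")
    ts = data[run.mask].T.copy()  # (time, n_vox)
    scale = np.maximum(ts.std(axis=0), np.finfo(float).tiny)
    dct = dct_highpass_basis(run.n_volumes, run.tr_seconds, highpass_cutoff_s)
    # drift set = linear ramp + low-frequency cosines, orthonormalized; a
    # DCT-only set leaves projection ripple on polynomial drifts
    ramp = np.arange(run.n_volumes, dtype=float)
    ramp -= ramp.mean()
    basis = np.column_stack([ramp / np.linalg.norm(ramp)] + (
        [dct] if dct.shape[1] else []))
    basis, _ = np.linalg.qr(basis)
    ts -= basis @ (basis.T @ ts)
    ts = signal.detrend(ts, axis=0, type="linear")
    sd = ts.std(axis=0)
    # constant relative to the raw time course (e.g. pure drift input) counts
    # as undefined, not as amplified numerical residue
    flat = sd <= 1e-8 * scale
    sd_safe = np.where(flat, 1.0, sd)
    ts = (ts - ts.mean(axis=0)) / sd_safe
    ts[:, flat] = 0.0
    if flat.any():
        logger.warning("preprocess_run %s: %d constant voxels zeroed", run.run_id, int(flat.sum()))
    out = np.zeros_like(data)
    out[run.mask] = ts.T
    return BoldRun(out, run.mask, run.tr_seconds, run.run_id)


def extract_trial_patterns(run: BoldRun, trial_onsets: np.ndarray) -> TrialPatternSet:
    """Average the 3rd and 4th volumes after each onset into trial patterns.

    ``trial_onsets`` are 0-based volume indices of stimulus onset; the
    extracted pattern is ``(data[..., onset+2] + data[..., onset+3]) / 2``
    restricted to the mask.  Trials whose peak volumes fall past the end of
    the run are dropped with a warning; the surviving onsets' positions are
    recorded in ``trial_index``.
    """
    onsets = np.asarray(trial_onsets, dtype=int)
    ok = onsets + 3 < run.n_volumes
    if not ok.all():
        logger.warning("extract_trial_patterns: dropping %d trials past run end", int((~ok).sum()))
    kept = np.flatnonzero(ok)
    rows = [
        (run.data[..., o + 2][run.mask] + run.data[..., o + 3][run.mask]) / 2.0
        for o in onsets[kept]
    ]
    patterns = np.stack(rows, axis=0) if rows else np.zeros((0, int(run.mask.sum())))
    return TrialPatternSet(
        patterns=patterns,
        mask=run.mask,
        grid_shape=run.mask.shape,
        trial_index=kept,
    )
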