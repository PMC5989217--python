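"""Analysis and simulation configuration.

All tunables of the pipeline live in two dataclasses.  A single root seed
drives every stochastic stage: per-stage child seeds are derived with
:func:`stage_seed` from the root and a stage name, so reruns are reproducible
and stages are statistically independent of each other.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import yaml

from .errors import ParameterError

#: five-level recognition response scale, from strongest "old" judgment
#: (recollection) to strongest "new" judgment (high-confidence new)
RESPONSE_LEVELS = ("R", "HC_old", "LC_old", "LC_new", "HC_new")

#: responses counting as a correct "old" judgment (hit) for old items
HIT_RESPONSES = ("R", "HC_old", "LC_old")

#: responses counting as a correct "new" judgment (correct rejection)
CR_RESPONSES = ("LC_new", "HC_new")


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a deterministic child seed (< 2**31) for a named pipeline stage."""
    h = zlib.crc32(f"{int(root_seed)}:{stage}".encode())
    return int(h % (2**31 - 1))


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages.

    Defaults reflect the study design the pipeline re-implements: top-1000
    voxel map comparisons, 7-voxel-diameter searchlights, 10,000 split-half
    iterations, 80/20 SVR cross-validation over 100 iterations, 25%
    probabilistic-ROI threshold, and a 5-trial category inclusion rule.
    """

    n_top_voxels: int = 1000
    searchlight_diameter_vox: int = 7
    consistency_iters: int = 10_000
    svr_train_frac: float = 0.8
    svr_iters: int = 100
    roi_prob_threshold: float = 0.25
    min_trials_per_category: int = 5
    min_subjects_per_category: int = 5
    min_searchlight_voxels: int = 10
    highpass_cutoff_s: float = 128.0
    tr_seconds: float = 2.0
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.svr_train_frac < 1.0):
            raise ParameterError("svr_train_frac must lie in (0, 1)")
        if self.searchlight_diameter_vox < 1 or self.searchlight_diameter_vox % 2 == 0:
            raise ParameterError("searchlight_diameter_vox must be an odd count >= 1")
        for name in (
            "n_top_voxels",
            "consistency_iters",
            "svr_iters",
            "min_trials_per_category",
            "min_subjects_per_category",
            "min_searchlight_voxels",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not (0.0 < self.roi_prob_threshold <= 1.0):
            raise ParameterError("roi_prob_threshold must lie in (0, 1]")

    @property
    def searchlight_radius_vox(self) -> int:
        return (self.searchlight_diameter_vox - 1) // 2


@dataclass
class SimulationParams:
    """Ground-truth study conditions for the synthetic-data generator.

    The online study emulates a continuous-recognition crowd experiment:
    20% of a worker's stream are targets repeating 91-109 images after first
    presentation, the rest fillers, some repeating at lag 1-7 as vigilance
    probes.  Latent memorability ``theta`` is normal on the logit scale,
    calibrated so the scored Pr distribution has mean ~0.35 and SD ~0.12;
    false-recognition propensity ``phi`` is correlated with theta at
    ``theta_phi_rho`` (free parameter, default 0.3).

    The scanner study has 16 subjects responding on the 5-level scale to
    200 old + 200 new items; BOLD-like patterns live on a 24^3 grid with an
    ellipsoidal brain mask containing two disjoint 200-voxel spherical
    regions: region A couples pattern similarity to stimulus memorability,
    region B to the subject's own remembered/forgotten outcome.
    """

    # online study
    n_images: int = 400
    n_workers: int = 200
    n_inattentive: int = 0
    target_frac: float = 0.20
    target_lag_range: tuple[int, int] = (91, 109)
    filler_lag_range: tuple[int, int] = (1, 7)
    filler_repeat_frac: float = 0.25
    theta_mean: float = -0.05
    theta_sd: float = 0.35
    phi_mean: float = -1.95
    phi_sd: float = 0.62
    theta_phi_rho: float = 0.3
    worker_skill_sd: float = 0.4
    criterion_offset: float = 0.0
    # probability logits for filler events (short lags make repeats easy)
    filler_hit_logit: float = 2.2
    filler_fa_logit: float = -2.6

    # scanner study
    n_subjects: int = 16
    n_old: int = 200
    n_new: int = 200
    subject_noise_sd: float = 0.8
    subject_criterion_sd: float = 0.25

    # BOLD patterns
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    mask_semiaxes: tuple[float, float, float] = (9.0, 9.0, 9.0)
    region_voxels: int = 200
    signal_gain: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_images < 20:
            raise ParameterError("n_images must be >= 20")
        if not (0.0 < self.target_frac < 1.0):
            raise ParameterError("target_frac must lie in (0, 1)")
        if not (0.0 <= self.signal_gain <= 1.0):
            raise ParameterError("signal_gain must lie in [0, 1]")
        for lo, hi in (self.target_lag_range, self.filler_lag_range):
            if lo < 1 or hi < lo:
                raise ParameterError("lag ranges must satisfy 1 <= lo <= hi")


def load_config(path) -> tuple[AnalysisConfig, SimulationParams]:
    """Read a YAML file with optional ``analysis:`` and ``simulation:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ana = raw.get("analysis", {}) or {}
    sim = raw.get("simulation", {}) or {}
    for block in (ana, sim):
        for key, val in block.items():
            if isinstance(val, list):
                block[key] = tuple(val)
    return AnalysisConfig(**ana), SimulationParams(**sim)


def dump_config(analysis: AnalysisConfig, simulation: SimulationParams, path) -> None:
    doc = {
        "analysis": dataclasses.asdict(analysis),
        "simulation": dataclasses.asdict(simulation),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
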