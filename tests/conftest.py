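import numpy as np
import pandas as pd
import pytest

from memrsa import (
    SimulationParams,
    WorkerResponseLog,
    gen_bold_patterns,
    gen_online_study,
    gen_scanner_study,
    make_ground_truth,
    score_images,
)
from memrsa.scoring import apply_vigilance_filter


def small_params(**over) -> SimulationParams:
    """A scaled-down study: short lag windows, small grid, few subjects."""
    base = dict(
        n_images=80,
        n_workers=40,
        n_old=40,
        n_new=40,
        n_subjects=4,
        grid_shape=(14, 14, 14),
        mask_semiaxes=(5.0, 5.0, 5.0),
        region_voxels=40,
        target_lag_range=(15, 25),
        filler_lag_range=(1, 5),
    )
    base.update(over)
    return SimulationParams(**base)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    sim = small_params()
    gt = make_ground_truth(sim, seed=11)
    logs = gen_online_study(sim, gt, seed=12)
    kept, report = apply_vigilance_filter(logs)
    memtable = score_images(kept)
    stim, tables = gen_scanner_study(sim, gt, seed=13)
    patterns = {
        sid: gen_bold_patterns(tt, gt, sim, seed=14 + k)
        for k, (sid, tt) in enumerate(tables.items())
    }
    return {
        "sim": sim,
        "gt": gt,
        "logs": logs,
        "kept": kept,
        "memtable": memtable,
        "stimulus": stim,
        "tables": tables,
        "patterns": patterns,
    }


def make_log(worker_id, rows):
    """Build a WorkerResponseLog from (image_id, is_repeat, pressed, role) rows."""
    df = pd.DataFrame(rows, columns=["image_id", "is_repeat", "pressed", "role"])
    df.insert(0, "position", np.arange(len(df)))
    df["lag"] = np.nan
    return WorkerResponseLog(worker_id=worker_id, events=df)
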