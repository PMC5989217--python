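"""File round-trips, configuration, seed derivation, pipeline orchestration."""

import json

import numpy as np
import pandas as pd
import pytest

from memrsa import AnalysisConfig, SimulationParams, StatMap
from memrsa import io as mio
from memrsa.config import dump_config, load_config, stage_seed
from memrsa.errors import (
    FormatError,
    IntegrityError,
    ParameterError,
    PipelineStageError,
    ShapeError,
)
from memrsa.pipeline import run_pipeline

from conftest import small_params


class TestConfig:
    def test_defaults_valid(self):
        cfg = AnalysisConfig()
        assert cfg.n_top_voxels == 1000
        assert cfg.searchlight_radius_vox == 3
        assert cfg.consistency_iters == 10_000
        assert cfg.svr_train_frac == 0.8 and cfg.svr_iters == 100
        assert cfg.roi_prob_threshold == 0.25

    @pytest.mark.parametrize(
        "bad",
        [dict(svr_train_frac=1.0), dict(searchlight_diameter_vox=4),
         dict(n_top_voxels=0), dict(roi_prob_threshold=0.0)],
    )
    def test_invalid_rejected(self, bad):
        with pytest.raises(ParameterError):
            AnalysisConfig(**bad)

    def test_simulation_invariants(self):
        with pytest.raises(ParameterError):
            SimulationParams(n_images=10)
        with pytest.raises(ParameterError):
            SimulationParams(signal_gain=1.2)
        with pytest.raises(ParameterError):
            SimulationParams(target_lag_range=(5, 2))

    def test_yaml_round_trip(self, tmp_path):
        ana = AnalysisConfig(n_top_voxels=77, rng_seed=9)
        sim = small_params(n_workers=12)
        dump_config(ana, sim, tmp_path / "cfg.yaml")
        ana2, sim2 = load_config(tmp_path / "cfg.yaml")
        assert ana2 == ana and sim2 == sim

    def test_stage_seeds_deterministic_and_bounded(self):
        s1 = stage_seed(42, "rsa")
        assert s1 == stage_seed(42, "rsa")
        assert s1 != stage_seed(42, "svr")
        assert 0 <= s1 < 2**31


class TestTabularRoundTrips:
    def test_response_log_round_trip(self, small_study, tmp_path):
        logs = small_study["logs"][:3]
        mio.write_response_log(logs, tmp_path / "log.tsv")
        back = mio.read_response_log(tmp_path / "log.tsv")
        assert [b.worker_id for b in back] == [l.worker_id for l in logs]
        for a, b in zip(logs, back):
            assert np.array_equal(a.events["pressed"], b.events["pressed"])
            assert list(a.events["image_id"]) == list(b.events["image_id"])

    def test_missing_column_is_format_error(self, tmp_path):
        pd.DataFrame({"worker_id": ["w"], "position": [0]}).to_csv(
            tmp_path / "bad.tsv", sep="\t", index=False
        )
        with pytest.raises(FormatError):
            mio.read_response_log(tmp_path / "bad.tsv")

    def test_duplicate_position_is_integrity_error(self, tmp_path):
        df = pd.DataFrame(
            {
                "worker_id": ["w", "w"],
                "position": [0, 0],
                "image_id": ["a", "b"],
                "is_repeat": [0, 0],
                "pressed": [0, 1],
            }
        )
        df.to_csv(tmp_path / "dup.tsv", sep="\t", index=False)
        with pytest.raises(IntegrityError):
            mio.read_response_log(tmp_path / "dup.tsv")

    def test_trial_table_round_trip(self, small_study, tmp_path):
        mio.write_trial_tables(small_study["tables"], tmp_path / "tt.tsv")
        back = mio.read_trial_tables(tmp_path / "tt.tsv")
        assert set(back) == set(small_study["tables"])
        for sid in back:
            pd.testing.assert_frame_equal(back[sid], small_study["tables"][sid])

    def test_memorability_table_round_trip(self, small_study, tmp_path):
        mio.write_memorability_table(small_study["memtable"], tmp_path / "mem.csv")
        back = mio.read_memorability_table(tmp_path / "mem.csv")
        pd.testing.assert_frame_equal(back, small_study["memtable"])

    def test_patterns_round_trip(self, small_study, tmp_path):
        ps = next(iter(small_study["patterns"].values()))
        mio.write_patterns(ps, tmp_path / "pat.tsv")
        back = mio.read_patterns(tmp_path / "pat.tsv", ps.grid_shape)
        assert np.array_equal(back.mask, ps.mask)
        assert np.allclose(back.patterns, ps.patterns, atol=1e-4)


class TestVolumes:
    def test_mask_grid_shape(self, tmp_path):
        mask = np.zeros((24, 24, 24))
        mask[8:16, 8:16, 8:16] = 1.0
        mio.write_volume(mask, tmp_path / "mask.nii")
        m, _ = mio.read_mask(tmp_path / "mask.nii")
        assert m.shape == (24, 24, 24)
        assert m.sum() == 8**3

    def test_statmap_round_trip_under_1e6(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = rng.random((6, 6, 6)) > 0.4
        sm = StatMap((6, 6, 6), mask, rng.normal(size=int(mask.sum())), "group_t")
        mio.write_map(sm, tmp_path / "map.nii")
        back = mio.read_map(tmp_path / "map.nii", value_kind="group_t")
        assert np.abs(back.values - sm.values).max() < 1e-6

    def test_4d_where_mask_expected_is_shape_error(self, tmp_path):
        mio.write_volume(np.zeros((4, 4, 4, 3)), tmp_path / "vol4.nii")
        with pytest.raises(ShapeError):
            mio.read_mask(tmp_path / "vol4.nii")

    def test_statmap_values_mask_agreement_enforced(self):
        with pytest.raises(ShapeError):
            StatMap((2, 2, 2), np.ones((2, 2, 2), bool), np.zeros(5))


@pytest.fixture(scope="module")
def pipe(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    ana = AnalysisConfig(
        consistency_iters=300, svr_iters=5, rng_seed=5, n_top_voxels=100,
        min_trials_per_category=3, min_subjects_per_category=3,
    )
    sim = small_params(n_subjects=4)
    res = run_pipeline(ana, sim, out)
    return res, out


class TestPipeline:
    def test_all_outputs_present(self, pipe):
        _, out = pipe
        expected = [
            "response_log.tsv", "trial_tables.tsv", "ground_truth.csv",
            "memorability_table.csv", "consistency.csv", "vigilance_report.csv",
            "anova.csv", "category_means_old.csv", "category_means_new.csv",
            "pairwise_old.csv", "pairwise_new.csv",
            "group_t_memorability.nii", "group_t_memory.nii",
            "group_t_hits.nii", "group_t_correct_rejections.nii",
            "overlap_sweep.csv", "roi_rsa.csv", "roi_svr.csv", "run_log.json",
        ]
        for name in expected:
            assert (out / name).exists(), name

    def test_run_log_records_seeds_and_versions(self, pipe):
        _, out = pipe
        log = json.loads((out / "run_log.json").read_text())
        assert log["analysis_config"]["rng_seed"] == 5
        assert set(log["seeds"]) >= {"ground_truth", "online", "scanner", "bold"}
        assert "memrsa" in log["versions"]

    def test_top_n_capped_when_exceeding_mask(self, pipe):
        res, _ = pipe
        # n_top_voxels=100 > region size 40: recovery used the capped N
        assert res.recovery["memorability_region_a"]["n_top"] <= 100

    def test_rerun_reproduces_tables(self, pipe, tmp_path):
        res, out = pipe
        ana = AnalysisConfig(
            consistency_iters=300, svr_iters=5, rng_seed=5, n_top_voxels=100,
            min_trials_per_category=3, min_subjects_per_category=3,
        )
        sim = small_params(n_subjects=4)
        res2 = run_pipeline(ana, sim, tmp_path / "again")
        pd.testing.assert_frame_equal(res.memtable, res2.memtable)
        a = (out / "memorability_table.csv").read_text()
        b = (tmp_path / "again" / "memorability_table.csv").read_text()
        assert a == b

    def test_stage_failure_names_stage(self, tmp_path):
        ana = AnalysisConfig(rng_seed=1)
        sim = small_params(n_subjects=1)  # scanner stage requires >= 2
        with pytest.raises(PipelineStageError, match="simulate"):
            run_pipeline(ana, sim, tmp_path / "fail")


class TestCli:
    def test_score_and_consistency_commands(self, small_study, tmp_path):
        from click.testing import CliRunner

        from memrsa.cli import main

        mio.write_response_log(small_study["logs"], tmp_path / "log.tsv")
        runner = CliRunner()
        r1 = runner.invoke(main, ["score", "--log", str(tmp_path / "log.tsv"),
                                  "--out", str(tmp_path / "mem.csv")])
        assert r1.exit_code == 0, r1.output
        table = mio.read_memorability_table(tmp_path / "mem.csv")
        assert len(table) == small_study["sim"].n_images
        r2 = runner.invoke(main, ["consistency", "--log", str(tmp_path / "log.tsv"),
                                  "--metric", "Pr", "--iters", "200",
                                  "--out", str(tmp_path / "cons.csv")])
        assert r2.exit_code == 0, r2.output
        assert (tmp_path / "cons.csv").exists()
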