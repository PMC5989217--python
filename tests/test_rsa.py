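"""Model/data RSMs, searchlight maps, group statistics, overlap, ROI RSA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memrsa import (
    RSM,
    RoiMask,
    SearchlightSpec,
    StatMap,
    build_memorability_rsm,
    build_memory_rsm,
    compare_rsms,
    data_rsm,
    group_map,
    overlap,
    overlap_sweep,
    roi_rsa,
    searchlight_rsa,
    searchlight_rsa_multi,
    sphere_offsets,
    top_n_mask,
)
from memrsa.errors import ParameterError, ShapeError
from memrsa.prep import TrialPatternSet
from memrsa.rsa import condition_rsa, condition_trial_indices


class TestModelRsms:
    def test_memorability_pairwise_means(self):
        rsm = build_memorability_rsm([0.2, 0.4, 0.6])
        v = rsm.values
        assert v[1, 0] == pytest.approx(0.3)
        assert v[2, 0] == pytest.approx(0.4)
        assert v[2, 1] == pytest.approx(0.5)
        assert np.array_equal(v, v.T)

    def test_memorability_entries_bounded_by_pr_range(self):
        pr = np.random.default_rng(0).uniform(0.1, 0.7, size=20)
        v = build_memorability_rsm(pr).values
        tri = v[np.tril_indices(20, k=-1)]
        assert tri.min() >= pr.min() and tri.max() <= pr.max()

    def test_memorability_missing_pr_names_image(self):
        with pytest.raises(ParameterError, match="img7"):
            build_memorability_rsm([0.2, np.nan], image_ids=np.array(["img3", "img7"]))

    def test_memory_coding_rule(self):
        v = build_memory_rsm([1.0, 0.0, 1.0]).values
        assert v[1, 0] == 0.5 and v[2, 0] == 1.0 and v[2, 1] == 0.5

    def test_memory_two_flags(self):
        v = build_memory_rsm([1.0, 0.0]).values
        assert v[1, 0] == 0.5

    def test_memory_rejects_new_history(self):
        with pytest.raises(ParameterError):
            build_memory_rsm([1.0, 0.0], history=["old", "new"])

    def test_degenerate_model_propagates_undefined(self):
        # all-remembered memory RSM has a constant triangle: comparisons are NaN
        model = build_memory_rsm([1.0, 1.0, 1.0])
        data = data_rsm(np.random.default_rng(1).normal(size=(3, 5)))
        r, z = compare_rsms(model, data)
        assert np.isnan(r) and np.isnan(z)


class TestDataRsm:
    def test_duplicate_trials_correlate_one(self):
        x = np.random.default_rng(2).normal(size=(1, 6))
        mat = np.vstack([x, x, np.random.default_rng(3).normal(size=(1, 6))])
        v = data_rsm(mat).values
        assert v[1, 0] == pytest.approx(1.0)

    def test_negated_trial_correlates_minus_one(self):
        x = np.random.default_rng(4).normal(size=(1, 6))
        mat = np.vstack([x, -x, np.random.default_rng(5).normal(size=(1, 6))])
        v = data_rsm(mat).values
        assert v[1, 0] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        """Hand-written covariance/sigma Pearson on a 3x4 matrix."""
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(3, 4))
        v = data_rsm(mat).values
        for i in range(3):
            for j in range(i):
                xi, xj = mat[i], mat[j]
                cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
                r = cov / (xi.std() * xj.std())
                assert v[i, j] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_trial_is_nan(self):
        mat = np.vstack([np.zeros(5), np.random.default_rng(7).normal(size=(2, 5))])
        v = data_rsm(mat).values
        assert np.isnan(v[1, 0]) and np.isnan(v[2, 0]) and np.isfinite(v[2, 1])

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ParameterError):
            data_rsm(np.zeros((3, 1)))
        with pytest.raises(ParameterError):
            data_rsm(np.random.default_rng(0).normal(size=(2, 4)))


class TestCompareRsms:
    def test_monotone_transform_of_model_gives_rho_one(self):
        rng = np.random.default_rng(8)
        pr = rng.uniform(0.1, 0.7, 8)
        model = build_memorability_rsm(pr)
        data = RSM(np.tanh(model.values * 3.0), kind="data")
        r, z = compare_rsms(model, data)
        assert r == pytest.approx(1.0)
        assert np.isfinite(z)  # capped, not +inf

    def test_atanh_closed_form(self):
        # construct RSM pair with a known intermediate rho, then verify z
        rng = np.random.default_rng(9)
        a = _random_rsm(rng, 10)
        b = _random_rsm(rng, 10)
        r, z = compare_rsms(a, b)
        assert z == pytest.approx(np.arctanh(r), abs=1e-12)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_matches_brute_force_spearman(self):
        """Rank-transform written out by hand on 5x5 RSMs, then Pearson."""
        rng = np.random.default_rng(10)
        a = _random_rsm(rng, 5)
        b = _random_rsm(rng, 5)
        x = a.values[np.tril_indices(5, k=-1)]
        y = b.values[np.tril_indices(5, k=-1)]

        def rank(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            r = [0.0] * len(v)
            for pos, i in enumerate(order):
                r[i] = pos + 1.0
            return np.array(r)

        rx, ry = rank(x), rank(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        r, _ = compare_rsms(a, b)
        assert r == pytest.approx(rho_oracle, abs=1e-10)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            compare_rsms(build_memorability_rsm([0.1, 0.2]),
                         data_rsm(np.random.default_rng(0).normal(size=(3, 4))))


def _random_rsm(rng, n):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    return RSM(m, kind="data")


class TestSphereGeometry:
    def test_radius_three_ball_has_123_lattice_points(self):
        offs = sphere_offsets(3)
        assert len(offs) == 123
        # oracle: enumerate the cube and count
        count = sum(
            1
            for dx in range(-3, 4)
            for dy in range(-3, 4)
            for dz in range(-3, 4)
            if dx * dx + dy * dy + dz * dz <= 9
        )
        assert count == 123

    def test_radius_zero_searchlight_everywhere_undefined(self):
        rng = np.random.default_rng(11)
        mask = np.ones((4, 4, 4), bool)
        ps = TrialPatternSet(rng.normal(size=(6, 64)), mask, (4, 4, 4))
        model = build_memorability_rsm(rng.uniform(0.1, 0.9, 6))
        m = searchlight_rsa(ps, model, SearchlightSpec(radius_vox=0, min_voxels=1))
        assert np.isnan(m.values).all()

    def test_empty_mask_rejected(self):
        ps_mask = np.zeros((3, 3, 3), bool)
        with pytest.raises(ParameterError):
            searchlight_rsa(
                TrialPatternSet(np.zeros((5, 0)), ps_mask, (3, 3, 3)),
                build_memorability_rsm([0.1, 0.2, 0.3, 0.4, 0.5]),
                SearchlightSpec(1, 1),
            )


class TestGroupMap:
    def _maps(self, arrays, mask):
        return [StatMap(mask.shape, mask, a, "fisher_z") for a in arrays]

    def test_zero_variance_voxel_undefined(self):
        mask = np.ones((2, 2, 1), bool)
        maps = self._maps([np.array([1.0, 0.5, 0.2, 0.1])] * 4, mask)
        t = group_map(maps)
        assert np.isnan(t.values).all()  # identical maps -> sd 0 everywhere

    def test_undefined_in_most_subjects_drops_voxel(self):
        mask = np.ones((2, 2, 1), bool)
        a = np.array([1.0, np.nan, 0.2, 0.3])
        b = np.array([0.5, np.nan, 0.1, 0.4])
        c = np.array([0.8, 0.2, np.nan, 0.5])
        t = group_map(self._maps([a, b, c], mask))
        assert np.isnan(t.values[1])  # defined in < 2 subjects
        assert np.isfinite(t.values[0])

    def test_matches_scipy_one_sample_t(self):
        rng = np.random.default_rng(12)
        mask = np.ones((3, 2, 1), bool)
        arrays = [rng.normal(size=6) + 0.3 for _ in range(8)]
        t = group_map(self._maps(arrays, mask))
        oracle = stats.ttest_1samp(np.stack(arrays), 0.0).statistic
        assert np.allclose(t.values, oracle, atol=1e-12)

    def test_needs_two_subjects(self):
        mask = np.ones((2, 1, 1), bool)
        with pytest.raises(ParameterError):
            group_map(self._maps([np.zeros(2)], mask))


class TestTopNOverlap:
    def test_shared_nine_of_thousand_is_0p9_percent(self):
        mask = np.ones((13, 13, 12), bool)  # 2028 voxels
        vals_a = np.zeros(2028)
        vals_b = np.zeros(2028)
        vals_a[:1000] = 2.0  # top-1000 of A = voxels 0..999
        vals_b[991:1991] = 2.0  # top-1000 of B = voxels 991..1990
        a = StatMap((13, 13, 12), mask, vals_a, "group_t")
        b = StatMap((13, 13, 12), mask, vals_b, "group_t")
        res = overlap(top_n_mask(a, 1000), top_n_mask(b, 1000))
        assert res.count == 9
        assert res.percent == pytest.approx(0.9)

    def test_identical_maps_fully_overlap_at_every_n(self):
        rng = np.random.default_rng(13)
        mask = np.ones((5, 5, 4), bool)
        m = StatMap((5, 5, 4), mask, rng.normal(size=100), "group_t")
        sweep = overlap_sweep(m, m, [5, 20, 50])
        assert (sweep["percent"] == 100.0).all()

    def test_ties_broken_by_voxel_index(self):
        mask = np.ones((2, 2, 2), bool)
        m = StatMap((2, 2, 2), mask, np.ones(8), "group_t")
        top = top_n_mask(m, 3)
        assert list(np.flatnonzero(top.ravel())) == [0, 1, 2]

    def test_n_capped_at_defined_voxels(self):
        mask = np.ones((2, 2, 2), bool)
        vals = np.full(8, np.nan)
        vals[:4] = [3.0, 2.0, 1.0, 0.5]
        m = StatMap((2, 2, 2), mask, vals, "group_t")
        assert top_n_mask(m, 100).sum() == 4


class TestConditionRsa:
    def _table(self, n_hits, n_crs, n_miss=3):
        rows = []
        for i in range(n_hits):
            rows.append((f"h{i}", "old", "R"))
        for i in range(n_miss):
            rows.append((f"m{i}", "old", "HC_new"))
        for i in range(n_crs):
            rows.append((f"c{i}", "new", "HC_new"))
        df = pd.DataFrame(rows, columns=["image_id", "history", "response"])
        df.insert(0, "trial", np.arange(len(df)))
        df.insert(0, "subject_id", "s0")
        return df

    def test_min_rule_balances_counts(self):
        idx = condition_trial_indices(self._table(10, 17), seed=0, min_trials=7)
        assert len(idx["hits"]) == len(idx["correct_rejections"]) == 10

    def test_equal_counts_seed_independent(self):
        t = self._table(12, 12)
        a = condition_trial_indices(t, seed=1, min_trials=5)
        b = condition_trial_indices(t, seed=99, min_trials=5)
        assert np.array_equal(a["hits"], b["hits"])
        assert np.array_equal(a["correct_rejections"], b["correct_rejections"])

    def test_insufficient_trials_raises(self):
        from memrsa.errors import InsufficientTrialsError

        with pytest.raises(InsufficientTrialsError):
            condition_trial_indices(self._table(4, 30), seed=0, min_trials=10)


@pytest.fixture(scope="module")
def planted_subject(small_study):
    sid, tt = next(iter(small_study["tables"].items()))
    return tt, small_study["patterns"][sid], small_study["gt"], small_study["memtable"]


class TestPlantedSearchlight:
    def test_region_a_z_exceeds_outside(self, planted_subject):
        """Searchlight z inside the memorability-coding region beats outside."""
        tt, ps, gt, mem = planted_subject
        pr = mem["Pr"].reindex(tt["image_id"]).to_numpy()
        model = build_memorability_rsm(pr)
        zmap = searchlight_rsa(ps, model, SearchlightSpec(2, 5))
        region = np.zeros(gt.mask.shape, bool)
        region[tuple(gt.region_a_voxels.T)] = True
        in_region = region[gt.mask]
        z_in = zmap.values[in_region & np.isfinite(zmap.values)]
        z_out = zmap.values[~in_region & np.isfinite(zmap.values)]
        t = stats.ttest_ind(z_in, z_out, equal_var=False, alternative="greater")
        assert t.pvalue < 0.01

    def test_multi_model_matches_single_model(self, planted_subject):
        tt, ps, gt, mem = planted_subject
        pr = mem["Pr"].reindex(tt["image_id"]).to_numpy()
        model = build_memorability_rsm(pr)
        spec = SearchlightSpec(2, 5)
        single = searchlight_rsa(ps, model, spec)
        multi = searchlight_rsa_multi(ps, {"m": (model, None)}, spec)["m"]
        assert np.array_equal(single.values, multi.values, equal_nan=True)

    def test_condition_rsa_runs_on_balanced_trials(self, planted_subject):
        tt, ps, gt, mem = planted_subject
        pr = mem["Pr"].reindex(tt["image_id"]).to_numpy()
        m = condition_rsa(tt, ps, pr, "hits", SearchlightSpec(2, 5), seed=3)
        assert m.value_kind == "fisher_z"
        assert np.isfinite(m.values).any()


class TestRoiRsa:
    def test_planted_region_significant_noise_not(self, small_study):
        gt = small_study["gt"]
        mem = small_study["memtable"]
        prob_a = np.zeros(gt.mask.shape)
        prob_a[tuple(gt.region_a_voxels.T)] = 1.0
        off = np.argwhere(gt.mask)[-len(gt.region_a_voxels):]
        prob_n = np.zeros(gt.mask.shape)
        prob_n[tuple(off.T)] = 1.0
        rois = [RoiMask("region_a", prob_a), RoiMask("noise", prob_n)]
        models = {}
        for sid, tt in small_study["tables"].items():
            models[sid] = build_memorability_rsm(
                mem["Pr"].reindex(tt["image_id"]).to_numpy()
            )
        df = roi_rsa(small_study["patterns"], models, rois)
        a = df.set_index("roi").loc["region_a"]
        n = df.set_index("roi").loc["noise"]
        # directional: planted positive coupling, so halve the two-sided p
        assert a["mean_r"] > 0 and a["t"] > 0 and a["p"] / 2 < 0.05
        assert abs(n["mean_r"]) < abs(a["mean_r"])

    def test_tiny_roi_skipped(self, small_study):
        gt = small_study["gt"]
        prob = np.zeros(gt.mask.shape)
        prob[tuple(np.argwhere(gt.mask)[:1].T)] = 1.0
        df = roi_rsa(small_study["patterns"],
                     build_memorability_rsm(
                         small_study["memtable"]["Pr"].reindex(
                             next(iter(small_study["tables"].values()))["image_id"]
                         ).to_numpy()),
                     [RoiMask("tiny", prob)])
        assert len(df) == 0


def test_rsm_symmetry_enforced():
    with pytest.raises(ShapeError):
        RSM(np.array([[1.0, 0.2], [0.3, 1.0]]))
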