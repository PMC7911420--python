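"""Seed-correlation maps, TFCE, sign-flip FWE inference, rcFC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thalfc.prep import TimeCourse
from thalfc.sca import (ScaMap, compare_rcfc, fisher_z, group_mean_effect,
                        mean_fc_over_mask, rcfc, seed_correlation_map,
                        tfce_enhance)


class TestSeedCorrelationMap:
    def test_identical_and_negated_series(self, small_scan):
        seed = TimeCourse(small_scan.data[1, 1, 1].copy(), small_scan.tr_s)
        data = small_scan.data.copy()
        data[2, 2, 2] = -seed.samples
        m = seed_correlation_map(small_scan.with_data(data), seed)
        assert m.values[1, 1, 1] == pytest.approx(1.0, abs=1e-10)
        assert m.values[2, 2, 2] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_brute_force_pearson(self, small_scan, rng):
        seed = TimeCourse(rng.normal(size=small_scan.n_volumes), small_scan.tr_s)
        m = seed_correlation_map(small_scan, seed)
        flat_idx = rng.choice(np.prod(small_scan.shape3d), 50, replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, small_scan.shape3d)
            expected = np.corrcoef(small_scan.data[idx], seed.samples)[0, 1]
            assert m.values[idx] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_voxel_flagged(self, small_scan):
        data = small_scan.data.copy()
        data[0, 0, 0] = 5.0
        seed = TimeCourse(data[1, 1, 1].copy(), small_scan.tr_s)
        m = seed_correlation_map(small_scan.with_data(data), seed)
        assert m.values[0, 0, 0] == 0.0
        assert m.zero_variance_mask[0, 0, 0]

    def test_length_mismatch_rejected(self, small_scan):
        with pytest.raises(ValueError, match="length"):
            seed_correlation_map(small_scan, TimeCourse(np.zeros(7), 3.01))


class TestFisherZ:
    def test_closed_form_values(self):
        aff = np.eye(4)
        m = ScaMap(np.array([[[0.0, 0.5]]]), aff)
        z = fisher_z(m)
        assert z.values[0, 0, 0] == 0.0
        assert z.values[0, 0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert z.fisher

    def test_monotone(self, rng):
        r = np.sort(rng.uniform(-0.99, 0.99, 50)).reshape(1, 1, -1)
        z = fisher_z(ScaMap(r, np.eye(4))).values.ravel()
        assert np.all(np.diff(z) > 0)

    def test_r_of_one_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(ScaMap(np.array([[[1.0]]]), np.eye(4)))
        assert np.isfinite(z.values).all()


class TestTfce:
    def test_zero_volume(self):
        assert np.array_equal(tfce_enhance(np.zeros((4, 4, 4))),
                              np.zeros((4, 4, 4)))

    def test_single_voxel_discrete_sum_oracle(self):
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = 1.0
        out = tfce_enhance(vol, E=0.5, H=2.0, dh=0.1)
        expected = sum((1 ** 0.5) * (h ** 2) * 0.1
                       for h in [0.1 * i for i in range(1, 11)])
        assert out[2, 2, 2] == pytest.approx(expected, rel=1e-10)
        assert out.sum() == pytest.approx(expected, rel=1e-10)

    def test_two_disjoint_blobs_local(self, rng):
        a = np.zeros((12, 6, 6))
        b = np.zeros((12, 6, 6))
        a[1:3, 1:3, 1:3] = rng.uniform(0.5, 1.0, (2, 2, 2))
        b[9:11, 3:5, 3:5] = rng.uniform(0.5, 1.0, (2, 2, 2))
        dh = 0.01
        joint = tfce_enhance(a + b, dh=dh)
        separate = tfce_enhance(a, dh=dh) + tfce_enhance(b, dh=dh)
        assert np.allclose(joint, separate, atol=1e-10)

    def test_negative_values_antisymmetric(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        assert np.allclose(tfce_enhance(-vol, dh=0.05),
                           -tfce_enhance(vol, dh=0.05), atol=1e-10)

    def test_monotone_in_stat(self, rng):
        vol = np.abs(rng.normal(size=(6, 6, 6)))
        bigger = vol + 0.3
        dh = 0.02
        assert np.all(tfce_enhance(bigger, dh=dh) >= tfce_enhance(vol, dh=dh) - 1e-12)

    def test_nonfinite_rejected(self):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            tfce_enhance(vol)


class TestGroupMeanEffect:
    def test_identical_positive_maps_min_fwe_is_one_over_32(self, rng):
        base = rng.uniform(0.2, 0.8, size=(5, 5, 4))
        maps = np.stack([base] * 5)
        gs = group_mean_effect(maps, n_perm=5000, seed=0)
        assert gs.exhaustive and gs.n_permutations == 32
        assert np.allclose(gs.fwe_p, 1.0 / 32)

    def test_subject_order_exchangeable(self, rng):
        maps = rng.normal(size=(5, 4, 4, 3)) + 0.5
        gs1 = group_mean_effect(maps, n_perm=100, seed=1)
        gs2 = group_mean_effect(maps[::-1].copy(), n_perm=100, seed=1)
        assert np.allclose(gs1.tstat, gs2.tstat)
        assert np.allclose(gs1.fwe_p, gs2.fwe_p)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            group_mean_effect(rng.normal(size=(1, 3, 3, 3)))

    def test_spatially_constant_maps_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            group_mean_effect(np.ones((4, 3, 3, 3)), n_perm=16)

    def test_fwe_calibration_under_sign_symmetric_null(self, rng):
        """Under a sign-symmetric null the familywise error stays near or
        below alpha (exhaustive 32-pattern null, 200 replicate datasets)."""
        alpha = 0.05
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            maps = rng.normal(size=(5, 5, 5, 3))
            gs = group_mean_effect(maps, n_perm=64, seed=0)
            hits += gs.fwe_p.min() < alpha
        rate = hits / n_rep
        mc_se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rate <= alpha + 3 * mc_se

    def test_covariate_effect_removed(self, rng):
        # adding a pure (centred-)covariate effect leaves the result unchanged
        cov = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        maps = rng.normal(0.3, 1.0, size=(5, 4, 4, 3))
        pattern = rng.normal(size=(4, 4, 3))
        cc = (cov - cov.mean())[:, 0]
        maps2 = maps + cc[:, None, None, None] * pattern[None]
        gs1 = group_mean_effect(maps, covariates=cov, n_perm=64, seed=0)
        gs2 = group_mean_effect(maps2, covariates=cov, n_perm=64, seed=0)
        assert np.allclose(gs1.tstat, gs2.tstat, atol=1e-8)
        assert np.allclose(gs1.fwe_p, gs2.fwe_p)


class TestRcfc:
    def test_mean_fc_excludes_zero_voxels(self):
        vals = np.array([[[0.0, 0.3, 0.5]]])
        mask = np.ones_like(vals, dtype=bool)
        assert mean_fc_over_mask(vals, mask) == pytest.approx(0.4)

    def test_mean_fc_uniform_and_mixture(self):
        mask = np.ones((1, 1, 4), dtype=bool)
        assert mean_fc_over_mask(np.full((1, 1, 4), 0.4), mask) == pytest.approx(0.4)
        half = np.array([[[0.2, 0.2, 0.6, 0.6]]])
        assert mean_fc_over_mask(half, mask) == pytest.approx(0.4)

    def test_all_zero_masked_values_error(self):
        with pytest.raises(ValueError, match="undefined"):
            mean_fc_over_mask(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool))

    def test_identities(self):
        assert rcfc(0.5, 0.5) == 0.0
        assert rcfc(0.4, 0.5) == pytest.approx(-0.2)
        # scale invariance
        for c in (0.1, 2.0, 37.0):
            assert rcfc(c * 0.4, c * 0.5) == pytest.approx(rcfc(0.4, 0.5))

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            rcfc(0.3, 0.0)


class TestCompareRcfc:
    @staticmethod
    def _rm_anova_oracle(values):
        """Closed-form two-way (subject-blocked) decomposition."""
        grand = values.mean()
        n_s, n_p = values.shape
        ss_phase = n_s * np.sum((values.mean(axis=0) - grand) ** 2)
        ss_subj = n_p * np.sum((values.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((values - grand) ** 2) - ss_phase - ss_subj
        F = (ss_phase / (n_p - 1)) / (ss_err / ((n_s - 1) * (n_p - 1)))
        p = stats.f.sf(F, n_p - 1, (n_s - 1) * (n_p - 1))
        return F, p

    def test_identical_phases_give_null_result(self):
        df = pd.DataFrame({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3],
                           "c": [0.1, 0.2, 0.3]})
        rep = compare_rcfc(df)
        assert rep["anova_F"] == 0.0 and rep["anova_p"] == 1.0

    def test_two_phases_match_paired_t_oracle(self, rng):
        a = rng.normal(0.5, 0.1, 8)
        b = rng.normal(0.3, 0.1, 8)
        rep = compare_rcfc(pd.DataFrame({"a": a, "b": b}))
        t, p = stats.ttest_rel(a, b)
        row = rep["pairwise"].iloc[0]
        assert row["t"] == pytest.approx(t)
        assert row["p_raw"] == pytest.approx(p)
        assert row["p_bonferroni"] == pytest.approx(min(1.0, p))  # factor 1
        # with two phases, F = t^2 and the p-values agree
        assert rep["anova_F"] == pytest.approx(t ** 2, rel=1e-6)

    def test_matches_rm_anova_closed_form(self, rng):
        values = rng.normal(0.4, 0.1, size=(6, 4))
        rep = compare_rcfc(pd.DataFrame(values, columns=list("abcd")))
        F, p = self._rm_anova_oracle(values)
        assert rep["anova_F"] == pytest.approx(F, rel=1e-8)
        assert rep["anova_p"] == pytest.approx(p, rel=1e-6)

    def test_bonferroni_multiplication(self, rng):
        values = rng.normal(0.4, 0.05, size=(5, 3))
        rep = compare_rcfc(pd.DataFrame(values, columns=list("abc")))
        assert rep["bonferroni_factor"] == 3
        for _, row in rep["pairwise"].iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_raw"] * 3))

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"a": [0.1, np.nan], "b": [0.2, 0.3]})
        with pytest.raises(ValueError, match="balanced"):
            compare_rcfc(df)
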