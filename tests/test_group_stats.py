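"""Voxel-wise ANCOVA, smoothness, cluster correction and associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from nirsvwm import forward_model as fm, group_stats as gs


def make_mask(dims=(8, 8, 4)):
    grid = fm.VoxelGrid(dims)
    return fm.MaskVolume(np.ones(dims, bool), grid)


def make_dataset(rng, P=12, dims=(8, 8, 4), values=None):
    mask = make_mask(dims)
    V = mask.n_true
    if values is None:
        values = rng.standard_normal((P, 3, 2, V))
    P = values.shape[0]
    return gs.GroupDataset(values=values, age=rng.uniform(4, 48, P), mask=mask)


class TestVoxelwiseAnova:
    def test_constant_data_gives_zero_F(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng, values=np.full((6, 3, 2, 256), 3.0))
        effects = gs.voxelwise_anova(ds)
        for em in effects.values():
            assert np.allclose(em.F, 0.0)

    def test_all_effects_present(self):
        rng = np.random.default_rng(1)
        effects = gs.voxelwise_anova(make_dataset(rng))
        assert set(effects) == set(gs.EFFECTS)

    def test_injected_interaction_raises_F_locally(self):
        rng = np.random.default_rng(2)
        P, V = 16, 256
        vals = rng.standard_normal((P, 3, 2, V))
        # chromophore×load pattern in voxels 0..19: HbO rises with load, HbR falls
        pattern = np.linspace(-1, 1, 3)
        vals[:, :, 0, :20] += 2 * pattern[None, :, None]
        vals[:, :, 1, :20] -= 2 * pattern[None, :, None]
        ds = make_dataset(rng, P=P, values=vals)
        em = gs.voxelwise_anova(ds)["chromophore_x_load"]
        assert em.F[:20].min() > np.median(em.F[20:])

    def test_single_voxel_matches_statsmodels_contrast_regression(self):
        """Each stratum's F equals an explicit OLS on the contrast scores."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        P = 10
        ds = make_dataset(rng, P=P, dims=(2, 2, 1))
        effects = gs.voxelwise_anova(ds)
        y = ds.values[:, :, :, 0]  # (P, 3, 2)
        age_c = ds.age - ds.age.mean()
        C_load = gs._orthonormal_contrasts(3)
        z = y.mean(axis=2) @ C_load.T  # (P, 2) contrast scores
        X = sm.add_constant(age_c)
        ss_load = ss_age = ss_err = 0.0
        for c in range(2):
            fit = sm.OLS(z[:, c], X).fit()
            ss_load += P * z[:, c].mean() ** 2
            ss_age += float(fit.params[1]) ** 2 * (age_c**2).sum()
            ss_err += fit.ssr
        F_load = (ss_load / 2) / (ss_err / (2 * (P - 2)))
        F_lxa = (ss_age / 2) / (ss_err / (2 * (P - 2)))
        assert effects["load"].F[0] == pytest.approx(F_load, rel=1e-8)
        assert effects["load_x_age"].F[0] == pytest.approx(F_lxa, rel=1e-8)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng, P=14, dims=(16, 16, 8))
        effects = gs.voxelwise_anova(ds)
        V = ds.mask.n_true
        for em in effects.values():
            rate = (em.p < 0.05).mean()
            # binomial 4σ band around 0.05 with V independent voxels
            band = 4 * np.sqrt(0.05 * 0.95 / V)
            assert abs(rate - 0.05) < band + 0.005, em.label


class TestSmoothness:
    def test_white_noise_estimates_voxel_size(self):
        rng = np.random.default_rng(5)
        mask = make_mask((16, 16, 8))
        maps = rng.standard_normal((10, 16, 16, 8))
        fwhm = gs.estimate_smoothness(maps, mask)
        assert np.allclose(fwhm, 2.0, atol=0.3)

    def test_known_kernel_recovered_and_scales(self):
        rng = np.random.default_rng(6)
        mask = make_mask((16, 16, 8))

        def est(fwhm_mm):
            sig = fwhm_mm / gs.FWHM_PER_SIGMA / 2.0  # voxels
            maps = np.stack([
                ndimage.gaussian_filter(rng.standard_normal((48, 48, 40)), sig)
                [16:32, 16:32, 16:24] for _ in range(20)])
            return gs.estimate_smoothness(maps, mask).mean()

        e6 = est(6.0)
        e12 = est(12.0)
        assert abs(e6 - 6.0) < 1.0
        assert abs(e12 / e6 - 2.0) < 0.3


class TestClusterThreshold:
    def test_alpha_one_gives_threshold_one(self):
        mask = make_mask((10, 10, 4))
        assert gs.cluster_threshold_mc(mask, 0.0, 0.001, 1.0, 200, 0) == 1

    def test_unsmoothed_sparse_threshold_small(self):
        mask = make_mask((10, 10, 10))
        thr = gs.cluster_threshold_mc(mask, 0.0, 0.001, 0.05, 1000, 1)
        assert thr <= 2

    def test_threshold_nondecreasing_in_fwhm(self):
        mask = make_mask((12, 12, 6))
        thrs = [gs.cluster_threshold_mc(mask, f, 0.01, 0.05, 400, 2)
                for f in (0.0, 4.0, 8.0)]
        assert thrs == sorted(thrs)


class TestExtractClusters:
    def make_effect(self, pvol, mask):
        p = pvol.ravel()[mask.indices()]
        F = stats.f.isf(np.clip(p, 1e-12, 1), 2, 20)
        return gs.EffectMap(label="chromophore", F=F, p=p, df=(2, 20),
                            mask=mask)

    def test_block_above_min_size_is_one_cluster(self):
        mask = make_mask((10, 10, 4))
        p = np.ones((10, 10, 4))
        p[2:5, 2:7, 1:3] = 1e-5  # 3·5·2 = 30 voxels
        recs = gs.extract_clusters(self.make_effect(p, mask),
                                   voxel_p=0.01, min_size=21)
        assert len(recs) == 1
        assert recs[0].size_voxels == 30
        assert recs[0].size_mm3 == pytest.approx(30 * 8.0)

    def test_block_below_min_size_dropped(self):
        mask = make_mask((10, 10, 4))
        p = np.ones((10, 10, 4))
        p[2:4, 2:7, 1:3] = 1e-5  # 20 voxels < 21
        assert gs.extract_clusters(self.make_effect(p, mask), 0.01, 21) == []

    def test_edge_touching_blocks_split_under_face_connectivity(self):
        mask = make_mask((5, 5, 2))
        p = np.ones((5, 5, 2))
        p[0, 0, 0] = 1e-5
        p[1, 1, 0] = 1e-5  # diagonal touch only
        p[1, 2, 0] = 1e-5
        recs6 = gs.extract_clusters(self.make_effect(p, mask), 0.01, 1,
                                    connectivity=6)
        recs26 = gs.extract_clusters(self.make_effect(p, mask), 0.01, 1,
                                     connectivity=26)
        assert len(recs6) == 2
        assert len(recs26) == 1


class TestPriorityClassification:
    def vol(self, idx, dims=(4, 4, 2)):
        v = np.zeros(dims, bool)
        for i in idx:
            v.ravel()[i] = True
        return v

    def test_priority_order_and_drop_rules(self):
        sig = {
            "chromophore_x_load": self.vol([0, 1]),
            "chromophore": self.vol([1, 2]),
            "load": self.vol([5]),  # no chromophore term → never labelled
        }
        lab = gs.classify_voxels_by_priority(sig)
        assert lab.ravel()[0] == 2  # chromophore×load rank
        assert lab.ravel()[1] == 2  # higher priority wins
        assert lab.ravel()[2] == 4  # chromophore main effect rank
        assert lab.ravel()[5] == 0
        # labels are a partition: single integer per voxel by construction
        assert lab.max() <= 4

    def test_empty_significance_labels_nothing(self):
        lab = gs.classify_voxels_by_priority({"chromophore": self.vol([])})
        assert not lab.any()


class TestCanonicalPattern:
    def test_boundaries(self):
        hbo = np.ones((5, 2))
        assert gs.canonical_pattern_rate(hbo, -hbo) == 1.0
        assert gs.canonical_pattern_rate(hbo, hbo) == 0.0

    def test_zero_is_no_pattern(self):
        assert gs.canonical_pattern_rate(np.array([1.0, 0.0]),
                                         np.array([-1.0, -1.0])) == 0.5

    def test_rate_rises_as_noise_falls(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.5, 2.0, size=(34, 3))
        rates = []
        for noise in (2.0, 0.5, 0.0):
            hbo = base + noise * rng.standard_normal(base.shape)
            hbr = -0.5 * base + noise * rng.standard_normal(base.shape)
            rates.append(gs.canonical_pattern_rate(hbo, hbr))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[-1] == 1.0


class TestAssociations:
    def test_perfect_linear_correlation(self):
        rng = np.random.default_rng(8)
        betas = rng.standard_normal(20)
        res = gs.brain_behavior_correlation(betas, 3.0 * betas)
        assert res["r"] == pytest.approx(1.0)
        assert res["robust"]

    def test_null_type_one_error(self):
        rng = np.random.default_rng(9)
        rej = sum(
            gs.brain_behavior_correlation(rng.standard_normal(34),
                                          rng.standard_normal(34))["p"] < 0.05
            for _ in range(1000))
        assert 30 <= rej <= 72  # 0.05 ± 3σ binomial

    def test_demographic_regression_recovers_dominant_predictor(self):
        rng = np.random.default_rng(10)
        edu = rng.uniform(0, 17, 34)
        income = rng.uniform(25e3, 2e5, 34)
        activation = 0.1 * income + 1.0 * rng.standard_normal(34)
        res = gs.demographic_regression(
            activation, pd.DataFrame({"maternal_education": edu,
                                      "income": income}))
        assert res["terms"] == ["income"]

    def test_exact_education_effect(self):
        rng = np.random.default_rng(11)
        edu = rng.uniform(0, 17, 34)
        res = gs.demographic_regression(
            2.0 * edu, pd.DataFrame({"maternal_education": edu,
                                     "income": rng.uniform(25e3, 2e5, 34)}))
        assert res["terms"] == ["maternal_education"]
        assert res["r_squared"] == pytest.approx(1.0)


class TestIdealRadar:
    def test_two_participants_one_ideal(self):
        vals = pd.DataFrame({"e1": [1.0, 2.0]})
        counts = gs.ideal_pattern_radar(vals, {"e1": "greater"})
        assert sorted(counts) == [0, 1]

    def test_maximal_participant_counts_all(self):
        rng = np.random.default_rng(12)
        vals = pd.DataFrame(rng.standard_normal((8, 7)),
                            columns=[f"e{i}" for i in range(7)])
        vals.iloc[0] = vals.max() + 1.0
        counts = gs.ideal_pattern_radar(
            vals, {c: "greater" for c in vals.columns})
        assert counts.iloc[0] == 7

    def test_flipping_benefit_complements(self):
        rng = np.random.default_rng(13)
        vals = pd.DataFrame(rng.standard_normal((9, 4)),
                            columns=list("abcd"))
        up = gs.ideal_pattern_radar(vals, {c: "greater" for c in "abcd"})
        dn = gs.ideal_pattern_radar(vals, {c: "suppression" for c in "abcd"})
        # continuous data: no median ties with odd n ⇒ exact complement
        # except the median participant per effect, who is non-ideal both ways
        assert ((up + dn) <= 4).all()
        assert (up + dn).sum() == 9 * 4 - 4


class TestClusterOverlap:
    def test_identity_disjoint_nested(self):
        a = np.zeros((4, 4, 2), bool)
        a[:2] = True
        same = gs.cluster_overlap(a, a)
        assert same["counts"]["intersection"] == a.sum()
        assert same["counts"]["a_only"] == 0
        b = np.zeros_like(a)
        b[3:] = True
        assert gs.cluster_overlap(a, b)["counts"]["intersection"] == 0
        nested = np.zeros_like(a)
        nested[0] = True
        res = gs.cluster_overlap(a, nested)
        assert res["counts"]["intersection"] == nested.sum()
        assert np.array_equal(res["intersection"], nested)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gs.cluster_overlap(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))
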