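"""Volumetrics, extrusion ratio, and the statistical test battery."""

import math

import numpy as np
import pytest
from scipy import stats

from pfasim import study_metrics as sm
from pfasim import synthetic as syn


def block_segmentation(frac_nonmyo=0.2, dims=(10, 20, 20)):
    labels = np.ones(dims, dtype=np.int8)
    n = labels.size
    k = int(round(frac_nonmyo * n))
    flat = labels.ravel()
    flat[:k] = sm.SEG_NON_MYOCARDIAL
    return sm.SegmentationVolume(labels=flat.reshape(dims))


class TestVolumeFractions:
    def test_direct_count(self):
        res = sm.volume_fractions(block_segmentation(0.2))
        assert res.nonmyo_pct == pytest.approx(20.0)
        assert res.v_pct == pytest.approx(80.0)

    def test_all_myocardium(self):
        res = sm.volume_fractions(block_segmentation(0.0))
        assert res.nonmyo_pct == 0.0

    def test_complement_is_exact(self):
        for f in (0.0, 0.1, 0.33, 0.9):
            res = sm.volume_fractions(block_segmentation(f))
            assert res.v_pct + res.nonmyo_pct == 100.0

    def test_background_excluded(self):
        labels = np.zeros((4, 10, 10), dtype=np.int8)
        labels[:, 2:8, :] = sm.SEG_MYOCARDIUM
        labels[:, 2, :] = sm.SEG_NON_MYOCARDIAL
        res = sm.volume_fractions(sm.SegmentationVolume(labels=labels))
        assert res.nonmyo_pct == pytest.approx(100.0 / 6.0)

    def test_per_slice_values(self):
        seg = block_segmentation(0.5, dims=(4, 10, 10))
        res = sm.volume_fractions(seg)
        assert set(res.per_slice.columns) == {"slice", "v_pct", "nonmyo_pct"}
        assert np.allclose(
            res.per_slice["v_pct"] + res.per_slice["nonmyo_pct"], 100.0
        )

    def test_generator_truth_recovery(self):
        seg, truth = syn.gen_segmentation(
            lesion_fraction=0.0, background_nonmyo_fraction=0.0925, seed=5
        )
        res = sm.volume_fractions(seg)
        assert res.nonmyo_pct == pytest.approx(9.25, abs=0.5)


class TestAblatedFraction:
    def test_printed_worked_example(self):
        """Treated 20.25% minus control 9.225% gives 11.03% ablated volume
        after two-decimal rounding."""
        out = sm.ablated_fraction(20.25, 9.225)
        assert sm.round_half_away(out, 2) == 11.03

    def test_identity_gives_zero(self):
        assert sm.ablated_fraction(15.0, 15.0) == 0.0

    def test_negative_flagged(self):
        with pytest.warns(UserWarning, match="negative"):
            out = sm.ablated_fraction(5.0, 9.0)
        assert out == pytest.approx(-4.0)

    def test_synthetic_lesion_recovery(self):
        """The subtraction estimator recovers the injected lesion fraction."""
        f, g = 0.11, 0.09
        seg, _ = syn.gen_segmentation(lesion_fraction=f, background_nonmyo_fraction=g, seed=2)
        ctl, _ = syn.gen_segmentation(lesion_fraction=0.0, background_nonmyo_fraction=g, seed=3)
        treated = sm.volume_fractions(seg).nonmyo_pct
        control = sm.volume_fractions(ctl).nonmyo_pct
        assert sm.ablated_fraction(treated, control) == pytest.approx(11.0, abs=0.5)

    def test_lesion_recovery_across_seeds(self):
        """Recovery within half a percentage point over ten seeds."""
        for seed in range(10):
            f = 0.05 + 0.01 * seed
            seg, truth = syn.gen_segmentation(
                lesion_fraction=f, background_nonmyo_fraction=0.09, seed=seed
            )
            ctl, _ = syn.gen_segmentation(
                lesion_fraction=0.0, background_nonmyo_fraction=0.09, seed=seed + 100
            )
            est = sm.ablated_fraction(
                sm.volume_fractions(seg).nonmyo_pct,
                sm.volume_fractions(ctl).nonmyo_pct,
            )
            assert est == pytest.approx(100.0 * f, abs=0.5)


class TestExtrusionReferenceRatio:
    def test_reference_cylinder_identity(self):
        seg, truth = syn.gen_segmentation(seed=0)
        thick = sm.wall_thickness_per_slice(seg).max()
        ref = math.pi * 6.5**2 * thick
        assert sm.extrusion_reference_ratio(seg, ref, 13.0) == pytest.approx(1.0)

    def test_known_ratio_recovery(self):
        """A synthetic atrium built to a 1.4 reference ratio is recovered."""
        seg, truth = syn.gen_segmentation(seed=1)
        ref = math.pi * 6.5**2 * truth["wall_mm"]
        ratio = sm.extrusion_reference_ratio(seg, 1.4 * ref, 13.0)
        assert ratio == pytest.approx(1.4, abs=0.1)

    def test_diameter_scaling(self):
        seg, _ = syn.gen_segmentation(seed=0)
        r1 = sm.extrusion_reference_ratio(seg, 500.0, 13.0)
        r2 = sm.extrusion_reference_ratio(seg, 500.0, 26.0)
        assert r1 == pytest.approx(4.0 * r2, rel=1e-9)

    def test_zero_diameter_rejected(self):
        seg, _ = syn.gen_segmentation(seed=0)
        with pytest.raises(ValueError):
            sm.extrusion_reference_ratio(seg, 500.0, 0.0)


class TestOneSampleT:
    def test_printed_worked_example(self):
        """mean 20.25, SD 4.40, n 5 vs control 9.225 gives p = 0.005."""
        t, p = sm.one_sample_t_summary(20.25, 4.40, 5, 9.225)
        assert round(p, 3) == 0.005

    def test_null_gives_p_one(self):
        t, p = sm.one_sample_t_summary(10.0, 2.0, 5, 10.0)
        assert t == 0.0 and p == 1.0

    def test_df3_tail(self):
        t, p = sm.one_sample_t_summary(10.0, 2.0, 4, 8.0)
        assert t == pytest.approx(2.0)
        assert p == pytest.approx(0.139, abs=5e-4)

    def test_matches_independent_t_cdf(self):
        """Closed form vs an independent t-CDF route (incomplete beta) on
        randomized summary tuples."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            mean = rng.normal(10, 5)
            sd = rng.uniform(0.5, 5.0)
            n = int(rng.integers(3, 40))
            mu0 = rng.normal(10, 5)
            t, p = sm.one_sample_t_summary(mean, sd, n, mu0)
            df = n - 1
            # t tail via the regularized incomplete beta function
            x = df / (df + t * t)
            p_beta = stats.beta.cdf(x, df / 2.0, 0.5)
            assert p == pytest.approx(p_beta, abs=1e-6)

    def test_zero_sd_convention(self):
        with pytest.warns(UserWarning, match="zero SD"):
            t, p = sm.one_sample_t_summary(10.0, 0.0, 5, 8.0)
        assert p == 0.0 and math.isinf(t)


class TestPairedChangeStats:
    def test_identical_pre_post(self):
        samples = [sm.EgmSample(2.0, 2.0, 40.0, 40.0) for _ in range(5)]
        out = sm.paired_change_stats(samples, "amplitude")
        assert out["mean_delta"] == 0.0 and out["p_value"] == 1.0

    def test_atrial_cohort_strongly_significant(self):
        """n = 30 at the study's atrial effect sizes: amplitude drop with
        p < 0.0001."""
        samples = syn.gen_egm_cohort(30, seed=0)
        out = sm.paired_change_stats(samples, "amplitude")
        assert out["p_value"] < 1e-4
        assert out["mean_delta"] < 0.0

    def test_mean_delta_matches_brute_force(self):
        samples = syn.gen_egm_cohort(12, seed=1)
        out = sm.paired_change_stats(samples, "duration")
        brute = np.mean(
            [s.post_duration_ms - s.pre_duration_ms for s in samples]
        )
        assert out["mean_delta"] == pytest.approx(float(brute), rel=1e-12)

    def test_welch_variant(self):
        samples = syn.gen_egm_cohort(20, seed=2)
        out = sm.paired_change_stats(samples, "impedance", welch=True)
        assert out["test"] == "welch_t"
        pre = [s.pre_impedance_ohm for s in samples]
        post = [s.post_impedance_ohm for s in samples]
        t, p = stats.ttest_ind(post, pre, equal_var=False)
        assert out["p_value"] == pytest.approx(float(p))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            sm.paired_change_stats([sm.EgmSample(2.0, 1.0, 40.0, 50.0)], "amplitude")


class TestKruskalDunn:
    def test_identical_groups_omnibus_one(self):
        groups = [np.full(5, 3.0)] * 3
        out = sm.kruskal_dunn(groups)
        assert out["p_omnibus"] == 1.0

    def test_h_matches_hand_ranked_oracle(self):
        """H statistic equals the brute-force rank computation on a 3x4 toy."""
        groups = [
            np.array([1.0, 5.0, 8.0, 2.0]),
            np.array([3.0, 9.0, 7.0, 4.0]),
            np.array([6.0, 10.0, 11.0, 12.0]),
        ]
        out = sm.kruskal_dunn(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = pooled.size
        r_groups = [ranks[i * 4 : (i + 1) * 4] for i in range(3)]
        h = 12.0 / (n * (n + 1)) * sum(
            4 * (rg.mean() - (n + 1) / 2.0) ** 2 for rg in r_groups
        )
        assert out["h"] == pytest.approx(h, rel=1e-12)

    def test_shifted_group_detected(self):
        """A group shifted by 10 SD is flagged by the adjusted pairwise tests."""
        rng = np.random.default_rng(7)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0, 1, 10)
        g3 = rng.normal(10, 1, 10)
        out = sm.kruskal_dunn([g1, g2, g3])
        pairs = out["pairs"]
        hit = pairs[(pairs.group_j == 2) | (pairs.group_i == 2)]
        assert (hit["p_adjusted"] < 0.01).all()

    def test_adjusted_never_below_unadjusted(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(i * 0.2, 1, 8) for i in range(4)]
        out = sm.kruskal_dunn(groups)
        assert (out["pairs"]["p_adjusted"] >= out["pairs"]["p_unadjusted"]).all()

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            sm.kruskal_dunn([np.ones(3), np.ones(3)])
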