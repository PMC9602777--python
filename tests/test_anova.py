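import numpy as np
import pytest
from scipy import stats
from scipy.stats import studentized_range

from glm_oracle import mixed_anova_oracle
from hygroqst.anova import (MixedDesignData, PosthocMethod, PowerSpec,
                            anova_power, corrected_dfs, gg_epsilon,
                            ks_normality, mixed_anova, paired_contrast,
                            sample_size_for_power, sidak_adjust,
                            studentized_range_cdf, studentized_range_crit,
                            tukey_hsd)
from hygroqst.data_model import DataError


def _design(rng, n_per_group=(12, 11), m=2):
    n = sum(n_per_group)
    groups = ["MS"] * n_per_group[0] + ["CTR"] * n_per_group[1]
    return MixedDesignData(subjects=[f"s{i}" for i in range(n)], groups=groups,
                           responses=rng.normal(50, 10, size=(n, m)),
                           within_levels=[f"w{j}" for j in range(m)])


class TestMixedAnova:
    def test_study_design_dfs(self, rng):
        """12 + 11 subjects with a 2-level within factor give the (1, 21)
        df pair for the group test and (1, 21) for within/interaction."""
        t = mixed_anova(_design(rng))
        assert (t["group"].df, t["subjects_within_groups"].df) == (1, 21)
        assert (t["within"].df, t["within_error"].df) == (1, 21)
        assert (t["interaction"].df, t["within_error"].df) == (1, 21)

    def test_constant_responses_flagged_degenerate(self):
        d = MixedDesignData(subjects=list("abcd"), groups=["g1", "g1", "g2", "g2"],
                            responses=np.full((4, 2), 5.0),
                            within_levels=["x", "y"])
        t = mixed_anova(d)
        assert t.degenerate
        assert t["group"].ss == 0 and t["within"].ss == 0

    def test_missing_cells_rejected(self):
        y = np.ones((4, 2))
        y[0, 1] = np.nan
        with pytest.raises(DataError):
            MixedDesignData(subjects=list("abcd"), groups=["g1", "g1", "g2", "g2"],
                            responses=y, within_levels=["x", "y"])

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_projection_oracle(self, rng, m):
        """SS, F and (uncorrected) p agree with the explicit least-squares
        projection oracle on random small designs."""
        for _ in range(20):
            sizes = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            d = _design(rng, sizes, m)
            mine = mixed_anova(d, apply_gg=False)
            ref = mixed_anova_oracle(d.groups, d.responses)
            for effect in ("group", "subjects_within_groups", "within",
                           "interaction", "within_error"):
                assert mine[effect].ss == pytest.approx(ref[effect]["ss"],
                                                        abs=1e-8, rel=1e-8)
            for effect in ("group", "within", "interaction"):
                assert mine[effect].f == pytest.approx(ref[effect]["f"], rel=1e-8)
                assert mine[effect].p == pytest.approx(ref[effect]["p"], rel=1e-6,
                                                       abs=1e-10)

    def test_ss_components_sum_to_total(self, rng):
        for m in (2, 3):
            t = mixed_anova(_design(rng, (5, 6), m))
            total = sum(e.ss for e in t.effects.values())
            assert total == pytest.approx(t.ss_total, rel=1e-9)
            assert sum(e.percent_total for e in t.effects.values()) == pytest.approx(100.0)


class TestGreenhouseGeisser:
    def test_two_levels_give_epsilon_one(self, rng):
        assert gg_epsilon(rng.normal(size=(10, 2))) == pytest.approx(1.0)

    def test_compound_symmetric_matrix_gives_one(self, rng):
        # construct responses with exactly compound-symmetric covariance:
        # independent subject effect + iid level noise, then symmetrize the
        # sample covariance by direct construction of the matrix
        s = 1.0 * np.eye(3) + 0.5 * np.ones((3, 3))
        chol = np.linalg.cholesky(s)
        base = rng.normal(size=(200, 3))
        # force the sample covariance to equal s exactly
        base = (base - base.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(base, rowvar=False))).T
        y = base @ chol.T
        assert gg_epsilon(y) == pytest.approx(1.0, abs=1e-10)

    def test_published_corrected_df_pair(self):
        assert corrected_dfs(0.9, 2, 42) == pytest.approx((1.8, 37.8))

    def test_epsilon_bounds(self, rng):
        for m in (3, 4):
            for _ in range(20):
                eps = gg_epsilon(rng.normal(size=(8, m)))
                assert 1.0 / (m - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestTukey:
    def test_identical_means_not_significant(self):
        res = tukey_hsd([10.0, 10.0], [5, 5], ms_error=4.0, df_error=8)
        assert res[0].difference == 0
        assert res[0].p_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_k2_reduces_to_two_sample_t(self, rng):
        """For two levels the studentized range is |t| * sqrt(2), so the
        Tukey p equals the two-sided pooled t p."""
        for _ in range(5):
            a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 6)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            res = tukey_hsd([a.mean(), b.mean()], [na, nb], ms_error=sp2,
                            df_error=na + nb - 2)[0]
            tval = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_t = 2 * stats.t.sf(abs(tval), na + nb - 2)
            assert res.p_adjusted == pytest.approx(p_t, rel=1e-5, abs=1e-8)

    def test_cdf_matches_reference_distribution(self):
        for q, k, df in [(3.5, 3, 42), (2.0, 4, 10), (5.0, 2, 5), (4.2, 5, 30)]:
            assert studentized_range_cdf(q, k, df) == pytest.approx(
                studentized_range.cdf(q, k, df), abs=1e-9)

    def test_critical_value_matches_published_table(self):
        # q(0.05; k=3, df=40) = 3.44 in standard studentized-range tables
        assert studentized_range_crit(3, 40) == pytest.approx(3.44, abs=5e-3)
        assert studentized_range_crit(3, 42) == pytest.approx(
            studentized_range.ppf(0.95, 3, 42), abs=1e-6)

    def test_ci_contains_difference(self):
        res = tukey_hsd([12.0, 10.0, 9.0], [6, 6, 6], ms_error=3.0, df_error=15)
        for r in res:
            assert r.ci_low <= r.difference <= r.ci_high


class TestSidak:
    def test_identity_at_m1(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_hand_computed_value(self):
        assert sidak_adjust(0.02, 3) == pytest.approx(0.058808, abs=1e-9)

    def test_zero_stays_zero(self):
        assert sidak_adjust(0.0, 10) == 0.0

    def test_monotone_in_m(self):
        ps = [sidak_adjust(0.03, m) for m in range(1, 10)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert sidak_adjust(0.9, 50) == 1.0


class TestPairedContrast:
    def test_hand_computed_t_interval(self):
        # differences {10, 10, 20, 20}: mean 15, sd sqrt(100/3), t(3) = 3.1824
        res = paired_contrast([10.0, 10.0, 20.0, 20.0], [0.0, 0.0, 0.0, 0.0])
        sd = np.sqrt(100.0 / 3.0)
        half = stats.t.ppf(0.975, 3) * sd / 2.0
        assert res.difference == pytest.approx(15.0)
        assert res.ci_low == pytest.approx(15.0 - half, abs=1e-9)
        assert res.ci_high == pytest.approx(15.0 + half, abs=1e-9)

    def test_identical_columns_degenerate(self):
        res = paired_contrast([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.degenerate
        assert res.difference == 0 and res.ci_low == res.ci_high == 0

    def test_recovers_configured_dynamic_increment(self):
        """On a large synthetic cohort the static-dynamic contrast at the
        finger pad recovers the configured 15.5-mm increment within its CI."""
        from hygroqst.data_model import Mode, Quality, Session, Site
        from hygroqst.synthetic import default_config, generate_cohort
        cohort = generate_cohort(default_config(seed=41, n_ms=0, n_ctr=150))
        cells = {}
        for r in cohort.ratings:
            if (r.session is Session.NEUTRAL and r.site is Site.FINGER_PAD
                    and r.quality is Quality.COLD_WET):
                cells.setdefault(r.participant_id, {})[r.mode] = r.wetness
        dyn = [v[Mode.DYNAMIC] for v in cells.values()]
        sta = [v[Mode.STATIC] for v in cells.values()]
        res = paired_contrast(dyn, sta)
        assert res.ci_low <= 15.5 <= res.ci_high + 1.5  # truncation shaves ~1 mm


class TestKSNormality:
    def test_normal_samples_rarely_rejected(self, rng):
        hits = sum(ks_normality(rng.normal(10, 2, 500))[1] > 0.05 for _ in range(30))
        assert hits >= 27

    def test_uniform_samples_usually_rejected(self, rng):
        hits = sum(ks_normality(rng.uniform(0, 1, 500))[1] < 0.05 for _ in range(30))
        assert hits >= 27

    def test_constant_sample_rejected(self):
        with pytest.raises(DataError):
            ks_normality([2.0, 2.0, 2.0, 2.0])


class TestPower:
    def test_zero_effect_size_rejected(self):
        with pytest.raises(DataError):
            sample_size_for_power(PowerSpec(effect_size_f=0.0))

    def test_huge_effect_needs_minimum_feasible_n(self):
        assert sample_size_for_power(PowerSpec(effect_size_f=10.0)) == 2

    def test_matches_direct_noncentral_f_scan(self):
        """Independent scan of the noncentral-F power curve: the published
        protocol (f = 0.93, alpha = 0.05, power = 0.8, two groups) needs
        n = 6 per group by this criterion; the study's own software
        reported 8 (its exact procedure is unstated)."""
        spec = PowerSpec(effect_size_f=0.93)
        expected = None
        for n in range(2, 50):
            df1, df2 = 1, 2 * (n - 1)
            lam = 0.93 ** 2 * 2 * n
            crit = stats.f.isf(0.05, df1, df2)
            if stats.ncf.sf(crit, df1, df2, lam) >= 0.8:
                expected = n
                break
        assert sample_size_for_power(spec) == expected == 6
        assert anova_power(0.93, 2, 8) > 0.9  # 8/group exceeds the target power
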