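import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hygroqst import study_data
from hygroqst.data_model import (DataError, Mode, PerceptualRating, Quality,
                                 Session, Site)
from hygroqst.profiling import (Label, ProfilingConfig, Transform,
                                build_normative, classify, log_transform,
                                normative_from_dataset, profile_cohort,
                                profile_participant, profiles_from_z,
                                read_normative_csv, summarize_abnormalities,
                                write_normative_csv, z_score)
from hygroqst.synthetic import default_config, generate_cohort

CFG = ProfilingConfig()


class TestLogTransform:
    def test_zero_with_unit_offset(self):
        assert log_transform(0.0, CFG) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert log_transform(99.0, CFG) == pytest.approx(2.0)

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            log_transform(-1.0, CFG)

    def test_raw_transform_is_identity(self):
        cfg = ProfilingConfig(transform=Transform.RAW)
        assert log_transform(37.5, cfg) == 37.5


class TestNormativeReference:
    def test_log_moments_recomputed_from_values(self):
        ref = build_normative([9.0, 99.0], Site.FOREHEAD, Quality.COLD_WET, CFG)
        assert ref.mean_log == pytest.approx(1.5)
        assert ref.n == 2

    def test_single_value_rejected(self):
        with pytest.raises(DataError):
            build_normative([50.0], Site.FOREHEAD, Quality.COLD_WET, CFG)

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(DataError):
            build_normative([42.0] * 10, Site.FOREHEAD, Quality.COLD_WET, CFG)

    def test_synthetic_controls_recover_configured_mean(self):
        cohort = generate_cohort(default_config(seed=17, n_ms=0, n_ctr=51))
        refs = normative_from_dataset(cohort,
                                      sites=[Site.FOREHEAD, Site.FINGER_PAD])
        ref = refs[(Site.FOREHEAD, Quality.COLD_WET)]
        # configured dynamic mean 53.7, sd 27.4: Monte-Carlo + truncation slack
        assert ref.mean_raw == pytest.approx(53.7, abs=3 * 27.4 / np.sqrt(51) + 1.5)
        assert ref.n == 51


class TestZScore:
    def test_hand_computed_example(self):
        # normative {9, 99} has logs {1, 2} with offset 1: mean 1.5, sd 1/sqrt(2)
        ref = build_normative([9.0, 99.0], Site.FOREHEAD, Quality.COLD_WET, CFG)
        assert z_score(99.0, ref, CFG) == pytest.approx(0.5 * np.sqrt(2.0))
        assert z_score(9.0, ref, CFG) == pytest.approx(-0.5 * np.sqrt(2.0))

    def test_value_at_back_transformed_mean_scores_zero(self):
        ref = build_normative([20.0, 40.0, 80.0], Site.FOREHEAD, Quality.COLD_WET, CFG)
        x = 10 ** ref.mean_log - CFG.log_offset
        assert z_score(x, ref, CFG) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=99.0))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_strictly_increasing_in_rating(self, x):
        ref = build_normative([15.0, 35.0, 60.0, 90.0], Site.FOREHEAD,
                              Quality.COLD_WET, CFG)
        assert z_score(x + 1.0, ref, CFG) > z_score(x, ref, CFG)


class TestClassify:
    @pytest.mark.parametrize("z,label", [
        (-16.47, Label.LOSS),     # most extreme published loss cell
        (-2.26, Label.LOSS),
        (-1.96, Label.NORMAL),    # boundary is strict
        (0.0, Label.NORMAL),
        (1.96, Label.NORMAL),
        (1.9601, Label.GAIN),
    ])
    def test_threshold_rule(self, z, label):
        assert classify(z, CFG) is label

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            classify(float("nan"), CFG)


class TestProfiles:
    def _refs(self):
        cohort = generate_cohort(default_config(seed=23, n_ms=0, n_ctr=51))
        return normative_from_dataset(cohort,
                                      sites=[Site.FOREHEAD, Site.FINGER_PAD])

    def test_ratings_at_normative_mean_are_all_normal(self):
        refs = self._refs()
        ratings = []
        for (site, quality), ref in refs.items():
            x = 10 ** ref.mean_log - CFG.log_offset
            ratings.append(PerceptualRating("p", Session.NEUTRAL, site, quality,
                                            Mode.DYNAMIC, wetness=x, thermal=0))
        profile = profile_participant(ratings, refs, CFG)
        assert len(profile.cells) == 6
        assert all(c.label is Label.NORMAL for c in profile.cells.values())
        assert not profile.flagged

    def test_sites_without_reference_skipped(self):
        refs = self._refs()
        ratings = [PerceptualRating("p", Session.NEUTRAL, Site.FOREARM,
                                    Quality.COLD_WET, Mode.DYNAMIC, 50, 0),
                   PerceptualRating("p", Session.NEUTRAL, Site.FOREHEAD,
                                    Quality.COLD_WET, Mode.DYNAMIC, 50, 0)]
        profile = profile_participant(ratings, refs, CFG)
        assert list(profile.cells) == [(Site.FOREHEAD, Quality.COLD_WET)]

    def test_published_profile_patterns(self):
        """Classifying the printed z-scores reproduces the published
        per-participant abnormality patterns."""
        profiles = {p.participant_id: p
                    for p in profiles_from_z(study_data.wetness_z_table(), CFG)}
        loss_1 = {(c.site, c.quality) for c in profiles["1"].abnormal_cells()}
        assert loss_1 == {(Site.FOREHEAD, Quality.COLD_WET),
                          (Site.FOREHEAD, Quality.WARM_WET),
                          (Site.FINGER_PAD, Quality.WARM_WET)}
        assert not profiles["6"].flagged   # z = -1.73 stays normal
        assert not profiles["4"].flagged   # z = -1.83 stays normal


class TestAbnormalitySummary:
    def test_all_normal_profiles_empty_summary(self):
        profiles = profiles_from_z(
            study_data.wetness_z_table().assign(z=0.0), CFG)
        s = summarize_abnormalities(profiles)
        assert s.n_flagged == 0 and s.proportion == 0.0

    def test_published_tables_flag_three_of_twelve(self):
        profiles = profiles_from_z(study_data.wetness_z_table(), CFG)
        s = summarize_abnormalities(profiles)
        assert s.flagged_participants == {"1", "2", "10"}
        assert s.n_flagged == 3
        assert s.proportion == pytest.approx(0.25)
        total_loss = sum(len(p.abnormal_cells()) for p in profiles)
        assert total_loss == 7

    def test_published_site_quality_patterns(self):
        profiles = profiles_from_z(study_data.wetness_z_table(), CFG)
        s = summarize_abnormalities(profiles)
        assert s.patterns["1"][:2] == (2, 2)
        assert s.patterns["2"][:2] == (2, 2)
        assert s.patterns["10"][:2] == (1, 2)


class TestStatisticalProperties:
    def test_self_consistency_of_normative_members(self):
        """z-scoring each normative member against its own reference yields
        sample mean 0 and sample SD 1 exactly (standardization algebra)."""
        cohort = generate_cohort(default_config(seed=29, n_ms=0, n_ctr=31))
        refs = normative_from_dataset(cohort, sites=[Site.FINGER_PAD])
        for ref in refs.values():
            z = np.array([z_score(v, ref, CFG) for v in ref.values])
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_threshold_coverage_near_five_percent(self):
        """Profiling normative members against their own reference flags on
        the order of 2*Phi(-1.96) ~ 5% of cells; the log transform skews the
        lower tail so the rate sits slightly above the Gaussian value."""
        flagged = total = 0
        for seed in range(8):
            cohort = generate_cohort(default_config(seed=100 + seed, n_ms=0, n_ctr=51))
            refs = normative_from_dataset(cohort,
                                          sites=[Site.FOREHEAD, Site.FINGER_PAD])
            for ref in refs.values():
                z = np.array([z_score(v, ref, CFG) for v in ref.values])
                flagged += int(np.sum(np.abs(z) > CFG.threshold))
                total += z.size
        assert 0.02 < flagged / total < 0.10


def test_normative_csv_roundtrip(tmp_path):
    cohort = generate_cohort(default_config(seed=31, n_ms=0, n_ctr=20))
    refs = normative_from_dataset(cohort, sites=[Site.FOREHEAD])
    path = tmp_path / "normative.csv"
    write_normative_csv(refs, path)
    back = read_normative_csv(path, CFG)
    assert set(back) == set(refs)
    for key in refs:
        assert back[key].mean_log == pytest.approx(refs[key].mean_log)
        assert back[key].n == refs[key].n
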