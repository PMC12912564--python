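import numpy as np
import pytest

from memfid.mixture import ErrorSample, fit_mixture_mle
from memfid.synthetic import (
    CohortConfig,
    ItemConfig,
    generate_cohort,
    generate_displays,
    generate_group_samples,
    generate_lifestyle_items,
)


def pairwise_min_separation(positions):
    pos = np.sort(np.asarray(positions))
    gaps = np.diff(np.concatenate([pos, [pos[0] + 360.0]]))
    return gaps.min()


class TestDisplays:
    def test_default_configuration(self):
        ds = generate_displays(seed=1)
        assert len(ds.displays) == 29
        assert sum(len(d.target_ids) for d in ds.displays) == 87
        assert ds.n_objects == 174  # each target has a perceptually similar lure
        for d in ds.displays:
            assert pairwise_min_separation(d.positions_deg) >= 62.04
            assert all(0.0 <= p < 360.0 for p in d.positions_deg)

    def test_object_ids_unique(self):
        ds = generate_displays(seed=2)
        ids = [i for d in ds.displays for i in d.target_ids + d.lure_ids]
        assert len(ids) == len(set(ids)) == 174

    def test_single_object_always_feasible(self):
        ds = generate_displays(n_scenes=5, objects_per_display=1, seed=3)
        assert len(ds.displays) == 5

    def test_pigeonhole_infeasible_config_refused(self):
        with pytest.raises(ValueError):
            generate_displays(objects_per_display=6, min_separation_deg=62.04)

    def test_deterministic_under_seed(self):
        a = generate_displays(seed=11)
        b = generate_displays(seed=11)
        assert a == b


class TestGroupSamples:
    def test_labels_and_sizes(self):
        from memfid.mixture import MixtureParams

        samples = generate_group_samples(
            6, 40, {"x": MixtureParams(0.8, 12.0), "y": MixtureParams(0.5, 12.0)}, seed=4
        )
        assert len(samples) == 12
        assert {s.label for s in samples} == {"x", "y"}
        assert all(s.n_trials == 40 for s in samples)


class TestCohort:
    def test_same_seed_byte_identical(self):
        c1, t1 = generate_cohort(seed=5)
        c2, t2 = generate_cohort(seed=5)
        assert c1.to_csv() == c2.to_csv()
        assert t1.to_csv() == t2.to_csv()

    def test_lifestyle_summary_matches_design(self):
        """Typical-pandemic correlation ~0.86 and mean decline ~4.47."""
        corrs, drops = [], []
        for seed in range(100):
            cohort, _ = generate_cohort(CohortConfig(trials_per_subject=1), seed=seed)
            t1 = cohort[cohort.timepoint == "T1"]
            corrs.append(np.corrcoef(t1.lifestyle_typical, t1.lifestyle_pandemic)[0, 1])
            drops.append((t1.lifestyle_typical - t1.lifestyle_pandemic).mean())
        assert abs(np.mean(corrs) - 0.86) < 0.1
        assert abs(np.mean(drops) - 4.47) < 1.5

    def test_zero_effect_config_is_null(self):
        diffs = []
        for seed in range(30):
            cfg = CohortConfig(n_subjects=30, trials_per_subject=1,
                               memory_change_mean=0.0, lifestyle_memory_effect=0.0)
            cohort, _ = generate_cohort(cfg, seed=seed)
            wide = cohort.pivot(index="subject_id", columns="timepoint", values="true_pt")
            diffs.append((wide["T1"] - wide["T2"]).mean())
        assert abs(np.mean(diffs)) < 0.02

    def test_attrition_drops_t2_rows_only(self):
        cfg = CohortConfig(n_subjects=40, trials_per_subject=1, attrition=0.4)
        cohort, _ = generate_cohort(cfg, seed=6)
        t1 = cohort[cohort.timepoint == "T1"]
        t2 = cohort[cohort.timepoint == "T2"]
        assert len(t1) == 40
        assert 0 < len(t2) < 40

    def test_mixture_round_trip_recovers_true_pt(self):
        """Group-level pT bias < 0.02 when each subject has 10k trials."""
        cfg = CohortConfig(n_subjects=6, trials_per_subject=10_000)
        cohort, trials = generate_cohort(cfg, seed=7)
        biases = []
        for (sid, tp), sub in trials.groupby(["subject_id", "timepoint"]):
            fit = fit_mixture_mle(ErrorSample(sub.error_deg.to_numpy()))
            truth = cohort.set_index(["subject_id", "timepoint"]).loc[(sid, tp), "true_pt"]
            biases.append(fit.params.p_t - truth)
        assert abs(np.mean(biases)) < 0.02

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=0)
        with pytest.raises(ValueError):
            CohortConfig(attrition=1.5)
        with pytest.raises(ValueError):
            CohortConfig(lifestyle_corr=1.0)


class TestLifestyleItems:
    def test_shape_and_range(self):
        df = generate_lifestyle_items(10, seed=8)
        assert len(df) == 10 * 17 * 2
        assert set(df.phase) == {"typical", "pandemic"}
        assert df.response.between(0, 5).all()

    def test_zero_shifts_are_null(self):
        from memfid.lifestyle import item_change_tests

        items = tuple((f"item_{i}", 2.5, 0.0) for i in range(10))
        cfg = ItemConfig(items=items)
        n_sig = 0
        for seed in range(5):
            df = generate_lifestyle_items(59, cfg, seed=seed)
            n_sig += item_change_tests(df).significant.sum()
        assert n_sig == 0

    def test_targeted_shift_detected(self):
        from memfid.lifestyle import item_change_tests

        items = tuple(
            (f"social_{i}", 3.0, 1.5) if i < 3 else (f"other_{i}", 3.0, 0.0)
            for i in range(17)
        )
        df = generate_lifestyle_items(59, ItemConfig(items=items), seed=9)
        res = item_change_tests(df).set_index("item_id")
        assert res.loc[[f"social_{i}" for i in range(3)], "significant"].all()
        assert not res.loc[[f"other_{i}" for i in range(3, 17)], "significant"].any()

    def test_deterministic(self):
        a = generate_lifestyle_items(12, seed=10)
        b = generate_lifestyle_items(12, seed=10)
        assert a.equals(b)
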