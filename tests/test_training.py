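"""Split plans, leakage guards, optimization loop, CV reproducibility."""

import numpy as np
import pytest

from specqc import (
    GOOD_CLASS,
    ModelSpec,
    NetworkModel,
    RFModel,
    SimulationConfig,
    SplitPlan,
    TrainConfig,
    generate_cohort,
    make_split_plan,
    preprocess_dataset,
    run_cross_validation,
    train_network,
    train_rf,
)

SMALL_CNN = ModelSpec(kind="CNN", cnn_conv_layers=3, base_channels=4, fc1_width=16)


@pytest.fixture(scope="module")
def nd40():
    """40 subjects, 10 per cohort tag, few voxels (plans only need subjects)."""
    return generate_cohort(SimulationConfig(n_subjects=40, voxels_per_subject=5, seed=21))


@pytest.fixture(scope="module")
def bt13():
    return generate_cohort(SimulationConfig(n_subjects=13, voxels_per_subject=5,
                                            tumor_mode=True, seed=22))


class TestSplitPlans:
    def test_nd_rotating_forty_subjects(self, nd40):
        plan = make_split_plan(nd40, "ND_rotating", seed=3)
        assert len(plan.folds) == 10
        tags = nd40.subject_tags
        tested = []
        for train, val, test in plan.folds:
            assert len(test) == 4 and len(val) == 4
            assert sorted(tags[s] for s in test) == ["MDD", "MS", "PD", "healthy"]
            assert sorted(tags[s] for s in val) == ["MDD", "MS", "PD", "healthy"]
            assert len(train) + 8 == 40
            tested.extend(test)
        # test subjects rotate without replacement: each appears at most once
        assert len(tested) == len(set(tested))

    def test_bt_leave_one_out_thirteen_subjects(self, bt13):
        plan = make_split_plan(bt13, "BT_leave_one_out", seed=3)
        assert len(plan.folds) == 13
        for train, val, test in plan.folds:
            assert (len(train), len(val), len(test)) == (10, 2, 1)
        assert sorted(t[0] for *_, t in plan.folds) == sorted(bt13.subjects)

    def test_all_folds_pairwise_disjoint(self, nd40, bt13):
        for ds, scheme in ((nd40, "ND_rotating"), (bt13, "BT_leave_one_out")):
            plan = make_split_plan(ds, scheme, seed=5)
            for train, val, test in plan.folds:  # brute-force set-intersection scan
                assert not set(train) & set(val)
                assert not set(train) & set(test)
                assert not set(val) & set(test)
                assert set(train) | set(val) | set(test) == set(ds.subjects)

    def test_deficient_cohort_tag_is_named(self):
        ds = generate_cohort(SimulationConfig(n_subjects=3, voxels_per_subject=4, seed=1))
        with pytest.raises(ValueError, match=r"tag '(healthy|MDD|MS|PD)'"):
            make_split_plan(ds, "ND_rotating", seed=0)

    def test_bt_needs_at_least_four_subjects(self):
        ds = generate_cohort(SimulationConfig(n_subjects=3, voxels_per_subject=4,
                                              tumor_mode=True, seed=1))
        with pytest.raises(ValueError):
            make_split_plan(ds, "BT_leave_one_out", seed=0)

    def test_plan_is_deterministic_in_seed(self, nd40):
        assert make_split_plan(nd40, "ND_rotating", seed=9).folds == \
            make_split_plan(nd40, "ND_rotating", seed=9).folds

    def test_overlapping_plan_rejected(self):
        plan = SplitPlan("ND_rotating", [(["a", "b"], ["b"], ["c"])], 1)
        with pytest.raises(ValueError, match="overlap"):
            plan.validate()


@pytest.fixture(scope="module")
def small_sets():
    ds = preprocess_dataset(generate_cohort(
        SimulationConfig(n_subjects=4, voxels_per_subject=30, seed=13)))
    subj = ds.subjects
    return ds.subset_subjects(subj[:2]), ds.subset_subjects(subj[2:3]), ds.subset_subjects(subj[3:])


class TestTrainNetwork:
    def test_epoch_count_sets_curve_length(self, small_sets):
        train_ds, val_ds, _ = small_sets
        _, curves = train_network(NetworkModel(SMALL_CNN, seed=0), train_ds, val_ds,
                                  TrainConfig(epochs=3, seed=0))
        assert all(len(curves[k]) == 3 for k in curves)

    def test_zero_learning_rate_freezes_parameters(self, small_sets):
        train_ds, val_ds, _ = small_sets
        net = NetworkModel(SMALL_CNN, seed=0)
        before = net.net.state()
        _, curves = train_network(net, train_ds, val_ds, TrainConfig(learning_rate=0.0,
                                                                     epochs=2, seed=0))
        for b, a in zip(before, net.net.state()):
            assert np.array_equal(b, a)
        assert abs(curves["train_loss"][0] - curves["train_loss"][1]) < 1e-7

    def test_subject_overlap_refused(self, small_sets):
        train_ds, _, _ = small_sets
        with pytest.raises(ValueError, match="leakage"):
            train_network(NetworkModel(SMALL_CNN), train_ds, train_ds, TrainConfig(epochs=1))


class TestTrainRF:
    def test_forest_has_200_trees(self, small_sets):
        train_ds, _, _ = small_sets
        model = train_rf(RFModel(ModelSpec(kind="RF"), seed=0), train_ds)
        assert len(model.forest.estimators_) == 200

    def test_deterministic_given_seed(self, small_sets):
        train_ds, _, test_ds = small_sets
        X = test_ds.spectra.astype(np.float32)
        a = train_rf(RFModel(ModelSpec(kind="RF"), seed=5), train_ds).predict_proba(X)
        b = train_rf(RFModel(ModelSpec(kind="RF"), seed=5), train_ds).predict_proba(X)
        assert np.array_equal(a, b)

    def test_separable_data_held_out_accuracy(self, pp_sep, sep_fold):
        train_ds, _, test_ds = sep_fold
        model = train_rf(RFModel(ModelSpec(kind="RF"), seed=0), train_ds)
        pred = model.predict_proba(test_ds.spectra.astype(np.float32))[:, GOOD_CLASS] >= 0.5
        assert np.mean(pred == test_ds.labels) >= 0.95


class TestRunCrossValidation:
    def test_single_fold_aggregate_std_is_zero(self, pp_sep):
        plan = make_split_plan(pp_sep, "ND_rotating", seed=2, n_repeats=1)
        result = run_cross_validation(pp_sep, ModelSpec(kind="RF"), TrainConfig(seed=0),
                                      plan, preprocess=False)
        assert len(result.fold_reports) == 1
        assert result.aggregate["auc"][1] == 0.0

    def test_rf_cv_metrics_reproducible(self, pp_sep):
        plan = make_split_plan(pp_sep, "ND_rotating", seed=2, n_repeats=2)
        kw = dict(preprocess=False)
        a = run_cross_validation(pp_sep, ModelSpec(kind="RF"), TrainConfig(seed=1), plan, **kw)
        b = run_cross_validation(pp_sep, ModelSpec(kind="RF"), TrainConfig(seed=1), plan, **kw)
        for ra, rb in zip(a.fold_reports, b.fold_reports):
            assert (ra.auc, ra.auc_pr, ra.accuracy) == (rb.auc, rb.auc_pr, rb.accuracy)

    def test_lesion_subset_reported_for_tumor_cohorts(self):
        ds = generate_cohort(SimulationConfig(n_subjects=5, voxels_per_subject=60,
                                              tumor_mode=True, lesion_fraction=0.4, seed=17))
        plan = make_split_plan(ds, "BT_leave_one_out", seed=0)
        result = run_cross_validation(ds, ModelSpec(kind="RF"), TrainConfig(seed=0), plan)
        assert len(result.fold_reports) == 5
        assert result.lesion_reports, "expected lesion-only reports on a tumor cohort"
        assert all(r.subset_tag == "lesion_only" for r in result.lesion_reports)
        assert result.lesion_aggregate is not None
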