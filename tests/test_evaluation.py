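"""Cross-validation protocols, the accuracy/STD aggregation, leak-freedom,
and the parameter-sweep machinery."""

import numpy as np
import pytest

from etongue import (
    DatasetSpec,
    ExcitationSpec,
    FSEConfig,
    KELMConfig,
    LabeledDataset,
    evaluate_model,
    generate_benchmark_mimic,
    generate_beverage_dataset,
    benchmark_spec,
    make_fourfold_splits,
    make_loo_replicate_splits,
    results_table,
    sensitivity_sweep,
)
from etongue.dataset import SensorResponseMatrix
from etongue.evaluation import EvalResult
from etongue.exceptions import ParameterError, ProtocolError

from conftest import SHORT_EXCITATION


def _check_partition(plan, n):
    seen = np.concatenate([te for _, te in plan.splits])
    assert sorted(seen) == list(range(n))
    for tr, te in plan.splits:
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == n


class TestLooReplicateSplits:
    def test_full_design_sizes(self, small_full_design):
        plan = make_loo_replicate_splits(small_full_design)
        assert len(plan) == 9
        for tr, te in plan.splits:
            assert len(tr) == 56 and len(te) == 7
        _check_partition(plan, 63)

    def test_each_test_set_has_one_sample_per_class(self, small_full_design):
        plan = make_loo_replicate_splits(small_full_design)
        labels = small_full_design.labels
        for _, te in plan.splits:
            assert len(set(labels[te])) == 7

    def test_two_by_two(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        assert len(plan) == 4  # 4 samples per class
        for tr, te in plan.splits:
            assert len(te) == 3 and len(tr) == 9

    def test_unbalanced_rejected(self, tiny_dataset):
        broken = LabeledDataset(samples=list(tiny_dataset.samples[:-1]))
        with pytest.raises(ProtocolError):
            make_loo_replicate_splits(broken)


class TestFourfoldSplits:
    def test_benchmark_group_sizes(self):
        spec = benchmark_spec(seed=2, excitation=ExcitationSpec(n_points=120))
        data = generate_benchmark_mimic(spec)
        plan = make_fourfold_splits(data, seed=0)
        sizes = sorted(len(te) for _, te in plan.splits)
        assert sizes == [28, 28, 29, 29]
        _check_partition(plan, 114)

    def test_every_class_in_every_group(self):
        spec = benchmark_spec(seed=2, excitation=ExcitationSpec(n_points=120))
        data = generate_benchmark_mimic(spec)
        plan = make_fourfold_splits(data, seed=1)
        labels = data.labels
        for _, te in plan.splits:
            assert len(set(labels[te])) == 13

    def test_four_classes_four_samples(self):
        spec = DatasetSpec(class_names=("a", "b", "c", "d"), concentrations=(1.0,),
                           replicates=4, excitation=ExcitationSpec(**SHORT_EXCITATION),
                           seed=0)
        data = generate_beverage_dataset(spec)
        plan = make_fourfold_splits(data, seed=0)
        labels = data.labels
        for _, te in plan.splits:
            assert len(te) == 4 and len(set(labels[te])) == 4

    def test_small_class_rejected(self, tiny_dataset):
        with pytest.raises(ProtocolError):
            make_fourfold_splits(tiny_dataset, seed=0, n_folds=5)


class TestEvaluateModel:
    def test_separable_case_is_perfect(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        res = evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(),
                             tiny_dataset, plan)
        assert res.mean_accuracy == 100.0
        assert res.std_accuracy == 0.0

    def test_shuffled_labels_drop_to_chance(self, small_full_design):
        labels = small_full_design.labels
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(labels))
            shuffled = LabeledDataset(samples=[
                SensorResponseMatrix(values=s.values, electrode_ids=s.electrode_ids,
                                     label=labels[perm[i]], sample_id=s.sample_id)
                for i, s in enumerate(small_full_design)
            ])
            # keep the 9-per-class balance so the protocol still applies
            if any(np.sum(shuffled.labels == c) != 9 for c in set(labels)):
                continue
            plan = make_loo_replicate_splits(shuffled)
            accs.append(evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(),
                                       shuffled, plan).mean_accuracy)
        assert accs, "permutation preserved balance in no replicate"
        assert np.mean(accs) < 40.0  # chance is 1/7 ~ 14%

    def test_aggregation_matches_recomputation(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        res = evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(),
                             tiny_dataset, plan)
        recomputed = [float(np.mean(p == t)) for p, t in
                      zip(res.per_split_predictions, res.per_split_truth)]
        assert recomputed == res.per_split_accuracy
        assert res.mean_accuracy == pytest.approx(100 * np.mean(recomputed))
        assert res.std_accuracy == pytest.approx(100 * np.std(recomputed, ddof=1))

    def test_single_perfect_split(self, tiny_dataset):
        from etongue.evaluation import SplitPlan

        plan = make_loo_replicate_splits(tiny_dataset)
        single = SplitPlan(splits=plan.splits[:1], protocol="loo_replicate")
        res = evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(),
                             tiny_dataset, single)
        assert res.mean_accuracy == 100.0 and res.std_accuracy == 0.0

    def test_no_information_leak_from_test_rows(self, tiny_dataset):
        """Corrupting a held-out sample must not move predictions for the
        other held-out samples of the same split."""
        plan = make_loo_replicate_splits(tiny_dataset)
        res = evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(),
                             tiny_dataset, plan)
        poisoned_idx = plan.splits[0][1][0]  # first test sample of split 0
        samples = [
            SensorResponseMatrix(values=(np.full_like(s.values, 1e6)
                                         if i == poisoned_idx else s.values),
                                 electrode_ids=s.electrode_ids, label=s.label,
                                 sample_id=s.sample_id)
            for i, s in enumerate(tiny_dataset)
        ]
        poisoned = LabeledDataset(samples=samples)
        res_p = evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(),
                               poisoned, plan)
        np.testing.assert_array_equal(res.per_split_predictions[0][1:],
                                      res_p.per_split_predictions[0][1:])
        for k in range(1, len(plan)):
            # the poisoned sample is in training for these splits only via
            # its features; splits not containing it in test keep their
            # test rows, so co-test predictions there may legitimately move.
            assert len(res_p.per_split_predictions[k]) == len(res.per_split_predictions[k])

    def test_elm_classifier_runs(self, tiny_dataset):
        from etongue import ELMConfig

        plan = make_loo_replicate_splits(tiny_dataset)
        res = evaluate_model("fse", FSEConfig(), "elm", ELMConfig(L=60, seed=0),
                             tiny_dataset, plan)
        assert 0.0 <= res.mean_accuracy <= 100.0

    @pytest.mark.parametrize("clf", ["svm", "rf", "lda", "nb"])
    def test_baseline_adapters_run(self, tiny_dataset, clf):
        plan = make_loo_replicate_splits(tiny_dataset)
        res = evaluate_model("fse", FSEConfig(), clf, None, tiny_dataset, plan)
        assert 0.0 <= res.mean_accuracy <= 100.0

    @pytest.mark.parametrize("method", ["rd", "pca", "dwt"])
    def test_baseline_features_run(self, tiny_dataset, method):
        plan = make_loo_replicate_splits(tiny_dataset)
        res = evaluate_model(method, None, "kelm", KELMConfig(), tiny_dataset, plan)
        assert 0.0 <= res.mean_accuracy <= 100.0

    def test_unknown_names_rejected(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        with pytest.raises(ParameterError):
            evaluate_model("wavelet", None, "kelm", None, tiny_dataset, plan)
        with pytest.raises(ParameterError):
            evaluate_model("fse", FSEConfig(), "perceptron", None, tiny_dataset, plan)


class TestSensitivitySweep:
    def test_grid_size_and_single_point(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        grid = [1e-3, 1e-2, 1e-1, 1, 10, 100, 1000]
        points = sensitivity_sweep("sigma", grid, tiny_dataset, plan)
        assert len(points) == 7
        single = sensitivity_sweep("sigma", [10.0], tiny_dataset, plan)
        direct = evaluate_model("fse", FSEConfig(sigma=10.0), "kelm", KELMConfig(),
                                tiny_dataset, plan)
        assert single[0].result.per_split_accuracy == direct.per_split_accuracy

    def test_grid_order_equivariance(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        grid = [0.1, 10.0, 1000.0]
        fwd = sensitivity_sweep("theta", grid, tiny_dataset, plan)
        rev = sensitivity_sweep("theta", grid[::-1], tiny_dataset, plan)
        for p, q in zip(fwd, rev[::-1]):
            assert p.value == q.value
            assert p.result.per_split_accuracy == q.result.per_split_accuracy

    def test_gamma_sweep_touches_regularization(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        points = sensitivity_sweep("gamma", [1e-3, 1e3], tiny_dataset, plan)
        assert all(p.result is not None for p in points)

    def test_empty_grid_rejected(self, tiny_dataset):
        plan = make_loo_replicate_splits(tiny_dataset)
        with pytest.raises(ParameterError):
            sensitivity_sweep("sigma", [], tiny_dataset, plan)

    def test_failed_point_is_recorded_not_raised(self, tiny_dataset, monkeypatch):
        import etongue.evaluation as ev

        plan = make_loo_replicate_splits(tiny_dataset)

        def boom(*a, **k):
            raise RuntimeError("degenerate features: all zero")

        real = ev.evaluate_model
        calls = []

        def flaky(feature_method, fc, *a, **k):
            if fc.sigma < 1e-2:
                boom()
            return real(feature_method, fc, *a, **k)

        monkeypatch.setattr(ev, "evaluate_model", flaky)
        points = ev.sensitivity_sweep("sigma", [1e-3, 10.0], tiny_dataset, plan)
        assert points[0].error is not None and points[0].result is None
        assert points[1].result is not None


def test_results_table_shape(tiny_dataset):
    plan = make_loo_replicate_splits(tiny_dataset)
    res = evaluate_model("fse", FSEConfig(), "kelm", KELMConfig(), tiny_dataset, plan)
    table = results_table([res])
    assert list(table["feature"]) == ["fse"]
    assert {"mean_accuracy", "std_accuracy", "n_splits"} <= set(table.columns)


def test_summary_formats_percent(tiny_dataset):
    res = EvalResult(per_split_accuracy=[1.0, 0.5],
                     model_spec={"feature": "fse", "classifier": "kelm"})
    assert res.mean_accuracy == 75.0
    assert "75.00%" in res.summary()
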