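"""Harness laws: splits, metrics, model registry, stacking, augmentation."""

import numpy as np
import pytest

from amidebench.benchmark import (
    ModelSpec,
    SplitPlan,
    StackSpec,
    augment_negatives,
    evaluate,
    fit_predict,
    make_splits,
    run_benchmark,
    stack_fit_predict,
    subset_by_amine_class,
)
from amidebench.mechanism import classify_amine


class TestMakeSplits:
    def test_ninety_ten(self):
        splits = make_splits(100, SplitPlan())
        for tr, te in splits:
            assert len(tr) == 90 and len(te) == 10
            assert set(tr).isdisjoint(te)
            assert len(set(tr) | set(te)) == 100

    def test_seed_reproducible(self):
        a = make_splits(200, SplitPlan(base_seed=4))
        b = make_splits(200, SplitPlan(base_seed=4))
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_five_splits_pairwise_differ(self):
        splits = make_splits(500, SplitPlan())
        tests = [frozenset(te) for _, te in splits]
        assert len(set(tests)) == len(tests)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SplitPlan(train_fraction=1.2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="more than 10"):
            make_splits(5, SplitPlan())


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert evaluate(y, y) == (1.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        pred = np.full_like(y, y.mean())
        r2, mae = evaluate(y, pred)
        assert r2 == pytest.approx(0.0)
        assert mae == pytest.approx(np.abs(y - y.mean()).mean())

    def test_constant_offset_mae(self):
        y = np.array([10.0, 20.0, 30.0])
        r2, mae = evaluate(y, y + 5)
        assert mae == pytest.approx(5.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate(np.ones(5), np.ones(5))


class TestFitPredict:
    def test_mean_baseline_predicts_training_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = rng.uniform(0, 100, 50)
        pred = fit_predict(ModelSpec("mean_baseline"), X, y, X[:7])
        assert np.allclose(pred, y.mean())

    def test_forest_recovers_noise_free_linear_signal(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(500, 5))
        y = 20 + 30 * X[:, 0] + 25 * X[:, 1]
        pred = fit_predict(
            ModelSpec("random_forest", params=(("n_estimators", 200),)),
            X[:400], y[:400], X[400:],
        )
        r2, _ = evaluate(y[400:], pred)
        assert r2 > 0.9

    def test_huge_ridge_penalty_approaches_training_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 3))
        y = rng.uniform(20, 80, 100)
        pred = fit_predict(
            ModelSpec("ridge", params=(("alpha", 1e9),)), X, y, X[:10]
        )
        assert np.allclose(pred, y.mean(), atol=0.5)

    def test_predictions_clipped_to_physical_range(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = np.linspace(0, 200, 20)  # force predictions beyond 100
        pred = fit_predict(ModelSpec("ridge", params=(("alpha", 1e-6),)), X, y, X)
        assert pred.min() >= 0.0 and pred.max() <= 100.0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            ModelSpec("transformer")

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="finite"):
            fit_predict(ModelSpec("ridge"), X, [1.0], X)


class TestRunBenchmark:
    def test_grid_bookkeeping(self, small_dataset, small_featurizer):
        plan = SplitPlan(n_splits=2)
        result = run_benchmark(
            small_dataset, small_featurizer, ["qm", "context"],
            [ModelSpec("mean_baseline"), ModelSpec("ridge")], plan,
        )
        assert len(result.cells) == 4
        for cell in result.cells.values():
            assert len(cell["r2_values"]) == 2
            assert cell["r2_std"] >= 0
            assert min(cell["r2_values"]) <= cell["r2_mean"] <= max(cell["r2_values"])

    def test_baseline_r2_is_near_zero(self, small_dataset, small_featurizer):
        result = run_benchmark(
            small_dataset, small_featurizer, ["qm"], [ModelSpec("mean_baseline")],
            SplitPlan(n_splits=3),
        )
        assert abs(result.cell("mean_baseline", "qm")["r2_mean"]) < 0.1

    def test_misaligned_featurizer_rejected(self, small_dataset, small_featurizer):
        other = small_dataset.subset(range(50))
        with pytest.raises(ValueError, match="not aligned"):
            run_benchmark(other, small_featurizer, ["qm"], [ModelSpec("ridge")])


@pytest.fixture(scope="module")
def stack_setup(small_data, small_featurizer):
    dataset, _ = small_data
    y = np.asarray(dataset.yields())
    tr, te = make_splits(len(dataset), SplitPlan(n_splits=1))[0]
    train_blocks, test_blocks = {}, {}
    for name in ("fingerprint", "battery2d", "aev", "qm"):
        block = small_featurizer.split_block(name, tr)
        train_blocks[name] = block.matrix[tr]
        test_blocks[name] = block.matrix[te]
    return y, tr, te, train_blocks, test_blocks


class TestStacking:
    def test_meta_prediction_is_exact_mean(self, stack_setup):
        y, tr, te, train_blocks, test_blocks = stack_setup
        stacked, base = stack_fit_predict(
            StackSpec(), train_blocks, y[tr], test_blocks
        )
        manual = np.mean(np.vstack(list(base.values())), axis=0)
        assert np.array_equal(stacked, manual)

    def test_identical_bases_collapse_to_any_base(self, stack_setup):
        y, tr, te, train_blocks, test_blocks = stack_setup
        same = {k: train_blocks["qm"] for k in train_blocks}
        same_te = {k: test_blocks["qm"] for k in test_blocks}
        stacked, base = stack_fit_predict(StackSpec(), same, y[tr], same_te)
        assert np.allclose(stacked, next(iter(base.values())))

    def test_stack_mae_bounded_by_worst_base(self, stack_setup):
        y, tr, te, train_blocks, test_blocks = stack_setup
        stacked, base = stack_fit_predict(
            StackSpec(), train_blocks, y[tr], test_blocks
        )
        base_maes = [evaluate(y[te], p)[1] for p in base.values()]
        assert evaluate(y[te], stacked)[1] <= max(base_maes)

    def test_missing_block_rejected(self, stack_setup):
        y, tr, te, train_blocks, test_blocks = stack_setup
        partial = {k: v for k, v in train_blocks.items() if k != "aev"}
        with pytest.raises(ValueError, match="missing feature blocks"):
            stack_fit_predict(StackSpec(), partial, y[tr], test_blocks)

    def test_duplicate_block_spec_rejected(self):
        with pytest.raises(ValueError, match="one base model"):
            StackSpec(base=(("qm", ModelSpec("ridge")), ("qm", ModelSpec("ridge"))))


class TestAugmentNegatives:
    def test_zero_fraction_is_identity(self, small_dataset):
        assert augment_negatives(small_dataset, 0.0) is small_dataset

    def test_counts_and_zero_yield(self, small_dataset):
        out = augment_negatives(small_dataset, 0.1, seed=0)
        added = [r for r in out.records if r.synthetic_negative]
        assert len(added) == int(0.1 * len(small_dataset))
        assert all(r.yield_percent == 0.0 for r in added)
        assert all(not validate_record_fails(r) for r in added)

    def test_no_added_pair_duplicates_an_existing_reaction(self, small_dataset):
        out = augment_negatives(small_dataset, 0.1, seed=1)
        existing = {
            (r.acid.smiles, r.amine.smiles)
            for r in small_dataset.records
        }
        for rec in out.records:
            if rec.synthetic_negative:
                assert (rec.acid.smiles, rec.amine.smiles) not in existing

    def test_deterministic(self, small_dataset):
        a = augment_negatives(small_dataset, 0.05, seed=3)
        b = augment_negatives(small_dataset, 0.05, seed=3)
        assert [r.reaction_id for r in a.records] == [r.reaction_id for r in b.records]
        assert [r.acid.smiles for r in a.records] == [r.acid.smiles for r in b.records]


def validate_record_fails(record):
    from amidebench.core import validate_record

    return bool(validate_record(record))


class TestSubsetByAmineClass:
    def test_partition_is_disjoint_and_exhaustive(self, small_dataset):
        subsets = subset_by_amine_class(small_dataset)
        sizes = {cls: len(ds) for cls, ds in subsets.items()}
        assert sum(sizes.values()) == len(small_dataset)
        all_ids = [r.reaction_id for ds in subsets.values() for r in ds.records]
        assert len(all_ids) == len(set(all_ids))

    def test_members_match_their_class(self, small_dataset):
        subsets = subset_by_amine_class(small_dataset)
        for cls, ds in subsets.items():
            for rec in ds.records[:10]:
                assert classify_amine(rec.amine) is cls
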