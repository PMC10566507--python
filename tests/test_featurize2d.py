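"""Connectivity descriptors: fingerprints, 2D battery, context, assembly, RFE."""

import numpy as np
import pytest

from amidebench.core import Context, ContextVocabulary
from amidebench.featurize2d import (
    FeatureBlock,
    SelectionPlan,
    VarianceFilter,
    assemble_reaction_features,
    battery_2d,
    battery_2d_names,
    encode_context,
    morgan_fingerprint,
    rfe_select,
    variance_filter,
)


class TestMorganFingerprint:
    def test_deterministic_for_identical_molecules(self):
        a = morgan_fingerprint("CC(=O)O")
        b = morgan_fingerprint("OC(=O)C")  # same molecule, different writing
        assert np.array_equal(a, b)

    def test_methane_sets_one_to_ten_bits(self):
        fp = morgan_fingerprint("C", radius=2, n_bits=2048)
        assert 1 <= fp.sum() < 10

    def test_tanimoto_with_self_is_one(self):
        fp = morgan_fingerprint("c1ccccc1CC(=O)O")
        inter = float((fp * fp).sum())
        union = float(fp.sum() + fp.sum() - inter)
        assert inter / union == 1.0

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError, match="n_bits"):
            morgan_fingerprint("C", n_bits=0)


class TestBattery2D:
    def test_battery_is_broad(self):
        assert len(battery_2d_names()) >= 200

    def test_water_molecular_weight(self):
        values = battery_2d("O")
        idx = battery_2d_names().index("MolWt")
        assert values[idx] == pytest.approx(18.02, abs=0.01)

    def test_benzene_heavy_atom_count(self):
        values = battery_2d("c1ccccc1")
        idx = battery_2d_names().index("HeavyAtomCount")
        assert values[idx] == 6

    def test_biphenyl_ring_count(self):
        values = battery_2d("c1ccc(-c2ccccc2)cc1")
        idx = battery_2d_names().index("RingCount")
        assert values[idx] == 2

    def test_pure_within_tolerance(self):
        a = battery_2d("COc1ccc(CC(=O)O)cc1")
        b = battery_2d("COc1ccc(CC(=O)O)cc1")
        finite = np.isfinite(a)
        assert np.allclose(a[finite], b[finite], atol=1e-10)


class TestEncodeContext:
    @pytest.fixture()
    def vocab(self):
        return ContextVocabulary(
            labels=[
                ("reagent", "dmap"),
                ("reagent", "hobt"),
                ("solvent", "dmf"),
                ("solvent", "thf"),
                ("condition", "rt"),
            ]
        )

    def test_single_known_solvent(self, vocab):
        vec = encode_context(Context(solvents=["dmf"]), vocab)
        assert vec.tolist() == [0, 0, 1, 0, 0]

    def test_empty_context_is_all_zero(self, vocab):
        assert encode_context(Context(), vocab).sum() == 0

    def test_multi_hot_sums(self, vocab):
        ctx = Context(reagents=["dmap", "hobt"], solvents=["thf"])
        assert encode_context(ctx, vocab).sum() == 3

    def test_unknown_label_contributes_nothing(self, vocab):
        vec = encode_context(Context(solvents=["water"]), vocab)
        assert vec.sum() == 0


class TestAssemble:
    def test_width_is_sum_of_role_widths(self, small_dataset):
        block = assemble_reaction_features(
            small_dataset, "fingerprint", roles=("acid", "amine"), n_bits=256
        )
        assert block.matrix.shape == (len(small_dataset), 512)
        assert len(block.feature_names) == 512

    def test_context_appends_vocab_dimension(self, small_dataset):
        base = assemble_reaction_features(
            small_dataset, "fingerprint", roles=("acid",), n_bits=128
        )
        with_ctx = assemble_reaction_features(
            small_dataset, "fingerprint", roles=("acid",), n_bits=128,
            include_context=True,
        )
        assert (
            with_ctx.n_features
            == base.n_features + small_dataset.context_vocab.dimension
        )

    def test_empty_role_list_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="role"):
            assemble_reaction_features(small_dataset, "fingerprint", roles=())

    def test_unknown_block_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown 2D block"):
            assemble_reaction_features(small_dataset, "soap")


class TestVarianceFilter:
    def test_constant_column_removed(self):
        mat = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        block = FeatureBlock("x", mat, ["const", "ramp"])
        out = variance_filter(block, threshold=1e-6)
        assert out.feature_names == ["ramp"]

    def test_zero_threshold_keeps_all_finite_columns(self):
        mat = np.column_stack(
            [np.ones(10), np.arange(10, dtype=float), np.full(10, np.nan)]
        )
        block = FeatureBlock("x", mat, ["const", "ramp", "missing"])
        out = variance_filter(block, threshold=0.0)
        assert out.feature_names == ["const", "ramp"]

    def test_retained_variances_respect_threshold(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0, rng.uniform(0.01, 2.0, size=30), size=(200, 30))
        block = FeatureBlock("x", mat, [f"c{i}" for i in range(30)])
        out = variance_filter(block, threshold=0.5)
        for name in out.feature_names:
            col = mat[:, int(name[1:])]
            # independent two-pass variance
            mean = col.sum() / len(col)
            var = ((col - mean) ** 2).sum() / len(col)
            assert var >= 0.5

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(50, 8))
        mat[:, 3] = 2.0
        block = FeatureBlock("x", mat, [f"c{i}" for i in range(8)])
        once = variance_filter(block, 0.01)
        twice = variance_filter(once, 0.01)
        assert once.feature_names == twice.feature_names
        assert np.array_equal(once.matrix, twice.matrix)

    def test_all_removed_is_an_error(self):
        block = FeatureBlock("x", np.ones((5, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="every column"):
            variance_filter(block, threshold=1.0)

    def test_train_fitted_filter_drops_test_varying_column(self):
        # canary: constant in train but varying in test must disappear
        train = np.column_stack([np.ones(20), np.arange(20, dtype=float)])
        full = np.vstack([train, np.column_stack([np.arange(5.0), np.arange(5.0)])])
        vf = VarianceFilter(1e-9).fit(train)
        out = vf.transform(FeatureBlock("x", full, ["canary", "ramp"]))
        assert out.feature_names == ["ramp"]


class TestRFESelect:
    def test_targets_control_merged_width(self):
        rng = np.random.default_rng(0)
        blocks = [
            FeatureBlock("a", rng.normal(size=(80, 20)), [f"a{i}" for i in range(20)]),
            FeatureBlock("b", rng.normal(size=(80, 15)), [f"b{i}" for i in range(15)]),
        ]
        y = rng.normal(size=80)
        plan = SelectionPlan(targets={"a": 6, "b": 4}, n_trees=20)
        merged = rfe_select(blocks, y, plan)
        assert merged.n_features == 10
        assert sum(n.startswith("a") for n in merged.feature_names) == 6

    def test_target_equal_to_width_is_identity(self):
        rng = np.random.default_rng(0)
        block = FeatureBlock("a", rng.normal(size=(40, 7)), [f"a{i}" for i in range(7)])
        merged = rfe_select([block], rng.normal(size=40), SelectionPlan(targets={"a": 7}))
        assert merged.feature_names == block.feature_names

    def test_target_above_width_rejected(self):
        block = FeatureBlock("a", np.ones((40, 3)) + np.random.default_rng(0).normal(size=(40,3)), ["a0", "a1", "a2"])
        with pytest.raises(ValueError, match="exceeds"):
            rfe_select([block], np.ones(40), SelectionPlan(targets={"a": 5}))

    def test_recovers_known_support(self):
        # y depends on exactly 3 of 50 columns; those should survive
        hits = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(150, 50))
            y = 3 * X[:, 4] - 2 * X[:, 17] + 4 * X[:, 31] + rng.normal(0, 0.1, 150)
            block = FeatureBlock("a", X, [f"a{i}" for i in range(50)])
            plan = SelectionPlan(targets={"a": 3}, n_trees=60, seed=seed)
            merged = rfe_select([block], y, plan)
            if set(merged.feature_names) == {"a4", "a17", "a31"}:
                hits += 1
        assert hits >= 0.9 * runs

    def test_seeded_and_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 12))
        y = X[:, 2] + rng.normal(0, 0.5, 60)
        block = FeatureBlock("a", X, [f"a{i}" for i in range(12)])
        plan = SelectionPlan(targets={"a": 4}, n_trees=30, seed=5)
        first = rfe_select([block], y, plan)
        second = rfe_select([block], y, plan)
        assert first.feature_names == second.feature_names
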