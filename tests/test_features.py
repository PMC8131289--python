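"""Descriptor computation, scaling and the three exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from kpuubrain.features import (
    DescriptorMatrix,
    compute_descriptors,
    filter_descriptors,
    load_smarts_battery,
    prepare_descriptors,
    scale_descriptors,
)


def _dm(frame, count_type=None):
    return DescriptorMatrix.from_frame(frame, count_type=count_type)


class TestComputeDescriptors:
    def test_benzene_reference_values(self):
        m = compute_descriptors(["c1ccccc1"])
        frame = m.to_frame()
        assert frame["prop_mw"].iloc[0] == pytest.approx(78.11, abs=0.01)
        assert frame["prop_tpsa"].iloc[0] == pytest.approx(0.0)
        assert frame["at_c_arom"].iloc[0] == 6

    def test_empty_input_gives_empty_matrix(self):
        m = compute_descriptors([])
        assert m.values.shape[0] == 0
        assert len(m.descriptor_names) > 100

    def test_identical_smiles_identical_rows(self):
        m = compute_descriptors(["CCO", "CCO"])
        assert np.array_equal(m.values[0], m.values[1])

    def test_unparseable_smiles_flagged_not_fatal(self):
        m = compute_descriptors(["CCO", "not_a_smiles", "c1ccccc1"],
                                ["a", "b", "c"])
        assert m.failed_structures == ("b",)
        assert m.compound_ids == ("a", "c")

    def test_battery_loads_and_counts_are_counts(self):
        patterns = load_smarts_battery()
        assert len(patterns) > 60
        m = compute_descriptors(["CC(=O)Nc1ccccc1"])
        frame = m.to_frame()
        assert frame["grp_amide"].iloc[0] >= 1


class TestScaleDescriptors:
    def test_hand_example_center_and_unit_sd(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaled = scale_descriptors(_dm(frame), [0, 1, 2])
        assert np.allclose(scaled.values[:, 0], [-1.0, 0.0, 1.0])
        assert scaled.scaling_params["x"] == (2.0, 1.0)

    def test_idempotent_on_standardized_column(self):
        frame = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        scaled = scale_descriptors(_dm(frame), [0, 1, 2])
        assert np.allclose(scaled.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_left_for_rule_one(self):
        frame = pd.DataFrame({"x": [2.0, 2.0, 2.0], "y": [1.0, 2.0, 3.0]})
        scaled = scale_descriptors(_dm(frame), [0, 1, 2])
        assert np.allclose(scaled.values[:, 0], 2.0)  # untouched
        assert "x" not in scaled.scaling_params

    def test_test_rows_use_train_parameters(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 100.0]})
        scaled = scale_descriptors(_dm(frame), [0, 1, 2])
        assert scaled.values[3, 0] == pytest.approx((100.0 - 2.0) / 1.0)

    def test_double_scaling_rejected(self):
        scaled = scale_descriptors(_dm(pd.DataFrame({"x": [1.0, 2.0, 3.0]})), [0, 1, 2])
        with pytest.raises(ValueError):
            scale_descriptors(scaled, [0, 1, 2])


class TestFilterDescriptors:
    def test_rule1_drops_near_constant(self):
        frame = pd.DataFrame({"const": np.full(50, 3.0),
                              "ok": np.linspace(0, 1, 50)})
        out = filter_descriptors(_dm(frame), np.linspace(0, 1, 50))
        assert out.descriptor_names == ("ok",)
        assert ("const", "rule1_low_sd") in out.excluded

    def test_rule2_drops_rare_counts_only(self):
        rng = np.random.default_rng(0)
        rare = np.zeros(100)
        rare[:3] = 1.0  # 3% < 4%
        frame = pd.DataFrame({
            "rare_count": rare,
            "common_count": (rng.uniform(size=100) > 0.5).astype(float),
            "continuous": rng.normal(size=100),
        })
        ct = {"rare_count": True, "common_count": True, "continuous": False}
        out = filter_descriptors(_dm(frame, ct), rng.normal(size=100))
        assert "rare_count" not in out.descriptor_names
        assert {"common_count", "continuous"} <= set(out.descriptor_names)
        assert ("rare_count", "rule2_rare") in out.excluded

    def test_rule2_spares_rare_continuous(self):
        rare = np.zeros(100)
        rare[:3] = 0.7
        frame = pd.DataFrame({"rare_cont": rare + np.linspace(0, 0.01, 100)})
        out = filter_descriptors(_dm(frame, {"rare_cont": False}),
                                 np.linspace(0, 1, 100))
        assert "rare_cont" in out.descriptor_names

    def test_rule3_duplicate_keeps_higher_y_correlation(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=80)
        strong = y + rng.normal(0, 0.1, 80)
        frame = pd.DataFrame({
            "strong": strong,
            "copy_weak": strong + rng.normal(0, 0.01, 80),  # r ~ 1 with strong
            "indep": rng.normal(size=80),
        })
        # make copy_weak's own correlation to y slightly weaker by noise
        out = filter_descriptors(_dm(frame), y)
        assert "strong" in out.descriptor_names or "copy_weak" in out.descriptor_names
        assert len([n for n in ("strong", "copy_weak")
                    if n in out.descriptor_names]) == 1
        dropped = [n for n, r in out.excluded if r == "rule3_correlated"][0]
        kept = ({"strong", "copy_weak"} - {dropped}).pop()
        ycorr = {c: abs(np.corrcoef(frame[c], y)[0, 1]) for c in ("strong", "copy_weak")}
        assert ycorr[kept] >= ycorr[dropped]

    def test_no_retained_pair_exceeds_threshold(self, rng):
        base = rng.normal(size=(120, 6))
        frame = pd.DataFrame(
            np.hstack([base, base[:, :3] + rng.normal(0, 0.01, (120, 3))]),
            columns=[f"c{i}" for i in range(9)])
        y = rng.normal(size=120)
        out = filter_descriptors(_dm(frame), y)
        vals = out.values
        corr = np.corrcoef(vals, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        assert np.all(np.abs(corr[iu]) <= 0.95 + 1e-12)

    def test_column_order_invariance(self, rng):
        X = rng.normal(size=(100, 8))
        X[:, 5] = X[:, 1] + rng.normal(0, 0.01, 100)
        names = [f"c{i}" for i in range(8)]
        y = X[:, 1] + rng.normal(0, 0.5, 100)
        frame = pd.DataFrame(X, columns=names)
        out1 = set(filter_descriptors(_dm(frame), y).descriptor_names)
        perm = [3, 1, 7, 0, 5, 2, 6, 4]
        out2 = set(filter_descriptors(
            _dm(frame[[names[i] for i in perm]]), y).descriptor_names)
        assert out1 == out2

    def test_training_rows_only_decide_exclusions(self, rng):
        X = rng.normal(size=(100, 4))
        X[80:, 0] = 0.0  # constant only in the *test* block
        X[:80, 1] = 5.0  # constant in the *train* block
        y = rng.normal(size=100)
        out = filter_descriptors(
            _dm(pd.DataFrame(X, columns=list("abcd"))), y, reference_rows=range(80))
        assert "a" in out.descriptor_names     # varies on train
        assert "b" not in out.descriptor_names  # constant on train

    def test_y_length_mismatch_rejected(self, rng):
        frame = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(ValueError):
            filter_descriptors(_dm(frame), np.zeros(7))


class TestPrepareDescriptors:
    def test_retained_columns_standardized_on_train(self, rng):
        frame = pd.DataFrame(rng.normal(2.0, 3.0, size=(60, 5)),
                             columns=list("abcde"))
        y = rng.normal(size=60)
        train = np.arange(40)
        out = prepare_descriptors(frame, y, train)
        sub = out.values[train]
        assert np.allclose(sub.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(sub.std(axis=0, ddof=1), 1.0, atol=1e-9)
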