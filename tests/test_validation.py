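"""Splits and evaluation statistics, checked against brute-force oracles."""

import numpy as np
import pytest

import kpuubrain as kb
from kpuubrain import validation
from kpuubrain.validation import (
    cluster_split,
    morgan_fingerprints,
    paired_squared_error_test,
    pct_within_2fold,
    r_squared,
    rmse,
    time_split,
)


# ------------------------------------------------------------------- oracles

def _r2_naive(obs, pred):
    m = sum(obs) / len(obs)
    rss = sum((o - p) ** 2 for o, p in zip(obs, pred))
    tss = sum((o - m) ** 2 for o in obs)
    return 1 - rss / tss


def _rmse_naive(obs, pred):
    return (sum((p - o) ** 2 for o, p in zip(obs, pred)) / len(obs)) ** 0.5


def _pct2_naive(obs, pred):
    n_ok = sum(1 for o, p in zip(obs, pred) if max(p / o, o / p) <= 2.0)
    return 100.0 * n_ok / len(obs)


class TestMetrics:
    def test_perfect_prediction(self):
        obs = [0.1, 0.5, 1.0]
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert rmse(obs, obs) == 0.0
        assert pct_within_2fold(obs, obs) == 100.0

    def test_null_model_r2_zero(self):
        obs = np.array([0.0, 1.0, 2.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_negative_r2(self):
        assert r_squared([0, 1, 2], [0, 1, 4]) == pytest.approx(-1.0)

    def test_hand_computed_rmse(self):
        assert rmse([0, 0], [0.3, 0.4]) == pytest.approx(0.3536, abs=5e-5)

    def test_constant_residual_rmse(self):
        obs = np.zeros(7)
        assert rmse(obs, obs + 0.3) == pytest.approx(0.3)

    def test_two_fold_boundary_inclusive(self):
        obs = np.ones(4)
        pred = np.array([1.9, 2.0, 2.1, 4.0])
        assert pct_within_2fold(obs, pred) == pytest.approx(50.0)

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            obs = rng.normal(size=n)
            pred = obs + rng.normal(0, 0.5, n)
            if np.var(obs) == 0:
                continue
            assert abs(r_squared(obs, pred) - _r2_naive(obs, pred)) < 1e-12
            assert abs(rmse(obs, pred) - _rmse_naive(obs, pred)) < 1e-12
            o_lin, p_lin = 10.0 ** obs, 10.0 ** pred
            assert abs(pct_within_2fold(o_lin, p_lin) - _pct2_naive(o_lin, p_lin)) < 1e-12

    def test_nonpositive_linear_values_rejected(self):
        with pytest.raises(ValueError):
            pct_within_2fold([1.0, -1.0], [1.0, 1.0])


class TestPairedTest:
    def test_identical_errors_degenerate(self):
        e = np.array([0.1, 0.2, 0.3, 0.4])
        p, degenerate = paired_squared_error_test(e, e)
        assert degenerate and p == 1.0

    def test_halved_errors_significant_at_n128(self, rng):
        eps = rng.normal(0, 0.3, 128)
        p, degenerate = paired_squared_error_test(eps, 2 * eps)
        assert not degenerate
        assert p < 0.01

    def test_symmetry_under_swap(self, rng):
        a = rng.normal(0, 0.2, 50)
        b = rng.normal(0, 0.4, 50)
        p_ab, _ = paired_squared_error_test(a, b)
        p_ba, _ = paired_squared_error_test(b, a)
        assert p_ab == pytest.approx(p_ba)


class TestTimeSplit:
    def test_distinct_dates_earliest_train(self):
        dates = [f"2020-01-{d:02d}" for d in range(1, 11)]
        s = time_split(dates)
        assert [s.labels[i] for i in range(8)] == ["train"] * 8
        assert list(s.labels[8:]) == ["test", "test"]

    def test_all_same_date_errors(self):
        with pytest.raises(ValueError, match="temporal"):
            time_split(["2020-01-01"] * 10)

    def test_cutoff_ties_go_to_train(self):
        dates = ["2020-01-01"] * 5 + ["2020-06-01"] * 30 + ["2020-12-01"] * 5
        s = time_split(dates, train_fraction=0.8)
        # the cutoff lands inside the tied middle block: all ties train
        labels = np.asarray(s.labels)
        assert (labels[5:35] == "train").all()
        assert (labels[35:] == "test").all()

    def test_missing_dates_rejected(self):
        with pytest.raises(ValueError):
            time_split(["2020-01-01", None, "2020-01-03"])


class TestClusterSplit:
    def test_single_cluster_cannot_split(self, rng):
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="cluster"):
            cluster_split(None, y, cluster_ids=np.zeros(20, dtype=int))

    def test_singletons_reduce_to_stratified_sampling(self, rng):
        y = rng.normal(size=100)
        s = cluster_split(None, y, cluster_ids=np.arange(100), seed=1)
        assert s.test_idx.size in (19, 20, 21)
        assert s.train_idx.size + s.test_idx.size == 100

    def test_no_family_straddles_the_split(self, small_dataset, derived_small):
        y = np.log10(derived_small["kpuu"].to_numpy())
        fams = small_dataset.scaffold_families
        s = cluster_split(None, y, cluster_ids=fams, seed=3)
        labels = np.asarray(s.labels)
        for fam in np.unique(fams):
            sides = set(labels[fams == fam])
            assert len(sides) == 1

    def test_deterministic_under_seed(self, rng):
        y = rng.normal(size=80)
        fams = rng.integers(0, 20, 80)
        s1 = cluster_split(None, y, cluster_ids=fams, seed=5)
        s2 = cluster_split(None, y, cluster_ids=fams, seed=5)
        assert s1.labels == s2.labels

    def test_test_fraction_within_one_compound(self, small_dataset, derived_small):
        y = np.log10(derived_small["kpuu"].to_numpy())
        s = cluster_split(None, y, cluster_ids=small_dataset.scaffold_families,
                          seed=0)
        n = len(y)
        assert abs(s.test_idx.size - round(0.2 * n)) <= 1

    def test_stratification_balances_response(self, rng):
        y = np.sort(rng.normal(size=200))
        s = cluster_split(None, y, cluster_ids=np.arange(200), seed=2)
        te = s.test_idx
        # test median close to overall median under stratified sampling
        assert abs(np.median(y[te]) - np.median(y)) < 0.5

    def test_threshold_domain_checked(self, rng):
        with pytest.raises(ValueError):
            cluster_split(None, rng.normal(size=10),
                          tanimoto_threshold=1.5, cluster_ids=np.arange(10))

    def test_fingerprint_clustering_groups_similar_structures(self):
        smiles = (["CCCCCCCCc1ccccc1", "CCCCCCCCCc1ccccc1", "CCCCCCCCCCc1ccccc1"]
                  * 5 + ["OC(=O)c1ccncc1F", "NS(=O)(=O)c1ccc2nncn2c1"] * 5)
        fps = morgan_fingerprints(smiles)
        rng_local = np.random.default_rng(0)
        order = rng_local.permutation(len(fps))
        clusters = validation._leader_clusters(fps, 0.6, order)
        alkyl = {clusters[i] for i in range(15)}
        other = {clusters[i] for i in range(15, 25)}
        assert alkyl.isdisjoint(other)


class TestEvaluateBundle:
    def test_report_fields_consistent(self, rng):
        obs = rng.normal(size=40)
        pred = obs + rng.normal(0, 0.2, 40)
        rep = validation.evaluate(obs, pred)
        assert rep.n_test == 40
        assert rep.rmse > 0
        assert 0 <= rep.pct_within_2fold <= 100
        assert rep.response_scale == "log10"

    def test_comparator_pvalue_attached(self, rng):
        obs = rng.normal(size=30)
        rep = validation.evaluate(obs, obs + rng.normal(0, 0.1, 30),
                                  comparator_pred_log=obs + rng.normal(0, 0.4, 30))
        assert 0 <= rep.comparison_pvalue <= 1
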