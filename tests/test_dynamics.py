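"""Energy/entropy statistics, standardization and statistical tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynsubgraphs.dynamics import (behavior_association, energy,
                                   energy_entropy_relation, entropy,
                                   entropy_rows, group_compare,
                                   mean_abs_derivative, motion_check,
                                   shuffle_null_correlation, standardize,
                                   summarize_dynamics)


def make_column_map(n_subjects, T):
    return pd.DataFrame({
        "column": np.arange(n_subjects * T),
        "subject": np.repeat(np.arange(n_subjects), T),
        "window": np.tile(np.arange(T), n_subjects),
    })


class TestPointStatistics:
    def test_energy_examples(self):
        assert energy(np.zeros(5)) == 0.0
        assert energy([1.0, 2.0, 2.0]) == 9.0

    def test_energy_matches_loop_oracle(self, rng):
        s = rng.random(51)
        assert energy(s) == pytest.approx(sum(v * v for v in s), abs=1e-12)

    def test_entropy_closed_forms(self):
        assert entropy(np.full(20, 3.0)) == 0.0
        two_level = np.array([0.0, 1.0] * 25)
        assert entropy(two_level) == pytest.approx(np.log(2))
        uniform = (np.arange(50) + 0.5) / 50
        assert entropy(uniform) == pytest.approx(np.log(10))

    def test_entropy_affine_invariance_and_energy_scaling(self, rng):
        s = rng.random(60)
        assert entropy(3.5 * s + 2.0) == pytest.approx(entropy(s))
        assert energy(3.0 * s) == pytest.approx(9.0 * energy(s))

    def test_derivative_examples_and_oracle(self, rng):
        assert mean_abs_derivative(np.full(7, 2.2)) == 0.0
        assert mean_abs_derivative([0.0, 1.0, 0.0, 1.0]) == 1.0
        s = rng.random(51)
        oracle = sum(abs(s[i + 1] - s[i]) for i in range(50)) / 50
        assert mean_abs_derivative(s) == pytest.approx(oracle, abs=1e-12)

    def test_entropy_rows_matches_histogram_loop(self, rng):
        V = rng.random((40, 51))
        V[3] = 0.7                                 # constant row
        vec = entropy_rows(V, n_bins=10)
        for i in range(40):
            assert vec[i] == pytest.approx(entropy(V[i], n_bins=10),
                                           abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            entropy([1.0, 2.0], n_bins=1)
        with pytest.raises(ValueError):
            entropy([1.0])
        with pytest.raises(ValueError):
            mean_abs_derivative([1.0])


class TestStandardize:
    def test_means_one_and_idempotent(self, rng):
        H = rng.random((3, 40)) + 0.1
        cmap = make_column_map(4, 10)
        H_std, missing = standardize(H, cmap)
        assert not missing.any()
        for s in range(4):
            cols = cmap.loc[cmap.subject == s, "column"].to_numpy()
            assert np.allclose(H_std[:, cols].mean(axis=1), 1.0, atol=1e-12)
        H2, _ = standardize(H_std, cmap)
        assert np.allclose(H2, H_std, atol=1e-12)

    def test_zero_mean_marked_missing(self):
        H = np.ones((2, 20))
        H[1, :10] = 0.0                       # subject 0, subgraph 1 all zero
        cmap = make_column_map(2, 10)
        H_std, missing = standardize(H, cmap)
        assert missing[0, 1] and not missing[0, 0] and not missing[1, 1]
        assert np.array_equal(H_std[1, :10], H[1, :10])


class TestEnergyEntropyRelation:
    def test_perfect_linearity_gives_r_one(self):
        summary = pd.DataFrame({
            "subject": [0] * 4,
            "subgraph": range(4),
            "energy": np.exp([1.0, 2.0, 3.0, 4.0]),
            "entropy": [0.1, 0.2, 0.3, 0.4],
        })
        r, p = energy_entropy_relation(summary)
        assert r == pytest.approx(1.0)

    def test_coupled_generator_high_correlation(self):
        from dynsubgraphs.synthetic import make_ground_truth, make_partition
        part = make_partition(24, 4)
        gt = make_ground_truth(
            24, 4, part, n_subjects=30, seed=9,
            subgraph_scales=np.geomspace(0.5, 2.0, 4),
            subgraph_switching=np.linspace(0.05, 0.35, 4))
        S, k, T = gt.coeffs_true.shape
        H = gt.coeffs_true.transpose(1, 0, 2).reshape(k, S * T)
        summary = summarize_dynamics(H, make_column_map(S, T))
        r, _ = energy_entropy_relation(summary)
        assert r > 0.9

    def test_decoupled_generator_small_correlation(self):
        from dynsubgraphs.synthetic import make_ground_truth, make_partition
        part = make_partition(24, 4)
        rs = []
        for seed in range(8):
            gt = make_ground_truth(24, 4, part, n_subjects=30,
                                   seed=100 + seed,
                                   energy_ratio=1.0,
                                   adult_switching_increment=0.0,
                                   subgraph_scales=np.ones(4),
                                   subgraph_switching=np.full(4, 0.15))
            S, k, T = gt.coeffs_true.shape
            H = gt.coeffs_true.transpose(1, 0, 2).reshape(k, S * T)
            summary = summarize_dynamics(H, make_column_map(S, T))
            rs.append(energy_entropy_relation(summary)[0])
        assert abs(np.mean(rs)) < 0.5

    def test_shuffle_null_detects_structure(self):
        from dynsubgraphs.synthetic import make_ground_truth, make_partition
        part = make_partition(24, 4)
        gt = make_ground_truth(
            24, 8, part, n_subjects=30, seed=21,
            subgraph_scales=np.geomspace(0.4, 2.5, 8),
            subgraph_switching=np.linspace(0.05, 0.4, 8))
        S, k, T = gt.coeffs_true.shape
        H = gt.coeffs_true.transpose(1, 0, 2).reshape(k, S * T)
        out = shuffle_null_correlation(H, make_column_map(S, T), n_perm=199,
                                       seed=5)
        assert out["pvalue"] <= 0.01
        # pre-shuffled matrix: observed is itself a null draw
        rng = np.random.default_rng(6)
        Hp = rng.permutation(H.ravel()).reshape(H.shape)
        out2 = shuffle_null_correlation(Hp, make_column_map(S, T),
                                        n_perm=199, seed=7)
        assert out2["pvalue"] > 0.01


class TestGroupCompare:
    def test_identical_groups_z_zero(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        z, p = group_compare(vals, labels)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        vals = np.concatenate([x, y])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        # exhaustive enumeration of all 20 assignments of ranks to group a
        obs = stats.rankdata(vals)[:3].sum()
        ranks = stats.rankdata(vals)
        null = [sum(ranks[list(c)]) for c in combinations(range(6), 3)]
        mu = np.mean(null)
        p_exact = np.mean([abs(w - mu) >= abs(obs - mu) for w in null])
        z, p = group_compare(vals, labels, exact=True)
        assert p == pytest.approx(p_exact)
        assert z < 0                    # second group has larger ranks
        _, p_norm = group_compare(vals, labels)
        assert abs(p_norm - p_exact) < 0.05

    def test_sign_convention(self):
        vals = np.array([5.0, 6, 7, 8, 1, 2, 3, 4])
        labels = np.array(["first"] * 4 + ["second"] * 4)
        z, _ = group_compare(vals, labels, group_order=("first", "second"))
        assert z > 0                    # first group has the larger ranks

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(np.arange(4.0), np.array(["a"] * 4))


class TestMotionAndBehavior:
    def test_motion_check_exact_correlation(self):
        motion = np.linspace(0.02, 0.1, 12)
        summary = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "subgraph": np.tile([0, 1], 12),
            "energy": np.repeat(motion, 2),        # equal to motion
            "entropy": np.repeat(motion ** 2, 2),
            "motion": np.repeat(motion, 2),
        })
        out = motion_check(summary)
        r_energy = out.loc[out.metric == "energy", "r"].iloc[0]
        assert r_energy == pytest.approx(1.0)

    def test_motion_constant_errors(self):
        summary = pd.DataFrame({
            "subject": range(5), "subgraph": 0,
            "energy": np.arange(5.0), "entropy": np.arange(5.0),
            "motion": 0.07,
        })
        with pytest.raises(ValueError, match="zero variance"):
            motion_check(summary)

    def test_behavior_signal_detected(self):
        rng = np.random.default_rng(17)
        n = 200
        age = rng.uniform(8, 22, n)
        flex = rng.normal(size=n)
        behavior = flex + rng.normal(size=n)      # SNR 1, age-independent
        r, p = behavior_association(flex, behavior, age, n_perm=499, seed=3)
        assert p <= 0.05 and r > 0.3

    def test_age_only_behavior_not_flagged(self):
        rng = np.random.default_rng(18)
        n = 200
        age = rng.uniform(8, 22, n)
        flex = rng.normal(size=n)
        behavior = 0.5 * age + 0.01 * rng.normal(size=n)
        r, p = behavior_association(flex, behavior, age, n_perm=499, seed=4)
        assert p > 0.05 and abs(r) < 0.2


class TestSummarizeDynamics:
    def test_table_columns_and_values(self, rng):
        H = rng.random((2, 30)) + 0.1
        cmap = make_column_map(3, 10)
        out = summarize_dynamics(H, cmap, group_labels=["a", "a", "b"],
                                 motion=[0.1, 0.2, 0.3])
        assert len(out) == 6
        row = out[(out.subject == 1) & (out.subgraph == 0)].iloc[0]
        block = H[0, 10:20]
        assert row["energy"] == pytest.approx(np.sum(block ** 2))
        assert row["entropy"] == pytest.approx(entropy(block))
        assert row["standardized_energy"] == pytest.approx(
            np.sum((block / block.mean()) ** 2))
        assert row["group"] == "a" and row["motion"] == 0.2
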