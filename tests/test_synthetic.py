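"""Synthetic cohort generator: determinism, planted effects, renderers."""

import numpy as np
import pytest

from dynsubgraphs.coherence import CoherenceConfig
from dynsubgraphs.dynamics import entropy, entropy_rows
from dynsubgraphs.networks import build_multilayer
from dynsubgraphs.synthetic import (attach_motion_confound, make_behavior,
                                    make_ground_truth, make_partition,
                                    render_bold, render_connectivity,
                                    simulate_cohort)


@pytest.fixture(scope="module")
def part():
    return make_partition(24, 4)


class TestGroundTruth:
    def test_determinism(self, part):
        a = make_ground_truth(24, 4, part, n_subjects=10, seed=3)
        b = make_ground_truth(24, 4, part, n_subjects=10, seed=3)
        assert np.array_equal(a.coeffs_true, b.coeffs_true)
        assert np.array_equal(a.basis_true, b.basis_true)

    def test_nonnegativity_and_shapes(self, part):
        gt = make_ground_truth(24, 3, part, n_windows=20, n_subjects=6,
                               seed=0)
        assert gt.basis_true.shape == (24 * 23 // 2, 3)
        assert gt.coeffs_true.shape == (6, 3, 20)
        assert (gt.basis_true >= 0).all() and (gt.coeffs_true >= 0).all()

    def test_no_planted_effect_when_ratio_one(self, part):
        gt = make_ground_truth(24, 4, part, n_subjects=400, seed=8,
                               energy_ratio=1.0,
                               adult_switching_increment=0.0)
        e = (gt.coeffs_true[:, 0, :] ** 2).sum(axis=1)
        adult = gt.group_labels == "adult"
        ratio = e[adult].mean() / e[~adult].mean()
        assert 0.9 < ratio < 1.1

    def test_zero_switching_constant_series(self, part):
        gt = make_ground_truth(24, 4, part, n_subjects=8, seed=5,
                               switching_prob=0.0,
                               adult_switching_increment=0.0)
        flat = gt.coeffs_true.reshape(-1, gt.n_windows)
        assert np.all(np.ptp(flat, axis=1) == 0)
        assert np.all(entropy_rows(flat) == 0)

    def test_energy_ratio_two_scaling_band(self, part):
        gt = make_ground_truth(24, 4, part, n_subjects=100, seed=12,
                               energy_ratio=2.0)
        # direct summation oracle on the stored coefficients
        eff = gt.effect_subgraph
        e = np.array([sum(v * v for v in gt.coeffs_true[s, eff])
                      for s in range(100)])
        adult = gt.group_labels == "adult"
        ratio = e[adult].mean() / e[~adult].mean()
        assert 1.8 ** 2 <= ratio <= 2.2 ** 2

    def test_effect_monotone_in_energy_ratio(self, part):
        diffs = []
        for ratio in (1.0, 1.5, 2.0):
            gt = make_ground_truth(24, 4, part, n_subjects=200, seed=4,
                                   energy_ratio=ratio)
            e = (gt.coeffs_true[:, gt.effect_subgraph, :] ** 2).sum(axis=1)
            adult = gt.group_labels == "adult"
            diffs.append(e[adult].mean() - e[~adult].mean())
        assert diffs[0] < diffs[1] < diffs[2]

    def test_entropy_limit_ln2_under_two_bins(self, part):
        # symmetric fast-switching chain, no transition silence: the
        # two-bin histogram entropy approaches ln 2
        gt = make_ground_truth(24, 1, part, n_windows=4000, n_subjects=4,
                               seed=2, switching_prob=0.5,
                               adult_switching_increment=0.0,
                               transition_silence_prob=0.0)
        ents = [entropy(gt.coeffs_true[s, 0], n_bins=2) for s in range(4)]
        assert np.allclose(ents, np.log(2), atol=0.01)

    def test_invalid_parameters(self, part):
        with pytest.raises(ValueError):
            make_ground_truth(24, 0, part)
        with pytest.raises(ValueError):
            make_ground_truth(24, 2, part, energy_ratio=0.0)
        with pytest.raises(ValueError, match="exceeds"):
            make_ground_truth(24, 99, part)


class TestRenderConnectivity:
    def test_noiseless_exact_product(self, part):
        gt = make_ground_truth(24, 4, part, n_subjects=5, seed=1)
        conn = render_connectivity(gt, 0.0)
        for s, C in enumerate(conn):
            assert np.array_equal(C, gt.basis_true @ gt.coeffs_true[s])

    def test_single_constant_subgraph_repeats_basis(self, part):
        gt = make_ground_truth(24, 1, part, n_subjects=2, seed=1,
                               switching_prob=0.0,
                               adult_switching_increment=0.0)
        gt.coeffs_true[:] = 1.0
        C = render_connectivity(gt, 0.0)[0]
        for t in range(C.shape[1]):
            assert np.array_equal(C[:, t], gt.basis_true[:, 0])

    def test_noise_level_matches_recomputation(self, part):
        gt = make_ground_truth(24, 4, part, n_subjects=4, seed=6)
        conn = render_connectivity(gt, 0.05, seed=77)
        for s, C in enumerate(conn):
            assert (C >= 0).all()
            WH = gt.basis_true @ gt.coeffs_true[s]
            rel = np.linalg.norm(C - WH) / np.linalg.norm(WH)
            # same noise realization recomputed independently
            rng = np.random.default_rng(77)
            for _ in range(s):
                rng.normal(0.0, 0.05, size=WH.shape)
            C2 = np.maximum(WH + rng.normal(0.0, 0.05, size=WH.shape), 0.0)
            rel2 = np.linalg.norm(C2 - WH) / np.linalg.norm(WH)
            assert rel == pytest.approx(rel2, abs=1e-12)

    def test_dimension_mismatch_rejected(self, part):
        gt = make_ground_truth(24, 2, part, n_subjects=2, seed=0)
        gt.basis_true = gt.basis_true[:, :1]
        with pytest.raises(ValueError, match="disagree"):
            render_connectivity(gt, 0.0)


class TestRenderBold:
    def test_determinism(self, part):
        gt = make_ground_truth(24, 4, part, n_windows=21, n_subjects=2,
                               seed=9)
        a = render_bold(gt, seed=50)
        b = render_bold(gt, seed=50)
        for x, y in zip(a.series, b.series):
            assert np.array_equal(x, y)

    def test_shared_latent_high_coherence(self):
        # two regions driven by one noiseless shared latent
        part2 = make_partition(2, 1)
        gt = make_ground_truth(2, 1, part2, n_windows=21, n_subjects=1,
                               seed=3, switching_prob=0.0,
                               adult_switching_increment=0.0)
        cohort = render_bold(gt, noise_sd=0.0)
        ml = build_multilayer(cohort.series[0], CoherenceConfig())
        assert ml.values[0, 1, :].min() > 0.95

    def test_within_higher_than_between_coherence(self, part):
        gt = make_ground_truth(24, 4, part, n_windows=21, n_subjects=1,
                               seed=13)
        cohort = render_bold(gt, noise_sd=1.0)
        ml = build_multilayer(cohort.series[0], CoherenceConfig())
        lab = part.node_to_system
        iu = np.triu_indices(24, 1)
        vals = ml.values[iu[0], iu[1], :].mean(axis=1)
        within = lab[iu[0]] == lab[iu[1]]
        cross_disjoint = (lab[iu[0]] == 2) & (lab[iu[1]] == 3)
        assert vals[within].mean() > vals[cross_disjoint].mean()

    def test_coherence_monotone_in_expression_level(self):
        """Windowed in-band coherence increases with the planted
        coefficient, probed across constant expression levels."""
        part2 = make_partition(6, 1)
        means = []
        for level in (0.1, 0.5, 1.0):
            gt = make_ground_truth(6, 1, part2, n_windows=21, n_subjects=1,
                                   seed=30, switching_prob=0.0,
                                   adult_switching_increment=0.0)
            gt.coeffs_true[:] = level
            cohort = render_bold(gt, noise_sd=1.0, seed=31)
            ml = build_multilayer(cohort.series[0], CoherenceConfig())
            iu = np.triu_indices(6, 1)
            means.append(ml.values[iu[0], iu[1], :].mean())
        assert means[0] < means[1] < means[2]

    def test_band_validation(self, part):
        gt = make_ground_truth(24, 2, part, n_windows=21, n_subjects=1,
                               seed=0)
        with pytest.raises(ValueError, match="band"):
            render_bold(gt, tr_seconds=3.0, band=(0.02, 0.3))


class TestMotionConfound:
    def test_zero_slope_changes_nothing(self, part):
        cohort = simulate_cohort(n_regions=24, n_subjects=6, n_windows=10,
                                 seed=14)
        conf = attach_motion_confound(cohort, 0.0, seed=1)
        for a, b in zip(conf.connectivity, cohort.connectivity):
            assert np.array_equal(a, b)
        assert (conf.motion >= 0).all()

    def test_positive_slope_confounds_every_edge(self, part):
        cohort = simulate_cohort(n_regions=10, n_subjects=200, n_windows=20,
                                 noise_sd=0.0, seed=15)
        conf = attach_motion_confound(cohort, 20.0, seed=2)
        V = np.stack(conf.connectivity).mean(axis=2)       # (S, E)
        m = conf.motion - conf.motion.mean()
        vc = V - V.mean(axis=0)
        corr = (m @ vc) / (np.linalg.norm(m) *
                           np.linalg.norm(vc, axis=0) + 1e-300)
        assert (corr > 0).all()

    def test_requires_connectivity(self, part):
        gt = make_ground_truth(24, 2, part, n_windows=21, n_subjects=2,
                               seed=0)
        cohort = render_bold(gt)
        with pytest.raises(ValueError, match="connectivity"):
            attach_motion_confound(cohort, 1.0)


class TestBehaviorAndCohort:
    def test_behavior_generated_deterministically(self):
        c1 = simulate_cohort(n_regions=24, n_subjects=8, n_windows=10,
                             seed=16)
        c2 = simulate_cohort(n_regions=24, n_subjects=8, n_windows=10,
                             seed=16)
        assert np.array_equal(c1.behavior, c2.behavior)
        assert c1.behavior.shape == (8,)
        assert c1.age is not None and (c1.age > 0).all()

    def test_group_ages_in_study_brackets(self):
        cohort = simulate_cohort(n_regions=24, n_subjects=20, n_windows=10,
                                 seed=17)
        child = cohort.group_labels == "child"
        assert cohort.age[child].min() >= 8.17
        assert cohort.age[child].max() <= 11.42
        assert cohort.age[~child].min() >= 19.58
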