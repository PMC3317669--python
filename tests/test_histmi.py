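"""Histogram grids, joint pmfs and plug-in mutual information."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from itfuse import (
    BinningSpec,
    build_histogram_grid,
    default_bin_count,
    estimate_joint_pmf,
    mi_about_behaviour,
    mi_about_stimulus,
    plugin_mutual_information,
)
from itfuse.histmi import JointPMF, digitize, mi_bits_from_counts
from conftest import make_null_tables


def brute_force_mi(joint):
    """Independent oracle: direct triple-loop over the joint table."""
    joint = np.asarray(joint, dtype=float)
    joint = joint / joint.sum()
    p_l = joint.sum(axis=1)
    p_c = joint.sum(axis=0)
    total = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            p = joint[i, j]
            if p > 0:
                total += p * np.log2(p / (p_l[i] * p_c[j]))
    return total


class TestBinCount:
    @pytest.mark.parametrize("N,d,expected", [(90, 1, 9), (90, 2, 3), (100, 1, 10),
                                              (200, 3, 2)])
    def test_sqrt_total_cells_rule(self, N, d, expected):
        assert default_bin_count(N, d) == expected

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            default_bin_count(3, 1)
        with pytest.raises(ValueError):
            default_bin_count(8, 2)  # would give a single bin per dimension


class TestGrid:
    def test_arithmetic_partition(self):
        edges = build_histogram_grid(np.arange(11.0), 5)
        assert np.allclose(edges, [0, 2, 4, 6, 8, 10])

    def test_closed_top_edge_conserves_counts(self):
        vals = np.arange(11.0)
        edges = build_histogram_grid(vals, 5)
        idx = digitize(vals, edges)
        assert idx.max() == 4 and idx[-1] == 4  # max value in last bin
        assert np.bincount(idx).sum() == len(vals)

    def test_outlier_widens_all_bins(self):
        base = np.linspace(0, 1, 50)
        edges = build_histogram_grid(base, 4)
        spread = build_histogram_grid(np.append(base, 100.0), 4)
        assert np.diff(spread)[0] > np.diff(edges)[0]
        assert spread[0] == 0.0 and spread[-1] == 100.0

    def test_constant_dimension_raises(self):
        with pytest.raises(ValueError, match="constant"):
            build_histogram_grid(np.full(10, 2.0), 4)


class TestJointPMF:
    def test_hand_placed_counts(self):
        # 8 trials on a 2 (level) x 2 x 2 grid, placed by hand
        levels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        responses = np.array(
            [[0.1, 0.1], [0.1, 0.9], [0.1, 0.1], [0.9, 0.9],
             [0.9, 0.1], [0.9, 0.9], [0.9, 0.9], [0.1, 0.1]]
        )
        spec = BinningSpec(rule="fixed", n_bins_per_dim=2)
        pmf = estimate_joint_pmf(levels, responses, spec)
        expected = np.array([[[2, 1], [0, 1]], [[1, 0], [1, 2]]]) / 8.0
        assert np.allclose(pmf.probs, expected)

    def test_normalisation_and_level_marginals(self):
        rng = np.random.default_rng(0)
        levels = rng.choice(["x", "y", "z"], 90)
        responses = rng.standard_normal(90)
        pmf = estimate_joint_pmf(levels, responses)
        assert pmf.probs.sum() == pytest.approx(1.0)
        for lab, n_s in zip(pmf.levels, pmf.level_counts):
            assert n_s == (levels == lab).sum()

    def test_missing_level_raises(self):
        levels = np.array(["a"] * 10)
        with pytest.raises(ValueError, match="zero trials|>= 2"):
            estimate_joint_pmf(levels, np.arange(10.0), expected_levels=["a", "b"])


class TestPluginMI:
    def test_analytic_cases(self):
        assert mi_bits_from_counts(np.array([[2.0, 2.0], [2.0, 2.0]])) == pytest.approx(0.0)
        assert mi_bits_from_counts(np.eye(2) * 5) == pytest.approx(1.0)
        assert mi_bits_from_counts(np.array([[0.4, 0.1], [0.1, 0.4]])) == pytest.approx(
            0.27807, abs=5e-6
        )

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            L = rng.integers(2, 5)
            C = rng.integers(2, 7)
            table = rng.integers(0, 20, size=(L, C)).astype(float)
            table[0, 0] += 1  # nonempty
            assert mi_bits_from_counts(table) == pytest.approx(
                brute_force_mi(table), abs=1e-12
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        L, C = int(rng.integers(2, 4)), int(rng.integers(2, 6))
        counts = rng.integers(0, 10, size=(L, C)).astype(float)
        counts[0, 0] += 1
        mi = float(mi_bits_from_counts(counts))
        p_l = counts.sum(1) / counts.sum()
        h_l = -np.sum(p_l[p_l > 0] * np.log2(p_l[p_l > 0]))
        assert -1e-12 <= mi <= min(h_l, np.log2(C)) + 1e-12


class TestStimulusMI:
    def test_perfect_separation_reaches_label_entropy(self):
        feats, sched = make_null_tables(0, 200)
        sep = (sched["informativeness"] == "low").astype(float) * 10.0
        feats.loc[feats.feature_id == "E", "value"] = np.repeat(sep.to_numpy(), 1)
        prob = mi_about_stimulus(feats, sched, "informativeness", ["E"])
        assert prob.naive_bits == pytest.approx(1.0)

    def test_bivariate_at_least_univariate_on_shared_grid(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            feats, sched = make_null_tables(rep, 120)
            spec = BinningSpec(rule="fixed", n_bins_per_dim=3)
            uni = mi_about_stimulus(feats, sched, "category", ["E"], spec)
            # bivariate on the same R1 edges
            spec2 = BinningSpec(rule="fixed", n_bins_per_dim=3)
            biv = mi_about_stimulus(feats, sched, "category", ["E", "R"], spec2)
            # shared grid: rebuild univariate with the bivariate's R1 edges
            uni_shared = mi_about_stimulus(
                feats, sched, "category", ["E"],
                BinningSpec(edges=[biv.pmf.edges[0]]),
            )
            assert biv.naive_bits >= uni_shared.naive_bits - 1e-12

    def test_label_permutation_kills_information(self):
        rng = np.random.default_rng(7)
        feats, sched = make_null_tables(1, 2000)
        sep = (sched["informativeness"] == "low").astype(float) * 10.0
        feats.loc[feats.feature_id == "E", "value"] = sep.to_numpy()
        sched = sched.copy()
        sched["informativeness"] = rng.permutation(sched["informativeness"].to_numpy())
        prob = mi_about_stimulus(feats, sched, "informativeness", ["E"])
        assert prob.naive_bits < 0.02

    def test_unknown_variable_rejected(self):
        feats, sched = make_null_tables(0, 40)
        with pytest.raises(ValueError, match="unknown stimulus variable"):
            mi_about_stimulus(feats, sched, "luminance", ["E"])


class TestBehaviourMI:
    def test_slow_trials_excluded_from_rt_analysis(self):
        feats, sched = make_null_tables(0, 120)
        sched.loc[:9, "rt"] = 1500.0
        prob = mi_about_behaviour(feats, sched, "rt", ["E"])
        assert len(prob.behaviour_values) == 110
        assert prob.behaviour_values.max() <= 1000.0

    def test_decision_analysis_uses_low_coherence_only(self):
        feats, sched = make_null_tables(0, 120)
        prob = mi_about_behaviour(feats, sched, "decision", ["E"])
        n_low = (sched["informativeness"] == "low").sum()
        assert prob.pmf.N == n_low

    def test_missing_decision_level_raises(self):
        feats, sched = make_null_tables(0, 120)
        sched["decision"] = "face"
        with pytest.raises(ValueError, match="zero trials"):
            mi_about_behaviour(feats, sched, "decision", ["E"])

    def test_affine_rescaling_of_features_leaves_mi_unchanged(self):
        feats, sched = make_null_tables(3, 160)
        prob = mi_about_behaviour(feats, sched, "rt", ["E", "R"])
        feats2 = feats.copy()
        feats2.loc[feats2.feature_id == "E", "value"] *= 3.7
        feats2.loc[feats2.feature_id == "E", "value"] += 11.0
        prob2 = mi_about_behaviour(feats2, sched, "rt", ["E", "R"])
        assert prob2.naive_bits == pytest.approx(prob.naive_bits, abs=1e-12)
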