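"""Pseudocount, per-level CLR, and two-stage hierarchical feature selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from necmil.bags import PatientBag
from necmil.preprocess import (
    PSEUDOCOUNT,
    ClrMatrix,
    CovariateEncoder,
    apply_pseudocount,
    assemble_instances,
    clr_level,
    clr_transform,
    fit_feature_selection,
    information_gain,
    prune_correlated,
    prune_zero_ig,
)
from necmil.synthetic import SimConfig, simulate_cohort
from necmil.taxonomy import TaxonomyTree


class TestPseudocount:
    def test_zeros_become_two_thirds_of_one_read(self):
        assert np.allclose(apply_pseudocount(np.array([0, 1, 2])), [0.66, 1, 2])
        assert np.allclose(apply_pseudocount(np.array([3, 5])), [3, 5])
        assert np.allclose(apply_pseudocount(np.array([0, 0])), [0.66, 0.66])

    def test_negative_input_is_an_error(self):
        with pytest.raises(ValueError):
            apply_pseudocount(np.array([-1, 2]))


class TestClr:
    def test_hand_computed_example(self):
        out = clr_level(np.array([1.0, 2.0, 4.0]))
        assert np.allclose(out, [-math.log(2), 0.0, math.log(2)], atol=1e-9)

    def test_constant_vector_maps_to_zero(self):
        assert np.allclose(clr_level(np.full(5, 3.7)), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        a = clr_level(np.array([1.0, 2.0, 4.0]))
        b = clr_level(np.array([10.0, 20.0, 40.0]))
        assert np.allclose(a, b, atol=1e-12)

    def test_nonpositive_is_an_error(self):
        with pytest.raises(ValueError):
            clr_level(np.array([1.0, 0.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=20),
           st.floats(0.01, 100.0))
    def test_sum_zero_and_scale_invariance_property(self, values, scale):
        v = np.array(values)
        out = clr_level(v)
        assert abs(out.sum()) < 1e-8
        assert np.allclose(out, clr_level(scale * v), atol=1e-8)

    def test_per_level_sums_are_zero(self, tiny_cohort):
        cohort, _ = tiny_cohort
        clr = clr_transform(cohort)
        for rank in set(clr.ranks):
            cols = [j for j, r in enumerate(clr.ranks) if r == rank]
            sums = clr.values[:, cols].sum(axis=1)
            assert np.all(np.abs(sums) < 1e-9)

    def test_single_taxon_level_is_zero(self, tiny_cohort):
        cohort, _ = tiny_cohort
        clr = clr_transform(cohort)
        kingdom_cols = [j for j, r in enumerate(clr.ranks) if r == "kingdom"]
        assert len(kingdom_cols) == 1
        assert np.allclose(clr.values[:, kingdom_cols], 0.0)


def _toy_tree_and_clr(columns: dict, parents: dict, sample_ids=None):
    """Build a small tree + CLR matrix from explicit columns (taxid -> values)."""
    tree = TaxonomyTree()
    for t in sorted(parents, key=lambda t: (parents[t] is not None, t)):
        tree.add_node(t, f"n{t}", "unranked", parent=parents[t])
    taxids = list(columns)
    values = np.column_stack([np.asarray(columns[t], dtype=float) for t in taxids])
    n = values.shape[0]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    clr = ClrMatrix(sample_ids=sample_ids, taxids=taxids,
                    ranks=["unranked"] * len(taxids), values=values)
    return tree, clr


class TestCorrelationPruning:
    def test_identical_child_is_pruned(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        tree, clr = _toy_tree_and_clr({1: x, 2: x}, {1: None, 2: 1})
        sel = prune_correlated(tree, clr, clr.sample_ids)
        assert sel.corr_pruned == {2}

    def test_anticorrelated_child_is_retained(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        tree, clr = _toy_tree_and_clr({1: x, 2: -x}, {1: None, 2: 1})
        sel = prune_correlated(tree, clr, clr.sample_ids)
        assert sel.corr_pruned == set()  # threshold applies to r, not |r|

    def test_zero_variance_column_gets_r_zero_and_is_retained(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        tree, clr = _toy_tree_and_clr({1: x, 2: [2.0] * 5}, {1: None, 2: 1})
        sel = prune_correlated(tree, clr, clr.sample_ids)
        assert sel.corr_pruned == set()
        assert sel.parent_r[2] == 0.0

    def test_pruned_nodes_children_compared_to_retained_ancestor(self):
        rng = np.random.default_rng(0)
        root = rng.normal(size=8)
        child = root + 1e-3 * rng.normal(size=8)        # pruned vs root
        grand = rng.normal(size=8)                      # independent of both
        tree, clr = _toy_tree_and_clr(
            {1: root, 2: child, 3: grand}, {1: None, 2: 1, 3: 2}
        )
        sel = prune_correlated(tree, clr, clr.sample_ids)
        assert sel.corr_pruned == {2}
        # node 3 was compared against node 1, the nearest retained ancestor
        r_expected = stats.pearsonr(grand, root).statistic
        assert sel.parent_r[3] == pytest.approx(r_expected, abs=1e-12)


class TestInformationGain:
    def test_perfect_split_gains_one_bit(self):
        assert information_gain(np.array([5.0, 6.0, 1.0, 2.0]),
                                np.array([1, 1, 0, 0])) == pytest.approx(1.0)

    def test_constant_feature_and_pure_labels_gain_zero(self):
        assert information_gain(np.array([2.0, 2.0, 2.0]), np.array([1, 0, 1])) == 0.0
        assert information_gain(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0])) == 0.0

    def test_matches_exhaustive_midpoint_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.integers(0, 2, size=12)

            def entropy(labels):
                n = len(labels)
                if n == 0:
                    return 0.0
                p = sum(labels) / n
                return -sum(q * math.log2(q) for q in (p, 1 - p) if q > 0)

            best = entropy(list(y))
            xs = np.unique(x)
            for lo, hi in zip(xs, xs[1:]):
                t = (lo + hi) / 2
                left = [yy for xx, yy in zip(x, y) if xx <= t]
                right = [yy for xx, yy in zip(x, y) if xx > t]
                child = (len(left) * entropy(left) + len(right) * entropy(right)) / len(y)
                best = min(best, child)
            expected = entropy(list(y)) - best
            assert information_gain(x, y) == pytest.approx(expected, abs=1e-12)


class TestTwoStageSelection:
    def test_perfect_separator_retained_constant_discarded(self):
        sep = [0.0, 0.0, 1.0, 1.0, 0.5, 0.9]
        const = [1.0] * 6
        tree, clr = _toy_tree_and_clr({1: sep, 2: const}, {1: None, 2: 1})
        sel = prune_correlated(tree, clr, clr.sample_ids)
        sel = prune_zero_ig(clr, sel, [0, 0, 1, 1, 0, 1])
        assert 1 in sel.retained_taxa
        assert 2 in sel.ig_pruned

    def test_all_discarded_is_an_error(self):
        tree, clr = _toy_tree_and_clr({1: [1.0] * 4, 2: [2.0] * 4}, {1: None, 2: 1})
        sel = prune_correlated(tree, clr, clr.sample_ids)
        with pytest.raises(ValueError, match="every taxon"):
            prune_zero_ig(clr, sel, [0, 1, 0, 1])

    def test_partition_invariant(self, tiny_cohort):
        cohort, _ = tiny_cohort
        clr = clr_transform(cohort)
        ids = [s.sample_id for s in cohort.samples]
        sel = fit_feature_selection(cohort.tree, clr, cohort, ids)
        all_taxa = set(sel.retained_taxa) | sel.corr_pruned | sel.ig_pruned
        assert all_taxa == set(clr.taxids)
        assert not set(sel.retained_taxa) & sel.corr_pruned
        assert not set(sel.retained_taxa) & sel.ig_pruned
        assert not sel.corr_pruned & sel.ig_pruned

    def test_leakage_guard(self, tiny_cohort):
        cohort, _ = tiny_cohort
        clr = clr_transform(cohort)
        patients = cohort.patients()[:8]
        train_ids = [s.sample_id for s in cohort.samples if s.patient_id in set(patients)]
        sel = fit_feature_selection(cohort.tree, clr, cohort, train_ids)
        assert set(sel.fitted_on) <= set(train_ids)


class TestInstanceAssembly:
    def test_feature_length_and_metadata_toggle(self, tiny_cohort):
        cohort, _ = tiny_cohort
        clr = clr_transform(cohort)
        ids = [s.sample_id for s in cohort.samples]
        sel = fit_feature_selection(cohort.tree, clr, cohort, ids)
        enc = CovariateEncoder().fit(cohort.metadata, cohort.patients())
        with_md = assemble_instances(clr, sel, cohort, enc, include_metadata=True)
        without = assemble_instances(clr, sel, cohort, include_metadata=False)
        n_taxa = len(sel.retained_taxa)
        assert with_md[0].instances[0].features.shape == (n_taxa + 10,)
        assert without[0].instances[0].features.shape == (n_taxa,)

    def test_encoder_uses_training_statistics_only(self, tiny_cohort):
        cohort, _ = tiny_cohort
        patients = cohort.patients()
        train = patients[:6]
        enc = CovariateEncoder().fit(cohort.metadata, train)
        ga = np.array([cohort.metadata[p].gestational_age_at_birth for p in train])
        test_md = cohort.metadata[patients[-1]]
        vec = enc.transform(test_md)
        expected = (test_md.gestational_age_at_birth - ga.mean()) / ga.std()
        assert vec[0] == pytest.approx(expected)

    def test_instances_sorted_by_day(self, tiny_cohort):
        cohort, _ = tiny_cohort
        clr = clr_transform(cohort)
        ids = [s.sample_id for s in cohort.samples]
        sel = fit_feature_selection(cohort.tree, clr, cohort, ids)
        bags = assemble_instances(clr, sel, cohort, include_metadata=False)
        for b in bags:
            assert b.days == sorted(b.days)
            assert isinstance(b, PatientBag)
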