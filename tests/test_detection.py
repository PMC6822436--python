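"""Core-group detection: presence logic, minimal core nodes, estimator API."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from helpers import brute_force_pcgs, random_instance
from pcgkit import (
    AbundanceTable,
    PCGDetector,
    Phylogeny,
    PresenceParams,
    core_nodes,
    find_pcgs,
    pcg_summary,
    presence_matrix,
)


class TestPresenceParams:
    def test_zero_signal_criterion_rejected(self):
        with pytest.raises(ValueError, match="never present"):
            PresenceParams(min_count=0, min_relabund=0.0)

    @pytest.mark.parametrize("kw", [
        {"min_relabund": 1.0}, {"min_relabund": -0.1},
        {"prevalence": 0.0}, {"prevalence": 1.5}, {"min_count": -1},
    ])
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ValueError):
            PresenceParams(**kw)

    def test_prevalence_threshold_rounding(self):
        # ceil(0.9 * 10) must be 9, not 10 via float representation
        assert PresenceParams(prevalence=0.9).n_required(10) == 9
        assert PresenceParams(prevalence=1.0).n_required(30) == 30
        assert PresenceParams(prevalence=0.5).n_required(3) == 2


class TestPresenceMatrix:
    def test_thresholds(self):
        t = AbundanceTable([[0, 1, 5, 994]], ["s1"], ["a", "b", "c", "d"])
        m = presence_matrix(t, PresenceParams(min_count=1))
        assert not m.loc["s1", "a"] and m.loc["s1", "b"]
        m = presence_matrix(t, PresenceParams(min_count=1, min_relabund=0.01))
        assert not m.loc["s1", "c"]  # 5/1000 = 0.005 < 0.01
        assert m.loc["s1", "d"]

    def test_empty_sample_is_error(self):
        t = AbundanceTable([[1, 0], [0, 0]], ["s1", "s2"], ["a", "b"])
        with pytest.raises(ValueError, match="zero total"):
            presence_matrix(t, PresenceParams())


class TestCoreNodes:
    def test_root_always_core_when_samples_nonempty(self, balanced_tree, worked_table):
        nodes = core_nodes(balanced_tree, worked_table, PresenceParams())
        assert balanced_tree.root in nodes

    def test_ubiquitous_leaf_is_core(self, balanced_tree):
        t = AbundanceTable(
            [[1, 0, 1, 0], [1, 2, 0, 0], [1, 0, 0, 3]],
            ["s1", "s2", "s3"], ["A", "B", "C", "D"],
        )
        nodes = core_nodes(balanced_tree, t, PresenceParams())
        assert any(n.is_tip() and n.name == "A" for n in nodes)

    def test_pooling_makes_clade_core_without_core_members(self, balanced_tree):
        # A: [5,0,2], B: [0,3,0] -> pooled [5,3,2] passes in every sample
        t = AbundanceTable(
            [[5, 0, 1, 0], [0, 3, 1, 0], [2, 0, 1, 0]],
            ["s1", "s2", "s3"], ["A", "B", "C", "D"],
        )
        nodes = core_nodes(balanced_tree, t, PresenceParams())
        sets = {balanced_tree.leaf_set(n) for n in nodes}
        assert frozenset("AB") in sets
        assert frozenset("A") not in sets and frozenset("B") not in sets

    def test_unaligned_inputs_rejected(self, balanced_tree):
        t = AbundanceTable([[1, 2]], ["s1"], ["A", "B"])
        with pytest.raises(ValueError, match="aligned"):
            core_nodes(balanced_tree, t, PresenceParams())


class TestFindPcgs:
    def test_worked_example_two_cherries(self, balanced_tree, worked_table):
        """No single taxon spans all samples, both cherries do; the root is
        excluded by minimality."""
        pcgs = find_pcgs(balanced_tree, worked_table)
        assert [p.member_taxa for p in pcgs] == [("A", "B"), ("C", "D")]
        assert all(p.prevalence == 1.0 for p in pcgs)
        assert all(p.depth == pytest.approx(1.0) for p in pcgs)

    def test_single_ubiquitous_leaf_is_a_depth_zero_pcg(self, balanced_tree):
        t = AbundanceTable(
            [[1, 0, 0, 0], [2, 0, 0, 0]], ["s1", "s2"], ["A", "B", "C", "D"]
        )
        pcgs = find_pcgs(balanced_tree, t)
        assert [p.member_taxa for p in pcgs] == [("A",)]
        assert pcgs[0].depth == 0.0

    def test_sample_below_thresholds_empties_the_set(self, balanced_tree):
        t = AbundanceTable(
            [[50, 0, 20, 0], [0, 30, 10, 0], [1, 1, 1, 1]],
            ["s1", "s2", "s3"], ["A", "B", "C", "D"],
        )
        pcgs = find_pcgs(balanced_tree, t, PresenceParams(min_count=5))
        assert len(pcgs) == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        tree, table, params = random_instance(seed)
        got = {frozenset(p.member_taxa) for p in find_pcgs(tree, table, params)}
        assert got == brute_force_pcgs(tree, table, params)

    @pytest.mark.parametrize("seed", range(15))
    def test_structural_invariants(self, seed):
        """Disjointness, minimality, achieved prevalence, nonemptiness."""
        tree, table, params = random_instance(1000 + seed)
        pcgs = find_pcgs(tree, table, params)
        sets = pcgs.member_sets()
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert sets[i].isdisjoint(sets[j])
        core_sets = {frozenset(tree.leaf_set(n))
                     for n in core_nodes(tree, table, params)}
        for s in sets:
            assert s in core_sets
            assert not any(c < s for c in core_sets)  # minimal
        for p in pcgs:
            assert p.prevalence >= params.prevalence - 1e-12
        # nonemptiness guarantee under the strict default criterion
        strict = find_pcgs(tree, table, PresenceParams())
        assert len(strict) >= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_threshold_monotonicity(self, seed):
        """Stricter thresholds never add a core node, so minimal core nodes
        can only move rootward: each strict PCG contains some looser PCG."""
        tree, table, _ = random_instance(2000 + seed)
        loose = PresenceParams(min_count=1, min_relabund=0.0, prevalence=0.75)
        for strict in (
            PresenceParams(min_count=3, prevalence=0.75),
            PresenceParams(min_count=1, min_relabund=0.05, prevalence=0.75),
            PresenceParams(min_count=1, prevalence=1.0),
        ):
            loose_core = {frozenset(tree.leaf_set(n))
                          for n in core_nodes(tree, table, loose)}
            strict_core = {frozenset(tree.leaf_set(n))
                           for n in core_nodes(tree, table, strict)}
            assert strict_core <= loose_core
            loose_sets = {frozenset(p.member_taxa)
                          for p in find_pcgs(tree, table, loose)}
            for s in find_pcgs(tree, table, strict).member_sets():
                assert any(l <= s for l in loose_sets)

    def test_polytomy_handled_natively(self):
        tree = Phylogeny.from_newick("((A:1,B:1,C:1):1,D:2);")
        t = AbundanceTable(
            [[1, 0, 0, 9], [0, 1, 0, 9], [0, 0, 1, 9]],
            ["s1", "s2", "s3"], ["A", "B", "C", "D"],
        )
        pcgs = find_pcgs(tree, t)
        assert {frozenset(p.member_taxa) for p in pcgs} == {
            frozenset("ABC"), frozenset("D")
        }


class TestSummary:
    def test_dominants_and_coverage(self, balanced_tree, worked_table):
        pcgs = find_pcgs(balanced_tree, worked_table)
        summ = pcg_summary(pcgs, worked_table, balanced_tree)
        assert list(summ.dominants["pcg_1"]) == ["A", "B", "A"]
        assert summ.coverage == pytest.approx(1.0)  # both cherries cover all

    def test_root_pcg_full_coverage(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t = AbundanceTable(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]],
            ["s1", "s2", "s3"], ["A", "B", "C", "D"],
        )
        pcgs = find_pcgs(tree, t)
        assert pcgs.member_sets() == [frozenset("ABCD")]
        summ = pcg_summary(pcgs, t, tree)
        assert np.allclose(summ.coverage_per_sample, 1.0)

    def test_dominant_tie_goes_to_smallest_label(self, balanced_tree):
        # neither A nor B alone spans all samples, so the cherry is the PCG;
        # in s1 its members tie at 2 reads each
        t = AbundanceTable(
            [[2, 2, 0, 0], [3, 0, 0, 0], [0, 3, 0, 0]],
            ["s1", "s2", "s3"], ["A", "B", "C", "D"],
        )
        pcgs = find_pcgs(balanced_tree, t)
        summ = pcg_summary(pcgs, t, balanced_tree)
        pid = summ.per_pcg.loc[summ.per_pcg.member_taxa == "A;B", "pcg_id"].iloc[0]
        assert summ.dominants.loc["s1", pid] == "A"


class TestPCGDetectorEstimator:
    def test_fit_transform_and_membership(self, balanced_tree, worked_table):
        det = PCGDetector(tree=balanced_tree).fit(worked_table.data)
        assert det.n_pcgs_ == 2
        assert det.membership_.to_dict() == {
            "A": "pcg_1", "B": "pcg_1", "C": "pcg_2", "D": "pcg_2"
        }
        feats = det.transform(worked_table.data)
        assert list(feats.columns) == ["pcg_1", "pcg_2"]
        assert np.allclose(feats.sum(axis=1), 1.0)  # cherries cover everything
        assert list(det.get_feature_names_out()) == ["pcg_1", "pcg_2"]

    def test_sklearn_param_protocol(self, balanced_tree):
        det = PCGDetector(tree=balanced_tree, min_count=2)
        cloned = clone(det)
        assert cloned.get_params()["min_count"] == 2
        cloned.set_params(prevalence=0.5)
        assert cloned.prevalence == 0.5

    def test_allow_empty_samples(self, balanced_tree):
        df = pd.DataFrame(
            [[1, 0, 1, 0], [0, 0, 0, 0]], index=["s1", "s2"],
            columns=["A", "B", "C", "D"],
        )
        with pytest.raises(ValueError, match="zero total"):
            PCGDetector(tree=balanced_tree).fit(df)
        det = PCGDetector(tree=balanced_tree, allow_empty_samples=True).fit(df)
        assert det.dropped_samples_ == ["s2"]
        assert det.n_pcgs_ >= 1

    def test_unfitted_transform_raises(self, balanced_tree, worked_table):
        with pytest.raises(ValueError, match="not fitted"):
            PCGDetector(tree=balanced_tree).transform(worked_table.data)
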