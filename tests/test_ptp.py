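import math

import dendropy
import pytest

import barcodelim as b
from barcodelim.errors import ConfigError, InputError
from barcodelim.ptp import (
    _class_loglik,
    _IndexedTree,
    count_delimitations,
    enumerate_delimitations,
)


def tree_from(newick: str) -> b.PhyloTree:
    return b.PhyloTree(
        dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    )


class TestLoglik:
    def test_single_class_closed_form(self):
        # one class with branches {0.5, 1.5}: rate 1, contribution -2
        tree = tree_from("(a:0.5,b:1.5);")
        assert b.ptp_loglik(tree, [0]) == pytest.approx(-2.0)

    def test_one_branch_class(self):
        assert _class_loglik(1, 1.0) == pytest.approx(-1.0)
        assert _class_loglik(2, 2.0) == pytest.approx(-2.0)

    def test_class_split_with_equal_means_additive(self):
        # equal per-class mean branch lengths: splitting changes nothing
        assert _class_loglik(4, 8.0) == pytest.approx(
            _class_loglik(2, 4.0) + _class_loglik(2, 4.0)
        )

    def test_zero_length_branches_never_crash(self):
        tree = tree_from("(a:0.0,(b:0.0,c:0.5):0.2);")
        val = b.ptp_loglik(tree, [0])
        assert math.isfinite(val)

    def test_invalid_antichain_rejected(self):
        tree = tree_from("(a:0.5,(b:0.2,c:0.5):0.2);")
        with pytest.raises(ConfigError):
            b.ptp_loglik(tree, [0, 1])  # root plus tip overlap


class TestEnumeration:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("(a:1,b:1);", 2),
            ("((a:1,b:1):1,c:1);", 3),
            ("((a:1,b:1):1,(c:1,d:1):1);", 5),
            ("(((a:1,b:1):1,c:1):1,d:1);", 4),
            ("((a:1,b:1):1,((c:1,d:1):1,e:1):1);", 7),
        ],
    )
    def test_antichain_counts_match_recursion(self, newick, expected):
        idx = _IndexedTree(tree_from(newick))
        assert count_delimitations(idx) == expected
        assert len(set(enumerate_delimitations(idx))) == expected

    def test_two_tip_tree_exhaustive(self):
        tree = tree_from("(a:0.01,b:0.01);")
        delim = b.ptp_ml_search(tree, method="exact")
        # candidates: 1 species (root) or 2 (both tips); argmax returned
        ll_one = b.ptp_loglik(tree, [0])
        ll_two = b.ptp_loglik(tree, [1, 2])
        assert delim.loglik == pytest.approx(max(ll_one, ll_two))


class TestSearch:
    def test_recovers_two_species_on_eight_tips(self):
        community = b.simulate_community(
            b.CommunityConfig(n_species=2, n_per_species=4, seed=5)
        )
        delim = b.ptp_ml_search(community.genealogy, method="exact")
        assert delim.to_partition() == community.true_partition

    @pytest.mark.parametrize("seed", range(15))
    def test_heuristic_equals_exact_on_small_trees(self, seed):
        community = b.simulate_community(
            b.CommunityConfig(n_species=3, n_per_species=3, seed=seed + 100)
        )
        exact = b.ptp_ml_search(community.genealogy, method="exact")
        heur = b.ptp_ml_search(community.genealogy, method="greedy")
        assert heur.loglik == pytest.approx(exact.loglik)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_loglik_at_least_baselines(self, seed):
        community = b.simulate_community(b.CommunityConfig(seed=seed))
        delim = b.ptp_ml_search(community.genealogy)
        idx = delim._indexed
        tips = [i for i in range(len(idx.nodes)) if idx.is_leaf[i]]
        ll_one = b.ptp_loglik(community.genealogy, [0])
        ll_tips = b.ptp_loglik(community.genealogy, tips)
        assert delim.loglik >= max(ll_one, ll_tips) - 1e-9

    def test_rescaling_preserves_argmax_and_shifts_loglik(self):
        community = b.simulate_community(
            b.CommunityConfig(n_species=3, n_per_species=3, seed=7)
        )
        tree = community.genealogy
        d1 = b.ptp_ml_search(tree, method="exact", min_branch=0.0)
        clone = tree.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 2.0
        d2 = b.ptp_ml_search(b.PhyloTree(clone), method="exact", min_branch=0.0)
        assert d2.species_roots == d1.species_roots
        n_edges = len(d1._indexed.nodes) - 1
        assert d2.loglik == pytest.approx(d1.loglik - n_edges * math.log(2.0))

    def test_unrooted_polytomy_rejected(self):
        tree = tree_from("(a:0.1,b:0.1,c:0.1);")
        with pytest.raises(InputError, match="root"):
            b.ptp_ml_search(tree)

    def test_multi_mode_penalises_free_rates(self, clean_community):
        single = b.ptp_ml_search(clean_community.genealogy, mode="single")
        multi = b.ptp_ml_search(clean_community.genealogy, mode="multi")
        # unpenalised multi would always max out splitting; AIC keeps it sane
        assert multi.n_species <= len(clean_community.alignment)
        assert math.isfinite(multi.aic)
        assert single.n_species >= 1


class TestToPartition:
    def test_one_species(self):
        tree = tree_from("((a:1,b:1):1,c:2);")
        delim = b.ptp_ml_search(tree, method="exact")
        one = b.PTPDelimitation(
            tree=tree, species_roots=frozenset([0]), mode="single",
            loglik=0.0, lambda_speciation=None, lambda_within=1.0,
            n_species=1, _indexed=delim._indexed,
        )
        assert b.delimitation_to_partition(one).n_blocks == 1

    def test_tip_per_species(self):
        tree = tree_from("((a:1,b:1):1,c:2);")
        delim = b.ptp_ml_search(tree, method="exact")
        idx = delim._indexed
        tips = frozenset(i for i in range(len(idx.nodes)) if idx.is_leaf[i])
        all_tips = b.PTPDelimitation(
            tree=tree, species_roots=tips, mode="single", loglik=0.0,
            lambda_speciation=1.0, lambda_within=None, n_species=3,
            _indexed=idx,
        )
        part = b.delimitation_to_partition(all_tips)
        assert part.n_blocks == 3
        assert part.domain == frozenset("abc")

    def test_two_species_blocks_are_subtree_tip_sets(self):
        community = b.simulate_community(
            b.CommunityConfig(n_species=2, n_per_species=4, seed=5)
        )
        part = b.ptp_ml_search(community.genealogy).to_partition()
        assert part.block_set() == community.true_partition.block_set()
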