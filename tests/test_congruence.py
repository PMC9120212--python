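import numpy as np
import pytest

import barcodelim as b
from barcodelim.congruence import round_half_even, truncate
from barcodelim.errors import ConfigError, DomainMismatchError


def P(blocks):
    return b.Partition.from_blocks(
        {f"B{i}": members for i, members in enumerate(blocks)}
    )


def random_partition(rng, ids, max_blocks=5):
    labels = rng.integers(0, max_blocks, size=len(ids))
    return b.Partition({i: f"g{l}" for i, l in zip(ids, labels)})


class TestMatchCount:
    def test_identical_partitions(self):
        p = P([["a", "b"], ["c"], ["d", "e"]])
        assert b.match_count(p, p) == 3

    def test_partial_overlap_hand_case(self):
        pa = P([["a", "b"], ["c", "d"], ["e", "f"]])
        pb = P([["a", "b"], ["c", "d", "e", "f"]])
        assert b.match_count(pa, pb) == 1

    def test_singletons_vs_one_block(self):
        pa = P([["a"], ["b"], ["c"]])
        pb = P([["a", "b", "c"]])
        assert b.match_count(pa, pb) == 0

    def test_disjoint_domains_error(self):
        with pytest.raises(DomainMismatchError):
            b.match_count(P([["a"]]), P([["z"]]))


class TestMatchRatio:
    def test_tcs_column_arithmetic(self):
        # 33 shared blocks out of 53 and 45 -> 0.67 at two decimals
        assert round_half_even(
            b.match_ratio_from_counts(33, 53, 45), 2
        ) == pytest.approx(0.67)

    def test_identical_is_one(self):
        p = P([["a", "b"], ["c"]])
        assert b.match_ratio(p, p) == 1.0

    def test_hand_computation(self):
        pa = P([["a", "b"], ["c", "d"], ["e", "f"]])
        pb = P([["a", "b"], ["c", "d", "e", "f"]])
        assert b.match_ratio(pa, pb) == pytest.approx(0.4)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(12)]
        for _ in range(10):
            pa, pb = random_partition(rng, ids), random_partition(rng, ids)
            assert b.match_ratio(pa, pb) == b.match_ratio(pb, pa)

    def test_count_bound(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(10)]
        for _ in range(20):
            pa, pb = random_partition(rng, ids), random_partition(rng, ids)
            res = b.congruence(pa, pb)
            assert res.n_match <= min(res.n_a, res.n_b)
            assert 0.0 <= res.match_ratio <= 1.0
            assert (res.match_ratio == 1.0) == (pa == pb)

    def test_counts_validation(self):
        with pytest.raises(ConfigError):
            b.match_ratio_from_counts(10, 5, 5)


class TestClassification:
    def test_split(self):
        statuses = b.classify_reference_blocks(
            P([["a", "b", "c"]]), P([["a", "b"], ["c"]])
        )
        assert list(statuses.values()) == ["split"]

    def test_lump_both_labels(self):
        statuses = b.classify_reference_blocks(
            b.Partition({"a": "r1", "b": "r1", "c": "r2", "d": "r2"}),
            P([["a", "b", "c", "d"]]),
        )
        assert statuses == {"r1": "lump", "r2": "lump"}

    def test_mixed_and_lump_case(self):
        statuses = b.classify_reference_blocks(
            b.Partition({"a": "x", "b": "x", "c": "x", "d": "y", "e": "y"}),
            P([["a", "b"], ["c", "d", "e"]]),
        )
        assert statuses == {"x": "mixed", "y": "lump"}

    def test_match(self):
        statuses = b.classify_reference_blocks(
            P([["a", "b"], ["c"]]), P([["a", "b"], ["c"]])
        )
        assert set(statuses.values()) == {"match"}

    def test_every_block_gets_exactly_one_status(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(15)]
        for _ in range(15):
            ref, motu = random_partition(rng, ids), random_partition(rng, ids)
            statuses = b.classify_reference_blocks(ref, motu)
            assert set(statuses) == set(ref.blocks())
            assert set(statuses.values()) <= {"match", "split", "lump", "mixed"}
            all_match = all(s == "match" for s in statuses.values())
            # all reference blocks matching both ways <=> ratio 1
            if b.match_ratio(ref, motu) == 1.0:
                assert all_match

    def test_refinement_bound(self):
        """Splitting one block of A in two changes n_match by at most +2
        (each new block can match at most one reference block) and at least
        -1, and the match-count cap survives (brute-force on random
        partitions)."""
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(12)]
        for _ in range(20):
            pa, pb = random_partition(rng, ids), random_partition(rng, ids)
            base = b.congruence(pb, pa)
            blocks = [m for m in pa.blocks().items() if len(m[1]) >= 2]
            if not blocks:
                continue
            label, members = blocks[0]
            members = sorted(members)
            refined = dict(pa.assignment)
            refined[members[0]] = label + "_x"
            pa2 = b.Partition(refined)
            after = b.congruence(pb, pa2)
            assert after.n_a == base.n_a + 1
            assert -1 <= after.n_match - base.n_match <= 2
            assert after.n_match <= min(after.n_a, after.n_b)


class TestUniversalMatch:
    def test_single_identical_method(self):
        p = P([["a", "b"], ["c"], ["d"]])
        assert b.universal_match_count(p, [p]) == 3

    def test_ref_vs_singletons(self):
        ref = P([["a", "b"], ["c", "d"]])
        singles = P([["a"], ["b"], ["c"], ["d"]])
        assert b.universal_match_count(ref, [ref, singles]) == 0

    def test_three_methods_share_two_blocks(self):
        ref = P([["a"], ["b"], ["c", "d"], ["e", "f"]])
        m1 = P([["a"], ["b"], ["c", "d"], ["e"], ["f"]])
        m2 = P([["a"], ["b"], ["c"], ["d"], ["e", "f"]])
        m3 = P([["a"], ["b"], ["c", "d", "e", "f"]])
        assert b.universal_match_count(ref, [m1, m2, m3]) == 2

    def test_empty_method_list_rejected(self):
        with pytest.raises(ConfigError):
            b.universal_match_count(P([["a"]]), [])


class TestPairwiseSimilarity:
    def test_identical_pair(self):
        p = P([["a", "b"], ["c"]])
        sim = b.pairwise_similarity({"m1": p, "m2": p})
        assert np.allclose(sim.values, 1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(10)]
        parts = {f"m{k}": random_partition(rng, ids) for k in range(4)}
        sim = b.pairwise_similarity(parts)
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)
        assert np.all((sim.values >= 0) & (sim.values <= 1))

    def test_hand_computed_entries(self):
        pa = P([["a", "b"], ["c", "d"], ["e", "f"]])
        pb = P([["a", "b"], ["c", "d", "e", "f"]])
        pc = P([["a"], ["b"], ["c", "d"], ["e", "f"]])
        sim = b.pairwise_similarity({"A": pa, "B": pb, "C": pc})
        assert sim.values[0, 1] == pytest.approx(0.4)       # {ab}: 2*1/(3+2)
        assert sim.values[0, 2] == pytest.approx(4 / 7)     # {cd},{ef}: 2*2/(3+4)
        assert sim.values[1, 2] == pytest.approx(0.0)       # no shared block


class TestDomainPolicy:
    def test_missing_specimens_dropped_with_warning(self, caplog):
        ref = b.Partition({"a": "x", "b": "x", "f9": "q"})
        motu = b.Partition({"a": "m", "b": "m"})
        with caplog.at_level("WARNING"):
            assert b.match_count(ref, motu) == 1
        assert any("dropping" in rec.message for rec in caplog.records)

    def test_strict_mode_errors(self):
        ref = b.Partition({"a": "x", "b": "x", "f9": "q"})
        motu = b.Partition({"a": "m", "b": "m"})
        with pytest.raises(DomainMismatchError):
            b.match_count(ref, motu, strict=True)


class TestRounding:
    @pytest.mark.parametrize(
        "value,half_even,trunc",
        [(0.675, 0.68, 0.67), (0.635294, 0.64, 0.63), (0.665, 0.66, 0.66),
         (0.5882, 0.59, 0.58)],
    )
    def test_both_reporting_conventions(self, value, half_even, trunc):
        assert round_half_even(value, 2) == half_even
        assert truncate(value, 2) == trunc
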