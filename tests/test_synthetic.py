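import numpy as np
import pytest

import barcodelim as b
from barcodelim.errors import ConfigError, InputError


class TestSimulateCommunity:
    def test_same_seed_byte_identical(self):
        c1 = b.simulate_community(b.CommunityConfig(seed=42))
        c2 = b.simulate_community(b.CommunityConfig(seed=42))
        assert c1.alignment.records == c2.alignment.records
        assert c1.true_partition == c2.true_partition
        assert (
            c1.genealogy.tree.as_string(schema="newick")
            == c2.genealogy.tree.as_string(schema="newick")
        )

    def test_different_seed_differs(self):
        c1 = b.simulate_community(b.CommunityConfig(seed=1))
        c2 = b.simulate_community(b.CommunityConfig(seed=2))
        assert c1.alignment.records != c2.alignment.records

    def test_shapes_and_ids_consistent(self, clean_community):
        c = clean_community
        assert len(c.alignment) == 20 and c.alignment.length == 658
        assert c.true_partition.n_blocks == 5
        assert c.genealogy.tip_labels == c.true_partition.domain
        assert frozenset(c.alignment.ids) == c.true_partition.domain

    def test_true_gap_respects_gap_factor(self, clean_community):
        max_within, min_between = clean_community.true_gap()
        cfg = clean_community.config
        assert min_between >= cfg.gap_factor * max_within - 1e-9

    def test_threshold_recovers_truth_by_construction(self, clean_community):
        dm = b.distance_matrix(clean_community.alignment)
        part = b.single_linkage_delimit(dm)
        assert part == clean_community.true_partition

    def test_seed_required(self):
        with pytest.raises(ConfigError):
            b.CommunityConfig()

    def test_saturating_parameters_rejected_before_simulation(self):
        with pytest.raises(ConfigError):
            b.CommunityConfig(intraspecific_theta=0.05, gap_factor=10, seed=1)

    def test_write_bundle(self, tmp_path, clean_community):
        clean_community.write(tmp_path)
        assert (tmp_path / "alignment.fasta").exists()
        back = b.read_fasta(tmp_path / "alignment.fasta")
        assert back.records == clean_community.alignment.records
        assert b.read_partition(
            tmp_path / "true_partition.tsv"
        ) == clean_community.true_partition
        assert b.read_newick(
            tmp_path / "genealogy.nwk"
        ).tip_labels == clean_community.genealogy.tip_labels


class TestRecentPairs:
    @pytest.mark.parametrize("seed", [3, 14, 27])
    def test_pair_lumped_by_threshold_clustering(self, seed):
        c = b.simulate_community(
            b.CommunityConfig(n_recent_pairs=1, seed=seed)
        )
        (event,) = [e for e in c.event_log if e["type"] == "recent_pair"]
        sp_a, sp_b = event["species"]
        dm = b.distance_matrix(c.alignment)
        part = b.single_linkage_delimit(dm)
        blocks = c.true_partition.blocks()
        motus = part.blocks()
        motu_of = {sid: lab for sid, lab in part.assignment.items()}
        a_labels = {motu_of[s] for s in blocks[sp_a]}
        b_labels = {motu_of[s] for s in blocks[sp_b]}
        assert a_labels & b_labels  # lumped into a shared MOTU
        assert b.match_ratio(c.true_partition, part) < 1.0


class TestGeoSplits:
    def test_event_logged_and_divergence_elevated(self):
        c = b.simulate_community(b.CommunityConfig(n_geo_splits=1, seed=9))
        (event,) = [e for e in c.event_log if e["type"] == "geo_split"]
        theta = c.config.intraspecific_theta
        assert event["divergence"] >= 2.9 * theta
        groups = event["haplogroups"]
        assert len(groups) == 2 and all(groups)


class TestIntrogression:
    def test_nearest_neighbour_is_donor(self):
        c = b.simulate_community(b.CommunityConfig(seed=8))
        c2 = b.inject_introgression(c, "sp01", "sp02", 1, seed=1)
        (event,) = [e for e in c2.event_log if e["type"] == "introgression"]
        target = event["specimens"][0]
        dm = b.distance_matrix(c2.alignment)
        i = dm.ids.index(target)
        row = dm.values[i].copy()
        row[i] = np.inf
        nearest = dm.ids[int(np.argmin(row))]
        assert c2.true_partition.assignment[nearest] == "sp01"

    def test_zero_specimens_is_identity(self):
        c = b.simulate_community(b.CommunityConfig(seed=8))
        c2 = b.inject_introgression(c, "sp01", "sp02", 0)
        assert c2.alignment.records == c.alignment.records

    def test_unknown_species_rejected(self):
        c = b.simulate_community(b.CommunityConfig(seed=8))
        with pytest.raises(InputError):
            b.inject_introgression(c, "nope", "sp02", 1)

    def test_recipient_classified_mixed_or_lumped(self):
        c = b.simulate_community(b.CommunityConfig(seed=8))
        c2 = b.inject_introgression(c, "sp01", "sp02", 1, seed=1)
        dm = b.distance_matrix(c2.alignment)
        part = b.single_linkage_delimit(dm)
        statuses = b.classify_reference_blocks(c2.true_partition, part)
        assert statuses["sp02"] in {"mixed", "lump", "split"}
        assert statuses["sp02"] != "match"


class TestMakePartitionPair:
    def test_requested_counts_recovered(self):
        ref, motu = b.make_partition_pair(10, 2, 1, 0, seed=0)
        assert b.match_count(ref, motu) == 2
        statuses = b.classify_reference_blocks(ref, motu)
        assert sum(s == "split" for s in statuses.values()) == 1
        assert sum(s == "lump" for s in statuses.values()) == 0

    def test_lump_labels_counted(self):
        ref, motu = b.make_partition_pair(12, 1, 0, 2, seed=3)
        statuses = b.classify_reference_blocks(ref, motu)
        assert sum(s == "lump" for s in statuses.values()) == 4

    def test_no_events_identical_partitions(self):
        ref, motu = b.make_partition_pair(6, 4, 0, 0, seed=1)
        assert ref == motu
        assert b.match_ratio(ref, motu) == 1.0

    def test_infeasible_request_names_bound(self):
        with pytest.raises(ConfigError, match="needs >= "):
            b.make_partition_pair(4, 2, 1, 1, seed=0)

    def test_deterministic_given_seed(self):
        a = b.make_partition_pair(20, 3, 2, 1, seed=5)
        c = b.make_partition_pair(20, 3, 2, 1, seed=5)
        assert a[0] == c[0] and a[1] == c[1]


class TestFromCounts:
    def test_table_like_counts_realised_exactly(self):
        ref, motu = b.make_partition_pair_from_counts(
            266, n_ref=45, n_motu=53, n_match=33, seed=0
        )
        assert ref.n_blocks == 45 and motu.n_blocks == 53
        assert b.match_count(ref, motu) == 33
        assert b.congruence(ref, motu).match_ratio == pytest.approx(
            2 * 33 / (53 + 45)
        )

    def test_infeasible_counts_rejected(self):
        # ref fully matched but one extra MOTU has nowhere to come from
        with pytest.raises(ConfigError):
            b.make_partition_pair_from_counts(10, 3, 4, 3, seed=0)
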