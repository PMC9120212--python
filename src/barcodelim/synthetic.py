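"""Synthetic barcode communities with known species boundaries.

The generator emulates the data regime single-locus delimitation studies
assume: a fixed-length (658 bp) alignment of multi-species communities with
intraspecific haplotype variation, a controllable barcode gap, and optional
discordance -- introgressed haplotypes, species pairs with near-zero
mitochondrial divergence but distinct (morphology-style) labels, and
geographically substructured species.

Genealogy model
---------------
Within-species subtrees are random Kingman coalescent shapes rescaled so the
mean pairwise path distance equals ``intraspecific_theta`` exactly.  Species
sit on a random ultrametric backbone whose join depths are drawn uniformly
in [B/2, B] with B = gap_factor x (largest within-species pairwise path
distance), so the minimum between-species divergence is at least
``gap_factor`` times the deepest within-species divergence.  Sequences
evolve along the genealogy under JC69 (exact per-site transition sampling),
so simulation and in-pipeline distances share one model.

``make_partition_pair`` builds reference/MOTU partition pairs realising
requested exact-match, split and lump counts -- deterministic fixtures for
the congruence statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dataio import (
    Alignment,
    Partition,
    PhyloTree,
    write_fasta,
    write_newick,
    write_partition,
)
from .errors import ConfigError, InputError

_BASES = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)

#: divergence (in units of theta) between the two haplogroups of a
#: geographically substructured species
GEO_SPLIT_FACTOR = 3.0


@dataclass(frozen=True)
class CommunityConfig:
    n_species: int = 5
    n_per_species: Union[int, Tuple[int, int]] = 4
    seq_length: int = 658
    intraspecific_theta: float = 0.005
    gap_factor: float = 10.0
    n_introgression: int = 0
    n_recent_pairs: int = 0
    n_geo_splits: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducible simulation")
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        if self.gap_factor <= 0:
            raise ConfigError("gap_factor must be > 0")
        if self.intraspecific_theta < 0:
            raise ConfigError("intraspecific_theta must be >= 0")
        for name in ("n_introgression", "n_recent_pairs", "n_geo_splits"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if 2 * self.n_recent_pairs + self.n_geo_splits > self.n_species:
            raise ConfigError(
                "not enough species for the requested recent pairs and geo splits"
            )
        # saturation guard: deepest between-species paths must stay well
        # inside the invertible JC69 range
        barrier = self.gap_factor * max(
            GEO_SPLIT_FACTOR if self.n_geo_splits else 2.0, 2.0
        ) * self.intraspecific_theta
        if 2 * barrier > 0.9:
            raise ConfigError(
                "gap_factor x theta too large: between-species divergence "
                "would saturate JC69 distances"
            )


@dataclass
class SyntheticCommunity:
    alignment: Alignment
    true_partition: Partition
    genealogy: PhyloTree
    event_log: List[dict]
    config: CommunityConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.alignment, outdir / "alignment.fasta")
        write_newick(self.genealogy, outdir / "genealogy.nwk")
        write_partition(self.true_partition, outdir / "true_partition.tsv")
        with open(outdir / "events.json", "w") as fh:
            json.dump(self.event_log, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def true_gap(self) -> Tuple[float, float]:
        """(max within-species, min between-species) patristic distance."""
        import dendropy

        pdm = self.genealogy.tree.phylogenetic_distance_matrix()
        labels = {t.label: t for t in self.genealogy.tree.taxon_namespace}
        assign = self.true_partition.assignment
        max_within, min_between = 0.0, math.inf
        ids = list(assign)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = pdm.patristic_distance(labels[a], labels[b])
                if assign[a] == assign[b]:
                    max_within = max(max_within, d)
                else:
                    min_between = min(min_between, d)
        return max_within, min_between


class _Clade:
    """A lineage under ultrametric construction: newick body + root height."""

    __slots__ = ("newick", "height", "tips")

    def __init__(self, newick: str, height: float, tips: List[str]):
        self.newick = newick
        self.height = height
        self.tips = tips


def _coalescent_clade(tips: Sequence[str], theta: float, rng) -> _Clade:
    """Random Kingman shape over `tips`, rescaled so the mean pairwise path
    distance equals `theta` exactly (singletons and theta=0 degenerate to
    zero-length shapes)."""
    tips = list(tips)
    if len(tips) == 1:
        return _Clade(tips[0], 0.0, tips)
    lineages = [_Clade(t, 0.0, [t]) for t in tips]
    t = 0.0
    weighted = 0.0  # sum over joins of n_left * n_right * 2 * depth
    n_pairs = len(tips) * (len(tips) - 1) // 2
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        weighted += len(a.tips) * len(b.tips) * 2.0 * t
        newick = (
            f"({a.newick}:{t - a.height:.10f},{b.newick}:{t - b.height:.10f})"
        )
        lineages = lineages[:i] + [_Clade(newick, t, a.tips + b.tips)] + lineages[i:]
    clade = lineages[0]
    mean_pairwise = weighted / n_pairs
    if mean_pairwise <= 0 or theta <= 0:
        return _rescale(clade, 0.0)
    return _rescale(clade, theta / mean_pairwise)


def _rescale(clade: _Clade, factor: float) -> _Clade:
    """Multiply every branch length in the clade's newick body by `factor`."""
    import re

    def repl(m):
        return f":{float(m.group(1)) * factor:.10f}"

    return _Clade(
        re.sub(r":([0-9.eE+-]+)", repl, clade.newick),
        clade.height * factor,
        clade.tips,
    )


def _relabel_interleaved(clade: _Clade, ids_a, ids_b) -> _Clade:
    """Reassign tip names so the two id sets alternate along the clade's
    tree-traversal tip order."""
    import re

    desired: List[str] = []
    queues = [list(ids_a), list(ids_b)]
    turn = 0
    for _ in clade.tips:
        if not queues[turn % 2]:
            turn += 1
        desired.append(queues[turn % 2].pop(0))
        turn += 1
    mapping = dict(zip(clade.tips, desired))
    pattern = "|".join(
        re.escape(t) for t in sorted(clade.tips, key=len, reverse=True)
    )
    newick = re.sub(pattern, lambda m: mapping[m.group(0)], clade.newick)
    return _Clade(newick, clade.height, desired)


def _join(a: _Clade, b: _Clade, depth: float) -> _Clade:
    newick = f"({a.newick}:{depth - a.height:.10f},{b.newick}:{depth - b.height:.10f})"
    return _Clade(newick, depth, a.tips + b.tips)


def _jc69_mutate(seq: np.ndarray, branch: float, rng) -> np.ndarray:
    """Evolve a base-index sequence along a branch under JC69."""
    p_sub = 0.75 * (1.0 - math.exp(-4.0 * branch / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p_sub)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


def _evolve_sequences(tree: PhyloTree, seq_length: int, rng) -> Dict[str, str]:
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: Dict[int, np.ndarray] = {}
    out: Dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = root_seq
        else:
            parent = seqs[id(node.parent_node)]
            seqs[id(node)] = _jc69_mutate(parent, node.edge.length or 0.0, rng)
        if node.is_leaf():
            idxs = seqs[id(node)]
            out[node.taxon.label] = "".join("ACGT"[i] for i in idxs)
    return out


def simulate_community(cfg: CommunityConfig) -> SyntheticCommunity:
    """Simulate a barcode community; same seed gives byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    theta = cfg.intraspecific_theta
    event_log: List[dict] = []

    if isinstance(cfg.n_per_species, tuple):
        lo, hi = cfg.n_per_species
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_species)]
    else:
        sizes = [int(cfg.n_per_species)] * cfg.n_species
    species = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]
    specimen_ids = {
        sp: [f"{sp}_{k + 1:02d}" for k in range(sizes[i])]
        for i, sp in enumerate(species)
    }

    # assign roles: recent pairs and geo splits on disjoint species sets
    pool = list(range(cfg.n_species))
    rng.shuffle(pool)
    recent_pairs = [
        (pool.pop(), pool.pop()) for _ in range(cfg.n_recent_pairs)
    ]
    geo_species = [pool.pop() for _ in range(cfg.n_geo_splits)]

    # within-species subtrees; a "recent pair" shares one coalescent pool
    # (near-zero mitochondrial divergence between the two labelled species)
    paired = {i for pair in recent_pairs for i in pair}
    clades: Dict[int, _Clade] = {}
    pair_clades: List[_Clade] = []
    for a, b_idx in recent_pairs:
        union = specimen_ids[species[a]] + specimen_ids[species[b_idx]]
        clade = _coalescent_clade(union, theta, rng)
        # incomplete lineage sorting: interleave the two species' labels in
        # tree-traversal order so both species carry haplotypes from every
        # deep pool lineage (no clade of >= 2 tips is pure-label)
        clade = _relabel_interleaved(
            clade, specimen_ids[species[a]], specimen_ids[species[b_idx]]
        )
        pair_clades.append(clade)
        event_log.append(
            {
                "type": "recent_pair",
                "species": [species[a], species[b_idx]],
                "divergence": 0.0,
            }
        )
    max_within = max([2 * c.height for c in pair_clades], default=0.0)
    for i, sp in enumerate(species):
        if i in paired:
            continue
        tips = specimen_ids[sp]
        if i in geo_species and len(tips) >= 2:
            half = max(1, len(tips) // 2)
            sub_a = _coalescent_clade(tips[:half], theta, rng)
            sub_b = _coalescent_clade(tips[half:], theta, rng)
            depth = max(
                GEO_SPLIT_FACTOR * theta / 2.0,
                sub_a.height + theta / 100.0,
                sub_b.height + theta / 100.0,
            )
            clades[i] = _join(sub_a, sub_b, depth)
            event_log.append(
                {
                    "type": "geo_split",
                    "species": sp,
                    "haplogroups": [sub_a.tips, sub_b.tips],
                    "divergence": 2 * depth,
                }
            )
        else:
            clades[i] = _coalescent_clade(tips, theta, rng)
        max_within = max(max_within, 2 * clades[i].height)
    if max_within <= 0:
        max_within = max(theta, 1e-4)

    barrier = cfg.gap_factor * max_within

    lineages: List[_Clade] = list(pair_clades)
    lineages.extend(clades[i] for i in range(cfg.n_species) if i not in paired)

    # backbone: random joins at depths uniform in [B/2, B]
    if len(lineages) > 1:
        depths = np.sort(rng.uniform(barrier / 2.0, barrier, size=len(lineages) - 1))
        for depth in depths:
            k = len(lineages)
            i, j = sorted(rng.choice(k, size=2, replace=False))
            b = lineages.pop(j)
            a = lineages.pop(i)
            depth = max(depth, a.height + theta / 100.0, b.height + theta / 100.0)
            lineages.insert(i, _join(a, b, depth))
    newick = lineages[0].newick + ";"

    import dendropy

    tree = PhyloTree(
        dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    )
    seqs = _evolve_sequences(tree, cfg.seq_length, rng)
    ordered = [sid for sp in species for sid in specimen_ids[sp]]
    alignment = Alignment({sid: seqs[sid] for sid in ordered})
    true_partition = Partition(
        {sid: sp for sp in species for sid in specimen_ids[sp]}
    )
    community = SyntheticCommunity(
        alignment=alignment,
        true_partition=true_partition,
        genealogy=tree,
        event_log=event_log,
        config=cfg,
    )

    for _ in range(cfg.n_introgression):
        donor, recipient = rng.choice(cfg.n_species, size=2, replace=False)
        community = inject_introgression(
            community, species[int(donor)], species[int(recipient)], 1, rng=rng
        )
    return community


def inject_introgression(
    community: SyntheticCommunity,
    donor_species: str,
    recipient_species: str,
    n_specimens: int,
    rng=None,
    seed: Optional[int] = None,
) -> SyntheticCommunity:
    """Replace recipient specimens' sequences with mutated donor haplotypes.

    True-partition labels are unchanged (the morphology still says
    'recipient'); the transfer is recorded in the event log.
    """
    blocks = community.true_partition.blocks()
    for sp in (donor_species, recipient_species):
        if sp not in blocks:
            raise InputError(f"unknown species label {sp!r}")
    recipients = sorted(blocks[recipient_species])
    donors = sorted(blocks[donor_species])
    if n_specimens > len(recipients):
        raise InputError(
            f"cannot introgress {n_specimens} specimens into "
            f"{recipient_species!r} of size {len(recipients)}"
        )
    if n_specimens == 0:
        return community
    if rng is None:
        rng = np.random.default_rng(
            seed if seed is not None else community.config.seed
        )
    theta = max(community.config.intraspecific_theta, 0.0)
    lut = {b: i for i, b in enumerate("ACGT")}
    records = dict(community.alignment.records)
    chosen = [
        recipients[int(i)]
        for i in rng.choice(len(recipients), size=n_specimens, replace=False)
    ]
    for target in chosen:
        src = donors[int(rng.integers(len(donors)))]
        donor_seq = np.array([lut[b] for b in records[src]], dtype=np.int64)
        mutated = _jc69_mutate(donor_seq, theta / 2.0, rng)
        records[target] = "".join("ACGT"[i] for i in mutated)
    event_log = community.event_log + [
        {
            "type": "introgression",
            "donor": donor_species,
            "recipient": recipient_species,
            "specimens": chosen,
        }
    ]
    return SyntheticCommunity(
        alignment=Alignment(records),
        true_partition=community.true_partition,
        genealogy=community.genealogy,
        event_log=event_log,
        config=community.config,
    )


# ---------------------------------------------------------------------------
# exact-count partition pairs
# ---------------------------------------------------------------------------

def make_partition_pair(
    domain_size: int,
    n_match: int,
    n_split_events: int,
    n_lump_events: int,
    seed: int,
    split_ways: Optional[Sequence[int]] = None,
    lump_ways: Optional[Sequence[int]] = None,
) -> Tuple[Partition, Partition]:
    """Construct (P_ref, P_motu) with exact congruence counts.

    Each split event turns one reference block into ``split_ways[i]`` MOTUs
    (default 2); each lump event merges ``lump_ways[j]`` reference blocks
    (default 2) into one MOTU.  ``match_count`` recovers ``n_match`` exactly
    and ``classify_reference_blocks`` yields exactly ``n_split_events``
    'split' labels and ``sum(lump_ways)`` 'lump' labels.  Construction is
    deterministic given the seed.
    """
    split_ways = list(split_ways) if split_ways is not None else [2] * n_split_events
    lump_ways = list(lump_ways) if lump_ways is not None else [2] * n_lump_events
    if len(split_ways) != n_split_events or len(lump_ways) != n_lump_events:
        raise ConfigError("ways lists must match the event counts")
    if any(k < 2 for k in split_ways):
        raise ConfigError("each split event needs fan-out >= 2")
    if any(m < 2 for m in lump_ways):
        raise ConfigError("each lump event needs >= 2 reference blocks")
    if n_match < 0:
        raise ConfigError("n_match must be >= 0")
    min_specimens = n_match + sum(split_ways) + sum(lump_ways)
    if min_specimens > domain_size:
        raise ConfigError(
            f"infeasible request: needs >= {min_specimens} specimens "
            f"(matches {n_match} x1, splits {sum(split_ways)}, "
            f"lumps {sum(lump_ways)}), domain has {domain_size}"
        )
    if min_specimens == 0:
        if domain_size > 0:
            raise ConfigError(
                "no blocks requested but the domain is non-empty"
            )
        raise ConfigError("empty domain")

    rng = np.random.default_rng(seed)
    specimens = [f"s{i + 1:04d}" for i in range(domain_size)]
    rng.shuffle(specimens)
    it = iter(specimens)

    ref_blocks: Dict[str, List[str]] = {}
    motu_blocks: Dict[str, List[str]] = {}
    # units: every slot a leftover specimen may later be appended to, as
    # (ref_label, motu_label) pairs that preserve all counts
    slots: List[Tuple[str, str]] = []

    for i in range(n_match):
        label = f"R{i + 1:03d}"
        sid = next(it)
        ref_blocks[label] = [sid]
        motu_blocks[f"M{label}"] = ref_blocks[label]  # same list: stay identical
        slots.append((label, f"M{label}"))
    for i, k in enumerate(split_ways):
        rlabel = f"RS{i + 1:03d}"
        ref_blocks[rlabel] = []
        for part in range(k):
            mlabel = f"MS{i + 1:03d}.{part + 1}"
            sid = next(it)
            ref_blocks[rlabel].append(sid)
            motu_blocks[mlabel] = [sid]
            slots.append((rlabel, mlabel))
    for j, m in enumerate(lump_ways):
        mlabel = f"ML{j + 1:03d}"
        motu_blocks[mlabel] = []
        for part in range(m):
            rlabel = f"RL{j + 1:03d}.{part + 1}"
            sid = next(it)
            ref_blocks[rlabel] = [sid]
            motu_blocks[mlabel].append(sid)
            slots.append((rlabel, mlabel))

    for sid in it:  # distribute leftovers without changing any count
        rlabel, mlabel = slots[int(rng.integers(len(slots)))]
        ref_blocks[rlabel].append(sid)
        if motu_blocks[mlabel] is not ref_blocks[rlabel]:
            motu_blocks[mlabel].append(sid)

    p_ref = Partition.from_blocks(ref_blocks)
    p_motu = Partition.from_blocks(motu_blocks)
    return p_ref, p_motu


def make_partition_pair_from_counts(
    domain_size: int, n_ref: int, n_motu: int, n_match: int, seed: int
) -> Tuple[Partition, Partition]:
    """A pair whose block counts and exact-match count equal the request.

    Solves for a feasible mix of k-way split and m-way lump events, then
    defers to :func:`make_partition_pair`.
    """
    if n_match > min(n_ref, n_motu):
        raise ConfigError("n_match cannot exceed either block count")
    extra_ref = n_ref - n_match
    extra_motu = n_motu - n_match
    solution = None
    for s in range(extra_ref + 1):
        rem_ref = extra_ref - s
        for lump_count in range(rem_ref // 2 + 1):
            if (lump_count == 0) != (rem_ref == 0):
                continue
            rem_motu = extra_motu - lump_count
            if (s == 0) != (rem_motu == 0):
                continue
            if s > 0 and rem_motu < 2 * s:
                continue
            if lump_count > 0 and rem_ref < 2 * lump_count:
                continue
            solution = (s, lump_count, rem_motu, rem_ref)
            break
        if solution:
            break
    if solution is None:
        raise ConfigError(
            f"no split/lump mix realises n_ref={n_ref}, n_motu={n_motu}, "
            f"n_match={n_match}"
        )
    s, lump_count, total_k, total_m = solution
    split_ways = _distribute(total_k, s)
    lump_ways = _distribute(total_m, lump_count)
    return make_partition_pair(
        domain_size, n_match, s, lump_count, seed,
        split_ways=split_ways, lump_ways=lump_ways,
    )


def _distribute(total: int, n_events: int) -> List[int]:
    if n_events == 0:
        return []
    ways = [2] * n_events
    ways[0] += total - 2 * n_events
    return ways
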