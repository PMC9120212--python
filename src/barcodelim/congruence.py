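"""Partition-congruence statistics: exact matches, match ratio, split/lump
classification, universal matches, and the pairwise method-similarity matrix.

The match ratio between a MOTU partition (N_mol blocks) and a reference
morphospecies partition (N_morph blocks) is

    match_ratio = 2 * N_match / (N_mol + N_morph),

where N_match counts blocks (specimen sets) present identically in both
partitions.  It is 1 exactly when the two partitions are identical.

Each reference block is further classified against the MOTUs:

* match -- exactly one MOTU equals the block;
* split -- the block's members occupy >= 2 MOTUs, all of them subsets;
* lump  -- the members sit in one MOTU that is a strict superset;
* mixed -- >= 2 MOTUs, at least one containing non-members too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .dataio import DistanceMatrix, Partition
from .errors import ConfigError, DomainMismatchError

logger = logging.getLogger(__name__)


@dataclass
class CongruenceResult:
    n_match: int
    n_a: int
    n_b: int
    match_ratio: float
    per_label: Dict[str, str]


@dataclass
class MethodSimilarity:
    methods: List[str]
    values: np.ndarray

    def to_distance_matrix(self) -> DistanceMatrix:
        from .ordination import similarity_to_distance

        return similarity_to_distance(self)


def _common_domain(p_a: Partition, p_b: Partition, strict: bool = False):
    dom_a, dom_b = p_a.domain, p_b.domain
    common = dom_a & dom_b
    if not common:
        raise DomainMismatchError(
            "partitions share no specimens", only_a=dom_a, only_b=dom_b
        )
    if dom_a != dom_b:
        if strict:
            raise DomainMismatchError(
                f"partition domains differ by {sorted(dom_a ^ dom_b)[:10]}",
                only_a=dom_a - common,
                only_b=dom_b - common,
            )
        dropped = sorted(dom_a ^ dom_b)
        logger.warning(
            "dropping %d specimens missing from one partition: %s",
            len(dropped), dropped[:10],
        )
        return p_a.restrict(common), p_b.restrict(common)
    return p_a, p_b


def match_count(p_a: Partition, p_b: Partition, strict: bool = False) -> int:
    """Number of specimen sets appearing as a block in both partitions."""
    p_a, p_b = _common_domain(p_a, p_b, strict=strict)
    return len(p_a.block_set() & p_b.block_set())


def match_ratio(p_a: Partition, p_b: Partition, strict: bool = False) -> float:
    """2 * N_match / (N_a + N_b); full precision (round only for reports)."""
    p_a, p_b = _common_domain(p_a, p_b, strict=strict)
    n_match = len(p_a.block_set() & p_b.block_set())
    return 2.0 * n_match / (p_a.n_blocks + p_b.n_blocks)


def match_ratio_from_counts(n_match: int, n_mol: int, n_morph: int) -> float:
    """The same statistic straight from counts (report bypass mode)."""
    if n_match < 0 or n_mol <= 0 or n_morph <= 0:
        raise ConfigError("counts must be positive")
    if n_match > min(n_mol, n_morph):
        raise ConfigError("n_match cannot exceed either block count")
    return 2.0 * n_match / (n_mol + n_morph)


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding, as used for reported ratios."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncation toward zero -- the other convention seen in printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


def classify_reference_blocks(
    p_ref: Partition, p_motu: Partition, strict: bool = False
) -> Dict[str, str]:
    """Status (match/split/lump/mixed) of every reference block vs the MOTUs."""
    p_ref, p_motu = _common_domain(p_ref, p_motu, strict=strict)
    motu_blocks = list(p_motu.block_set())
    statuses: Dict[str, str] = {}
    for label, block in p_ref.blocks().items():
        touching = [m for m in motu_blocks if m & block]
        if len(touching) == 1:
            m = touching[0]
            if m == block:
                statuses[label] = "match"
            else:  # strict superset
                statuses[label] = "lump"
        else:
            if all(m <= block for m in touching):
                statuses[label] = "split"
            else:
                statuses[label] = "mixed"
    return statuses


def congruence(p_ref: Partition, p_motu: Partition, strict: bool = False) -> CongruenceResult:
    p_ref_c, p_motu_c = _common_domain(p_ref, p_motu, strict=strict)
    n_match = len(p_ref_c.block_set() & p_motu_c.block_set())
    return CongruenceResult(
        n_match=n_match,
        n_a=p_motu_c.n_blocks,
        n_b=p_ref_c.n_blocks,
        match_ratio=2.0 * n_match / (p_motu_c.n_blocks + p_ref_c.n_blocks),
        per_label=classify_reference_blocks(p_ref_c, p_motu_c),
    )


def universal_match_count(
    p_ref: Partition, motu_partitions: Sequence[Partition], strict: bool = False
) -> int:
    """Reference blocks recovered identically by every delimitation method."""
    if not motu_partitions:
        raise ConfigError("need at least one MOTU partition")
    blocks = p_ref.block_set()
    for p in motu_partitions:
        ref_c, p_c = _common_domain(p_ref, p, strict=strict)
        blocks = blocks & p_c.block_set()
    return len(blocks)


def pairwise_similarity(
    partitions: Mapping[str, Partition], strict: bool = False
) -> MethodSimilarity:
    """Symmetric matrix of match ratios over all method pairs (diagonal 1)."""
    if len(partitions) < 2:
        raise ConfigError("need at least 2 partitions")
    names = list(partitions)
    n = len(names)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = match_ratio(partitions[names[i]], partitions[names[j]], strict=strict)
            values[i, j] = values[j, i] = r
    return MethodSimilarity(methods=names, values=values)
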