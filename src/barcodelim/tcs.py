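"""Statistical-parsimony delimitation (TCS-style networks as MOTUs).

Haplotypes are connected when their substitution-step count does not exceed
the parsimony connection limit -- the largest number of observed differences
that still has >= 95% probability (by default) of involving no superimposed
substitution.  Networks (connected components, via sampled intermediates)
are the MOTUs; full network topology is never needed for delimitation.

Parsimony-probability convention
--------------------------------
The probability that ``j`` observed differences involve no superimposed
change is evaluated combinatorially: ``j`` substitutions thrown uniformly on
``L`` sites occupy ``j`` distinct sites with probability

    P(j; L) = prod_{i=1}^{j-1} (1 - i / L).

This is parameter-free and slightly conservative relative to the TCS 1.21
program (which connects ~2% divergent haplotypes at 658 bp; this rule
connects ~1.2%), so networks here may split where TCS would connect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dataio import Alignment, Partition
from .distances import step_matrix
from .errors import ConfigError


@dataclass(frozen=True)
class ParsimonyLimit:
    confidence: float = 0.95
    max_steps: int = 1

    def __post_init__(self):
        if not (0 < self.confidence < 1):
            raise ConfigError("confidence must be in (0, 1)")
        if self.max_steps < 0:
            raise ConfigError("max_steps must be >= 0")


@dataclass
class HaplotypeTable:
    """Unique sequences plus the specimens carrying each."""

    haplotypes: List[str]
    membership: Dict[int, frozenset]  # haplotype index -> specimen ids

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def parsimony_probability(j: int, seq_length: int) -> float:
    """P that j observed differences involve no superimposed substitution."""
    if j <= 1:
        return 1.0
    log_p = 0.0
    for i in range(1, j):
        frac = 1.0 - i / seq_length
        if frac <= 0:
            return 0.0
        log_p += math.log(frac)
    return math.exp(log_p)


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest j with parsimony probability >= confidence for L sites."""
    if seq_length < 1:
        raise ConfigError("seq_length must be >= 1")
    j = 1
    while parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Merge sequences identical under the missing-tolerant policy.

    Two sequences are mergeable when every site is either identical or
    missing in at least one of them; merging is by transitive closure so the
    result is order-independent.
    """
    enc = aln.encoded()
    present = enc != 0
    n = len(aln)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        comparable = present[i] & present[i + 1 :]
        diff = comparable & ((enc[i] & enc[i + 1 :]) == 0)
        same = ~diff.any(axis=1)
        adj[i, i + 1 :] = same
    _, labels = connected_components(
        csr_matrix(adj | adj.T), directed=False, connection="weak"
    )
    ids = aln.ids
    groups: Dict[int, List[str]] = {}
    for sid, g in zip(ids, labels):
        groups.setdefault(int(g), []).append(sid)
    # order haplotypes by first specimen appearance; representative = first member
    ordered = sorted(groups.values(), key=lambda members: ids.index(members[0]))
    haplotypes = [aln[members[0]] for members in ordered]
    membership = {k: frozenset(members) for k, members in enumerate(ordered)}
    return HaplotypeTable(haplotypes=haplotypes, membership=membership)


def tcs_delimit(aln: Alignment, limit: ParsimonyLimit | None = None) -> Partition:
    """Partition specimens into statistical-parsimony networks.

    With no explicit limit, the connection limit is computed from the
    alignment length at 95% confidence.
    """
    if limit is None:
        limit = ParsimonyLimit(
            confidence=0.95, max_steps=connection_limit(aln.length, 0.95)
        )
    table = collapse_haplotypes(aln)
    reps = [next(iter(sorted(table.membership[k]))) for k in range(table.n_haplotypes)]
    sub = aln.subset(reps)
    steps = step_matrix(sub)
    adj = steps <= limit.max_steps
    np.fill_diagonal(adj, False)
    _, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    order: Dict[int, int] = {}
    assignment: Dict[str, str] = {}
    for sid in aln.ids:
        hap = next(k for k, members in table.membership.items() if sid in members)
        comp = int(labels[hap])
        if comp not in order:
            order[comp] = len(order) + 1
        assignment[sid] = f"net{order[comp]:03d}"
    return Partition(assignment)
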