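"""Ranked hierarchical partitioning (ASAP-style).

Every single-linkage merge height yields a candidate partition (the blocks
formed at that height).  Each candidate is scored by

* a probability of panmixia: a seeded Monte-Carlo permutation test of the
  statistic (mean between-block distance - mean within-block distance),
  small when the grouping reflects real structure, and
* a relative gap width ``w = (next height - height) / height``, large when a
  wide distance gap opens just above the candidate's threshold.

Candidates are ranked on each metric (1 = smallest p, 1 = largest w) and the
ASAP score is the mean of the two ranks; lower is better.  The published
method derives its panmixia probability from coalescent theory; the
permutation test used here has the same contract (small under structure,
large under panmixia) without claiming bit-compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from .dataio import DistanceMatrix, Partition
from .errors import ConfigError


@dataclass
class ASAPCandidate:
    threshold: float
    partition: Partition
    p_val: float
    w: float
    rank_p: int = 0
    rank_w: int = 0
    asap_score: float = 0.0


def _partition_at(dm: DistanceMatrix, linkage_matrix: np.ndarray, height: float) -> Partition:
    labels = fcluster(linkage_matrix, t=height, criterion="distance")
    order: dict[int, int] = {}
    assignment = {}
    for sid, lab in zip(dm.ids, labels):
        lab = int(lab)
        if lab not in order:
            order[lab] = len(order) + 1
        assignment[sid] = f"motu{order[lab]:03d}"
    return Partition(assignment)


def dendrogram_levels(dm: DistanceMatrix) -> List[tuple[float, Partition]]:
    """Distinct single-linkage merge heights with the partition formed at each.

    Tied merge heights are coalesced into a single candidate; partitions are
    nested and strictly coarsen with height.
    """
    if len(dm) < 2:
        raise ConfigError("dendrogram needs at least 2 specimens")
    Z = linkage(dm.condensed(), method="single")
    heights = np.unique(Z[:, 2])
    return [(float(h), _partition_at(dm, Z, float(h))) for h in heights]


def panmixia_pval(
    dm: DistanceMatrix,
    partition: Partition,
    R: int = 999,
    seed: int = 0,
) -> float:
    """Permutation probability that the grouping is compatible with panmixia.

    statistic = mean between-block - mean within-block distance; the p-value
    is (1 + #{permuted strictly > observed}) / (R + 1).  Partitions with no
    between-block or no within-block pairs (one block; all singletons) have
    p = 1 by definition.
    """
    if R < 1:
        raise ConfigError("R must be >= 1")
    ids = dm.ids
    labels = np.array([partition.assignment[sid] for sid in ids])
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    dvals = dm.values[iu]
    same = labels[iu[0]] == labels[iu[1]]
    if same.all() or not same.any():
        return 1.0
    obs = dvals[~same].mean() - dvals[same].mean()
    rng = np.random.default_rng(seed)
    # vectorised permutations: each row of `order` is one shuffled labelling
    codes = np.unique(labels, return_inverse=True)[1]
    order = np.argsort(rng.random((R, n)), axis=1)
    perm = codes[order]
    s = perm[:, iu[0]] == perm[:, iu[1]]  # (R, n_pairs)
    n_same = s.sum(axis=1)
    sum_same = s @ dvals
    total = dvals.sum()
    n_pairs = dvals.size
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = (total - sum_same) / (n_pairs - n_same) - sum_same / n_same
    stats = np.where((n_same == 0) | (n_same == n_pairs), -np.inf, stats)
    # strictly-greater comparison: permutations merely re-creating the same
    # grouping (stat == obs) carry no evidence against it, and would
    # otherwise put a resolution floor under coarse partitions
    hits = int((stats > obs + 1e-12).sum())
    return (1 + hits) / (R + 1)


def relative_gap_width(heights: List[float], index: int) -> float:
    """w = (next height - height) / height; 0 at the top level or height 0."""
    h = heights[index]
    if h <= 0:
        return 0.0
    if index == len(heights) - 1:
        return 0.0
    return (heights[index + 1] - h) / h


def asap_delimit(
    dm: DistanceMatrix, R: int = 999, seed: int = 0
) -> List[ASAPCandidate]:
    """Score and rank every merge-level candidate; best (lowest score) first.

    Ties in the final score break toward fewer blocks, then lower threshold.
    The seed fixes the permutation draws and hence the entire ranked list.
    """
    levels = dendrogram_levels(dm)
    heights = [h for h, _ in levels]
    candidates = []
    for k, (h, part) in enumerate(levels):
        p = panmixia_pval(dm, part, R=R, seed=seed + k)
        w = relative_gap_width(heights, k)
        candidates.append(ASAPCandidate(threshold=h, partition=part, p_val=p, w=w))
    p_ranks = rankdata([c.p_val for c in candidates], method="min")
    w_ranks = rankdata([-c.w for c in candidates], method="min")
    for c, rp, rw in zip(candidates, p_ranks, w_ranks):
        c.rank_p = int(rp)
        c.rank_w = int(rw)
        c.asap_score = (c.rank_p + c.rank_w) / 2.0
    candidates.sort(key=lambda c: (c.asap_score, c.partition.n_blocks, c.threshold))
    return candidates
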