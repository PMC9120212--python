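"""Barcode-gap discovery with recursive partitioning (ABGD-style).

For each prior intraspecific divergence on a geometric grid, the ranked
pairwise distances are scanned for the first "gap" -- an inter-rank jump
that exceeds ``gap_width_x`` times the local mean jump (a sliding window of
the preceding ``n_bins`` ranks).  Specimens are split into connected
components below the gap, and with recursion enabled the search is repeated
inside every block until no block splits (blocks smaller than 4 specimens
are never re-split: a gap is meaningless on fewer than 3 within-block
distances).

Fidelity is to the behavioural contract of barcode-gap discovery (gap found
when present, one partition per prior, recursive refinement), not
bit-compatibility with the original web server.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .dataio import DistanceMatrix, Partition
from .errors import ConfigError
from .threshold import components_below

#: blocks smaller than this are never recursively re-split
MIN_RECURSION_BLOCK = 4


@dataclass(frozen=True)
class ABGDConfig:
    p_min: float = 0.001
    p_max: float = 0.1
    steps: int = 50
    gap_width_x: float = 1.0
    n_bins: int = 20
    recursive: bool = True

    def __post_init__(self):
        if not (0 < self.p_min < self.p_max < 1):
            raise ConfigError("need 0 < p_min < p_max < 1")
        if self.steps < 2:
            raise ConfigError("steps must be >= 2")
        if self.gap_width_x <= 0:
            raise ConfigError("gap_width_x must be > 0")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")


@dataclass
class GapResult:
    prior: float
    threshold: Optional[float]
    partition: Partition
    n_motu: int


def prior_grid(cfg: ABGDConfig) -> np.ndarray:
    """Geometric grid of `steps` priors from p_min to p_max inclusive."""
    return np.geomspace(cfg.p_min, cfg.p_max, cfg.steps)


def sorted_distances(dm: DistanceMatrix) -> np.ndarray:
    """Upper-triangle distances, stably sorted by (value, pair order)."""
    n = len(dm.ids)
    iu = np.triu_indices(n, k=1)
    vals = dm.values[iu]
    order = np.lexsort((iu[1], iu[0], vals))
    return vals[order]


def find_gap_threshold(
    sorted_vals: np.ndarray,
    prior: float,
    gap_width_x: float = 1.0,
    n_bins: int = 20,
) -> Optional[float]:
    """First barcode gap closing above `prior`, or None.

    Scanning ranked distances, the gap is the first jump d[i+1]-d[i] with
    d[i+1] > prior (a gap straddling the prior still counts) that exceeds
    gap_width_x times the local jump scale -- the mean of the nonzero jumps
    among the preceding (up to n_bins) ranks.  Ties carry no scale
    information (identical haplotypes give many zero jumps), so windows with
    only zero jumps cannot host a gap.  The returned threshold is the jump
    midpoint; None when no qualifying jump exists or fewer than 2 distances
    lie above the prior.
    """
    vals = np.asarray(sorted_vals, dtype=float)
    if (vals > prior).sum() < 2:
        return None
    jumps = np.diff(vals)
    # scale-aware tie tolerance: float-level jumps are ties, not structure
    tie_eps = 1e-9 * max(float(vals[-1]), 1e-12)
    for i in range(len(vals) - 1):
        if vals[i + 1] <= prior:
            continue  # the gap must close above the prior
        jump = float(jumps[i])
        if jump <= tie_eps:
            continue
        window = jumps[max(0, i - n_bins) : i]
        nonzero = window[window > tie_eps]
        if nonzero.size == 0:
            continue  # ties only: no local jump scale established yet
        local = float(nonzero.mean())
        # strict relative margin: exactly-equal spacing never reads as a gap
        if jump > gap_width_x * local * (1.0 + 1e-9):
            mid = float(vals[i] + vals[i + 1]) / 2.0
            # any threshold inside the gap yields the same components; keep
            # it strictly above the prior
            return max(mid, (prior + float(vals[i + 1])) / 2.0)
    return None


def _split_recursively(
    dm: DistanceMatrix, partition: Partition, cfg: ABGDConfig, prior: float
) -> Partition:
    changed = True
    current = partition
    while changed:
        changed = False
        new_blocks = {}
        for label, members in sorted(current.blocks().items()):
            members = sorted(members)
            if len(members) < MIN_RECURSION_BLOCK:
                new_blocks[label] = members
                continue
            sub = dm.submatrix(members)
            thr = find_gap_threshold(
                sorted_distances(sub), prior, cfg.gap_width_x, cfg.n_bins
            )
            if thr is None:
                new_blocks[label] = members
                continue
            sub_part = components_below(sub, thr)
            if sub_part.n_blocks <= 1:
                new_blocks[label] = members
                continue
            changed = True
            for k, (_, sub_members) in enumerate(sorted(sub_part.blocks().items())):
                new_blocks[f"{label}.{k + 1}"] = sorted(sub_members)
        current = Partition.from_blocks(new_blocks)
    return current


def abgd_delimit(dm: DistanceMatrix, cfg: ABGDConfig | None = None) -> List[GapResult]:
    """One GapResult per prior on the grid (duplicates collapsed downstream)."""
    cfg = cfg or ABGDConfig()
    ranked = sorted_distances(dm)
    results: List[GapResult] = []
    for prior in prior_grid(cfg):
        thr = find_gap_threshold(ranked, float(prior), cfg.gap_width_x, cfg.n_bins)
        if thr is None:
            partition = Partition({sid: "motu001" for sid in dm.ids})
        else:
            partition = components_below(dm, thr)
            if cfg.recursive:
                partition = _split_recursively(dm, partition, cfg, float(prior))
        results.append(
            GapResult(
                prior=float(prior),
                threshold=thr,
                partition=partition,
                n_motu=partition.n_blocks,
            )
        )
    return results


def unique_partitions(results: List[GapResult]) -> List[GapResult]:
    """Collapse duplicate partitions across priors (first prior kept)."""
    seen = set()
    out = []
    for res in results:
        key = res.partition.block_set()
        if key not in seen:
            seen.add(key)
            out.append(res)
    return out
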