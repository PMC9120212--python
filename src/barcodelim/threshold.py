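"""Fixed-threshold single-linkage clustering.

A proxy for BOLD's BIN assignment: specimens are linked whenever their
pairwise distance falls below the cutoff and MOTUs are the connected
components.  The default cutoff of 0.022 substitutions/site is the BOLD seed
threshold (2.2%).  RESL's refinement steps are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dataio import DistanceMatrix, Partition
from .errors import ConfigError


@dataclass(frozen=True)
class ThresholdConfig:
    threshold: float = 0.022

    def __post_init__(self):
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")


def components_below(dm: DistanceMatrix, threshold: float) -> Partition:
    """Connected components of the graph with an edge (i,j) iff d[i,j] < threshold."""
    adj = dm.values < threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    # deterministic labels: number components by first specimen appearance
    order: dict[int, int] = {}
    assignment = {}
    for sid, comp in zip(dm.ids, labels):
        if comp not in order:
            order[comp] = len(order) + 1
        assignment[sid] = f"motu{order[comp]:03d}"
    return Partition(assignment)


def single_linkage_delimit(dm: DistanceMatrix, cfg: ThresholdConfig | None = None) -> Partition:
    cfg = cfg or ThresholdConfig()
    return components_below(dm, cfg.threshold)
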