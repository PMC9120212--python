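"""Similarity-to-distance transform and principal coordinate analysis.

PCoA embeds a distance matrix by eigendecomposition of the Gower-centred
matrix B = -1/2 J D^2 J (J the centring operator, D^2 entry-wise squares).
Coordinates are eigenvectors scaled by the square root of their (positive)
eigenvalues; negative eigenvalues -- possible because match-ratio distances
need not be Euclidean -- are reported and their axes dropped.  Axis signs
are fixed so the first nonzero coordinate on each axis is positive, making
outputs reproducible across BLAS implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping

import numpy as np

from .congruence import MethodSimilarity, pairwise_similarity
from .dataio import DistanceMatrix, Partition
from .errors import InputError, OrdinationError

#: eigenvalues below this fraction of the largest magnitude are treated as 0
EIG_TOL = 1e-10


@dataclass
class PCoAResult:
    names: List[str]
    coordinates: np.ndarray          # (n, k) for the k retained positive axes
    eigenvalues: np.ndarray          # retained, descending, > 0
    proportion_explained: np.ndarray  # sums to 1 over retained axes
    negative_eigenvalues: np.ndarray  # reported, axes dropped


def similarity_to_distance(sim: MethodSimilarity, mode: str = "linear") -> DistanceMatrix:
    """d = 1 - s (default) or sqrt(1 - s), which is metric for match-ratio-like
    similarities."""
    values = np.asarray(sim.values, dtype=float)
    if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
        raise InputError("similarity entries must lie in [0, 1]")
    d = 1.0 - np.clip(values, 0.0, 1.0)
    if mode == "sqrt":
        d = np.sqrt(d)
    elif mode != "linear":
        raise InputError(f"unknown transform mode {mode!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sim.methods, d)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    n = len(dm)
    if n < 3:
        raise OrdinationError("PCoA needs at least 3 points")
    D2 = dm.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    tol = EIG_TOL * scale
    keep = eigvals > tol
    negative = eigvals[eigvals < -tol]
    vals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(vals)
    # sign convention: first nonzero coordinate on each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    if vals.size:
        prop = vals / vals.sum()
    else:
        coords = np.zeros((n, 0))
        prop = np.array([])
    return PCoAResult(
        names=list(dm.ids),
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=prop,
        negative_eigenvalues=negative,
    )


def ordinate_methods(
    partitions: Mapping[str, Partition], transform: str = "linear"
) -> PCoAResult:
    """pairwise_similarity -> similarity_to_distance -> pcoa.

    One point per delimitation method; include the reference (morphospecies)
    partition in the mapping to ordinate it alongside the methods.
    """
    if len(partitions) < 3:
        raise OrdinationError("ordination needs at least 3 partitions")
    sim = pairwise_similarity(partitions)
    return pcoa(similarity_to_distance(sim, mode=transform))
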