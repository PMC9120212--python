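"""Pairwise distances: uncorrected p-distance and the JC69 correction.

Ambiguity codes compatible with the opposing base (e.g. R vs A) count as a
match, which is conservative toward lumping; gap ``-`` and ``?`` are missing
data and excluded under pairwise deletion (default) or mask whole columns
under complete deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataio import Alignment, DistanceMatrix, IUPAC_MASKS
from .errors import ConfigError, SaturationError, UndefinedDistanceError

#: p at which the JC69 log argument reaches zero.
JC69_MAX_P = 0.75


@dataclass(frozen=True)
class DistanceModel:
    """A named distance model plus a missing-data deletion policy."""

    name: str = "p"
    deletion: str = "pairwise"

    def __post_init__(self):
        if self.name not in {"p", "jc69"}:
            raise ConfigError(f"unknown distance model {self.name!r}")
        if self.deletion not in {"pairwise", "complete"}:
            raise ConfigError(f"unknown deletion policy {self.deletion!r}")


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for ch, mask in IUPAC_MASKS.items():
        lut[ord(ch)] = mask
    return lut[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """Proportion of differing comparable sites between two aligned sequences."""
    if len(a) != len(b):
        raise UndefinedDistanceError("sequences of unequal length")
    ea, eb = _encode(a), _encode(b)
    comparable = (ea != 0) & (eb != 0)
    if deletion == "complete":
        # with only two sequences, complete == pairwise deletion
        pass
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    diff = comparable & ((ea & eb) == 0)
    return float(diff.sum()) / n


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p), in subs/site."""
    if p < 0:
        raise UndefinedDistanceError(f"negative proportion {p}")
    if p >= JC69_MAX_P:
        raise SaturationError(
            f"p={p} >= {JC69_MAX_P}: JC69 distance undefined (saturated pair)"
        )
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def distance_matrix(aln: Alignment, model: DistanceModel | None = None) -> DistanceMatrix:
    """All pairwise distances under the given model.

    Saturated pairs (p >= 0.75 under jc69) and pairs with no comparable sites
    raise, naming the offending pair.
    """
    model = model or DistanceModel()
    ids = aln.ids
    if len(ids) < 2:
        raise ConfigError("distance matrix needs at least 2 records")
    enc = aln.encoded()
    present = enc != 0
    if model.deletion == "complete":
        keep = present.all(axis=0)
        enc = enc[:, keep]
        present = present[:, keep]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        ei = enc[i]
        comparable = present[i] & present[i + 1 :]
        diff = comparable & ((ei & enc[i + 1 :]) == 0)
        counts = comparable.sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            if counts[k] == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = diff[k].sum() / counts[k]
            if model.name == "jc69":
                try:
                    d = jc69_distance(float(p))
                except SaturationError as exc:
                    raise SaturationError(
                        f"pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                    ) from exc
            else:
                d = float(p)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)


def step_matrix(aln: Alignment) -> np.ndarray:
    """Integer pairwise substitution-step counts (missing sites excluded).

    The raw material for statistical-parsimony connection: absolute nucleotide
    differences, with ambiguity-compatible sites counting as matches.
    """
    enc = aln.encoded()
    present = enc != 0
    n = len(aln)
    steps = np.zeros((n, n), dtype=int)
    for i in range(n):
        comparable = present[i] & present[i + 1 :]
        diff = comparable & ((enc[i] & enc[i + 1 :]) == 0)
        counts = diff.sum(axis=1)
        steps[i, i + 1 :] = counts
        steps[i + 1 :, i] = counts
    return steps
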