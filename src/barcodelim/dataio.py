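"""Core data containers and on-disk formats.

The pipeline's currency is four objects keyed by specimen id:

* :class:`Alignment` -- fixed-length nucleotide sequences (FASTA),
* :class:`Partition` -- a disjoint labelling of specimens into blocks
  (MOTUs or morphospecies; 2-column TSV),
* :class:`DistanceMatrix` -- symmetric pairwise distances (labelled TSV or
  lower-triangle PHYLIP dialect, auto-detected),
* :class:`PhyloTree` -- a rooted tree with branch lengths (Newick, via
  dendropy).

Specimen ids are the join key across files; mismatched id sets are reported
as a set difference (:class:`~barcodelim.errors.DomainMismatchError`) and are
fatal unless the caller asks for the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, DomainMismatchError, InputError

#: IUPAC nucleotide codes as bitmasks over {A, C, G, T}; 0 encodes missing.
IUPAC_MASKS: Dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
    # gap and unknown are treated identically as missing data
    "-": 0, "?": 0,
}


@dataclass(frozen=True)
class Specimen:
    """A voucher specimen: unique id plus optional morphospecies label.

    Specimens without a ``morph_label`` (e.g. females lacking diagnostic
    characters) are excluded from congruence counts unless explicitly
    assigned.
    """

    id: str
    morph_label: Optional[str] = None
    locality: Optional[str] = None
    notes: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise InputError("specimen id must be a non-empty string")

    @property
    def has_morph_label(self) -> bool:
        return self.morph_label is not None and self.morph_label != ""


class Alignment:
    """Fixed-length aligned sequences keyed by specimen id (insertion order kept)."""

    def __init__(self, records: Mapping[str, str]):
        if not records:
            raise AlignmentError("alignment must contain at least one record")
        self.records: Dict[str, str] = {}
        length = None
        for sid, seq in records.items():
            if not sid:
                raise InputError("empty specimen id in alignment")
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: record {sid!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            bad = set(seq) - set(IUPAC_MASKS)
            if bad:
                raise InputError(
                    f"illegal characters {sorted(bad)} in record {sid!r}"
                )
            if sid in self.records:
                raise InputError(f"duplicate specimen id {sid!r}")
            self.records[sid] = seq
        self.length: int = length or 0

    @property
    def ids(self) -> List[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sid: str) -> str:
        return self.records[sid]

    def encoded(self) -> np.ndarray:
        """(n, length) uint8 array of IUPAC bitmasks; 0 marks missing data."""
        lut = np.zeros(128, dtype=np.uint8)
        for ch, mask in IUPAC_MASKS.items():
            lut[ord(ch)] = mask
        out = np.empty((len(self), self.length), dtype=np.uint8)
        for i, sid in enumerate(self.records):
            out[i] = lut[np.frombuffer(self.records[sid].encode(), dtype=np.uint8)]
        return out

    def subset(self, ids: Iterable[str]) -> "Alignment":
        ids = list(ids)
        missing = [i for i in ids if i not in self.records]
        if missing:
            raise DomainMismatchError(
                f"ids not in alignment: {sorted(missing)}", only_b=missing
            )
        return Alignment({i: self.records[i] for i in ids})


class Partition:
    """A labelling of specimens into disjoint blocks (MOTUs or morphospecies)."""

    def __init__(self, assignment: Mapping[str, str]):
        if not assignment:
            raise InputError("partition must assign at least one specimen")
        self.assignment: Dict[str, str] = {}
        for sid, label in assignment.items():
            if not sid:
                raise InputError("empty specimen id in partition")
            if label is None or label == "":
                raise InputError(f"empty block label for specimen {sid!r}")
            if sid in self.assignment:
                raise InputError(f"duplicate specimen {sid!r} in partition")
            self.assignment[sid] = str(label)

    @property
    def domain(self) -> frozenset:
        return frozenset(self.assignment)

    @property
    def labels(self) -> List[str]:
        seen: Dict[str, None] = {}
        for label in self.assignment.values():
            seen.setdefault(label)
        return list(seen)

    def blocks(self) -> Dict[str, frozenset]:
        """Map block label -> frozenset of specimen ids."""
        out: Dict[str, set] = {}
        for sid, label in self.assignment.items():
            out.setdefault(label, set()).add(sid)
        return {label: frozenset(members) for label, members in out.items()}

    def block_set(self) -> frozenset:
        """The set of blocks, ignoring labels (order-independent)."""
        return frozenset(self.blocks().values())

    @property
    def n_blocks(self) -> int:
        return len(set(self.assignment.values()))

    def restrict(self, ids: Iterable[str]) -> "Partition":
        keep = {i: self.assignment[i] for i in ids if i in self.assignment}
        return Partition(keep)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.block_set() == other.block_set()

    def __hash__(self):
        return hash(self.block_set())

    def __len__(self) -> int:
        return len(self.assignment)

    @classmethod
    def from_blocks(cls, blocks: Mapping[str, Iterable[str]]) -> "Partition":
        assignment: Dict[str, str] = {}
        for label, members in blocks.items():
            for sid in members:
                if sid in assignment:
                    raise InputError(f"specimen {sid!r} in two blocks")
                assignment[sid] = label
        return cls(assignment)


class DistanceMatrix:
    """Symmetric pairwise distances over an ordered list of specimen ids."""

    SYMMETRY_TOL = 1e-12

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        if len(set(ids)) != len(ids):
            raise InputError("duplicate ids in distance matrix")
        if values.shape != (len(ids), len(ids)):
            raise InputError(
                f"matrix shape {values.shape} does not match {len(ids)} ids"
            )
        if np.any(values < 0):
            raise InputError("negative distances")
        if np.any(np.abs(values - values.T) > self.SYMMETRY_TOL):
            i, j = np.unravel_index(
                np.argmax(np.abs(values - values.T)), values.shape
            )
            raise InputError(
                f"asymmetric matrix: d[{ids[i]},{ids[j]}]={values[i, j]} vs "
                f"d[{ids[j]},{ids[i]}]={values[j, i]}"
            )
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.ids: List[str] = ids
        self.values: np.ndarray = values

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths over specimen tips (dendropy-backed)."""

    tree: dendropy.Tree
    _tip_labels: frozenset = field(init=False)

    def __post_init__(self):
        labels = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise InputError("unlabeled tip in tree")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise InputError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise InputError("negative branch length in tree")
        self._tip_labels = frozenset(labels)

    @property
    def tip_labels(self) -> frozenset:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def prune(self, drop: Iterable[str]) -> "PhyloTree":
        drop = set(drop)
        keep = [t for t in self._tip_labels if t not in drop]
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        return PhyloTree(clone)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> Alignment:
    """Read a FASTA alignment; the header token before whitespace is the id."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in records:
            raise InputError(f"duplicate specimen id {sid!r} in {path}")
        records[sid] = str(rec.seq)
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records.items():
            fh.write(f">{sid}\n{seq}\n")


def read_partition(path) -> Partition:
    """Read a 2-column TSV (specimen_id, label); an optional header is skipped."""
    assignment: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, label = parts[0].strip(), parts[1].strip()
            if lineno == 1 and sid.lower() in {"specimen", "specimen_id", "id"}:
                continue
            if sid in assignment:
                raise InputError(f"{path}:{lineno}: duplicate specimen {sid!r}")
            if not label:
                raise InputError(f"{path}:{lineno}: empty label for {sid!r}")
            assignment[sid] = label
    return Partition(assignment)


def write_partition(partition: Partition, path) -> None:
    with open(path, "w") as fh:
        fh.write("specimen_id\tlabel\n")
        for sid, label in partition.assignment.items():
            fh.write(f"{sid}\t{label}\n")


def read_newick(path) -> PhyloTree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(
        path=str(path), schema="newick", unquoted_underscores=True,
        suppress_rooting=True,
    )


def _looks_phylip(first_line: str) -> bool:
    # PHYLIP-dialect matrices start with the (numeric) taxon count.
    token = first_line.strip().split()[0] if first_line.strip() else ""
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_matrix(path) -> DistanceMatrix:
    """Read a distance matrix: labelled square TSV, or PHYLIP dialect.

    Dialect auto-detection: if the first token of the file is numeric the file
    is parsed as PHYLIP (count line, then ``id d1 d2 ...`` rows, full or
    lower-triangle); otherwise as a TSV with an id header row and id first
    column.
    """
    with open(path) as fh:
        content = fh.read()
    lines = [ln for ln in content.splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"empty matrix file {path}")
    if _looks_phylip(lines[0]):
        n = int(lines[0].split()[0])
        rows = lines[1 : 1 + n]
        if len(rows) != n:
            raise InputError(f"{path}: expected {n} matrix rows, found {len(rows)}")
        ids, data = [], []
        for row in rows:
            parts = row.split()
            ids.append(parts[0])
            data.append([float(x) for x in parts[1:]])
        values = np.zeros((n, n))
        lower = all(len(data[i]) == i for i in range(n))
        if lower:
            for i in range(n):
                for j in range(i):
                    values[i, j] = values[j, i] = data[i][j]
        else:
            if any(len(d) != n for d in data):
                raise InputError(f"{path}: ragged PHYLIP matrix rows")
            values = np.array(data)
        return DistanceMatrix(ids, values)
    # labelled TSV
    header = lines[0].split("\t")
    ids = [h.strip() for h in header[1:]]
    data = []
    row_ids = []
    for row in lines[1:]:
        parts = row.split("\t")
        row_ids.append(parts[0].strip())
        data.append([float(x) for x in parts[1:]])
    if row_ids != ids:
        raise InputError(f"{path}: row ids do not match column ids")
    return DistanceMatrix(ids, np.array(data))


def write_matrix(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + dm.ids) + "\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(repr(float(v)) for v in dm.values[i])
            fh.write(f"{sid}\t{row}\n")


def check_same_domain(*domains: Iterable[str], intersect: bool = False) -> frozenset:
    """Verify that id sets agree; return the common domain.

    With ``intersect=False`` (default) any difference is fatal and reported as
    a set difference.  With ``intersect=True`` the intersection is returned so
    analyses can be restricted to the common subset.
    """
    sets = [frozenset(d) for d in domains]
    common = frozenset.intersection(*sets)
    if not intersect:
        for i, s in enumerate(sets):
            if s != common:
                union = frozenset.union(*sets)
                raise DomainMismatchError(
                    f"id sets differ: {sorted(union - common)[:10]} not shared "
                    f"by all inputs (pass intersect=True to restrict)",
                    only_a=s - common,
                    only_b=union - s,
                )
    if not common:
        raise DomainMismatchError("no specimen ids shared by all inputs")
    return common
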