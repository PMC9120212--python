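"""Poisson tree processes (PTP) maximum-likelihood species delimitation.

Branches of a rooted tree are classified into a speciation class (edges on
paths from the root down to, and including, each species root) and
within-species classes (edges strictly inside species subtrees).  Each class
is exponential with its own rate; profiling the rates at their ML values
gives, for a class with n branches summing to s,

    lambda_hat = n / s,    contribution = n * ln(n/s) - n.

A delimitation is an antichain of nodes covering all tips; ML search is
exact (full antichain enumeration) for small trees and a greedy root-to-tip
split search with a local exchange pass otherwise.  The single-rate variant
(mlPTP) shares one within-species rate; the multi-rate variant (mPTP) gives
each species its own rate and compares delimitations by AIC, since
unpenalized per-species rates always favour maximal splitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, Iterator, List, Optional, Tuple

from .dataio import Partition, PhyloTree
from .errors import ConfigError, InputError

#: absolute floor for zero-length branches so rates stay finite
BRANCH_FLOOR = 1e-9

#: default minimum informative branch length, substitutions/site.  A branch
#: carrying less than ~one substitution per kilobase is below the resolution
#: of a single barcode locus; such branches are floored before rate
#: estimation (the same role as mPTP's --minbr), which keeps the profile
#: likelihood from building degenerate near-infinite-rate classes out of
#: effectively-zero branches.
MIN_BRANCH = 1e-3


class _IndexedTree:
    """Array view of a rooted tree: preorder node indices, parents, lengths."""

    def __init__(self, ptree: PhyloTree, min_branch: float = MIN_BRANCH):
        tree = ptree.tree
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            raise InputError(
                "tree root is a polytomy; the tree appears unrooted -- root it "
                "(e.g. on an outgroup) before PTP delimitation"
            )
        self.nodes = list(tree.preorder_node_iter())
        if sum(1 for n in self.nodes if n.is_leaf()) < 2:
            raise ConfigError("PTP needs a tree with at least 2 tips")
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = [-1] * n
        self.children: List[List[int]] = [[] for _ in range(n)]
        self.length = [0.0] * n  # edge into node i (floored); root edge unused
        self.is_leaf = [False] * n
        self.label = [""] * n
        for i, node in enumerate(self.nodes):
            self.is_leaf[i] = node.is_leaf()
            if node.is_leaf():
                self.label[i] = node.taxon.label
            if node.parent_node is not None:
                p = self.index[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                raw = node.edge.length or 0.0
                self.length[i] = max(float(raw), min_branch, BRANCH_FLOOR)
        # edge count / length sum over edges strictly below each node
        self.sub_count = [0] * n
        self.sub_sum = [0.0] * n
        for i in range(n - 1, -1, -1):
            for c in self.children[i]:
                self.sub_count[i] += 1 + self.sub_count[c]
                self.sub_sum[i] += self.length[c] + self.sub_sum[c]
        self.total_count = n - 1
        self.total_sum = sum(self.length[1:])
        self.root = 0

    def tips_below(self, i: int) -> List[str]:
        if self.is_leaf[i]:
            return [self.label[i]]
        out: List[str] = []
        stack = [i]
        while stack:
            v = stack.pop()
            if self.is_leaf[v]:
                out.append(self.label[v])
            else:
                stack.extend(reversed(self.children[v]))
        return out


def _class_loglik(n: int, s: float) -> float:
    if n == 0:
        return 0.0
    return n * math.log(n / s) - n


@dataclass
class PTPDelimitation:
    """An ML delimitation: species roots plus profiled rates and loglik."""

    tree: PhyloTree
    species_roots: FrozenSet[int]
    mode: str
    loglik: float
    lambda_speciation: Optional[float]
    lambda_within: object  # float (single) or dict root-index -> rate (multi)
    n_species: int
    aic: float = float("nan")
    _indexed: _IndexedTree = field(repr=False, default=None)

    def to_partition(self) -> Partition:
        return delimitation_to_partition(self)


def _score(idx: _IndexedTree, roots: FrozenSet[int], mode: str) -> Tuple[float, float]:
    """(loglik, aic) of a species-root set under the given mode."""
    within_n = sum(idx.sub_count[r] for r in roots)
    within_s = sum(idx.sub_sum[r] for r in roots)
    spec_n = idx.total_count - within_n
    spec_s = idx.total_sum - within_s
    ll = _class_loglik(spec_n, spec_s)
    k = 1 if spec_n else 0
    if mode == "single":
        ll += _class_loglik(within_n, within_s)
        k += 1 if within_n else 0
    else:
        for r in roots:
            ll += _class_loglik(idx.sub_count[r], idx.sub_sum[r])
            k += 1 if idx.sub_count[r] else 0
    return ll, 2 * k - 2 * ll


def ptp_loglik(
    tree: PhyloTree, species_roots, mode: str = "single",
    min_branch: float = MIN_BRANCH,
) -> float:
    """Profile log-likelihood of a delimitation given as a set of node indices
    (preorder numbering, 0 = root)."""
    if mode not in {"single", "multi"}:
        raise ConfigError(f"unknown PTP mode {mode!r}")
    idx = _IndexedTree(tree, min_branch=min_branch)
    roots = frozenset(int(r) for r in species_roots)
    _validate_antichain(idx, roots)
    return _score(idx, roots, mode)[0]


def _validate_antichain(idx: _IndexedTree, roots: FrozenSet[int]) -> None:
    if not roots:
        raise ConfigError("empty species-root set")
    covered: set = set()
    for r in roots:
        if not (0 <= r < len(idx.nodes)):
            raise ConfigError(f"node index {r} out of range")
        tips = idx.tips_below(r)
        if covered.intersection(tips):
            raise ConfigError("species subtrees overlap")
        covered.update(tips)
    if len(covered) != sum(idx.is_leaf):
        raise ConfigError("species subtrees do not cover all tips")


def enumerate_delimitations(idx: _IndexedTree) -> Iterator[FrozenSet[int]]:
    """All antichains of nodes covering every tip (each node's subtree = one
    species), by the recursion choices(v) = {v} | product over children."""

    def choices(v: int) -> List[FrozenSet[int]]:
        out = [frozenset([v])]
        if not idx.is_leaf[v]:
            for combo in product(*(choices(c) for c in idx.children[v])):
                out.append(frozenset().union(*combo))
        return out

    yield from choices(idx.root)


def count_delimitations(idx: _IndexedTree) -> int:
    """Antichain count: c(leaf) = 1, c(node) = 1 + prod c(children)."""
    memo: Dict[int, int] = {}

    def c(v: int) -> int:
        if v not in memo:
            if idx.is_leaf[v]:
                memo[v] = 1
            else:
                prod = 1
                for ch in idx.children[v]:
                    prod *= c(ch)
                memo[v] = 1 + prod
        return memo[v]

    return c(idx.root)


def _key(idx: _IndexedTree, roots: FrozenSet[int], mode: str) -> Tuple:
    ll, aic = _score(idx, roots, mode)
    objective = -ll if mode == "single" else aic
    return (objective, len(roots), tuple(sorted(roots)))


def _exact_search(idx: _IndexedTree, mode: str) -> FrozenSet[int]:
    return min(enumerate_delimitations(idx), key=lambda r: _key(idx, r, mode))


def _local_search(idx: _IndexedTree, roots: FrozenSet[int], mode: str) -> FrozenSet[int]:
    """Hill-climb by single species-root splits and sibling merges."""
    best_key = _key(idx, roots, mode)
    improved = True
    while improved:
        improved = False
        moves: List[FrozenSet[int]] = []
        for r in roots:  # split moves
            if not idx.is_leaf[r]:
                moves.append(roots - {r} | frozenset(idx.children[r]))
        for v in range(len(idx.nodes)):  # merge moves (local exchange)
            if v in roots:
                continue
            kids = idx.children[v]
            if kids and all(c in roots for c in kids):
                moves.append(roots - frozenset(kids) | {v})
        for cand in moves:
            key = _key(idx, cand, mode)
            if key < best_key:
                best_key = key
                roots = cand
                improved = True
    return roots


def _dp_antichain(idx: _IndexedTree, lam_s: float, lam_w: float) -> FrozenSet[int]:
    """For FIXED rates the best antichain decomposes over the tree:
    best(v) = max(all edges below v within; v's child edges speciation +
    best(children)).  Ties prefer the coarser choice."""
    n = len(idx.nodes)
    f_s = [math.log(lam_s) - lam_s * idx.length[i] for i in range(n)]
    f_w = [math.log(lam_w) - lam_w * idx.length[i] for i in range(n)]
    fw_sub = [0.0] * n  # sum of f_w over edges strictly below each node
    best = [0.0] * n
    as_root = [True] * n
    for v in range(n - 1, -1, -1):
        if idx.is_leaf[v]:
            continue
        for c in idx.children[v]:
            fw_sub[v] += f_w[c] + fw_sub[c]
        split_val = sum(f_s[c] + best[c] for c in idx.children[v])
        if split_val > fw_sub[v] + 1e-12:
            best[v] = split_val
            as_root[v] = False
        else:
            best[v] = fw_sub[v]
    roots: List[int] = []
    stack = [idx.root]
    while stack:
        v = stack.pop()
        if as_root[v]:
            roots.append(v)
        else:
            stack.extend(idx.children[v])
    return frozenset(roots)


def _heuristic_search(idx: _IndexedTree, mode: str) -> FrozenSet[int]:
    """Large-tree search: seed (speciation, within) rate pairs from edge-length
    quantile splits, alternate the fixed-rate DP with rate re-estimation to a
    fixed point, then polish with local split/merge moves."""
    lengths = sorted(idx.length[1:])
    n_edges = len(lengths)
    seeds: List[Tuple[float, float]] = []
    for q in (0.5, 0.7, 0.8, 0.9, 0.95):
        cut = max(1, min(n_edges - 1, int(q * n_edges)))
        short, long = lengths[:cut], lengths[cut:]
        if not long:
            continue
        lam_w = len(short) / max(sum(short), BRANCH_FLOOR)
        lam_s = len(long) / max(sum(long), BRANCH_FLOOR)
        if lam_s < lam_w:  # speciation edges are the long (slow-rate) ones
            seeds.append((lam_s, lam_w))
    candidates = [frozenset([idx.root])]
    for lam_s, lam_w in seeds:
        roots = None
        for _ in range(50):
            new_roots = _dp_antichain(idx, lam_s, lam_w)
            if new_roots == roots:
                break
            roots = new_roots
            within_n = sum(idx.sub_count[r] for r in roots)
            within_s = sum(idx.sub_sum[r] for r in roots)
            spec_n = idx.total_count - within_n
            spec_s = idx.total_sum - within_s
            if spec_n == 0 or within_n == 0:
                break
            lam_s = spec_n / spec_s
            lam_w = within_n / within_s
        if roots:
            candidates.append(roots)
    # evaluate single-rate ML candidates under the requested mode's key
    best = min(candidates, key=lambda r: _key(idx, r, mode))
    return _local_search(idx, best, mode)


def ptp_ml_search(
    tree: PhyloTree,
    mode: str = "single",
    method: str = "auto",
    exact_limit: int = 12,
    min_branch: float = MIN_BRANCH,
) -> PTPDelimitation:
    """ML delimitation search.

    ``method='auto'`` uses exact antichain enumeration for trees with at most
    ``exact_limit`` tips and the heuristic (rate-conditioned DP plus local
    split/merge exchange) above that; the returned solution never scores
    worse than the one-species or every-tip-a-species baselines.
    """
    if mode not in {"single", "multi"}:
        raise ConfigError(f"unknown PTP mode {mode!r}")
    idx = _IndexedTree(tree, min_branch=min_branch)
    n_tips = sum(idx.is_leaf)
    if method == "auto":
        method = "exact" if n_tips <= exact_limit else "greedy"
    if method == "exact":
        roots = _exact_search(idx, mode)
    elif method == "greedy":
        roots = _heuristic_search(idx, mode)
    else:
        raise ConfigError(f"unknown search method {method!r}")
    # guarantee: never below the trivial baselines
    baselines = [
        frozenset([idx.root]),
        frozenset(i for i in range(len(idx.nodes)) if idx.is_leaf[i]),
    ]
    roots = min([roots] + baselines, key=lambda r: _key(idx, r, mode))
    ll, aic = _score(idx, roots, mode)
    within_n = sum(idx.sub_count[r] for r in roots)
    within_s = sum(idx.sub_sum[r] for r in roots)
    spec_n = idx.total_count - within_n
    spec_s = idx.total_sum - within_s
    lam_spec = spec_n / spec_s if spec_n else None
    if mode == "single":
        lam_within = within_n / within_s if within_n else None
    else:
        lam_within = {
            r: (idx.sub_count[r] / idx.sub_sum[r] if idx.sub_count[r] else None)
            for r in roots
        }
    return PTPDelimitation(
        tree=tree,
        species_roots=roots,
        mode=mode,
        loglik=ll,
        lambda_speciation=lam_spec,
        lambda_within=lam_within,
        n_species=len(roots),
        aic=aic,
        _indexed=idx,
    )


def delimitation_to_partition(delim: PTPDelimitation) -> Partition:
    """One block per species subtree; tips inherit their species label."""
    idx = delim._indexed or _IndexedTree(delim.tree)
    blocks = {}
    for k, r in enumerate(sorted(delim.species_roots)):
        blocks[f"sp{k + 1:03d}"] = idx.tips_below(r)
    return Partition.from_blocks(blocks)
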