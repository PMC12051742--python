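"""Topology weighting of block gene trees and ternary comparison.

Gene trees are built in blocks of 50 SNPs (neighbour joining on
substitution-corrected distances, rooted on the outgroup); for each block
the weight of every possible rooted ingroup topology is the fraction of
single-individual-per-taxon subtrees matching it.  Three-taxon weights are
computed exactly by subtree counting; larger taxon sets enumerate all
combinations below a cap or fall back to Monte-Carlo sampling.  Weight
vectors of three-taxon analyses live on a simplex and are binned on a
k-fold triangular subdivision (k=20 gives 400 congruent cells) to compare
observed against simulated distributions by per-bin differences and L1
distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .coalescent_engine import GeneTree
from .errors import ConfigurationError

__all__ = [
    "SnpBlock",
    "RootedTree",
    "TernaryBinGrid",
    "partition_blocks",
    "build_block_tree",
    "topology_weights",
    "weights_table",
    "label_three_taxon",
    "ternary_bin",
    "compare_distributions",
    "EXACT_CAP",
]

#: Above this many leaf combinations, exact mode refuses and sampled mode
#: (Monte-Carlo over combinations) should be used.
EXACT_CAP = 50_000

DEFAULT_SAMPLED_ITER = 10_000


@dataclass
class SnpBlock:
    """A block of consecutive SNPs on one contig with phased haplotypes
    (plus, optionally, an appended outgroup haplotype)."""

    contig: str
    start: int
    end: int
    positions: np.ndarray
    haps: np.ndarray            # sites x haplotypes
    hap_labels: list
    alphabet: str = "01"
    full: bool = True           # False for a trailing short block

    @property
    def n_snps(self) -> int:
        return self.haps.shape[0]


def partition_blocks(genotypes, block_size: int = 50,
                     outgroup_label: str = "OUT"):
    """Cut a genotype table into consecutive non-overlapping blocks of
    ``block_size`` SNPs; blocks never span contigs and the trailing short
    block of each contig is retained with ``full=False``.

    When the table carries ancestral alleles, an outgroup haplotype (the
    ancestral allele at every site) is appended as the last column.
    """
    gt = genotypes
    hap_labels = []
    for s in gt.samples:
        hap_labels.extend([f"{s}_a", f"{s}_b"])
    blocks = []
    for contig in dict.fromkeys(gt.contigs.tolist()):
        idx = np.flatnonzero(gt.contigs == contig)
        if len(idx) == 0:
            continue
        cpos = gt.pos[idx]
        if np.any(np.diff(cpos) < 0):
            raise ConfigurationError(f"SNPs unsorted on {contig}")
        for w0 in range(0, len(idx), block_size):
            sel = idx[w0:w0 + block_size]
            haps = gt.haps[sel].copy()
            labels = list(hap_labels)
            if gt.ancestral is not None:
                anc = gt.ancestral[sel].reshape(-1, 1).astype(np.int8)
                haps = np.hstack([haps, anc])
                labels = labels + [outgroup_label]
            blocks.append(SnpBlock(
                contig=contig, start=int(gt.pos[sel[0]]),
                end=int(gt.pos[sel[-1]]), positions=gt.pos[sel].copy(),
                haps=haps, hap_labels=labels, alphabet="01",
                full=len(sel) == block_size,
            ))
    return blocks


# ---------------------------------------------------------------------------
# distances and neighbour joining
# ---------------------------------------------------------------------------

def _pairwise_valid(a, b, missing):
    ok = (a != missing) & (b != missing)
    n = ok.sum()
    return ok, n


def _p_distance(H, missing=-1):
    n = H.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok, m = _pairwise_valid(H[:, i], H[:, j], missing)
            D[i, j] = D[j, i] = (
                float((H[ok, i] != H[ok, j]).mean()) if m else 0.0)
    return D


_TS_PAIRS = {(65, 71), (71, 65), (67, 84), (84, 67)}  # A<->G, C<->T


def _nucleotide_distance(H):
    """Distance cascade for A/C/G/T byte matrices: log-det (the
    GTR-consistent paralinear distance) -> K2P -> JC -> p, per pair."""
    n = H.shape[1]
    D = np.zeros((n, n))
    fallbacks = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = H[:, i], H[:, j]
            m = len(a)
            d = None
            # log-det / paralinear
            F = np.zeros((4, 4))
            codes = {65: 0, 67: 1, 71: 2, 84: 3}
            for x, y in zip(a, b):
                F[codes[int(x)], codes[int(y)]] += 1
            F /= m
            det = np.linalg.det(F)
            if det > 0:
                fa = F.sum(axis=1)
                fb = F.sum(axis=0)
                if np.all(fa > 0) and np.all(fb > 0):
                    d = -0.25 * (math.log(det)
                                 - 0.5 * (np.log(fa).sum() + np.log(fb).sum()))
            if d is None or not np.isfinite(d) or d < 0:
                # K2P
                diff = a != b
                P = np.mean([(int(x), int(y)) in _TS_PAIRS
                             for x, y in zip(a, b)]) if m else 0.0
                Q = diff.mean() - P
                arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
                if arg1 > 0 and arg2 > 0:
                    d = -0.5 * math.log(arg1 * math.sqrt(arg2))
                    fallbacks += 1
                else:
                    p = diff.mean()
                    arg = 1 - 4.0 * p / 3.0
                    if arg > 0:
                        d = -0.75 * math.log(arg)   # JC
                    else:
                        d = p                        # raw p-distance
                    fallbacks += 1
            D[i, j] = D[j, i] = max(d, 0.0)
    return D, fallbacks


@dataclass
class RootedTree:
    """Rooted tree in parent-array form (parent index > child index);
    internal nodes may have been created by deterministic left-first
    resolution of polytomies (zero-length in spirit; classification uses
    topology only)."""

    parent: np.ndarray
    leaf_labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def children(self):
        out = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            out[self.parent[v]].append(v)
        return out

    def mrca(self, u: int, v: int) -> int:
        while u != v:
            if u < v:
                u = self.parent[u]
            else:
                v = self.parent[v]
        return u

    def is_descendant(self, u: int, v: int) -> bool:
        """Is node u a descendant of (or equal to) node v?"""
        while u < v:
            u = self.parent[u]
        return u == v

    @classmethod
    def from_gene_tree(cls, tree: GeneTree) -> "RootedTree":
        return cls(parent=np.asarray(tree.parent), leaf_labels=list(tree.leaf_labels))


def _rooted_from_adjacency(adj, label_list, outgroup: str) -> RootedTree:
    """Root an unrooted tree (adjacency over node ids, leaves labelled in
    ``label_list``) on the outgroup leaf, suppressing unlabelled degree-2
    nodes and resolving polytomies left-first, and emit a parent array in
    post-order (parent index always greater than child index)."""
    out_idx = label_list.index(outgroup)
    if len(adj[out_idx]) != 1:
        raise ConfigurationError("outgroup must be a leaf")
    (start,) = tuple(adj[out_idx])

    new_parent = []
    new_labels = []

    def new_internal(child_ids):
        new_labels.append(None)
        new_parent.append(-1)
        me = len(new_parent) - 1
        for c in child_ids:
            new_parent[c] = me
        return me

    def emit(node, parent):
        kids = [n for n in adj[node] if n != parent]
        # suppress unlabelled pass-through nodes (e.g. the arbitrary NJ root)
        while len(kids) == 1 and label_list[node] is None:
            parent, node = node, kids[0]
            kids = [n for n in adj[node] if n != parent]
        if not kids:
            new_labels.append(label_list[node])
            new_parent.append(-1)
            return len(new_parent) - 1
        child_ids = [emit(k, node) for k in kids]
        while len(child_ids) > 2:  # left-first polytomy resolution
            child_ids = [new_internal(child_ids[:2])] + child_ids[2:]
        return new_internal(child_ids)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(20 * (len(label_list) + 5) + 100)
    try:
        top = emit(start, out_idx)
    finally:
        sys.setrecursionlimit(old)
    new_labels.append(outgroup)
    new_parent.append(-1)
    og = len(new_parent) - 1
    root = new_internal([top, og])

    # renumber so leaves occupy 0..n-1 while preserving post-order among
    # internal nodes (ancestors keep larger indices than descendants)
    n_nodes = len(new_parent)
    lab = new_labels
    leaves = [i for i in range(n_nodes) if lab[i] is not None]
    internals = [i for i in range(n_nodes) if lab[i] is None]
    order = leaves + internals
    rank = {old_i: new_i for new_i, old_i in enumerate(order)}
    parent_arr = np.full(n_nodes, -1, dtype=np.int64)
    for old_i in range(n_nodes):
        pa = new_parent[old_i]
        parent_arr[rank[old_i]] = rank[pa] if pa >= 0 else -1
    leaf_labels = [lab[i] for i in order if lab[i] is not None]
    rt = RootedTree(parent=parent_arr, leaf_labels=leaf_labels)
    _check_parent_order(rt)
    return rt


def build_block_tree(block: SnpBlock, outgroup: str = "OUT",
                     min_haplotypes: int = 4) -> RootedTree:
    """Neighbour-joining tree of one SNP block, rooted on the outgroup.

    Distances: log-det (GTR-consistent) with K2P/JC/p fallbacks for
    nucleotide data, p-distance for 0/1 data.  Negative NJ branch lengths
    are immaterial here because downstream classification is purely
    topological.  Identical sequences yield zero distances; the resulting
    arbitrary resolution is deterministic.  The number of per-pair distance
    fallbacks is attached as ``n_distance_fallbacks``.
    """
    if block.haps.shape[1] < min_haplotypes:
        raise ConfigurationError("need at least 4 haplotypes incl. outgroup")
    if outgroup not in block.hap_labels:
        raise ConfigurationError(f"outgroup '{outgroup}' not in block")
    if block.alphabet == "01":
        D = _p_distance(block.haps)
        n_fallback = 0
    else:
        D, n_fallback = _nucleotide_distance(block.haps)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [f"x{i}" for i in range(len(block.hap_labels))]
    sk = nj(DistanceMatrix(D, ids))
    nodes = list(sk.traverse(include_self=True))
    index = {id(nd): i for i, nd in enumerate(nodes)}
    adj = {i: set() for i in range(len(nodes))}
    label_list = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.is_tip() and nd.name is not None:
            label_list[i] = block.hap_labels[int(nd.name[1:])]
        for ch in nd.children:
            j = index[id(ch)]
            adj[i].add(j)
            adj[j].add(i)
    tree = _rooted_from_adjacency(adj, label_list, outgroup)
    tree.n_distance_fallbacks = n_fallback
    return tree


def _check_parent_order(tree: RootedTree):
    for v in range(tree.n_nodes - 1):
        pa = tree.parent[v]
        if pa >= 0 and pa <= v:
            raise AssertionError("parent-array order violated")


# ---------------------------------------------------------------------------
# topology weights
# ---------------------------------------------------------------------------

def _canonical_cherry(x: str, y: str) -> tuple:
    return tuple(sorted((x, y)))


def _three_taxon_exact(tree: RootedTree, taxon_map: dict) -> dict:
    taxa = list(taxon_map)
    tidx = {t: i for i, t in enumerate(taxa)}
    leaf_taxon = np.full(tree.n_leaves, -1, dtype=np.int64)
    pos = {lb: i for i, lb in enumerate(tree.leaf_labels)}
    for t, leaves in taxon_map.items():
        for lb in leaves:
            leaf_taxon[pos[lb]] = tidx[t]
    counts = np.zeros((tree.n_nodes, 3), dtype=np.int64)
    for v in range(tree.n_leaves):
        if leaf_taxon[v] >= 0:
            counts[v, leaf_taxon[v]] = 1
    ch = tree.children()
    for v in range(tree.n_leaves, tree.n_nodes):
        for c in ch[v]:
            counts[v] += counts[c]
    totals = counts[tree.root]
    weights = {}
    pairs = [(0, 1), (0, 2), (1, 2)]
    for (x, y) in pairs:
        z = 3 - x - y
        acc = 0
        for v in range(tree.n_leaves, tree.n_nodes):
            kids = ch[v]
            if len(kids) != 2:
                # resolved trees only; polytomies were binarised upstream
                continue
            L, R = kids
            pairs_xy = (counts[L, x] * counts[R, y]
                        + counts[L, y] * counts[R, x])
            if pairs_xy:
                acc += pairs_xy * (totals[z] - counts[v, z])
        weights[_canonical_cherry(taxa[x], taxa[y])] = acc
    denom = int(totals.prod())
    if denom == 0:
        raise ConfigurationError("a taxon has no leaves in the tree")
    return {k: v / denom for k, v in weights.items()}


def _classify_triplet(tree: RootedTree, a, b, c, names):
    mab, mac, mbc = tree.mrca(a, b), tree.mrca(a, c), tree.mrca(b, c)
    top = max(mab, mac, mbc)
    if mab < top:
        return _canonical_cherry(names[0], names[1])
    if mac < top:
        return _canonical_cherry(names[0], names[2])
    return _canonical_cherry(names[1], names[2])


def _classify_quartet(tree: RootedTree, leaves, names):
    """Rooted topology of four sampled leaves.

    Find a cherry (a pair whose MRCA has no other quartet leaf beneath),
    then place the remaining two leaves by where they join the cherry
    lineage: both at the same node gives the balanced shape, otherwise the
    earlier joiner is the middle leaf of a caterpillar.  Node indices along
    one root path are ancestry-ordered (post-order parent arrays), so the
    comparisons are index comparisons."""
    pair_ids = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    cherry = None
    for p in pair_ids:
        mp = tree.mrca(leaves[p[0]], leaves[p[1]])
        others = [q for q in range(4) if q not in p]
        if not any(tree.is_descendant(leaves[o], mp) for o in others):
            cherry = (p, mp)
            break
    (x, y), mxy = cherry
    z, w = [q for q in range(4) if q not in (x, y)]
    t_z = tree.mrca(mxy, leaves[z])
    t_w = tree.mrca(mxy, leaves[w])
    ch = _canonical_cherry(names[x], names[y])
    if t_z == t_w:
        other = _canonical_cherry(names[z], names[w])
        lo, hi = sorted([ch, other])
        return f"(({lo[0]},{lo[1]}),({hi[0]},{hi[1]}))"
    if t_z < t_w:
        mid, outer = z, w
    else:
        mid, outer = w, z
    return f"((({ch[0]},{ch[1]}),{names[mid]}),{names[outer]})"


def topology_weights(tree, taxon_map: dict, mode: str = "auto",
                     n_iter: int = DEFAULT_SAMPLED_ITER,
                     seed: int = 0) -> dict:
    """Topology weights of one gene tree.

    ``taxon_map`` maps taxon name -> list of leaf labels (the outgroup used
    for rooting is simply left out).  Returns ``{topology_key: weight}``
    summing to 1; for three taxa the key is the cherry pair tuple, for four
    taxa a canonical newick-like string.

    mode="exact" enumerates every combination of one leaf per taxon
    (refusing above :data:`EXACT_CAP` combinations); "sampled" Monte-Carlo
    approximates with ``n_iter`` draws; "auto" picks exact when feasible.
    Three-taxon exact weights use closed-form subtree counting.
    """
    if isinstance(tree, GeneTree):
        tree = RootedTree.from_gene_tree(tree)
    taxa = list(taxon_map)
    for t, leaves in taxon_map.items():
        if len(leaves) == 0:
            raise ConfigurationError(f"taxon '{t}' has no leaves")
    n_comb = int(np.prod([len(v) for v in taxon_map.values()]))
    if mode == "auto":
        mode = "exact" if (len(taxa) == 3 or n_comb <= EXACT_CAP) \
            else "sampled"
    if mode == "exact" and len(taxa) == 3:
        # closed-form subtree counting; no enumeration, no cap
        return _three_taxon_exact(tree, taxon_map)
    if mode == "exact" and n_comb > EXACT_CAP:
        raise ConfigurationError(
            f"{n_comb} combinations exceed the exact-mode cap "
            f"({EXACT_CAP}); use mode='sampled'")

    pos = {lb: i for i, lb in enumerate(tree.leaf_labels)}
    leaf_ids = {t: [pos[lb] for lb in v] for t, v in taxon_map.items()}

    def classify(combo):
        if len(taxa) == 3:
            return _classify_triplet(tree, *combo, names=taxa)
        if len(taxa) == 4:
            return _classify_quartet(tree, combo, names=taxa)
        raise ConfigurationError("weights support 3 or 4 ingroup taxa")

    counts = {}
    if mode == "exact":
        for combo in itertools.product(*(leaf_ids[t] for t in taxa)):
            key = classify(combo)
            counts[key] = counts.get(key, 0) + 1
        total = n_comb
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        pools = [leaf_ids[t] for t in taxa]
        for _ in range(n_iter):
            combo = tuple(p[rng.integers(len(p))] for p in pools)
            key = classify(combo)
            counts[key] = counts.get(key, 0) + 1
        total = n_iter
    else:
        raise ConfigurationError(f"unknown mode '{mode}'")
    return {k: v / total for k, v in counts.items()}


def label_three_taxon(t1: str, t2: str, t3: str) -> dict:
    """Canonical topo labels for a three-taxon analysis ``(t1, t2, t3)``:
    topo1 = (t1,t3) cherry, topo2 = (t2,t3) cherry, topo3 = (t1,t2) cherry.

    With (SPA, EURw, EURns): topo2 groups EURw with EURns
    (introgression/ILS signal), topo3 groups SPA with EURw (the carrion
    species tree)."""
    return {
        "topo1": _canonical_cherry(t1, t3),
        "topo2": _canonical_cherry(t2, t3),
        "topo3": _canonical_cherry(t1, t2),
    }


def weights_table(trees, taxon_map: dict, mode: str = "auto",
                  n_iter: int = DEFAULT_SAMPLED_ITER, seed: int = 0,
                  labels: Optional[dict] = None) -> pd.DataFrame:
    """Per-block topology weights as a DataFrame (one row per tree).

    ``labels`` optionally renames topology keys (e.g. the canonical
    topo1/2/3 mapping from :func:`label_three_taxon`)."""
    rows = []
    for i, tree in enumerate(trees):
        w = topology_weights(tree, taxon_map, mode=mode, n_iter=n_iter,
                             seed=seed + i)
        rows.append(w)
    all_keys = sorted({k for r in rows for k in r}, key=str)
    df = pd.DataFrame([{str(k): r.get(k, 0.0) for k in all_keys}
                       for r in rows])
    if labels:
        inv = {str(v): k for k, v in labels.items()}
        df = df.rename(columns=inv)
        for name in labels:
            if name not in df.columns:
                df[name] = 0.0
        df = df[sorted(labels)]
    return df


# ---------------------------------------------------------------------------
# ternary binning
# ---------------------------------------------------------------------------

@dataclass
class TernaryBinGrid:
    """Counts of weight vectors on the k-subdivided simplex (k^2 cells).

    Cells are keyed ``(i, j, o)`` with ``i = floor(k*w1)``,
    ``j = floor(k*w2)`` and orientation ``o`` (0 = upward, 1 = downward
    triangle)."""

    k: int
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_cells(self) -> int:
        return self.k * self.k

    def to_frame(self) -> pd.DataFrame:
        rows = [{"i": i, "j": j, "orientation": o, "count": c}
                for (i, j, o), c in sorted(self.counts.items())]
        return pd.DataFrame(rows)


def _ternary_cell(w, k: int):
    """Cell of a simplex point under k-fold triangular subdivision.

    Interior points have floor coordinates summing to k-1 (upward cell) or
    k-2 (downward); lattice-boundary points are pushed to the adjacent cell
    with the lowest index deterministically."""
    f = [w[0] * k, w[1] * k, w[2] * k]
    ij = [int(math.floor(x)) for x in f]
    frac = [x - i for x, i in zip(f, ij)]
    s = sum(ij)
    while s > k - 1:
        # a coordinate hit an exact lattice line; move to the lowest-index
        # coordinate with zero fractional part (boundary rule)
        zeros = [t for t in range(3) if frac[t] <= 1e-12 and ij[t] > 0]
        t = zeros[0] if zeros else int(np.argmax(frac))
        ij[t] -= 1
        frac[t] += 1.0
        s -= 1
    o = 0 if s == k - 1 else 1
    return (ij[0], ij[1], o)


def ternary_bin(weights, k: int = 20, tol: float = 1e-9) -> TernaryBinGrid:
    """Bin three-topology weight vectors on the k-subdivided simplex
    (k=20 -> 400 congruent triangular cells)."""
    W = np.asarray(weights, dtype=float)
    if isinstance(weights, pd.DataFrame):
        W = weights.to_numpy(dtype=float)
    if W.ndim == 1:
        W = W.reshape(1, -1)
    if W.shape[1] != 3:
        raise ConfigurationError("ternary binning needs 3-topology weights")
    sums = W.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ConfigurationError("weights do not sum to 1")
    grid = TernaryBinGrid(k=k)
    for row in W:
        cell = _ternary_cell(row, k)
        grid.counts[cell] = grid.counts.get(cell, 0) + 1
    return grid


def compare_distributions(observed: TernaryBinGrid,
                          simulated: TernaryBinGrid):
    """Per-bin (simulated - observed) differences with the simulated grid
    rescaled to the observed total; returns ``(DataFrame, L1 distance)``."""
    if observed.k != simulated.k:
        raise ConfigurationError("grids have different subdivision factors")
    scale = (observed.total / simulated.total) if simulated.total else 0.0
    keys = sorted(set(observed.counts) | set(simulated.counts))
    rows = []
    l1 = 0.0
    for key in keys:
        o = observed.counts.get(key, 0)
        s = simulated.counts.get(key, 0) * scale
        diff = s - o
        l1 += abs(diff)
        rows.append({"i": key[0], "j": key[1], "orientation": key[2],
                     "observed": o, "simulated_rescaled": s,
                     "difference": diff})
    return pd.DataFrame(rows), float(l1)
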