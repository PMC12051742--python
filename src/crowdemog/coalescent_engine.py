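"""Structured-coalescent simulation of independent non-recombining loci.

This is the generative core of the package: genealogies are drawn under a
:class:`~crowdemog.demography.DemographicModel` (splits, per-branch sizes,
exponential growth, epochs of asymmetric migration) by an exact
event-driven backward simulation, and mutations are dropped on branches
either under an infinite-sites model (0/1 haplotypes, every site
polymorphic) or a finite-sites HKY-style model with a configurable
transition fraction (recurrent hits and back-mutation possible).

Haploid lineages are simulated; diploid individuals are consecutive
haplotype pairs in row order, so phase is known by construction in
synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .demography import (
    DemographicModel,
    Population,
    SplitEvent,
    years_to_generations,
)
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SampleConfig",
    "GeneTree",
    "HaplotypeBlock",
    "CompiledDemography",
    "compile_demography",
    "simulate_locus",
    "simulate_tree_set",
    "mutate_infinite_sites",
    "mutate_finite_sites",
    "batch_pair_sfs",
    "with_outgroup",
    "locus_seed",
]

_BASES = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def locus_seed(master: int, index: int, stream: int = 0) -> int:
    """Counter-based per-locus seed: locus ``index`` is reproducible
    independently of how many loci are simulated."""
    ss = np.random.SeedSequence((int(master), int(index), int(stream)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class SampleConfig:
    """Per-population haploid sample counts (2 x diploids)."""

    def __init__(self, haploids: dict):
        self.haploids = {k: int(v) for k, v in haploids.items()}
        if any(v < 0 for v in self.haploids.values()):
            raise ConfigurationError("sample counts must be >= 0")
        if sum(self.haploids.values()) < 2:
            raise ConfigurationError("need at least 2 haploid samples in total")

    @classmethod
    def from_diploids(cls, diploids: dict) -> "SampleConfig":
        return cls({k: 2 * int(v) for k, v in diploids.items()})

    @classmethod
    def from_model(cls, model: DemographicModel) -> "SampleConfig":
        return cls.from_diploids(
            {p.name: p.n_diploid_samples for p in model.populations
             if p.n_diploid_samples > 0}
        )

    def total(self) -> int:
        return sum(self.haploids.values())

    def __repr__(self):
        return f"SampleConfig({self.haploids})"


@dataclass
class GeneTree:
    """A rooted binary genealogy in parent-array form.

    Nodes ``0..n-1`` are leaves at time 0; internal nodes are appended in
    coalescence order, so a parent always has a larger index than its
    children and the last node is the root.  Branch lengths are in
    generations; the tree is ultrametric by construction.
    """

    parent: np.ndarray
    times: np.ndarray
    leaf_labels: list
    leaf_pops: list
    locus_id: Optional[str] = None

    @property
    def n_leaves(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def children(self):
        """List of child lists per node."""
        out = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            out[self.parent[v]].append(v)
        return out

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        nonroot = self.parent >= 0
        bl[nonroot] = self.times[self.parent[nonroot]] - self.times[nonroot]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> np.ndarray:
        """Boolean matrix (n_nodes x n_leaves): descendant leaves per node."""
        n, m = self.n_leaves, self.n_nodes
        desc = np.zeros((m, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for v in range(m - 1):
            desc[self.parent[v]] |= desc[v]
        return desc

    def newick(self, precision: int = 6) -> str:
        ch = self.children()

        def render(v):
            if v < self.n_leaves:
                name = self.leaf_labels[v]
            else:
                name = ""
            if ch[v]:
                inner = ",".join(render(c) for c in ch[v])
                name = f"({inner}){name}"
            if self.parent[v] >= 0:
                bl = self.times[self.parent[v]] - self.times[v]
                return f"{name}:{bl:.{precision}f}"
            return name

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)


@dataclass
class HaplotypeBlock:
    """Alleles of one non-recombining locus, haplotypes x sites.

    ``matrix`` holds 0/1 (infinite sites, 0 = ancestral) or ASCII byte
    values of A/C/G/T (finite sites).  Row order matches the tree's leaf
    order; ``positions`` are strictly increasing 1-based coordinates."""

    locus_id: str
    locus_length: int
    positions: np.ndarray
    matrix: np.ndarray
    ancestral: np.ndarray
    sample_labels: list
    sample_pops: list
    alphabet: str = "01"
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def segregating(self) -> np.ndarray:
        """Boolean mask of polymorphic columns."""
        return np.array([len(np.unique(self.matrix[:, j])) > 1
                         for j in range(self.matrix.shape[1])])


@dataclass
class CompiledDemography:
    """Flattened piecewise-constant demography ready for the kernel."""

    pop_names: list
    bounds: np.ndarray
    N0: np.ndarray
    G: np.ndarray
    MB: np.ndarray
    MIGOUT: np.ndarray
    merge_iv: np.ndarray
    merge_from: np.ndarray
    merge_to: np.ndarray
    lin_pop0: np.ndarray
    leaf_labels: list
    leaf_pops: list
    mutation_rate: float

    @property
    def n_haploids(self) -> int:
        return len(self.lin_pop0)


def compile_demography(model: DemographicModel,
                       samples: Optional[SampleConfig] = None) -> CompiledDemography:
    """Convert a validated model (times in years, forward migration) into
    kernel arrays (times in generations, backward lineage-movement rates)."""
    violations = model.validate()
    if violations:
        raise ValidationError(violations)
    if samples is None:
        samples = SampleConfig.from_model(model)
    names = model.population_names
    for pop in samples.haploids:
        if pop not in names:
            raise ConfigurationError(f"samples reference unknown population '{pop}'")
    idx = {nm: i for i, nm in enumerate(names)}
    P = len(names)
    cfg = model.config
    gy = lambda t: years_to_generations(t, cfg)

    btimes = {0.0}
    for s in model.splits:
        btimes.add(gy(s.time))
    for e in model.migration_epochs:
        btimes.add(gy(e.start_time))
        btimes.add(gy(e.end_time))
    for p in model.populations:
        if p.growth_rate > 0 and p.growth_start_time > 0:
            btimes.add(gy(p.growth_start_time))
    bounds = np.array(sorted(btimes))
    n_int = len(bounds)

    # per-pop size overrides from splits where the pop is the receiver
    overrides = {nm: [] for nm in names}
    for s in model.splits:
        if s.ancestral_ne is not None:
            overrides[s.ancestral_pop].append((gy(s.time), float(s.ancestral_ne)))
    for nm in overrides:
        overrides[nm].sort()

    N0 = np.empty((n_int, P))
    G = np.zeros((n_int, P))
    for p in model.populations:
        j = idx[p.name]
        tegr = gy(p.growth_start_time) if p.growth_rate > 0 else 0.0
        for iv, b in enumerate(bounds):
            ov = [ne for (t0, ne) in overrides[p.name] if t0 <= b + 1e-12]
            if ov:
                N0[iv, j] = ov[-1]
            elif b < tegr:
                N0[iv, j] = p.ne_present * np.exp(-p.growth_rate * b)
                G[iv, j] = p.growth_rate
            else:
                N0[iv, j] = p.ne_present * np.exp(-p.growth_rate * tegr)

    MB = np.zeros((n_int, P, P))
    for e in model.migration_epochs:
        s_g, e_g = gy(e.start_time), gy(e.end_time)
        for (donor, recipient), m in e.normalised_rates().items():
            if m == 0.0:
                continue
            for iv, b in enumerate(bounds):
                if s_g - 1e-12 <= b < e_g - 1e-12:
                    # forward donor->recipient: backward, a lineage sampled in
                    # the recipient traces back into the donor
                    MB[iv, idx[recipient], idx[donor]] += m
    MIGOUT = MB.sum(axis=2)

    merges = sorted(
        ((gy(s.time), idx[s.derived_pop], idx[s.ancestral_pop]) for s in model.splits)
    )
    merge_iv = np.array(
        [int(np.searchsorted(bounds, t)) for t, _, _ in merges], dtype=np.int64
    )
    # searchsorted finds the boundary equal to the merge time; merges apply
    # on entry to the interval starting at that boundary
    for (t, _, _), mi in zip(merges, merge_iv):
        assert abs(bounds[mi] - t) < 1e-9
    merge_from = np.array([f for _, f, _ in merges], dtype=np.int64)
    merge_to = np.array([a for _, _, a in merges], dtype=np.int64)

    lin_pop0 = []
    leaf_labels = []
    leaf_pops = []
    for nm in names:
        h = samples.haploids.get(nm, 0)
        for i in range(h):
            lin_pop0.append(idx[nm])
            leaf_labels.append(f"{nm}_{i // 2}_{'a' if i % 2 == 0 else 'b'}")
            leaf_pops.append(nm)
    return CompiledDemography(
        pop_names=names,
        bounds=bounds,
        N0=N0,
        G=G,
        MB=MB,
        MIGOUT=MIGOUT,
        merge_iv=merge_iv,
        merge_from=merge_from,
        merge_to=merge_to,
        lin_pop0=np.array(lin_pop0, dtype=np.int64),
        leaf_labels=leaf_labels,
        leaf_pops=leaf_pops,
        mutation_rate=cfg.mutation_rate,
    )


def _run_tree(comp: CompiledDemography, seed: int, locus_id=None) -> GeneTree:
    n = comp.n_haploids
    if n < 1:
        raise ConfigurationError("zero lineages requested")
    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    node_pop = np.empty(n_nodes, dtype=np.int64)
    status = _kernel._simulate_tree(
        seed, comp.lin_pop0, comp.bounds, comp.N0, comp.G, comp.MB, comp.MIGOUT,
        comp.merge_iv, comp.merge_from, comp.merge_to, parent, times, node_pop,
    )
    if status != _kernel.OK:
        raise RuntimeError("coalescent simulation exceeded the event cap; "
                           "check that the model funnels all lineages into "
                           "a single root population")
    return GeneTree(parent=parent, times=times, leaf_labels=list(comp.leaf_labels),
                    leaf_pops=list(comp.leaf_pops), locus_id=locus_id)


def simulate_locus(model: DemographicModel, samples: Optional[SampleConfig],
                   locus_length: int, mutation_model: str = "infinite_sites",
                   seed: int = 0):
    """Simulate one non-recombining locus: a genealogy plus mutated haplotypes.

    Returns ``(GeneTree, HaplotypeBlock)``; deterministic given ``seed``.
    """
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    comp = model if isinstance(model, CompiledDemography) else \
        compile_demography(model, samples)
    tree = _run_tree(comp, locus_seed(seed, 0, stream=0))
    mut_seed = locus_seed(seed, 0, stream=1)
    if mutation_model == "infinite_sites":
        block = mutate_infinite_sites(tree, locus_length, comp.mutation_rate,
                                      seed=mut_seed)
    elif mutation_model == "hky":
        block = mutate_finite_sites(tree, locus_length, seed=mut_seed,
                                    mutation_rate=comp.mutation_rate)
    else:
        raise ConfigurationError(f"unknown mutation model '{mutation_model}'")
    return tree, block


def simulate_tree_set(model: DemographicModel, samples: Optional[SampleConfig],
                      n_loci: int, locus_length: int, seed: int = 0):
    """Simulate ``n_loci`` independent genealogies (no mutations).

    Locus ``i`` depends only on ``(seed, i)``, not on ``n_loci``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    comp = model if isinstance(model, CompiledDemography) else \
        compile_demography(model, samples)
    return [
        _run_tree(comp, locus_seed(seed, i, stream=0), locus_id=f"locus{i}")
        for i in range(n_loci)
    ]


def mutate_infinite_sites(tree: GeneTree, locus_length: int,
                          mutation_rate: float, seed: int = 0) -> HaplotypeBlock:
    """Poisson mutations on branches; every mutation hits a fresh site, so
    the number of polymorphic sites equals the number of mutations."""
    rng = np.random.default_rng(seed)
    bl = tree.branch_lengths()
    total = bl.sum()
    n_mut = int(rng.poisson(mutation_rate * locus_length * total))
    n_mut = min(n_mut, locus_length)  # cannot exceed the number of distinct sites
    n = tree.n_leaves
    if n_mut == 0:
        return HaplotypeBlock(
            locus_id=tree.locus_id or "locus", locus_length=locus_length,
            positions=np.empty(0, dtype=np.int64),
            matrix=np.zeros((n, 0), dtype=np.int8),
            ancestral=np.empty(0, dtype=np.int8),
            sample_labels=list(tree.leaf_labels),
            sample_pops=list(tree.leaf_pops), alphabet="01",
        )
    branches = rng.choice(tree.n_nodes, size=n_mut, p=bl / total)
    positions = np.sort(rng.choice(locus_length, size=n_mut, replace=False) + 1)
    desc = tree.leaf_sets()
    matrix = desc[branches].T.astype(np.int8)  # haplotypes x sites
    return HaplotypeBlock(
        locus_id=tree.locus_id or "locus", locus_length=locus_length,
        positions=positions.astype(np.int64), matrix=matrix,
        ancestral=np.zeros(n_mut, dtype=np.int8),
        sample_labels=list(tree.leaf_labels),
        sample_pops=list(tree.leaf_pops), alphabet="01",
        meta={"n_mutations": int(n_mut)},
    )


def mutate_finite_sites(tree: GeneTree, locus_length: int,
                        ts_fraction: float = 0.5, seed: int = 0,
                        mutation_rate: float = 3.18e-9) -> HaplotypeBlock:
    """Finite-sites mutation with equal base frequencies.

    Sites are drawn uniformly with replacement (recurrent hits allowed);
    each mutation is a transition with probability ``ts_fraction``,
    otherwise one of the two transversions equiprobably.  With
    ``ts_fraction = 0.5`` each transversion type carries probability 0.25,
    i.e. a per-type rate ratio kappa = 2 (HKY with ts/tv ratio 2).
    """
    if not 0 <= ts_fraction <= 1:
        raise ValueError("ts_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bl = tree.branch_lengths()
    total = bl.sum()
    n_mut = int(rng.poisson(mutation_rate * locus_length * total))
    n = tree.n_leaves
    n_nodes = tree.n_nodes
    if n_mut == 0:
        return HaplotypeBlock(
            locus_id=tree.locus_id or "locus", locus_length=locus_length,
            positions=np.empty(0, dtype=np.int64),
            matrix=np.zeros((n, 0), dtype=np.uint8),
            ancestral=np.empty(0, dtype=np.uint8),
            sample_labels=list(tree.leaf_labels),
            sample_pops=list(tree.leaf_pops), alphabet="ACGT",
            meta={"n_mutations": 0, "n_transitions": 0},
        )
    branches = rng.choice(n_nodes, size=n_mut, p=bl / total)
    sites = rng.integers(1, locus_length + 1, size=n_mut)
    # mutation ages uniform along each branch
    ages = (tree.times[branches]
            + rng.random(n_mut) * bl[branches])
    is_ts = rng.random(n_mut) < ts_fraction
    tv_pick = rng.integers(0, 2, size=n_mut)

    hit_sites = np.unique(sites)
    site_col = {s: j for j, s in enumerate(hit_sites)}
    ancestral = rng.integers(0, 4, size=len(hit_sites))

    # state per node per hit site, filled root-down (parent index > child)
    state = np.empty((n_nodes, len(hit_sites)), dtype=np.int8)
    state[tree.root] = ancestral
    # group mutations by branch, oldest first within a branch
    order = np.lexsort((-ages, branches))
    by_branch = {}
    for k in order:
        by_branch.setdefault(int(branches[k]), []).append(k)
    n_transitions = 0
    for v in range(n_nodes - 2, -1, -1):
        pa = tree.parent[v]
        state[v] = state[pa]
        for k in by_branch.get(v, ()):  # oldest first
            j = site_col[int(sites[k])]
            cur = int(state[v, j])
            if is_ts[k]:
                state[v, j] = _TRANSITION[cur]
                n_transitions += 1
            else:
                others = [b for b in range(4) if b != cur and b != _TRANSITION[cur]]
                state[v, j] = others[int(tv_pick[k])]
    matrix = _BASES[state[:n]]
    return HaplotypeBlock(
        locus_id=tree.locus_id or "locus", locus_length=locus_length,
        positions=hit_sites.astype(np.int64), matrix=matrix,
        ancestral=_BASES[ancestral],
        sample_labels=list(tree.leaf_labels),
        sample_pops=list(tree.leaf_pops), alphabet="ACGT",
        meta={"n_mutations": int(n_mut), "n_transitions": int(n_transitions)},
    )


def with_outgroup(model: DemographicModel, name: str = "OUT", ne: float = 1e4,
                  divergence_time: float = 1e7, n_diploid: int = 1) -> DemographicModel:
    """Return a copy of the model with an outgroup population joined to the
    root lineage (defaults: Ne 10,000; 10 My divergence)."""
    d = model.to_dict()
    new = DemographicModel.from_dict(d)
    derived = {s.derived_pop for s in new.splits}
    roots = [p.name for p in new.populations if p.name not in derived]
    if len(roots) != 1:
        raise ValidationError([f"expected a single root population, found {roots}"])
    new.populations.append(
        Population(name=name, ne_present=ne, n_diploid_samples=n_diploid)
    )
    new.splits.append(
        SplitEvent(divergence_time, name, roots[0], ancestral_ne=None)
    )
    new.name = f"{model.name}+outgroup"
    return new


def _fold_cell(i: int, j: int, na: int, nb: int):
    s, comp = i + j, (na - i) + (nb - j)
    if s > comp:
        return na - i, nb - j
    if s == comp and (i, j) > (na - i, nb - j):
        return na - i, nb - j
    return i, j


def fold_index_map(na: int, nb: int) -> np.ndarray:
    """Flat map from raw cell (i,j) -> folded flat cell, -1 for the two
    monomorphic corners."""
    m = np.empty((na + 1) * (nb + 1), dtype=np.int64)
    for i in range(na + 1):
        for j in range(nb + 1):
            idx = i * (nb + 1) + j
            if (i, j) in ((0, 0), (na, nb)):
                m[idx] = -1
            else:
                fi, fj = _fold_cell(i, j, na, nb)
                m[idx] = fi * (nb + 1) + fj
    return m


def batch_pair_sfs(model: DemographicModel, samples: Optional[SampleConfig],
                   pairs, n_loci: int, locus_length: int, seed: int = 0,
                   mode: str = "branch"):
    """Simulate ``n_loci`` loci and accumulate folded joint-SFS matrices for
    the requested population pairs.

    mode="branch" accumulates branch lengths (a Rao-Blackwellised estimate
    of expected per-site cell mass); mode="poisson" draws actual mutation
    counts (one draw per branch shared across pairs) for synthetic observed
    spectra.  Returns ``{(popA, popB): matrix}`` with shape
    ``(nA+1, nB+1)`` in haploid counts.
    """
    comp = model if isinstance(model, CompiledDemography) else \
        compile_demography(model, samples)
    pidx = {nm: i for i, nm in enumerate(comp.pop_names)}
    nhap = {nm: int((comp.lin_pop0 == pidx[nm]).sum()) for nm in comp.pop_names}
    pair_a = np.array([pidx[a] for a, b in pairs], dtype=np.int64)
    pair_b = np.array([pidx[b] for a, b in pairs], dtype=np.int64)
    nhap_a = np.array([nhap[a] for a, b in pairs], dtype=np.int64)
    nhap_b = np.array([nhap[b] for a, b in pairs], dtype=np.int64)
    fold_maps = [fold_index_map(nhap[a], nhap[b]) for a, b in pairs]
    fold_off = np.zeros(len(pairs), dtype=np.int64)
    off = 0
    for k, fm in enumerate(fold_maps):
        fold_off[k] = off
        off += len(fm)
    fold_flat = np.concatenate(fold_maps)
    out_off = fold_off.copy()
    out_flat = np.zeros(off, dtype=np.float64)
    seeds = np.array(
        [locus_seed(seed, i, stream=0) for i in range(n_loci)], dtype=np.int64
    )
    theta = comp.mutation_rate * locus_length
    status = _kernel._batch_pair_sfs(
        seeds, comp.lin_pop0, comp.bounds, comp.N0, comp.G, comp.MB, comp.MIGOUT,
        comp.merge_iv, comp.merge_from, comp.merge_to,
        pair_a, pair_b, nhap_a, nhap_b,
        fold_flat, fold_off, out_off, out_flat,
        mode == "poisson", theta,
    )
    if status != _kernel.OK:
        raise RuntimeError("coalescent simulation exceeded the event cap")
    out = {}
    for k, (a, b) in enumerate(pairs):
        na, nb = nhap[a], nhap[b]
        mat = out_flat[out_off[k]:out_off[k] + (na + 1) * (nb + 1)]
        out[(a, b)] = mat.reshape(na + 1, nb + 1).copy()
    return out
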