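"""Folded joint-SFS composite likelihood: spectra, fitting, AIC, bootstrap.

The data are folded two-dimensional site-frequency spectra of population
pairs.  The expected spectrum under a demographic model is estimated by
coalescent simulation (branch lengths subtending each cell, a
Rao-Blackwellised Monte-Carlo estimate of per-site cell probabilities), and
models are scored by the multinomial composite log-likelihood summed over
the six population pairs, treating sites as independent.  Fitting follows a
cyclic conditional-maximisation scheme (one golden-section line search per
free parameter per cycle) with common random numbers across evaluations so
the simulated likelihood surface is smooth enough for line search.

The model/results split follows the usual statistical-modelling
convention: :class:`CompositeLikelihoodModel` holds the observed spectra
and the scenario template; ``fit()`` returns a :class:`DemographicFit`
carrying estimates, likelihood, AIC, trace and ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .coalescent_engine import (
    SampleConfig,
    batch_pair_sfs,
    compile_demography,
    fold_index_map,
)
from .demography import DemographicModel
from .errors import ConfigurationError, LikelihoodError, ValidationError

__all__ = [
    "JointSFS",
    "BinnedSFS",
    "ParameterEstimate",
    "BootstrapResult",
    "CompositeLikelihoodModel",
    "DemographicFit",
    "folded_jsfs",
    "bin_jsfs_14",
    "expected_jsfs",
    "composite_loglik",
    "fit_model",
    "aic",
    "parametric_bootstrap",
    "bias_correct",
    "neutral_genome_scaling",
    "bootstrap_locus_count",
    "PAIRS",
]

LN10 = math.log(10.0)

#: The six population pairs of the four-population panel.
PAIRS = [
    ("SPA", "EURw"), ("SPA", "EURns"), ("SPA", "IRQ"),
    ("EURw", "EURns"), ("EURw", "IRQ"), ("EURns", "IRQ"),
]

#: Floor applied to zero cells of a simulated expected SFS before taking
#: logs (finite simulation cannot populate every cell); renormalised.
P_FLOOR = 1e-8


def _unfolded_mask(na: int, nb: int) -> np.ndarray:
    """Boolean matrix of the kept (representative) folded cells."""
    fm = fold_index_map(na, nb)
    mask = np.zeros((na + 1) * (nb + 1), dtype=bool)
    for idx in range(len(fm)):
        if fm[idx] == idx:
            mask[idx] = True
    return mask.reshape(na + 1, nb + 1)


@dataclass
class JointSFS:
    """Folded joint site-frequency spectrum of one population pair.

    ``matrix`` has shape ``(nA+1, nB+1)`` (haploid counts); only the kept
    folded cells are populated, the two monomorphic corners are masked and
    carry zero.
    """

    pop_a: str
    pop_b: str
    n_hap_a: int
    n_hap_b: int
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = (self.n_hap_a + 1, self.n_hap_b + 1)
        if self.matrix.shape != expected:
            raise ConfigurationError(
                f"matrix shape {self.matrix.shape} != {expected}")

    @property
    def mask(self) -> np.ndarray:
        return _unfolded_mask(self.n_hap_a, self.n_hap_b)

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    @property
    def pair(self):
        return (self.pop_a, self.pop_b)

    # -- I/O ----------------------------------------------------------------

    def to_obs(self, path=None) -> str:
        """Serialise in a fastsimcoal-style .obs dialect."""
        lines = ["1 observations"]
        lines.append("\t".join([""] + [f"d{self.pop_b}_{j}"
                                       for j in range(self.n_hap_b + 1)]))
        for i in range(self.n_hap_a + 1):
            row = [f"d{self.pop_a}_{i}"] + [f"{v:g}" for v in self.matrix[i]]
            lines.append("\t".join(row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_obs(cls, text_or_path, pop_a="A", pop_b="B") -> "JointSFS":
        s = str(text_or_path)
        if "\n" not in s:
            with open(s) as fh:
                s = fh.read()
        lines = [l for l in s.strip().split("\n")]
        if "observations" not in lines[0]:
            raise ConfigurationError("not an .obs file: missing header")
        header = lines[1].split("\t")
        nb = len([h for h in header if h]) - 1
        rows = []
        names_a = []
        for line in lines[2:]:
            parts = line.split("\t")
            names_a.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        mat = np.array(rows)
        na = mat.shape[0] - 1
        # recover labels when the writer embedded them
        h1 = header[1] if len(header) > 1 else ""
        if h1.startswith("d") and "_" in h1:
            pop_b = h1[1:].rsplit("_", 1)[0]
        if names_a and names_a[0].startswith("d") and "_" in names_a[0]:
            pop_a = names_a[0][1:].rsplit("_", 1)[0]
        return cls(pop_a, pop_b, na, nb, mat)


@dataclass
class BinnedSFS:
    """14-bin reduction of a folded joint SFS.

    Per-axis categories are {absent, singleton, interior, fixed}; the 4x4
    grid minus the two fully-monomorphic corner combinations leaves 14 bins.
    """

    pop_a: str
    pop_b: str
    counts: dict

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def to_tsv(self, path=None) -> str:
        lines = ["bin\tcount"]
        for k, v in self.counts.items():
            lines.append(f"{k}\t{v:g}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


_CATS = ("0", "singleton", "interior", "fixed")


def _axis_category(i: int, n: int) -> str:
    if i == 0:
        return "0"
    if i == 1:
        return "singleton"
    if i == n:
        return "fixed"
    return "interior"


def bin_jsfs_14(jsfs: JointSFS) -> BinnedSFS:
    """Aggregate the folded joint SFS into the 14 polymorphism bins."""
    if jsfs.n_hap_a < 2 or jsfs.n_hap_b < 2:
        raise ConfigurationError("need at least 2 haploids per population")
    counts = {}
    for ca in _CATS:
        for cb in _CATS:
            if (ca, cb) in (("0", "0"), ("fixed", "fixed")):
                continue
            counts[f"{ca}/{cb}"] = 0.0
    mask = jsfs.mask
    for i in range(jsfs.n_hap_a + 1):
        for j in range(jsfs.n_hap_b + 1):
            if not mask[i, j] or jsfs.matrix[i, j] == 0:
                continue
            key = f"{_axis_category(i, jsfs.n_hap_a)}/{_axis_category(j, jsfs.n_hap_b)}"
            counts[key] += float(jsfs.matrix[i, j])
    assert len(counts) == 14
    return BinnedSFS(jsfs.pop_a, jsfs.pop_b, counts)


# ---------------------------------------------------------------------------
# building folded spectra from genotypes
# ---------------------------------------------------------------------------

def folded_jsfs(genotypes, pop_a: str, pop_b: str, mode: str = "complete_case"):
    """Folded joint SFS of two populations from diploid genotypes.

    ``genotypes`` is a :class:`crowdemog.vcfio.GenotypeTable` (or anything
    with ``alt_counts``/``called_counts`` per population).  Per site the
    alternate-allele counts ``(i, j)`` are folded with the complementary
    cell ``(nA-i, nB-j)``: the cell with the smaller total count keeps the
    site; exact ties go to the lexicographically smaller index.  Sites
    monomorphic across both populations fall in the masked corners and are
    excluded.

    mode="complete_case" uses only sites with no missing calls in either
    population; mode="projection:<nA>,<nB>" projects each site down to the
    requested haploid sizes by the hypergeometric expectation.
    """
    ac_a, an_a = genotypes.pop_alt_counts(pop_a)
    ac_b, an_b = genotypes.pop_alt_counts(pop_b)
    na_full = genotypes.n_haploids(pop_a)
    nb_full = genotypes.n_haploids(pop_b)
    if na_full == 0 or nb_full == 0:
        raise ConfigurationError("empty population in folded_jsfs")

    if mode == "complete_case":
        keep = (an_a == na_full) & (an_b == nb_full)
        na, nb = na_full, nb_full
        mat = np.zeros((na + 1, nb + 1))
        fm = fold_index_map(na, nb)
        idx = ac_a[keep] * (nb + 1) + ac_b[keep]
        cells = fm[idx]
        good = cells >= 0
        np.add.at(mat.reshape(-1), cells[good], 1.0)
        return JointSFS(pop_a, pop_b, na, nb, mat)

    if mode.startswith("projection"):
        try:
            spec = mode.split(":", 1)[1]
            na, nb = (int(x) for x in spec.split(","))
        except (IndexError, ValueError):
            raise ConfigurationError(
                "projection mode must be 'projection:<nA>,<nB>'")
        from scipy.stats import hypergeom
        mat = np.zeros((na + 1, nb + 1))
        keep = (an_a >= na) & (an_b >= nb)
        for i0, m_a, j0, m_b in zip(ac_a[keep], an_a[keep],
                                    ac_b[keep], an_b[keep]):
            wa = hypergeom.pmf(np.arange(na + 1), m_a, i0, na)
            wb = hypergeom.pmf(np.arange(nb + 1), m_b, j0, nb)
            mat += np.outer(wa, wb)
        # fold the projected mass
        fm = fold_index_map(na, nb)
        flat = mat.reshape(-1)
        out = np.zeros_like(flat)
        for idx in range(len(fm)):
            if fm[idx] >= 0:
                out[fm[idx]] += flat[idx]
        return JointSFS(pop_a, pop_b, na, nb, out.reshape(na + 1, nb + 1))

    raise ConfigurationError(f"unknown mode '{mode}'")


# ---------------------------------------------------------------------------
# expected spectra and likelihood
# ---------------------------------------------------------------------------

def _normalise_probs(mat: np.ndarray, mask: np.ndarray,
                     floor: Optional[float] = P_FLOOR) -> np.ndarray:
    p = np.where(mask, mat, 0.0)
    tot = p.sum()
    if tot <= 0:
        raise LikelihoodError("expected SFS has no mass")
    p = p / tot
    if floor is not None:
        p = np.where(mask & (p < floor), floor, p)
        p = np.where(mask, p, 0.0)
        p = p / p.sum()
    return p


def expected_jsfs(model: DemographicModel, pair, n_sim_loci: int,
                  locus_length: int = 2000, seed: int = 0,
                  floor: Optional[float] = P_FLOOR) -> np.ndarray:
    """Monte-Carlo estimate of per-polymorphic-site folded cell
    probabilities for one population pair; unmasked cells sum to 1."""
    if n_sim_loci < 1:
        raise ConfigurationError("n_sim_loci must be >= 1")
    mats = batch_pair_sfs(model, None, [tuple(pair)], n_sim_loci,
                          locus_length, seed=seed, mode="branch")
    mat = mats[tuple(pair)]
    na, nb = mat.shape[0] - 1, mat.shape[1] - 1
    return _normalise_probs(mat, _unfolded_mask(na, nb), floor)


def composite_loglik(obs, expected, floor: Optional[float] = P_FLOOR) -> float:
    """Multinomial composite log10-likelihood ``sum O_c * log10(p_c)``.

    ``obs`` may be a JointSFS (with an expected probability matrix) or a
    BinnedSFS (with a dict of bin probabilities).
    """
    if isinstance(obs, BinnedSFS):
        ll = 0.0
        for k, o in obs.counts.items():
            if o == 0:
                continue
            p = expected.get(k, 0.0) if hasattr(expected, "get") else expected[k]
            if p <= 0:
                if floor is None:
                    raise LikelihoodError(f"zero expected probability in bin {k}")
                p = floor
            ll += o * math.log10(p)
        return ll
    mat = obs.matrix
    p = np.asarray(expected, dtype=float)
    mask = obs.mask & (mat > 0)
    if np.any(mask & (p <= 0)):
        if floor is None:
            raise LikelihoodError("zero expected probability where observed > 0")
        p = np.where(mask & (p <= 0), floor, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, mat * np.log10(np.where(p > 0, p, 1.0)), 0.0)
    return float(terms.sum())


def aic(log10_lik: float, k: int) -> float:
    """AIC from a log10 composite likelihood: ``2k - 2 ln(10) log10(L)``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * LN10 * log10_lik


def neutral_genome_scaling(n_snps_used: int, n_total_neutral_snps: int,
                           n_neutral_invariant: int) -> int:
    """Neutral genome length: ``used/total x (total + invariant)``, in bp."""
    if n_total_neutral_snps <= 0 or n_neutral_invariant <= 0 or n_snps_used <= 0:
        raise ValueError("all counts must be > 0")
    if n_snps_used > n_total_neutral_snps:
        raise ValueError("n_snps_used cannot exceed n_total_neutral_snps")
    return int(round(n_snps_used / n_total_neutral_snps
                     * (n_total_neutral_snps + n_neutral_invariant)))


def bootstrap_locus_count(n_neutral_snps: int = 11_146_221,
                          n_neutral_invariant: int = 625_134_484,
                          locus_length: int = 1000) -> int:
    """Number of bootstrap loci covering the neutral genome at the given
    locus length (ceiling division)."""
    return -(-(n_neutral_snps + n_neutral_invariant) // locus_length)


# ---------------------------------------------------------------------------
# model object and fitting
# ---------------------------------------------------------------------------

@dataclass
class ParameterEstimate:
    """Point estimate of one model fit."""

    model_name: str
    params: dict
    log10_lik: float
    k: int
    trace: list = field(default_factory=list)
    converged: bool = True
    message: str = ""

    @property
    def aic(self) -> float:
        return aic(self.log10_lik, self.k)


@dataclass
class BootstrapResult:
    """Parametric-bootstrap replicate estimates with bias correction."""

    param_names: list
    replicates: np.ndarray            # n_reps x p
    point: np.ndarray                 # original point estimate
    corrected: np.ndarray             # 2*point - mean(replicates)
    quantiles: dict                   # prob -> vector
    n_failed: int = 0

    def summary_frame(self):
        import pandas as pd
        rows = {}
        rows["point"] = self.point
        rows["boot_mean"] = self.replicates.mean(axis=0)
        rows["bias_corrected"] = self.corrected
        for q, v in self.quantiles.items():
            rows[f"q{q:g}"] = v
        return pd.DataFrame(rows, index=self.param_names)


def bias_correct(point, replicates):
    """Efron-Tibshirani bootstrap bias correction ``2*theta - mean(theta*)``
    plus quantiles (quartiles, extremes, and the 2.5/97.5 percent tails)."""
    reps = np.atleast_2d(np.asarray(replicates, dtype=float))
    if reps.shape[0] < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    point = np.asarray(point, dtype=float)
    corrected = 2.0 * point - reps.mean(axis=0)
    probs = (0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0)
    quantiles = {p: np.quantile(reps, p, axis=0) for p in probs}
    return corrected, quantiles


@dataclass
class FreeParameter:
    """A free parameter with its search range and scale ('linear'/'log')."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"

    def to_internal(self, x):
        return math.log(x) if self.scale == "log" else x

    def from_internal(self, u):
        return math.exp(u) if self.scale == "log" else u


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class CompositeLikelihoodModel:
    """Composite-likelihood model: observed folded joint spectra of the
    population pairs plus a parameterised demographic scenario.

    Parameters
    ----------
    observed : dict
        ``(popA, popB) -> JointSFS``; the pairs' contributions are summed
        (pairwise-composite likelihood).
    builder : callable
        ``params dict -> DemographicModel`` (e.g. ``build_gws_model``).
    fixed_params : dict
        Parameters held at these values.
    free_params : list of FreeParameter or (name, lo, hi[, scale]) tuples
        Parameters optimised by ``fit``; may be empty.
    n_sim_loci, locus_length :
        Simulation effort per likelihood evaluation.
    name : str
        Reported model name.
    """

    def __init__(self, observed: dict, builder: Callable, fixed_params: dict,
                 free_params=(), n_sim_loci: int = 2000,
                 locus_length: int = 2000, samples: Optional[SampleConfig] = None,
                 name: Optional[str] = None):
        self.observed = {tuple(k): v for k, v in observed.items()}
        self.builder = builder
        self.fixed_params = dict(fixed_params)
        self.free_params = [
            fp if isinstance(fp, FreeParameter) else FreeParameter(*fp)
            for fp in free_params
        ]
        names = [fp.name for fp in self.free_params]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate free parameter names")
        self.n_sim_loci = int(n_sim_loci)
        self.locus_length = int(locus_length)
        self.samples = samples
        self.name = name or builder.__name__.replace("build_", "").replace("_model", "")
        self.pairs = sorted(self.observed.keys())

    # -- likelihood evaluation ------------------------------------------

    def loglik(self, params: dict, sim_seed: int = 0,
               n_sim_loci: Optional[int] = None) -> float:
        """Composite log10-likelihood at ``params`` (free values merged over
        the fixed set), with simulation seed ``sim_seed``.

        Migration epochs are clamped to coexistence windows and structurally
        infeasible parameter combinations (split-order violations explored
        by the optimiser) score ``-inf``.
        """
        full = dict(self.fixed_params)
        full.update(params)
        full.setdefault("clamp_epochs", True)
        try:
            model = self.builder(full)
        except ValidationError:
            return -math.inf
        mats = batch_pair_sfs(
            model, self.samples, self.pairs,
            n_sim_loci or self.n_sim_loci, self.locus_length,
            seed=sim_seed, mode="branch",
        )
        total = 0.0
        for pair in self.pairs:
            obs = self.observed[pair]
            p = _normalise_probs(mats[pair], obs.mask)
            total += composite_loglik(obs, p)
        return total

    def profile(self, param: str, grid, sim_seed: int = 0,
                n_sim_loci: Optional[int] = None):
        """Single-parameter profile of the composite likelihood over a grid
        (other parameters fixed), with common random numbers across grid
        points.  Returns (grid, log10-likelihood array)."""
        grid = np.asarray(list(grid), dtype=float)
        lls = np.array([
            self.loglik({param: g}, sim_seed=sim_seed, n_sim_loci=n_sim_loci)
            for g in grid
        ])
        return grid, lls

    # -- fitting ----------------------------------------------------------

    def _golden(self, fp: FreeParameter, current: dict, sim_seed: int,
                n_evals: int):
        """Golden-section conditional maximisation of one parameter."""
        a = fp.to_internal(fp.lower)
        b = fp.to_internal(fp.upper)
        cache = {}

        def f(u):
            if u not in cache:
                trial = dict(current)
                trial[fp.name] = fp.from_internal(u)
                cache[u] = self.loglik(trial, sim_seed=sim_seed)
            return cache[u]

        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)
        f1, f2 = f(x1), f(x2)
        for _ in range(max(0, n_evals - 2)):
            if f1 < f2:
                a, x1, f1 = x1, x2, f2
                x2 = a + _GOLDEN * (b - a)
                f2 = f(x2)
            else:
                b, x2, f2 = x2, x1, f1
                x1 = b - _GOLDEN * (b - a)
                f1 = f(x1)
        u_best = max(cache, key=cache.get)
        return fp.from_internal(u_best), cache[u_best]

    def fit(self, n_cycles: int = 3, n_starts: int = 1, seed: int = 0,
            n_evals_per_param: int = 8, final_n_sim_loci: Optional[int] = None
            ) -> "DemographicFit":
        """Cyclic conditional maximisation (ECM-style) of the composite
        likelihood; multi-start with the best start reported.

        Each cycle line-searches every free parameter in turn by golden
        section; all evaluations within one start share a simulation seed
        (common random numbers).  ``final_n_sim_loci`` optionally re-scores
        the best parameters with more simulated loci.
        """
        k = len(self.free_params)
        if k == 0:
            sim_seed = _derived_seed(seed, 0)
            ll = self.loglik({}, sim_seed=sim_seed,
                             n_sim_loci=final_n_sim_loci or self.n_sim_loci)
            est = ParameterEstimate(self.name, dict(self.fixed_params), ll, 0,
                                    trace=[("fixed", ll)])
            return DemographicFit(self, est)

        best = None
        rng = np.random.default_rng(_derived_seed(seed, 1))
        for start in range(n_starts):
            sim_seed = _derived_seed(seed, 100 + start)
            current = {}
            for fp in self.free_params:
                if start == 0 and fp.name in self.fixed_params:
                    current[fp.name] = self.fixed_params[fp.name]
                else:
                    u = rng.uniform(fp.to_internal(fp.lower),
                                    fp.to_internal(fp.upper))
                    current[fp.name] = fp.from_internal(u)
            trace = []
            ll = self.loglik(current, sim_seed=sim_seed)
            trace.append(("start", dict(current), ll))
            for cycle in range(n_cycles):
                for fp in self.free_params:
                    val, ll = self._golden(fp, current, sim_seed,
                                           n_evals_per_param)
                    current[fp.name] = val
                trace.append((f"cycle{cycle}", dict(current), ll))
            if final_n_sim_loci:
                ll = self.loglik(current, sim_seed=_derived_seed(seed, 7),
                                 n_sim_loci=final_n_sim_loci)
                trace.append(("rescore", dict(current), ll))
            if best is None or ll > best[1]:
                best = (dict(current), ll, trace)

        params = dict(self.fixed_params)
        params.update(best[0])
        est = ParameterEstimate(self.name, params, best[1], k, trace=best[2])
        return DemographicFit(self, est)


def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence((int(seed), int(salt))).generate_state(1)[0]
               & 0x7FFFFFFF)


class DemographicFit:
    """Results of a composite-likelihood fit."""

    def __init__(self, model: CompositeLikelihoodModel,
                 estimate: ParameterEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def params(self) -> dict:
        return self.estimate.params

    @property
    def free_values(self) -> np.ndarray:
        return np.array([self.estimate.params[fp.name]
                         for fp in self.model.free_params])

    @property
    def log10_lik(self) -> float:
        return self.estimate.log10_lik

    @property
    def k(self) -> int:
        return self.estimate.k

    @property
    def aic(self) -> float:
        return self.estimate.aic

    @property
    def trace(self):
        return self.estimate.trace

    def summary(self) -> str:
        lines = [
            f"Composite-likelihood fit: {self.estimate.model_name}",
            f"  pairs:            {', '.join('-'.join(p) for p in self.model.pairs)}",
            f"  sites:            {sum(s.total for s in self.model.observed.values()):.0f}",
            f"  free parameters:  {self.k}",
            f"  log10 L:          {self.log10_lik:.4f}",
            f"  AIC:              {self.aic:.2f}",
            "  estimates:",
        ]
        free = {fp.name for fp in self.model.free_params}
        for name, val in sorted(self.estimate.params.items()):
            tag = "*" if name in free else " "
            lines.append(f"   {tag}{name:<16s} {val:.6g}")
        lines.append("  (* = optimised)")
        return "\n".join(lines)

    def parametric_bootstrap(self, n_reps: int = 100,
                             n_loci: int = 636_281, locus_length: int = 1000,
                             mutation_model: str = "infinite_sites",
                             seed: int = 0, n_cycles: int = 2,
                             n_evals_per_param: int = 6) -> BootstrapResult:
        """Simulate datasets at the point estimate and refit each,
        initialising at the point estimate."""
        return parametric_bootstrap(
            self.model, self.estimate, n_reps=n_reps, n_loci=n_loci,
            locus_length=locus_length, mutation_model=mutation_model,
            seed=seed, n_cycles=n_cycles,
            n_evals_per_param=n_evals_per_param,
        )


def fit_model(observed: dict, builder: Callable, fixed_params: dict,
              free_params=(), n_cycles: int = 3, sims_per_cycle: int = 2000,
              locus_length: int = 2000, n_starts: int = 1, seed: int = 0
              ) -> ParameterEstimate:
    """Functional wrapper: build a CompositeLikelihoodModel and fit it."""
    m = CompositeLikelihoodModel(observed, builder, fixed_params, free_params,
                                 n_sim_loci=sims_per_cycle,
                                 locus_length=locus_length)
    return m.fit(n_cycles=n_cycles, n_starts=n_starts, seed=seed).estimate


def simulate_observed_set(model: DemographicModel, pairs=None,
                          n_loci: int = 5000, locus_length: int = 2000,
                          seed: int = 0,
                          samples: Optional[SampleConfig] = None) -> dict:
    """Synthetic observed folded spectra: actual Poisson mutation counts on
    simulated genealogies (one draw per branch shared across pairs, so all
    pairwise spectra describe the same sites)."""
    pairs = [tuple(p) for p in (pairs or PAIRS)]
    mats = batch_pair_sfs(model, samples, pairs, n_loci, locus_length,
                          seed=seed, mode="poisson")
    out = {}
    for pair, mat in mats.items():
        na, nb = mat.shape[0] - 1, mat.shape[1] - 1
        out[pair] = JointSFS(pair[0], pair[1], na, nb, mat)
    return out


def parametric_bootstrap(model: CompositeLikelihoodModel,
                         estimate: ParameterEstimate, n_reps: int = 100,
                         n_loci: int = 636_281, locus_length: int = 1000,
                         mutation_model: str = "infinite_sites", seed: int = 0,
                         n_cycles: int = 2, n_evals_per_param: int = 6
                         ) -> BootstrapResult:
    """Parametric bootstrap of a fitted model.

    ``n_reps`` datasets are simulated at the point estimate and refit with
    the same free parameters, initialised at the point estimate; failures
    are recorded and excluded.  ``mutation_model`` is accepted for interface
    symmetry; spectra are generated from Poisson draws per branch, which is
    the infinite-sites observation model.
    """
    free_names = [fp.name for fp in model.free_params]
    if not free_names:
        raise ConfigurationError("parametric bootstrap needs free parameters")
    gen_model = model.builder(estimate.params)
    point = np.array([estimate.params[n] for n in free_names])
    reps = []
    n_failed = 0
    for r in range(n_reps):
        rep_seed = _derived_seed(seed, 1000 + r)
        try:
            obs = simulate_observed_set(gen_model, pairs=model.pairs,
                                        n_loci=n_loci,
                                        locus_length=locus_length,
                                        seed=rep_seed, samples=model.samples)
            sub = CompositeLikelihoodModel(
                obs, model.builder,
                fixed_params=dict(estimate.params),
                free_params=model.free_params,
                n_sim_loci=model.n_sim_loci,
                locus_length=model.locus_length,
                samples=model.samples, name=model.name,
            )
            fit = sub.fit(n_cycles=n_cycles, n_starts=1, seed=rep_seed,
                          n_evals_per_param=n_evals_per_param)
            reps.append([fit.params[n] for n in free_names])
        except Exception:
            n_failed += 1
    if len(reps) < 2:
        raise LikelihoodError(
            f"bootstrap produced {len(reps)} usable replicates "
            f"({n_failed} failed)")
    reps = np.array(reps)
    corrected, quantiles = bias_correct(point, reps)
    return BootstrapResult(param_names=free_names, replicates=reps,
                           point=point, corrected=corrected,
                           quantiles=quantiles, n_failed=n_failed)
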