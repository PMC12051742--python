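"""Synthetic whole-dataset generation with a chr18-like barrier region.

A dataset is a tiling of independent non-recombining loci over synthetic
contigs, simulated under one of the two demographic scenarios.  Loci inside
the declared barrier span are simulated under the same model with
EURw<->EURns and SPA<->EURw migration removed: divergent selection at a
barrier locus is emulated through its effect on *effective* migration, not
through fitness.  The output is a phased GT-only VCF, a population map, a
sidecar outgroup/ancestral-allele table, and a truth record sufficient to
regenerate the dataset byte-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .coalescent_engine import (
    SampleConfig,
    compile_demography,
    locus_seed,
    mutate_infinite_sites,
    _run_tree,
)
from .demography import DemographicModel, build_gws_model, build_lsi_model
from .errors import ConfigurationError, LayoutError
from .vcfio import (
    GenotypeTable,
    read_popmap,
    write_popmap,
    write_outgroup_tsv,
    write_vcf,
)

__all__ = [
    "DatasetLayout",
    "TruthRecord",
    "SyntheticDataset",
    "generate_dataset",
    "spike_missingness",
    "load_dataset",
]

_BUILDERS = {"gws": build_gws_model, "lsi": build_lsi_model}


@dataclass
class DatasetLayout:
    """Contig tiling: ``n_contigs`` x ``loci_per_contig`` loci of
    ``locus_length`` bp, gapless; the barrier span is a bp interval on one
    contig (loci fully inside it use the barrier model)."""

    n_contigs: int = 20
    loci_per_contig: int = 50
    locus_length: int = 2000
    barrier_contig: str = "contig18"
    barrier_span: Optional[tuple] = None  # (start_bp, end_bp), 1-based incl.

    def __post_init__(self):
        if self.barrier_span is None:
            # default: 40 central loci of the barrier contig
            n_barrier = min(40, self.loci_per_contig)
            first = (self.loci_per_contig - n_barrier) // 2
            self.barrier_span = (
                first * self.locus_length + 1,
                (first + n_barrier) * self.locus_length,
            )
        self.barrier_span = tuple(self.barrier_span)

    @property
    def contig_length(self) -> int:
        return self.loci_per_contig * self.locus_length

    @property
    def contig_names(self):
        return [f"contig{i + 1}" for i in range(self.n_contigs)]

    def validate(self):
        if self.n_contigs < 1 or self.loci_per_contig < 1 or self.locus_length < 1:
            raise LayoutError("layout counts must be >= 1")
        if self.barrier_contig not in self.contig_names:
            raise LayoutError(
                f"barrier contig {self.barrier_contig!r} not in layout")
        s, e = self.barrier_span
        if not (1 <= s <= e <= self.contig_length):
            raise LayoutError(
                f"barrier span {self.barrier_span} exceeds contig length "
                f"{self.contig_length}")

    def is_barrier_locus(self, contig: str, locus_index: int) -> bool:
        if contig != self.barrier_contig:
            return False
        start = locus_index * self.locus_length + 1
        end = (locus_index + 1) * self.locus_length
        return start >= self.barrier_span[0] and end <= self.barrier_span[1]


@dataclass
class TruthRecord:
    """Everything needed to regenerate a dataset byte-identically."""

    scenario: str
    params: dict
    master_seed: int
    layout: dict
    barrier_contig: str
    barrier_span: tuple
    locus_seeds: dict = field(default_factory=dict)  # "contig:locus" -> seed
    missingness: Optional[dict] = None

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["barrier_span"] = list(d["barrier_span"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TruthRecord":
        s = str(text_or_path)
        if not s.lstrip().startswith("{"):
            with open(s) as fh:
                s = fh.read()
        d = json.loads(s)
        d["barrier_span"] = tuple(d["barrier_span"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """File bundle plus in-memory genotypes of one synthetic dataset."""

    vcf_path: str
    popmap_path: str
    outgroup_path: str
    truth_path: str
    contig_lengths: dict
    truth: TruthRecord
    genotypes: Optional[GenotypeTable] = None


def _barrier_model(scenario: str, params: dict) -> DemographicModel:
    """Same scenario with EURw<->EURns and SPA<->EURw migration zeroed."""
    p = dict(params)
    for key in ("m_spa_eurw", "m_eurw_spa", "m_eurns_eurw", "m_eurw_eurns"):
        p[key] = 0.0
    return _BUILDERS[scenario](p)


def generate_dataset(scenario: str, params: dict, layout=None, seed: int = 0,
                     outdir: str = ".", prefix: Optional[str] = None,
                     samples: Optional[SampleConfig] = None) -> SyntheticDataset:
    """Generate a full synthetic dataset under a scenario.

    Neutral loci follow the scenario model; barrier loci the same model
    with the carrion-side migration edges removed.  Biallelic SNPs are
    written as phased VCF with the ancestral allele as REF and recorded in
    the outgroup sidecar table.  Deterministic given ``seed``.
    """
    if scenario not in _BUILDERS:
        raise ConfigurationError(f"unknown scenario '{scenario}' (gws|lsi)")
    layout = layout if isinstance(layout, DatasetLayout) else \
        DatasetLayout(**(layout or {}))
    layout.validate()
    model = _BUILDERS[scenario](params)
    barrier = _barrier_model(scenario, params)
    if samples is None:
        samples = SampleConfig.from_model(model)
    comp_neutral = compile_demography(model, samples)
    comp_barrier = compile_demography(barrier, samples)
    mu = model.config.mutation_rate

    contigs_out, pos_out, hap_rows = [], [], []
    locus_seeds = {}
    gidx = 0
    for contig in layout.contig_names:
        for l in range(layout.loci_per_contig):
            tree_seed = locus_seed(seed, gidx, stream=0)
            mut_seed = locus_seed(seed, gidx, stream=1)
            locus_seeds[f"{contig}:{l}"] = tree_seed
            comp = comp_barrier if layout.is_barrier_locus(contig, l) \
                else comp_neutral
            tree = _run_tree(comp, tree_seed, locus_id=f"{contig}:{l}")
            block = mutate_infinite_sites(tree, layout.locus_length, mu,
                                          seed=mut_seed)
            if block.n_sites:
                offset = l * layout.locus_length
                contigs_out.extend([contig] * block.n_sites)
                pos_out.extend((block.positions + offset).tolist())
                hap_rows.append(block.matrix.T)  # sites x haplotypes
            gidx += 1

    samples_names = []
    popmap = {}
    for pop in comp_neutral.pop_names:
        n_dip = samples.haploids.get(pop, 0) // 2
        for i in range(n_dip):
            nm = f"{pop}_{i}"
            samples_names.append(nm)
            popmap[nm] = pop

    haps = (np.vstack(hap_rows) if hap_rows
            else np.zeros((0, 2 * len(samples_names)), dtype=np.int8))
    contig_lengths = {c: layout.contig_length for c in layout.contig_names}
    gt = GenotypeTable(
        contigs=np.array(contigs_out, dtype=object),
        pos=np.array(pos_out, dtype=np.int64),
        haps=haps, samples=samples_names, popmap=popmap,
        ref=np.full(len(pos_out), "A", dtype=object),
        alt=np.full(len(pos_out), "T", dtype=object),
        ancestral=np.zeros(len(pos_out), dtype=np.int8),
        contig_lengths=contig_lengths,
    )

    prefix = prefix or f"{scenario}_seed{seed}"
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, f"{prefix}.vcf"),
        "popmap": os.path.join(outdir, f"{prefix}.popmap.tsv"),
        "outgroup": os.path.join(outdir, f"{prefix}.outgroup.tsv"),
        "truth": os.path.join(outdir, f"{prefix}.truth.json"),
    }
    write_vcf(gt, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    outgroup = {(c, int(p)): "A" for c, p in zip(gt.contigs, gt.pos)}
    write_outgroup_tsv(outgroup, paths["outgroup"])
    truth = TruthRecord(
        scenario=scenario,
        params={k: v for k, v in params.items()},
        master_seed=int(seed),
        layout={
            "n_contigs": layout.n_contigs,
            "loci_per_contig": layout.loci_per_contig,
            "locus_length": layout.locus_length,
            "barrier_contig": layout.barrier_contig,
            "barrier_span": list(layout.barrier_span),
        },
        barrier_contig=layout.barrier_contig,
        barrier_span=layout.barrier_span,
        locus_seeds=locus_seeds,
    )
    truth.to_json(paths["truth"])
    return SyntheticDataset(
        vcf_path=paths["vcf"], popmap_path=paths["popmap"],
        outgroup_path=paths["outgroup"], truth_path=paths["truth"],
        contig_lengths=contig_lengths, truth=truth, genotypes=gt,
    )


def regenerate(truth: TruthRecord, outdir: str = ".",
               prefix: Optional[str] = None) -> SyntheticDataset:
    """Rebuild a dataset from its truth record (byte-identical files)."""
    layout = dict(truth.layout)
    layout["barrier_span"] = tuple(layout["barrier_span"])
    ds = generate_dataset(truth.scenario, truth.params,
                          layout=DatasetLayout(**layout),
                          seed=truth.master_seed, outdir=outdir, prefix=prefix)
    if truth.missingness:
        ds = spike_missingness(ds, truth.missingness["rate"],
                               truth.missingness["seed"])
    return ds


def spike_missingness(dataset: SyntheticDataset, rate: float,
                      seed: int = 0) -> SyntheticDataset:
    """Set genotype calls to missing independently at the given rate.

    Missingness is applied per diploid call (both haplotypes of a sample at
    a site).  Returns a dataset with rewritten VCF and updated truth.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    gt = dataset.genotypes
    if gt is None:
        raise ConfigurationError("dataset carries no in-memory genotypes")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    haps = gt.haps.copy()
    n_samp = len(gt.samples)
    drop = rng.random((gt.n_sites, n_samp)) < rate
    for i in range(n_samp):
        haps[drop[:, i], 2 * i] = -1
        haps[drop[:, i], 2 * i + 1] = -1
    new_gt = GenotypeTable(
        contigs=gt.contigs, pos=gt.pos, haps=haps, samples=list(gt.samples),
        popmap=dict(gt.popmap), ref=gt.ref, alt=gt.alt,
        ancestral=gt.ancestral, contig_lengths=dict(gt.contig_lengths),
    )
    base, ext = os.path.splitext(dataset.vcf_path)
    vcf_path = f"{base}.miss{rate:g}{ext}"
    write_vcf(new_gt, vcf_path)
    truth = TruthRecord(**{**asdict(dataset.truth)})
    truth.barrier_span = tuple(truth.barrier_span)
    truth.missingness = {"rate": float(rate), "seed": int(seed)}
    truth_path = f"{base}.miss{rate:g}.truth.json"
    truth.to_json(truth_path)
    return SyntheticDataset(
        vcf_path=vcf_path, popmap_path=dataset.popmap_path,
        outgroup_path=dataset.outgroup_path, truth_path=truth_path,
        contig_lengths=dict(dataset.contig_lengths), truth=truth,
        genotypes=new_gt,
    )


def load_dataset(vcf_path, popmap_path, outgroup_path=None,
                 truth_path=None) -> SyntheticDataset:
    """Load a dataset bundle from disk into memory."""
    from .vcfio import read_vcf, read_outgroup_tsv

    popmap = read_popmap(popmap_path)
    gt = read_vcf(vcf_path, popmap)
    if outgroup_path:
        gt.attach_outgroup(read_outgroup_tsv(outgroup_path))
    truth = TruthRecord.from_json(truth_path) if truth_path else None
    return SyntheticDataset(
        vcf_path=str(vcf_path), popmap_path=str(popmap_path),
        outgroup_path=str(outgroup_path or ""), truth_path=str(truth_path or ""),
        contig_lengths=dict(gt.contig_lengths), truth=truth, genotypes=gt,
    )
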