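"""Genotype containers and VCF / TSV input-output.

Synthetic datasets are written as plain-text VCF 4.2 with GT-only FORMAT
and phased genotypes; reading goes through cyvcf2.  Haplotypes are the
primary representation (phase is known by construction in synthetic data);
diploid dosages derive from them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GenotypeTable",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_outgroup_tsv",
    "write_outgroup_tsv",
]


@dataclass
class GenotypeTable:
    """Biallelic SNP haplotypes with positions and a population map.

    ``haps`` has shape (sites, 2 * n_samples), values 0 (REF), 1 (ALT) or
    -1 (missing); columns ``2i, 2i+1`` are the two haplotypes of sample
    ``i``.  ``ancestral`` (optional) holds 0/1 per site when the ancestral
    allele is known from an outgroup (-1 unknown).
    """

    contigs: np.ndarray          # per-site contig name (object/str array)
    pos: np.ndarray              # per-site 1-based position
    haps: np.ndarray             # (sites, 2*n_samples) int8
    samples: list
    popmap: dict                 # sample -> population
    ref: Optional[np.ndarray] = None
    alt: Optional[np.ndarray] = None
    ancestral: Optional[np.ndarray] = None
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape != (len(self.pos), 2 * len(self.samples)):
            raise ConfigurationError("haplotype matrix shape mismatch")
        missing = [s for s in self.samples if s not in self.popmap]
        if missing:
            raise ConfigurationError(
                f"samples missing from population map: {missing[:5]}")

    # -- basic views -----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def populations(self):
        return sorted(set(self.popmap[s] for s in self.samples))

    def sample_indices(self, pop: str):
        return [i for i, s in enumerate(self.samples) if self.popmap[s] == pop]

    def hap_columns(self, pop: str) -> np.ndarray:
        cols = []
        for i in self.sample_indices(pop):
            cols.extend((2 * i, 2 * i + 1))
        return np.array(cols, dtype=np.int64)

    def n_haploids(self, pop: str) -> int:
        return 2 * len(self.sample_indices(pop))

    def pop_alt_counts(self, pop: str):
        """Per-site (alternate allele count, called allele count)."""
        cols = self.hap_columns(pop)
        sub = self.haps[:, cols]
        called = (sub >= 0).sum(axis=1)
        alt = np.where(sub > 0, sub, 0).sum(axis=1)
        return alt.astype(np.int64), called.astype(np.int64)

    def pop_freqs(self, pop: str) -> np.ndarray:
        """Per-site alternate allele frequency (NaN where uncalled)."""
        alt, called = self.pop_alt_counts(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / called, np.nan)

    def derived_freqs(self, pop: str) -> np.ndarray:
        """Per-site derived allele frequency, polarised by ``ancestral``.

        NaN where the ancestral state is unknown."""
        if self.ancestral is None:
            raise ConfigurationError("no ancestral alleles attached")
        f = self.pop_freqs(pop)
        anc = self.ancestral
        out = np.where(anc == 0, f, np.where(anc == 1, 1.0 - f, np.nan))
        return out

    def subset_sites(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            contigs=self.contigs[mask], pos=self.pos[mask],
            haps=self.haps[mask], samples=list(self.samples),
            popmap=dict(self.popmap),
            ref=None if self.ref is None else self.ref[mask],
            alt=None if self.alt is None else self.alt[mask],
            ancestral=None if self.ancestral is None else self.ancestral[mask],
            contig_lengths=dict(self.contig_lengths),
        )

    def attach_outgroup(self, table) -> None:
        """Polarise sites from an outgroup allele table
        ``{(contig, pos): allele}`` (allele is the REF/ALT base or 0/1)."""
        anc = np.full(self.n_sites, -1, dtype=np.int8)
        for k in range(self.n_sites):
            key = (self.contigs[k], int(self.pos[k]))
            if key not in table:
                continue
            a = table[key]
            if a in (0, 1):
                anc[k] = a
            elif self.ref is not None and a == self.ref[k]:
                anc[k] = 0
            elif self.alt is not None and a == self.alt[k]:
                anc[k] = 1
        self.ancestral = anc


def read_popmap(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


def write_popmap(popmap: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_outgroup_tsv(path) -> dict:
    """Sidecar outgroup/ancestral-allele table: contig, pos, allele."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("contig\t"):
                continue
            contig, pos, allele = line.split("\t")[:3]
            try:
                allele = int(allele)
            except ValueError:
                pass
            out[(contig, int(pos))] = allele
    return out


def write_outgroup_tsv(table, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tancestral\n")
        for (contig, pos), allele in table.items():
            fh.write(f"{contig}\t{pos}\t{allele}\n")


def write_vcf(gt: GenotypeTable, path, source: str = "crowdemog") -> None:
    """Write a GT-only phased VCF 4.2 (plain text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        seen = []
        for c in gt.contigs:
            if c not in seen:
                seen.append(c)
        for c in seen:
            length = gt.contig_lengths.get(c)
            if length:
                fh.write(f"##contig=<ID={c},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.samples) + "\n")
        ref = gt.ref if gt.ref is not None else np.full(gt.n_sites, "A", dtype=object)
        alt = gt.alt if gt.alt is not None else np.full(gt.n_sites, "T", dtype=object)
        code = {-1: ".", 0: "0", 1: "1"}
        for k in range(gt.n_sites):
            row = gt.haps[k]
            cells = [
                f"{code[int(row[2*i])]}|{code[int(row[2*i+1])]}"
                for i in range(len(gt.samples))
            ]
            fh.write(f"{gt.contigs[k]}\t{gt.pos[k]}\t.\t{ref[k]}\t{alt[k]}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


def read_vcf(path, popmap) -> GenotypeTable:
    """Read biallelic SNPs from a VCF into a GenotypeTable via cyvcf2.

    Non-biallelic records are skipped.  Unphased genotypes are accepted
    (allele order taken as written, which is immaterial for frequency- and
    count-based statistics).
    """
    from cyvcf2 import VCF

    if isinstance(popmap, (str, os.PathLike)):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contigs, pos, ref, alt, rows = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF is None or len(var.REF) != 1 \
                or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = np.array(var.genotype.array()[:, :2], dtype=np.int16)
        rows.append(g.reshape(-1).astype(np.int8))
        contigs.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    contig_lengths = {}
    for c, l in zip(vcf.seqnames, vcf.seqlens or []):
        contig_lengths[c] = l
    haps = (np.vstack(rows) if rows
            else np.zeros((0, 2 * len(samples)), dtype=np.int8))
    table = GenotypeTable(
        contigs=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        haps=haps, samples=samples,
        popmap={s: popmap[s] for s in samples},
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        contig_lengths=contig_lengths,
    )
    table.n_skipped_non_biallelic = n_skipped
    return table
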