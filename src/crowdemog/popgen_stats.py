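"""Windowed diversity, divergence and introgression statistics.

Estimators follow the standard population-genomic conventions: nucleotide
diversity and d_XY as mean pairwise differences per accessible site,
Hudson's F_ST averaged as a ratio of sums per window, net divergence
d_a = d_XY - (pi_x + pi_y)/2, Patterson's D with block-jackknife standard
errors, f4-ratio ancestry proportions, Malinsky's f_dM in 50-SNP windows
(dynamic-donor denominator), the four-gamete recombination statistic,
Tajima's D, and an exact Hardy-Weinberg filter with a barrier-contig
exemption.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .demography import GlobalConfig
from .errors import ConfigurationError

__all__ = [
    "window_stats",
    "net_divergence",
    "da_to_years",
    "patterson_d",
    "f4_ratio",
    "fdm_windows",
    "length_vs_introgression",
    "four_gamete_fraction",
    "hwe_exact_test",
    "hwe_filter",
    "tajimas_d",
]


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _pi_site(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Mean pairwise difference per site within a population."""
    n = called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    return np.where(called >= 2, h, 0.0)


def _dxy_site(alt1, n1, alt2, n2) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / n1
        p2 = alt2 / n2
        d = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where((n1 > 0) & (n2 > 0), d, 0.0)


def _hudson_site(alt1, n1, alt2, n2):
    """Per-site numerator/denominator of Hudson's F_ST (Bhatia et al. form)."""
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / n1
        p2 = alt2 / n2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (n1 >= 2) & (n2 >= 2)
    return np.where(ok, num, 0.0), np.where(ok, den, 0.0)


def net_divergence(d_xy: float, pi_x: float, pi_y: float) -> float:
    """d_a = d_XY - (pi_x + pi_y)/2; may legitimately be negative."""
    return d_xy - (pi_x + pi_y) / 2.0


def da_to_years(d_a: float, config: Optional[GlobalConfig] = None) -> float:
    """Convert net divergence to years: T = d_a / (2 mu) generations.

    Assumes all net divergence accumulated after the split at rate 2 mu per
    site per generation (one lineage each side).  Returns NaN for d_a <= 0.
    """
    config = config or GlobalConfig()
    if d_a is None or not d_a > 0:
        return float("nan")
    return d_a / (2.0 * config.mutation_rate) * config.generation_time


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------

def window_stats(genotypes, pops=None, window: int = 50_000,
                 accessible=None) -> pd.DataFrame:
    """Windowed pi, d_XY, Hudson F_ST and d_a along the genome.

    Windows are fixed-bp, left-anchored, non-overlapping, reported 1-based
    inclusive; the final short window of each contig is retained.
    ``accessible`` maps contig -> accessible bp per window (callable
    ``(contig, start, end) -> int``); by default every bp of the window is
    accessible, which is the correct normalisation for synthetic data where
    all monomorphic sites are observed.

    Windows with zero accessible sites report NaN statistics.
    """
    gt = genotypes
    pops = list(pops) if pops is not None else gt.populations
    counts = {p: gt.pop_alt_counts(p) for p in pops}
    rows = []
    contig_order = list(dict.fromkeys(gt.contigs.tolist()))
    for contig in contig_order:
        cmask = gt.contigs == contig
        cpos = gt.pos[cmask]
        clen = gt.contig_lengths.get(contig, int(cpos.max()) if len(cpos) else 0)
        for start in range(1, max(clen, 1) + 1, window):
            end = min(start + window - 1, clen)
            sel = np.flatnonzero(cmask)[(cpos >= start) & (cpos <= end)]
            if accessible is None:
                n_acc = end - start + 1
            else:
                n_acc = accessible(contig, start, end)
            row = {"contig": contig, "start": start, "end": end,
                   "n_variant": int(len(sel)), "n_accessible": int(n_acc)}
            if n_acc <= 0:
                for p in pops:
                    row[f"pi_{p}"] = np.nan
                for i, a in enumerate(pops):
                    for b in pops[i + 1:]:
                        row[f"dxy_{a}_{b}"] = np.nan
                        row[f"fst_{a}_{b}"] = np.nan
                        row[f"da_{a}_{b}"] = np.nan
                rows.append(row)
                continue
            pis = {}
            for p in pops:
                alt, called = counts[p]
                pis[p] = _pi_site(alt[sel], called[sel]).sum() / n_acc
                row[f"pi_{p}"] = pis[p]
            for i, a in enumerate(pops):
                alt_a, n_a = counts[a]
                for b in pops[i + 1:]:
                    alt_b, n_b = counts[b]
                    dxy = _dxy_site(alt_a[sel], n_a[sel],
                                    alt_b[sel], n_b[sel]).sum() / n_acc
                    num, den = _hudson_site(alt_a[sel], n_a[sel],
                                            alt_b[sel], n_b[sel])
                    fst = num.sum() / den.sum() if den.sum() > 0 else np.nan
                    row[f"dxy_{a}_{b}"] = dxy
                    row[f"fst_{a}_{b}"] = fst
                    row[f"da_{a}_{b}"] = net_divergence(dxy, pis[a], pis[b])
            rows.append(row)
    return pd.DataFrame(rows)


def hudson_fst(genotypes, pop_a: str, pop_b: str, sites=None) -> float:
    """Genome-wide Hudson F_ST (ratio of sums) between two populations."""
    alt_a, n_a = genotypes.pop_alt_counts(pop_a)
    alt_b, n_b = genotypes.pop_alt_counts(pop_b)
    if sites is not None:
        alt_a, n_a, alt_b, n_b = alt_a[sites], n_a[sites], alt_b[sites], n_b[sites]
    num, den = _hudson_site(alt_a, n_a, alt_b, n_b)
    return float(num.sum() / den.sum()) if den.sum() > 0 else float("nan")


# ---------------------------------------------------------------------------
# ABBA-BABA statistics
# ---------------------------------------------------------------------------

def _abba_baba_site(p1, p2, p3, pO):
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def _jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray):
    """Delete-one block jackknife of a ratio-of-sums statistic."""
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        return float("nan"), float("nan")
    est = tot_n / tot_d
    ids = np.unique(blocks)
    if len(ids) < 2:
        return est, float("nan")
    loo = []
    for b in ids:
        m = blocks != b
        d = den[m].sum()
        if d > 0:
            loo.append(num[m].sum() / d)
    loo = np.array(loo)
    g = len(loo)
    se = math.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
    return float(est), float(se)


def _default_blocks(contigs, pos, block_bp: int = 5_000_000) -> np.ndarray:
    codes = pd.factorize(contigs)[0].astype(np.int64)
    return codes * 10_000 + (np.asarray(pos) // block_bp)


def patterson_d(p1, p2, p3, pO, blocks=None, contigs=None, pos=None,
                min_blocks: int = 20):
    """Patterson's D for (((P1,P2),P3),O) from per-site derived frequencies.

    D = sum(ABBA - BABA) / sum(ABBA + BABA); the standard error comes from
    a delete-one block jackknife (default 5-Mb blocks when coordinates are
    supplied).  Returns ``(D, SE, Z)``; D is NaN when the denominator
    vanishes, SE when fewer than ``min_blocks`` blocks are available.
    """
    p1, p2, p3, pO = (np.asarray(x, dtype=float) for x in (p1, p2, p3, pO))
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    p1, p2, p3, pO = p1[ok], p2[ok], p3[ok], pO[ok]
    abba, baba = _abba_baba_site(p1, p2, p3, pO)
    num, den = abba - baba, abba + baba
    if den.sum() == 0:
        return float("nan"), float("nan"), float("nan")
    if blocks is None and contigs is not None:
        blocks = _default_blocks(np.asarray(contigs)[ok], np.asarray(pos)[ok])
    if blocks is None:
        d = float(num.sum() / den.sum())
        return d, float("nan"), float("nan")
    blocks = np.asarray(blocks)[: len(num)] if len(blocks) != len(num) \
        else np.asarray(blocks)
    d, se = _jackknife(num, den, blocks)
    if len(np.unique(blocks)) < min_blocks:
        se = float("nan")
    z = d / se if se and not math.isnan(se) and se > 0 else float("nan")
    return d, se, z


def _f4(pa, pb, pc, pd_):
    return (pa - pb) * (pc - pd_)


def f4_ratio(pA, pB, pX, pC, pO, blocks=None):
    """f4-ratio estimate of the ancestry proportion of target X from donor B.

    alpha = f4(A,O; X,C) / f4(A,O; B,C) for the arrangement where A is an
    unadmixed reference on the donor side, C on the other side, and O the
    outgroup.  alpha ~ 1 when X is a clone of the donor lineage and ~ 0
    when X carries none of it.  Returns ``(alpha, SE)``; flagged unstable
    (NaN) when the denominator f4 is ~ 0.
    """
    arrs = [np.asarray(x, dtype=float) for x in (pA, pB, pX, pC, pO)]
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    pA, pB, pX, pC, pO = (a[ok] for a in arrs)
    num = _f4(pA, pO, pX, pC)
    den = _f4(pA, pO, pB, pC)
    if abs(den.sum()) < 1e-12:
        return float("nan"), float("nan")
    if blocks is None:
        return float(num.sum() / den.sum()), float("nan")
    blocks = np.asarray(blocks)[ok]
    a, se = _jackknife(num, den, blocks)
    return a, se


def fdm_windows(genotypes, trio, outgroup_freqs=None, window_snps: int = 50
                ) -> pd.DataFrame:
    """Malinsky's f_dM in non-overlapping windows of ``window_snps`` SNPs.

    ``trio`` is ``(P1, P2, P3)`` for the arrangement (((P1,P2),P3),O);
    positive values indicate excess derived-allele sharing (gene flow)
    between P2 and P3, negative between P1 and P3.  The denominator uses
    the dynamic-donor convention: per site the donor frequency is the
    larger of the in-pair and P3 frequencies, with the sign arranged so
    complete P2-P3 introgression gives +1 and complete P1-P3 gives -1.

    Sites are polarised with the table's ancestral alleles (or an explicit
    outgroup frequency vector).  Windows with an undefined denominator are
    reported as NaN; per-contig means are available via groupby.
    """
    p1n, p2n, p3n = trio
    f1 = genotypes.derived_freqs(p1n)
    f2 = genotypes.derived_freqs(p2n)
    f3 = genotypes.derived_freqs(p3n)
    fO = (np.zeros_like(f1) if outgroup_freqs is None
          else np.asarray(outgroup_freqs, dtype=float))
    ok = ~(np.isnan(f1) | np.isnan(f2) | np.isnan(f3) | np.isnan(fO))
    idx = np.flatnonzero(ok)
    rows = []
    contigs = genotypes.contigs
    pos = genotypes.pos
    # windows never span contigs
    for contig in dict.fromkeys(contigs.tolist()):
        cidx = idx[contigs[idx] == contig]
        for w0 in range(0, len(cidx), window_snps):
            sel = cidx[w0:w0 + window_snps]
            if len(sel) == 0:
                continue
            v = fdm(f1[sel], f2[sel], f3[sel], fO[sel])
            rows.append({
                "contig": contig,
                "start": int(pos[sel[0]]),
                "end": int(pos[sel[-1]]),
                "n_snps": int(len(sel)),
                "fdm": v,
            })
    return pd.DataFrame(rows)


def fdm(p1, p2, p3, pO) -> float:
    """f_dM over a set of sites (see :func:`fdm_windows`)."""
    p1, p2, p3, pO = (np.asarray(x, dtype=float) for x in (p1, p2, p3, pO))
    abba, baba = _abba_baba_site(p1, p2, p3, pO)
    num = abba - baba
    den = np.empty_like(num)
    m = p2 >= p1
    pd23 = np.maximum(p2, p3)
    a, b = _abba_baba_site(p1, pd23, pd23, pO)
    den[m] = (a - b)[m]
    pd13 = np.maximum(p1, p3)
    a, b = _abba_baba_site(pd13, p2, pd13, pO)
    den[~m] = -(a - b)[~m]
    dsum = den.sum()
    if dsum == 0:
        return float("nan")
    return float(num.sum() / dsum)


def length_vs_introgression(mean_fdm, lengths):
    """Pearson correlation of per-chromosome mean f_dM against chromosome
    length; returns ``(r, p)``, NaN for constant input."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(mean_fdm, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ConfigurationError("need at least 3 chromosomes")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# recombination signal
# ---------------------------------------------------------------------------

def four_gamete_fraction(haps: np.ndarray) -> float:
    """Fraction of polymorphic site pairs displaying all four gametes.

    ``haps`` is a (sites x haplotypes) 0/1 matrix of one window (phased).
    On a single non-recombining genealogy under infinite sites the fraction
    is exactly 0.  Returns NaN with < 2 polymorphic sites.
    """
    H = np.asarray(haps)
    if H.ndim != 2:
        raise ValueError("haps must be 2-D (sites x haplotypes)")
    poly = [i for i in range(H.shape[0])
            if 0 < H[i][H[i] >= 0].sum() < (H[i] >= 0).sum()]
    if len(poly) < 2:
        return float("nan")
    Hp = H[poly].astype(np.int64)
    ok = Hp >= 0
    A = (Hp * ok).astype(np.float64)         # 1-alleles, missing as 0
    B = ((1 - Hp) * ok).astype(np.float64)   # 0-alleles, missing as 0
    g11 = (A @ A.T) > 0
    g10 = (A @ B.T) > 0
    g01 = (B @ A.T) > 0
    g00 = (B @ B.T) > 0
    viol = g11 & g10 & g01 & g00
    m = len(poly)
    iu = np.triu_indices(m, k=1)
    return float(viol[iu].mean())


# ---------------------------------------------------------------------------
# Hardy-Weinberg filtering
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value (mid-less enumeration
    over heterozygote counts conditional on allele counts)."""
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    # enumerate possible het counts with the same parity as n_rare
    probs = {}
    het0 = n_rare % 2
    # start from a mid het count and recurse both ways for stability
    mid = n_rare * (2 * n - n_rare) // (2 * n - 1) if (2 * n - 1) else het0
    if mid % 2 != n_rare % 2:
        mid += 1
    mid = min(max(mid, het0), n_rare)
    probs[mid] = 1.0
    h = mid
    while h >= het0 + 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h <= n_rare - 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    tot = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / tot
    return min(1.0, sum(v for v in probs.values() if v / tot <= p_obs + 1e-12) / tot)


def hwe_filter(genotypes, alpha: float = 1e-4,
               barrier_contig: Optional[str] = None):
    """Exact HWE test per site per population; a site is removed when
    p < alpha in ANY tested population.  Sites on the designated barrier
    contig are exempt (retained regardless).

    Returns ``(kept_site_mask, removal_log DataFrame)``.
    """
    gt = genotypes
    keep = np.ones(gt.n_sites, dtype=bool)
    log = []
    pops = gt.populations
    genos = {}
    for p in pops:
        cols = gt.hap_columns(p)
        a = gt.haps[:, cols[0::2]]
        b = gt.haps[:, cols[1::2]]
        called = (a >= 0) & (b >= 0)
        het = ((a + b) == 1) & called
        hom_alt = (a == 1) & (b == 1)
        hom_ref = (a == 0) & (b == 0)
        genos[p] = (het.sum(axis=1), hom_ref.sum(axis=1), hom_alt.sum(axis=1))
    for k in range(gt.n_sites):
        if barrier_contig is not None and gt.contigs[k] == barrier_contig:
            continue
        for p in pops:
            het, hr, ha = (int(genos[p][0][k]), int(genos[p][1][k]),
                           int(genos[p][2][k]))
            if het + hr + ha == 0:
                continue
            pval = hwe_exact_test(het, hr, ha)
            if pval < alpha:
                keep[k] = False
                log.append({"contig": gt.contigs[k], "pos": int(gt.pos[k]),
                            "population": p, "p_value": pval})
                break
    return keep, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d(alt: np.ndarray, called: np.ndarray) -> float:
    """Tajima's D from per-site alternate counts of one population.

    Uses the standard normalising constants with the modal sample size of
    the input; returns NaN with no segregating sites or n < 3.
    """
    alt = np.asarray(alt)
    called = np.asarray(called)
    if alt.size == 0:
        return float("nan")
    full = called == called.max()
    alt = alt[full]
    n = int(called.max())
    if n < 3:
        return float("nan")
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    k = _pi_site(alt[seg], np.full(S, n)).sum()
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((k - S / a1) / math.sqrt(var))


def tajimas_d_pop(genotypes, pop: str) -> float:
    alt, called = genotypes.pop_alt_counts(pop)
    return tajimas_d(alt, called)
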