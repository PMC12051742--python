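import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crowdemog import popgen_stats as ps
from crowdemog.demography import GlobalConfig
from crowdemog.vcfio import GenotypeTable


def make_table(haps, pops, contig="c1", pos=None, contig_length=None):
    """Small GenotypeTable: haps is (sites x haplotypes), two haplotypes per
    sample; pops assigns a population per SAMPLE."""
    haps = np.asarray(haps, dtype=np.int8)
    n_samp = haps.shape[1] // 2
    samples = [f"s{i}" for i in range(n_samp)]
    popmap = {f"s{i}": pops[i] for i in range(n_samp)}
    pos = np.asarray(pos if pos is not None
                     else np.arange(1, haps.shape[0] + 1))
    return GenotypeTable(
        contigs=np.array([contig] * haps.shape[0], dtype=object),
        pos=pos, haps=haps, samples=samples, popmap=popmap,
        ancestral=np.zeros(haps.shape[0], dtype=np.int8),
        contig_lengths={contig: contig_length or int(pos.max())},
    )


class TestWindowStats:
    def test_pi_one_difference_in_100_sites(self):
        # one diploid: its two haplotypes differ at 1 site in a 100-bp window
        haps = np.zeros((1, 2), dtype=np.int8)
        haps[0, 0] = 1
        gt = make_table(haps, ["A"], pos=[10], contig_length=100)
        df = ps.window_stats(gt, window=100)
        assert df.loc[0, "pi_A"] == pytest.approx(0.01)

    def test_fixed_differences_fst_and_dxy_one(self):
        haps = np.array([[1, 1, 0, 0]] * 5, dtype=np.int8)
        gt = make_table(haps, ["A", "B"], contig_length=5)
        df = ps.window_stats(gt, window=5)
        assert df.loc[0, "fst_A_B"] == pytest.approx(1.0)
        assert df.loc[0, "dxy_A_B"] == pytest.approx(1.0)

    def test_identical_frequencies_zero_numerator(self):
        haps = np.array([[1, 0, 1, 0]] * 4, dtype=np.int8)
        gt = make_table(haps, ["A", "B"], contig_length=4)
        assert ps.hudson_fst(gt, "A", "B") <= 0  # numerator sum <= 0

    def test_zero_accessible_flagged_missing(self):
        haps = np.zeros((1, 4), dtype=np.int8)
        gt = make_table(haps, ["A", "B"], pos=[1], contig_length=100)
        df = ps.window_stats(gt, window=100,
                             accessible=lambda c, s, e: 0)
        assert math.isnan(df.loc[0, "pi_A"])

    def test_da_identity_holds_per_window(self, small_dataset):
        pops = ["SPA", "EURw", "EURns", "IRQ"]
        df = ps.window_stats(small_dataset.genotypes, pops=pops,
                             window=20_000)
        for a, b in itertools.combinations(pops, 2):
            expect = df[f"dxy_{a}_{b}"] - (df[f"pi_{a}"] + df[f"pi_{b}"]) / 2
            assert np.allclose(df[f"da_{a}_{b}"], expect, equal_nan=True)

    def test_column_permutation_invariance(self, small_dataset, rng):
        gt = small_dataset.genotypes
        df1 = ps.window_stats(gt, pops=["SPA", "IRQ"], window=30_000)
        # permute samples within each population
        order = []
        for s in gt.samples:
            order.append(s)
        perm = sorted(order, key=lambda s: (gt.popmap[s], rng.random()))
        idx = [order.index(s) for s in perm]
        cols = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
        gt2 = GenotypeTable(
            contigs=gt.contigs, pos=gt.pos, haps=gt.haps[:, cols],
            samples=perm, popmap=dict(gt.popmap), ancestral=gt.ancestral,
            contig_lengths=dict(gt.contig_lengths))
        df2 = ps.window_stats(gt2, pops=["SPA", "IRQ"], window=30_000)
        for col in ("pi_SPA", "pi_IRQ", "dxy_SPA_IRQ", "fst_SPA_IRQ"):
            assert np.allclose(df1[col], df2[col], equal_nan=True)


class TestNetDivergence:
    def test_formula_values(self):
        assert ps.net_divergence(0.004, 0.003, 0.003) == pytest.approx(0.001)
        assert ps.net_divergence(0.003, 0.003, 0.003) == pytest.approx(0.0)
        assert ps.net_divergence(0.002, 0.003, 0.003) == pytest.approx(-0.001)

    def test_da_to_years(self):
        cfg = GlobalConfig()
        assert ps.da_to_years(2 * cfg.mutation_rate, cfg) == \
            pytest.approx(5.79)
        assert ps.da_to_years(3.767e-4, cfg) == pytest.approx(343_000, rel=1e-3)
        assert ps.da_to_years(0.001, cfg) == pytest.approx(910_377, rel=1e-4)
        assert math.isnan(ps.da_to_years(0.0, cfg))
        assert math.isnan(ps.da_to_years(-0.001, cfg))


def brute_force_d(p1, p2, p3, pO):
    """Pattern-count oracle on haploid 0/1 data (frequencies in {0,1})."""
    abba = baba = 0
    for a, b, c, o in zip(p1, p2, p3, pO):
        if (a, b, c, o) == (0, 1, 1, 0):
            abba += 1
        if (a, b, c, o) == (1, 0, 1, 0):
            baba += 1
    if abba + baba == 0:
        return float("nan")
    return (abba - baba) / (abba + baba)


class TestPattersonD:
    def test_pure_abba_site(self):
        d, _, _ = ps.patterson_d([0], [1], [1], [0])
        assert d == pytest.approx(1.0)

    def test_balanced_patterns_zero(self):
        d, _, _ = ps.patterson_d([0, 1], [1, 0], [1, 1], [0, 0])
        assert d == pytest.approx(0.0)

    def test_frequency_example(self):
        d, _, _ = ps.patterson_d([0.2], [0.8], [0.6], [0.0])
        # ABBA = 0.384, BABA = 0.024 -> D = 0.36/0.408
        assert d == pytest.approx(0.882, abs=1e-3)

    def test_matches_pattern_count_oracle(self, rng):
        for _ in range(20):
            n = 100
            p1, p2, p3 = (rng.integers(0, 2, n) for _ in range(3))
            pO = np.zeros(n)
            d, _, _ = ps.patterson_d(p1, p2, p3, pO)
            expect = brute_force_d(p1, p2, p3, pO)
            if math.isnan(expect):
                assert math.isnan(d)
            else:
                assert d == pytest.approx(expect)

    def test_jackknife_se_with_blocks(self, rng):
        n = 5000
        p1 = rng.random(n)
        p2 = np.clip(p1 + rng.normal(0, 0.1, n), 0, 1)
        p3 = rng.random(n)
        blocks = np.arange(n) // 200
        d, se, z = ps.patterson_d(p1, p2, p3, np.zeros(n), blocks=blocks)
        assert np.isfinite(se) and se > 0
        assert z == pytest.approx(d / se)


class TestF4Ratio:
    def test_clone_target_alpha_one(self, rng):
        n = 4000
        pA = rng.random(n)
        pB = np.clip(pA + rng.normal(0, 0.3, n), 0, 1)
        pC = np.clip(pA + rng.normal(0, 0.3, n), 0, 1)
        pO = np.zeros(n)
        a, _ = ps.f4_ratio(pA, pB, pB.copy(), pC, pO)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_unadmixed_target_alpha_zero(self, rng):
        n = 4000
        pA = rng.random(n)
        pB = np.clip(pA + rng.normal(0, 0.3, n), 0, 1)
        pC = np.clip(pA + rng.normal(0, 0.3, n), 0, 1)
        a, _ = ps.f4_ratio(pA, pB, pC.copy(), pC, np.zeros(n))
        assert a == pytest.approx(0.0, abs=1e-9)


class TestFdm:
    def test_sign_convention(self):
        # complete P2-P3 sharing -> +1; complete P1-P3 sharing -> -1
        assert ps.fdm([0, 0], [1, 1], [1, 1], [0, 0]) == pytest.approx(1.0)
        assert ps.fdm([1, 1], [0, 0], [1, 1], [0, 0]) == pytest.approx(-1.0)

    def test_windows_shape_and_range(self, small_dataset):
        df = ps.fdm_windows(small_dataset.genotypes, ("SPA", "EURw", "EURns"))
        assert set(df.columns) >= {"contig", "start", "end", "n_snps", "fdm"}
        v = df.fdm.dropna()
        assert ((v >= -1) & (v <= 1)).all()
        assert (df.n_snps <= 50).all()

    def test_length_vs_introgression_examples(self):
        r, p = ps.length_vs_introgression([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)
        r, _ = ps.length_vs_introgression([4, 3, 2, 1], [10, 20, 30, 40])
        assert r < 0
        r, p = ps.length_vs_introgression([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(r)

    def test_permutation_p_uniformity(self, rng):
        # unrelated vectors: permutation p-values roughly uniform
        pvals = []
        for _ in range(200):
            y = rng.normal(size=8)
            x = rng.normal(size=8)
            _, p = ps.length_vs_introgression(y, x)
            pvals.append(p)
        assert 0.3 < np.mean(np.array(pvals) < 0.5) < 0.7


class TestFourGamete:
    def test_all_four_gametes(self):
        haps = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert ps.four_gamete_fraction(haps) == pytest.approx(1.0)

    def test_single_tree_infinite_sites_zero(self, gws_model):
        from crowdemog.coalescent_engine import simulate_locus

        for seed in (1, 2, 3):
            _, block = simulate_locus(gws_model, None, 10_000, seed=seed)
            if block.n_sites >= 2:
                assert ps.four_gamete_fraction(block.matrix.T) == 0.0

    def test_too_few_sites_missing(self):
        assert math.isnan(ps.four_gamete_fraction(np.array([[0, 1]])))


def hwe_brute_force(n_het, n_hom_ref, n_hom_alt):
    """Exact HWE p by full enumeration of genotype configurations."""
    n = n_het + n_hom_ref + n_hom_alt
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            continue
        logp = (math.lgamma(n + 1) - math.lgamma(hr + 1)
                - math.lgamma(h + 1) - math.lgamma(hc + 1)
                + h * math.log(2))
        probs[h] = math.exp(logp)
    z = sum(probs.values())
    p_obs = probs[n_het] / z
    return sum(v for v in probs.values() if v / z <= p_obs + 1e-12) / z


class TestHwe:
    @pytest.mark.parametrize("counts", [
        (5, 10, 5), (0, 10, 10), (20, 0, 0), (3, 7, 1), (1, 1, 1),
        (10, 45, 45), (57, 14, 50)])
    def test_exact_test_matches_enumeration(self, counts):
        assert ps.hwe_exact_test(*counts) == \
            pytest.approx(hwe_brute_force(*counts), rel=1e-6)

    def test_all_heterozygous_removed(self):
        haps = np.tile([0, 1], (3, 100)).astype(np.int8)  # 100 samples, all het
        gt = make_table(haps, ["A"] * 100)
        keep, log = ps.hwe_filter(gt, alpha=1e-4)
        assert not keep.any()
        assert (log.population == "A").all()

    def test_hwe_proportions_retained(self, rng):
        # genotype counts at Hardy-Weinberg proportions: p = 0.5, n = 100
        cols = []
        for _ in range(100):
            g = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25])
            cols.append([1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0]))
        haps = np.array([np.array(cols).reshape(-1)], dtype=np.int8)
        gt = make_table(haps, ["A"] * 100)
        keep, _ = ps.hwe_filter(gt, alpha=1e-4)
        assert keep.all()

    def test_barrier_contig_exempt(self):
        haps = np.tile([0, 1], (2, 50)).astype(np.int8)
        gt = make_table(haps, ["A"] * 50, contig="chr18")
        keep, _ = ps.hwe_filter(gt, alpha=1e-4, barrier_contig="chr18")
        assert keep.all()


class TestTajimasD:
    def test_matches_dendropy_on_toy_alignment(self):
        # independent oracle: dendropy's population-genetics implementation
        import dendropy
        from dendropy.calculate import popgenstat

        seqs = ["AAAA", "AAAT", "ATAA", "TTAA"]  # n=4, S=3
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(4)])
        mat = dendropy.DnaCharacterMatrix.from_dict(
            {f"t{i}": s for i, s in enumerate(seqs)},
            taxon_namespace=taxa)
        expect = popgenstat.tajimas_d(mat)
        alt = np.array([sum(s[j] == "T" for s in seqs) for j in range(4)])
        called = np.full(4, 4)
        assert ps.tajimas_d(alt, called) == pytest.approx(expect, abs=1e-9)

    def test_equilibrium_near_zero_and_growth_negative(self):
        from crowdemog.coalescent_engine import simulate_locus
        from test_coalescent_engine import one_pop_model

        const = one_pop_model(ne=10_000, n_diploid=10)
        grow = one_pop_model(ne=200_000, n_diploid=10, growth=5e-4,
                             tegr=30_000)
        means = {}
        for name, model in (("const", const), ("grow", grow)):
            ds = []
            for i in range(400):
                _, block = simulate_locus(model, None, 20_000, seed=i)
                alt = block.matrix.sum(axis=0)
                d = ps.tajimas_d(alt, np.full(block.n_sites, 20))
                if not math.isnan(d):
                    ds.append(d)
            means[name] = np.mean(ds)
        assert abs(means["const"]) < 0.12
        assert means["grow"] < -0.25
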