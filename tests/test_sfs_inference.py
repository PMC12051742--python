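import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdemog.coalescent_engine import fold_index_map
from crowdemog.demography import (
    DemographicModel,
    GlobalConfig,
    Population,
    SplitEvent,
    build_gws_model,
)
from crowdemog.errors import ConfigurationError
from crowdemog.sfs_inference import (
    BinnedSFS,
    CompositeLikelihoodModel,
    FreeParameter,
    JointSFS,
    aic,
    bias_correct,
    bin_jsfs_14,
    bootstrap_locus_count,
    composite_loglik,
    expected_jsfs,
    folded_jsfs,
    neutral_genome_scaling,
    simulate_observed_set,
)
from crowdemog.vcfio import GenotypeTable


def brute_force_fold(raw, na, nb):
    """Independent fold oracle: enumerate every cell pair explicitly."""
    out = np.zeros_like(raw, dtype=float)
    for i in range(na + 1):
        for j in range(nb + 1):
            if (i, j) in ((0, 0), (na, nb)):
                continue
            ci, cj = na - i, nb - j
            if (i + j, i, j) < (ci + cj, ci, cj):
                keep = (i, j)
            else:
                keep = (ci, cj)
            out[keep] += raw[i, j]
    return out


class TestFolding:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(na=st.integers(2, 6), nb=st.integers(2, 6), seed=st.integers(0, 10_000))
    def test_fold_map_matches_brute_force(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        raw = rng.integers(0, 20, size=(na + 1, nb + 1)).astype(float)
        fm = fold_index_map(na, nb)
        folded = np.zeros((na + 1) * (nb + 1))
        for idx in range((na + 1) * (nb + 1)):
            if fm[idx] >= 0:
                folded[fm[idx]] += raw.reshape(-1)[idx]
        assert np.allclose(folded.reshape(na + 1, nb + 1),
                           brute_force_fold(raw, na, nb))

    def test_single_site_example(self):
        # nA=nB=2 haploids; alternate counts (2,1) fold into cell (0,1)
        # popA = sample a0 (haplotypes 1,1) -> count 2 of 2;
        # popB = sample b0 (haplotypes 1,0) -> count 1 of 2
        haps = np.array([[1, 1, 1, 0]], dtype=np.int8)
        gt = GenotypeTable(
            contigs=np.array(["c1"], dtype=object), pos=np.array([10]),
            haps=haps, samples=["a0", "b0"], popmap={"a0": "A", "b0": "B"})
        j = folded_jsfs(gt, "A", "B")
        assert j.matrix[0, 1] == 1
        assert j.matrix.sum() == 1

    def test_monomorphic_input_all_zero(self):
        haps = np.zeros((5, 4), dtype=np.int8)
        gt = GenotypeTable(
            contigs=np.array(["c1"] * 5, dtype=object),
            pos=np.arange(1, 6), haps=haps, samples=["a0", "b0"],
            popmap={"a0": "A", "b0": "B"})
        j = folded_jsfs(gt, "A", "B")
        assert j.matrix.sum() == 0

    def test_output_shape_31x31_for_15_diploids(self, small_dataset):
        j = folded_jsfs(small_dataset.genotypes, "SPA", "EURw")
        assert j.matrix.shape == (31, 31)

    def test_complete_case_skips_missing(self):
        haps = np.array([[1, -1, 0, 0], [1, 0, 0, 1]], dtype=np.int8)
        gt = GenotypeTable(
            contigs=np.array(["c1", "c1"], dtype=object),
            pos=np.array([1, 2]), haps=haps, samples=["a0", "b0"],
            popmap={"a0": "A", "b0": "B"})
        j = folded_jsfs(gt, "A", "B")
        assert j.total == 1  # first site has a missing call in A

    def test_empty_population_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            folded_jsfs(small_dataset.genotypes, "SPA", "NOPE")


class TestBinning:
    def test_always_14_bins_and_conservation(self, small_dataset):
        j = folded_jsfs(small_dataset.genotypes, "EURw", "EURns")
        b = bin_jsfs_14(j)
        assert len(b.counts) == 14
        assert b.total == pytest.approx(j.total)

    def test_single_category_concentration(self):
        mat = np.zeros((5, 5))
        mat[2, 0] = 7.0  # doubleton in A, absent in B
        j = JointSFS("A", "B", 4, 4, mat)
        b = bin_jsfs_14(j)
        assert b.counts["interior/0"] == 7.0
        assert sum(v for k, v in b.counts.items() if k != "interior/0") == 0

    def test_uniform_matrix_aggregates_by_group_size(self):
        na = nb = 4
        fm = fold_index_map(na, nb)
        mat = np.zeros((na + 1, nb + 1))
        kept = [(i, j) for i in range(na + 1) for j in range(nb + 1)
                if fm[i * (nb + 1) + j] == i * (nb + 1) + j]
        for i, j in kept:
            mat[i, j] = 3.0
        j_ = JointSFS("A", "B", na, nb, mat)
        b = bin_jsfs_14(j_)
        # independent aggregation oracle
        def cat(i, n):
            return {0: "0", 1: "singleton", n: "fixed"}.get(i, "interior")
        expect = {}
        for i, j in kept:
            expect[f"{cat(i, na)}/{cat(j, nb)}"] = \
                expect.get(f"{cat(i, na)}/{cat(j, nb)}", 0) + 3.0
        for k, v in expect.items():
            assert b.counts[k] == v


class TestLikelihood:
    def test_two_cell_example(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = 3
        mat[1, 0] = 1
        j = JointSFS("A", "B", 2, 2, mat)
        p = np.zeros((3, 3))
        p[0, 1] = 0.75
        p[1, 0] = 0.25
        ll = composite_loglik(j, p, floor=None)
        assert ll == pytest.approx(-0.976876, abs=1e-5)
        assert ll * math.log(10) == pytest.approx(-2.24934, abs=1e-4)

    def test_all_zero_observation(self):
        j = JointSFS("A", "B", 2, 2, np.zeros((3, 3)))
        assert composite_loglik(j, np.full((3, 3), 0.1)) == 0.0

    def test_uniform_probabilities(self):
        na = nb = 3
        fm = fold_index_map(na, nb)
        kept = [idx for idx in range((na + 1) ** 2) if fm[idx] == idx]
        C = len(kept)
        mat = np.zeros((na + 1, nb + 1))
        N = 0
        for idx in kept:
            mat[divmod(idx, nb + 1)] = 2
            N += 2
        j = JointSFS("A", "B", na, nb, mat)
        p = np.where(j.mask, 1.0 / C, 0.0)
        assert composite_loglik(j, p, floor=None) == \
            pytest.approx(N * math.log10(1 / C))

    def test_binned_likelihood(self):
        b = BinnedSFS("A", "B", {"0/singleton": 3, "singleton/0": 1})
        p = {"0/singleton": 0.75, "singleton/0": 0.25}
        assert composite_loglik(b, p, floor=None) == \
            pytest.approx(-0.976876, abs=1e-5)


class TestAic:
    def test_examples(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 2) == pytest.approx(50.0517, abs=1e-3)

    def test_lower_aic_wins(self):
        assert aic(-100.0, 2) < aic(-200.0, 2)


class TestScalingArithmetic:
    def test_neutral_genome_scaling_reproduces_printed_value(self):
        assert neutral_genome_scaling(5_774_276, 11_146_221,
                                      625_134_484) == 329_623_861

    def test_degenerate_cases(self):
        assert neutral_genome_scaling(2, 2, 2) == 4
        assert neutral_genome_scaling(1, 2, 2) == 2
        with pytest.raises(ValueError):
            neutral_genome_scaling(0, 2, 2)
        with pytest.raises(ValueError):
            neutral_genome_scaling(3, 2, 2)

    def test_bootstrap_locus_count(self):
        assert bootstrap_locus_count() == 636_281
        assert bootstrap_locus_count(10, 9, 10) == 2


class TestBiasCorrection:
    def test_arithmetic(self):
        corrected, q = bias_correct([10.0], [[12.0], [12.0]])
        assert corrected[0] == pytest.approx(8.0)
        corrected, _ = bias_correct([5.0], [[5.0], [5.0], [5.0]])
        assert corrected[0] == pytest.approx(5.0)

    def test_constant_replicates_constant_quantiles(self):
        _, q = bias_correct([1.0], [[3.0]] * 5)
        for v in q.values():
            assert v[0] == pytest.approx(3.0)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            bias_correct([1.0], [[2.0]])


class TestExpectedSfs:
    def test_probabilities_sum_to_one(self, gws_model):
        p = expected_jsfs(gws_model, ("SPA", "IRQ"), 300, seed=3)
        assert p.sum() == pytest.approx(1.0)
        assert p.min() >= 0

    def test_panmictic_marginal_matches_watterson_shape(self):
        # two demes split essentially at the present = one panmictic
        # population; the folded SFS over total count s follows
        # (1/s + 1/(n-s)) / (1 + delta_{s,n-s}), normalised
        n_dip = 3
        model = DemographicModel(
            name="pan",
            populations=[
                Population("A", ne_present=10_000, n_diploid_samples=n_dip),
                Population("B", ne_present=10_000, n_diploid_samples=n_dip)],
            splits=[SplitEvent(1e-6, "B", "A")],
            migration_epochs=[], config=GlobalConfig())
        p = expected_jsfs(model, ("A", "B"), 40_000, seed=5, floor=None)
        n = 4 * n_dip
        by_total = {}
        na = nb = 2 * n_dip
        for i in range(na + 1):
            for j in range(nb + 1):
                if p[i, j] > 0:
                    s = i + j if (i + j) <= n - (i + j) else n - (i + j)
                    by_total[s] = by_total.get(s, 0.0) + p[i, j]
        expect = {}
        for s in range(1, n // 2 + 1):
            expect[s] = (1 / s + 1 / (n - s)) / (2.0 if s == n - s else 1.0)
        z = sum(expect.values())
        for s in expect:
            assert by_total[s] == pytest.approx(expect[s] / z, abs=0.01)

    def test_long_divergence_concentrates_private_mass(self):
        model = DemographicModel(
            name="iso",
            populations=[
                Population("A", ne_present=1000, n_diploid_samples=2),
                Population("B", ne_present=1000, n_diploid_samples=2)],
            splits=[SplitEvent(5.79e6, "B", "A")],
            migration_epochs=[], config=GlobalConfig())
        p = expected_jsfs(model, ("A", "B"), 2000, seed=6)
        private = p[1:, 0].sum() + p[0, 1:].sum() + p[:-1, -1].sum() \
            + p[-1, :-1].sum()
        assert private > 0.95


class TestFitting:
    def test_zero_free_parameters_returns_fixed_likelihood(self, gws_params,
                                                           gws_model):
        obs = simulate_observed_set(gws_model, n_loci=200, seed=1)
        clm = CompositeLikelihoodModel(obs, build_gws_model, gws_params, [],
                                       n_sim_loci=200)
        fit = clm.fit(seed=3)
        assert fit.k == 0
        assert fit.aic == aic(fit.log10_lik, 0)
        assert fit.params["t_anc"] == gws_params["t_anc"]

    def test_same_seed_identical_traces(self, gws_params, gws_model):
        obs = simulate_observed_set(gws_model, n_loci=200, seed=2)
        free = [FreeParameter("t_anc", 2e5, 9e5)]
        fits = []
        for _ in range(2):
            clm = CompositeLikelihoodModel(obs, build_gws_model, gws_params,
                                           free, n_sim_loci=150)
            fits.append(clm.fit(n_cycles=1, seed=11, n_evals_per_param=4))
        assert fits[0].trace == fits[1].trace
        assert fits[0].params == fits[1].params

    def test_summary_mentions_free_parameters(self, gws_params, gws_model):
        obs = simulate_observed_set(gws_model, n_loci=200, seed=2)
        clm = CompositeLikelihoodModel(
            obs, build_gws_model, gws_params,
            [FreeParameter("t_anc", 2e5, 9e5)], n_sim_loci=100)
        fit = clm.fit(n_cycles=1, seed=1, n_evals_per_param=3)
        s = fit.summary()
        assert "t_anc" in s and "AIC" in s

    def test_parametric_bootstrap_toy_recovery(self, gws_params, gws_model):
        # single free split time; replicate refits initialised at the point
        # estimate scatter around it and bias correction stays moderate
        obs = simulate_observed_set(gws_model, n_loci=800, seed=4)
        free = [FreeParameter("t_anc", 2.5e5, 8e5)]
        clm = CompositeLikelihoodModel(obs, build_gws_model, gws_params, free,
                                       n_sim_loci=400)
        fit = clm.fit(n_cycles=1, seed=5, n_evals_per_param=5)
        boot = fit.parametric_bootstrap(n_reps=4, n_loci=800,
                                        locus_length=1000, seed=6,
                                        n_cycles=1, n_evals_per_param=5)
        assert boot.replicates.shape == (4, 1)
        assert boot.n_failed == 0
        # replicates and correction stay inside the search range order
        assert 1e5 < boot.corrected[0] < 1.2e6
        lo, hi = boot.quantiles[0.0][0], boot.quantiles[1.0][0]
        assert lo <= boot.replicates.mean() <= hi


class TestObsIO:
    def test_obs_round_trip(self, small_dataset):
        j = folded_jsfs(small_dataset.genotypes, "SPA", "IRQ")
        text = j.to_obs()
        j2 = JointSFS.from_obs(text)
        assert j2.pop_a == "SPA" and j2.pop_b == "IRQ"
        assert np.allclose(j2.matrix, j.matrix)
        assert text.startswith("1 observations")
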