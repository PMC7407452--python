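"""Context counting, beta-posterior sampling and the weighted variance
statistics (total, per-direction, marginalised, CpG, strand asymmetry)."""

import numpy as np
import pandas as pd
import pytest

from mutvar import context as ctx
from mutvar import synthetic
from mutvar._util import BASE_TO_CODE, DIRECTIONS, string_to_kmer
from mutvar.genomic_io import RegionMask
from mutvar.synthetic import (ContextRateModel, GenomeSimParams,
                              NeighborEffect)

from conftest import make_variant


def mask_of(chrom, start, end, strand="+"):
    return RegionMask(pd.DataFrame([(chrom, start, end, "intronic", strand)],
                                   columns=["chrom", "start", "end", "cls", "strand"]))


class TestCountContexts:
    def test_enumeration_on_four_bases(self):
        counts = ctx.count_contexts({"chr1": "ACGT"}, mask_of("chr1", 0, 4), 3)
        assert counts.sum() == 2
        assert counts[string_to_kmer("ACG")] == 1
        assert counts[string_to_kmer("CGT")] == 1

    def test_minus_strand_counts_reverse_complement(self):
        counts = ctx.count_contexts({"chr1": "ACGT"}, mask_of("chr1", 0, 4, "-"), 3)
        assert counts[string_to_kmer("ACG")] == 1  # revcomp of CGT
        assert counts[string_to_kmer("CGT")] == 1  # revcomp of ACG

    def test_windows_with_n_skipped(self):
        counts = ctx.count_contexts({"chr1": "ACNGT"}, mask_of("chr1", 0, 5), 3)
        assert counts.sum() == 0

    def test_uniform_genome_frequencies(self):
        g, mask, _, _ = synthetic.simulate_genome(GenomeSimParams(length=2_000_000, seed=14))
        counts = ctx.count_contexts(g, mask, 3)
        n = counts.sum()
        sd = np.sqrt(n * (1 / 64) * (1 - 1 / 64))
        assert np.all(np.abs(counts - n / 64) < 5 * sd)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            ctx.count_contexts({"chr1": "ACGT"}, mask_of("chr1", 0, 4), 2)

    def test_empty_mask_zero_contexts(self):
        counts = ctx.count_contexts({"chr1": "ACGT"}, RegionMask(), 3)
        assert counts.sum() == 0


class TestTally:
    def test_single_variant_bookkeeping(self):
        genome = {"chr1": "AAACGAAA"}
        variants = [make_variant("chr1", 3, "C", "T")]
        table = ctx.tally_cells(variants, genome, mask_of("chr1", 0, 8), 3)
        assert table.cell("ACG", ("C", "T")) == (1, 1)
        assert table.successes.sum() == 1

    def test_minus_strand_variant_oriented(self):
        genome = {"chr1": "AAACGAAA"}
        variants = [make_variant("chr1", 3, "C", "T")]
        table = ctx.tally_cells(variants, genome, mask_of("chr1", 0, 8, "-"), 3)
        # context ACG revcomps to CGT, direction C->T to G->A
        assert table.cell("CGT", ("G", "A")) == (1, 1)

    def test_mismatching_ancestral_base_raises_above_threshold(self):
        genome = {"chr1": "AAAAAAAA"}
        variants = [make_variant("chr1", 3, "C", "T")]
        with pytest.raises(ValueError, match="mismatch"):
            ctx.tally_cells(variants, genome, mask_of("chr1", 0, 8), 3)

    def test_empty_mask_gives_zero_trials_and_variance_errors(self):
        table = ctx.tally_cells([], {"chr1": "ACGTACGT"}, RegionMask(), 3)
        assert table.trials.sum() == 0
        with pytest.raises(ValueError):
            ctx.variance_total(table, n_draws=10, seed=0)

    def test_cell_ratios_recover_simulation_truth(self, small_genome_sim):
        g, mask, vs, tt = small_genome_sim
        table = ctx.tally_cells(vs, g, mask, 3)  # unfiltered: unbiased rates
        big = table.trials >= 1000
        for t in range(4):
            sel = big & (table.central_base != t) & (tt.probs[:, t] > 0)
            p = tt.probs[sel, t]
            obs = table.successes[sel, t] / table.trials[sel]
            sd = np.sqrt(p * (1 - p) / table.trials[sel])
            assert np.all(np.abs(obs - p) < 5 * sd)


class TestBetaPosteriors:
    def test_conjugacy_closed_form(self):
        trials = np.zeros(4, dtype=np.int64)
        succ = np.zeros((4, 4), dtype=np.int64)
        trials[0] = 2
        succ[0, 1] = 1  # A->C cell with n=2, s=1 => Beta(2,2), mean 1/2
        table = ctx.ContextTable(1, trials, succ)
        draws = ctx.sample_posteriors(table, 100_000, seed=1)
        assert draws[0, 1].mean() == pytest.approx(0.5, abs=0.01)
        # analytic check of the Beta(2,2) sd as well
        assert draws[0, 1].std() == pytest.approx(np.sqrt(1 / 20), abs=0.01)

    def test_empty_cell_is_uniform(self):
        table = ctx.ContextTable(1, np.zeros(4, dtype=np.int64),
                                 np.zeros((4, 4), dtype=np.int64))
        draws = ctx.sample_posteriors(table, 50_000, seed=2)
        assert draws[0, 1].mean() == pytest.approx(0.5, abs=0.01)
        assert draws[0, 1].min() >= 0 and draws[0, 1].max() <= 1

    def test_concentration_at_large_counts(self):
        trials = np.full(4, 10 ** 6, dtype=np.int64)
        succ = np.zeros((4, 4), dtype=np.int64)
        succ[0, 1] = 1000
        table = ctx.ContextTable(1, trials, succ)
        draws = ctx.sample_posteriors(table, 10_000, seed=3)
        assert draws[0, 1].mean() == pytest.approx(0.001, abs=1e-4)

    def test_cell_streams_do_not_interfere(self):
        """Counter-based streams: a cell's draws ignore other cells' counts."""
        t1 = np.array([100, 0, 0, 0], dtype=np.int64)
        s1 = np.zeros((4, 4), dtype=np.int64); s1[0, 1] = 7
        t2 = np.array([100, 50, 60, 70], dtype=np.int64)
        s2 = s1.copy(); s2[1, 0] = 3; s2[2, 3] = 4
        d1 = ctx.sample_posteriors(ctx.ContextTable(1, t1, s1), 100, seed=9)
        d2 = ctx.sample_posteriors(ctx.ContextTable(1, t2, s2), 100, seed=9)
        assert np.array_equal(d1[0, 1], d2[0, 1])


class TestVarianceTotal:
    def test_two_context_hand_computation(self):
        # pc = [.5,.5], rates [.1,.3] -> mbar=.2, sigma2=.01
        probs = np.zeros((4, 4))
        probs[0, 1] = 0.1  # A contexts: total rate .1
        probs[3, 2] = 0.3  # T contexts: total rate .3
        w = np.array([0.5, 0.0, 0.0, 0.5])
        assert ctx.exact_weighted_variance(probs, w) == pytest.approx(0.01)
        table = ctx.table_from_rates(probs, w, k=1, total_trials=1e9)
        vp = ctx.variance_total(table, n_draws=400, seed=4)
        assert vp.mean == pytest.approx(0.01, rel=0.01)

    def test_shared_rate_gives_zero_variance(self):
        probs = np.zeros((4, 4))
        for c in range(4):
            probs[c, (c + 1) % 4] = 0.05
        w = np.full(4, 0.25)
        assert ctx.exact_weighted_variance(probs, w) == 0.0

    def test_posterior_matches_truth_table_oracle(self, small_genome_sim):
        g, mask, vs, tt = small_genome_sim
        brute = ctx.exact_weighted_variance(tt.probs, tt.weights)
        table = ctx.table_from_rates(tt.probs, tt.weights, k=3, total_trials=1e9)
        vp = ctx.variance_total(table, n_draws=1000, seed=5)
        assert abs(vp.mean - brute) < 3 * vp.draws.std()

    def test_draws_deterministic_under_seed(self, small_genome_sim):
        g, mask, vs, tt = small_genome_sim
        table = ctx.table_from_rates(tt.probs, tt.weights, k=3, total_trials=1e6)
        a = ctx.variance_total(table, n_draws=200, seed=6)
        b = ctx.variance_total(table, n_draws=200, seed=6)
        assert np.array_equal(a.draws, b.draws)


class TestVarianceByDirection:
    def _two_cell_table(self):
        # two C-centered 3-mers ACA, GCA with C->T rates .02/.04, equal weight
        probs = np.zeros((64, 4))
        w = np.zeros(64)
        for km, r in (("ACA", 0.02), ("GCA", 0.04)):
            probs[string_to_kmer(km), BASE_TO_CODE["T"]] = r
            w[string_to_kmer(km)] = 0.5
        return probs, w

    def test_direction_convention_hand_computation(self):
        probs, w = self._two_cell_table()
        v = ctx.exact_variance_by_direction(probs, w, 3, ("C", "T"))
        assert v == pytest.approx(1e-4)
        table = ctx.table_from_rates(probs, w, k=3, total_trials=1e9)
        vp = ctx.variance_by_direction(table, ("C", "T"), n_draws=400, seed=7)
        assert vp.mean == pytest.approx(1e-4, rel=0.02)

    def test_literal_convention_differs(self):
        probs, w = self._two_cell_table()
        # give both contexts additional C->G rate so mbar_C = 0.05
        for km in ("ACA", "GCA"):
            probs[string_to_kmer(km), BASE_TO_CODE["G"]] = 0.02
        v = ctx.exact_variance_by_direction(probs, w, 3, ("C", "T"),
                                            mean_convention="literal")
        assert v == pytest.approx(5e-4)
        table = ctx.table_from_rates(probs, w, k=3, total_trials=1e9)
        vp = ctx.variance_by_direction(table, ("C", "T"), n_draws=400, seed=8,
                                       mean_convention="literal")
        assert vp.mean == pytest.approx(5e-4, rel=0.02)

    def test_single_context_zero_variance(self):
        probs = np.zeros((4, 4))
        probs[1, 3] = 0.02  # k=1: single C "context"
        w = np.array([0.0, 1.0, 0.0, 0.0])
        assert ctx.exact_variance_by_direction(probs, w, 1, ("C", "T")) == 0.0

    def test_unknown_convention_rejected(self, small_genome_sim):
        *_, tt = small_genome_sim
        table = ctx.table_from_rates(tt.probs, tt.weights, k=3, total_trials=1e6)
        with pytest.raises(ValueError):
            ctx.variance_by_direction(table, ("C", "T"), n_draws=10, seed=0,
                                      mean_convention="bogus")


class TestMarginalised:
    def test_central_base_only_signal_vanishes(self):
        g, mask, vs, _ = synthetic.simulate_genome(GenomeSimParams(
            length=2_000_000, rate_model=ContextRateModel(), seed=15))
        table = ctx.tally_cells(vs, g, mask, 3)
        marg = ctx.variance_marginalised(table, n_draws=1000, seed=9)
        total = ctx.variance_total(table, n_draws=1000, seed=9)
        assert marg.mean < 0.5 * total.mean

    def test_five_prime_two_class_closed_form(self):
        # rate depends only on the 5' neighbor: classes r and 2r of equal
        # frequency -> marginalised variance = ((2r-r)*3/2 /? ) delta^2
        base = 0.002
        rm = ContextRateModel(
            direction_rates={d: base for d in DIRECTIONS},
            neighbor_effects=(NeighborEffect(-1, "G", 2.0),
                              NeighborEffect(-1, "T", 2.0)))
        g, mask, vs, tt = synthetic.simulate_genome(GenomeSimParams(
            length=4_000_000, rate_model=rm, seed=16))
        table = ctx.tally_cells(vs, g, mask, 3)  # unfiltered variants
        marg = ctx.variance_marginalised(table, n_draws=1000, seed=10)
        low, high = 3 * base, 6 * base  # total site rates per class
        delta = (high - low) / 2
        exact = ctx.exact_variance_marginalised(*tt.at_k(3), 3)
        assert exact == pytest.approx(delta ** 2, rel=1e-9)
        assert marg.mean == pytest.approx(delta ** 2, rel=0.15)

    def test_marginalised_not_above_total(self, small_genome_sim):
        g, mask, vs, _ = small_genome_sim
        table = ctx.tally_cells(vs, g, mask, 3)
        marg = ctx.variance_marginalised(table, n_draws=1000, seed=11)
        total = ctx.variance_total(table, n_draws=1000, seed=11)
        assert marg.mean <= total.mean

    def test_k1_rejected(self):
        table = ctx.ContextTable(1, np.ones(4, dtype=np.int64),
                                 np.zeros((4, 4), dtype=np.int64))
        with pytest.raises(ValueError):
            ctx.variance_marginalised(table, n_draws=10, seed=0)


class TestTruthTableInvariants:
    def test_mean_density_decomposition_across_k(self, cpg_truth):
        means = []
        for k in (1, 3, 5, 7):
            p, w = cpg_truth.at_k(k)
            means.append(float(np.dot(w, p.sum(axis=1))))
        assert np.allclose(means, means[0])

    def test_variance_monotone_in_k(self, cpg_truth):
        vals = [ctx.exact_weighted_variance(*cpg_truth.at_k(k))
                for k in (1, 3, 5, 7)]
        eps = 1e-12 * max(vals)
        assert all(b >= a - eps for a, b in zip(vals, vals[1:]))
        assert vals[1] > vals[0]  # the CpG effect is a genuine 3-mer signal


class TestCpG:
    def test_subset_and_complement_partition_weights(self, small_genome_sim):
        g, mask, vs, _ = small_genome_sim
        table = ctx.tally_cells(vs, g, mask, 3)
        sub = ctx.cpg_subset(3)
        w = table.weights
        assert w[sub].sum() + w[~sub].sum() == pytest.approx(1.0)

    def test_null_share_is_small(self):
        g, mask, vs, _ = synthetic.simulate_genome(GenomeSimParams(
            length=2_000_000, rate_model=ContextRateModel(cpg_multiplier=1.0),
            seed=17))
        table = ctx.tally_cells(vs, g, mask, 3)
        cv = ctx.variance_cpg(table, n_draws=1000, seed=12)
        assert cv.share.mean < 0.3

    def test_dominant_effect_share_exceeds_half(self):
        g, mask, vs, _ = synthetic.simulate_genome(GenomeSimParams(
            length=2_000_000, rate_model=ContextRateModel(cpg_multiplier=25.0),
            seed=18))
        table = ctx.tally_cells(vs, g, mask, 3)
        cv = ctx.variance_cpg(table, n_draws=1000, seed=13)
        assert cv.share.mean > 0.5

    def test_mirrored_orientation_is_distinct(self):
        std = ctx.cpg_subset(3, "standard")
        lit = ctx.cpg_subset(3, "mirrored")
        assert std.sum() == lit.sum() == 8
        assert not np.array_equal(std, lit)
        assert std[string_to_kmer("ACG")] and not lit[string_to_kmer("ACG")]
        assert lit[string_to_kmer("GCA")]


class TestStrandAsymmetry:
    def test_identical_posteriors_symmetric(self):
        draws = np.random.default_rng(0).random(1000)
        a = ctx.VariancePosterior(draws, "direction", 3, ("T", "C"))
        b = ctx.VariancePosterior(draws.copy(), "direction", 3, ("A", "G"))
        assert not ctx.strand_asymmetry(a, b).asymmetric

    def test_separated_posteriors_asymmetric(self):
        rng = np.random.default_rng(1)
        a = ctx.VariancePosterior(1e-4 + 1e-6 * rng.random(1000), "direction", 3)
        b = ctx.VariancePosterior(4e-4 + 1e-6 * rng.random(1000), "direction", 3)
        res = ctx.strand_asymmetry(a, b)
        assert res.asymmetric
        assert res.percentiles["a"][1] < res.percentiles["b"][0]

    def test_mismatched_k_rejected(self):
        a = ctx.VariancePosterior(np.ones(10), "direction", 3)
        b = ctx.VariancePosterior(np.ones(10), "direction", 5)
        with pytest.raises(ValueError):
            ctx.strand_asymmetry(a, b)
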