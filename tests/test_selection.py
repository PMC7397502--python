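"""Gene-level enrichment testing and expression-rate regression."""

import math

import numpy as np
import pytest

from exposig.selection import (
    count_gene_mutations,
    enrichment_tails,
    expression_rate_regression,
    fdr_adjust,
    gene_enrichment_test,
)
from exposig.types import GeneModel, MutationRecord


def snv(pos, contig="chr1", sample="s"):
    return MutationRecord(sample, contig, pos, "C", "A", "SNV")


class TestCounting:
    def test_boundary_conventions(self):
        gene = GeneModel("g", [("chr1", 0, 100)])
        assert count_gene_mutations([snv(50)], [gene])["g"] == 1
        assert count_gene_mutations([snv(100)], [gene])["g"] == 1  # 0-based 99
        assert count_gene_mutations([snv(101)], [gene])["g"] == 0

    def test_overlapping_genes_count_twice(self):
        g1 = GeneModel("g1", [("chr1", 0, 100)])
        g2 = GeneModel("g2", [("chr1", 50, 150)])
        counts = count_gene_mutations([snv(75)], [g1, g2])
        assert counts == {"g1": 1, "g2": 1}

    def test_indel_counts_at_first_changed_base(self):
        gene = GeneModel("g", [("chr1", 100, 200)])
        # anchor at 1-based 100 (outside), deleted base at 101 (inside)
        rec = MutationRecord("s", "chr1", 100, "CA", "C", "DEL")
        assert count_gene_mutations([rec], [gene])["g"] == 1

    def test_matches_brute_force_double_loop(self):
        rng = np.random.Generator(np.random.PCG64(67))
        genes = [
            GeneModel(f"g{i}", [("chr1", int(s), int(s) + int(l))])
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 9_000, 50), rng.integers(50, 500, 50))
            )
        ]
        muts = [snv(int(p)) for p in rng.integers(1, 10_000, 400)]
        fast = count_gene_mutations(muts, genes)
        for g in genes:
            brute = sum(
                1
                for m in muts
                if any(s <= m.pos - 1 < e for c, s, e in g.intervals if c == m.contig)
            )
            assert fast[g.name] == brute


class TestEnrichment:
    def test_observed_zero_upper_tail_is_one(self):
        _, p_over, _ = enrichment_tails(0, 1000, 10_000, 1_000_000)
        assert p_over == 1.0

    def test_poisson_hand_values(self):
        # lambda = 1000 * 1e5/1e8 = 1
        expected, p_over, _ = enrichment_tails(5, 1000, 100_000, 100_000_000)
        assert expected == pytest.approx(1.0)
        want = 1 - math.exp(-1) * (1 + 1 + 0.5 + 1 / 6 + 1 / 24)
        assert p_over == pytest.approx(want, abs=1e-12)
        _, _, p_under = enrichment_tails(0, 1000, 500_000, 100_000_000)
        assert p_under == pytest.approx(math.exp(-5.0), rel=1e-12)

    def test_matches_brute_force_pmf_summation(self):
        """Oracle: direct Poisson pmf sums via lgamma arithmetic."""
        for lam_frac in (0.001, 0.01):
            total = 10_000
            genome = 1_000_000
            fp = int(lam_frac * genome)
            lam = total * fp / genome
            for obs in range(0, 30):
                _, p_over, p_under = enrichment_tails(obs, total, fp, genome)
                pmf = [
                    math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
                    for k in range(0, max(obs + 1, int(lam + 30 * lam**0.5) + 30))
                ]
                assert p_under == pytest.approx(sum(pmf[: obs + 1]), abs=1e-10)
                assert p_over == pytest.approx(1 - sum(pmf[:obs]), abs=1e-10)

    def test_binomial_agrees_when_footprint_small(self):
        """Poisson and exact binomial tails within 10% relative when
        footprint/genome <= 1e-3."""
        for obs in (0, 2, 5, 12):
            _, po_p, pu_p = enrichment_tails(obs, 5000, 1000, 1_000_000)
            _, po_b, pu_b = enrichment_tails(obs, 5000, 1000, 1_000_000, model="binomial")
            assert po_b == pytest.approx(po_p, rel=0.1)
            assert pu_b == pytest.approx(pu_p, rel=0.1)

    def test_footprint_larger_than_genome_fatal(self):
        with pytest.raises(ValueError, match="exceeds"):
            enrichment_tails(1, 10, 2_000_000, 1_000_000)

    def test_family_calls_with_planted_signal(self):
        observed = {f"g{i}": 10 for i in range(20)}
        observed["hot"] = 60
        observed["cold"] = 0
        footprints = {g: 10_000 for g in observed}
        res = gene_enrichment_test(observed, 10_000, footprints, 10_000_000)
        calls = {r.gene: r.call for r in res}
        assert calls["hot"] == "overmutated"
        assert calls["cold"] == "protected"
        assert all(v == "consistent" for g, v in calls.items() if g not in ("hot", "cold"))


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (fdr_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


def _genes_with_expression(n=30, fp=1000):
    return [
        GeneModel(f"g{i}", [("chr1", i * 2 * fp, i * 2 * fp + fp)], expression=float(i))
        for i in range(n)
    ]


class TestRegression:
    def test_flat_rates_give_zero_slope(self):
        genes = _genes_with_expression()
        muts = [snv(int(g.intervals[0][1]) + 5) for g in genes]  # one per gene
        res = expression_rate_regression(muts, genes, n_bins=5)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_exactly_linear_rates_are_perfect_fit(self):
        genes = _genes_with_expression(n=30)
        muts = []
        # bin b (genes 6b..6b+5) gets b+1 mutations per gene: rate linear in bin
        for i, g in enumerate(genes):
            per_gene = i // 6 + 1
            start = g.intervals[0][1]
            muts.extend(snv(start + 3 + 7 * k) for k in range(per_gene))
        res = expression_rate_regression(muts, genes, n_bins=5)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-12
        assert res.slope > 0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="genes with expression"):
            expression_rate_regression([], _genes_with_expression(5), n_bins=10)

    def test_recovers_generating_slope_from_simulation(self):
        """A single expression-coupled clone recovers the analytic slope
        within two standard errors."""
        from exposig.simulate import SimulationConfig, simulate_study

        beta = 0.01
        cfg = SimulationConfig(
            seed=101,
            n_contigs=1,
            contig_length_bp=800_000,
            n_control_clones=0,
            n_exposed_clones=1,
            background_burden=0.0,
            exposure_burden=12_000.0,
            dbs_fraction=0.0,
            indel_fraction=0.0,
            n_genes=100,
            gene_length_bp=4_000,
            expression_rate_slope=beta,
        )
        study = simulate_study(cfg)
        muts = study.all_records()
        res = expression_rate_regression(
            muts, study.genes, n_bins=10, x_mode="mean_expression"
        )
        genome_bp = study.genome.total_length
        fp = sum(g.footprint_bp for g in study.genes)
        sum_w = (genome_bp - fp) + sum(
            (1 + beta * g.expression) * g.footprint_bp for g in study.genes
        )
        truth_slope = len(muts) * 1e6 * beta / sum_w
        assert res.slope > 0
        assert abs(res.slope - truth_slope) <= 2 * res.slope_stderr
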