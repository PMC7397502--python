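"""Gene-level selection statistics: overmutation testing under a
uniform-placement null and mutation rate vs transcription level.

Part 1 places mutations without any gene coupling and plants a 10x
count on one gene: it should be the only overmutated call.  Part 2
couples per-gene mutation rate to expression and recovers a positive
regression slope.
"""

from exposig.selection import (
    enrichment_table,
    count_gene_mutations,
    expression_rate_regression,
    gene_enrichment_test,
)
from exposig.simulate import SimulationConfig, simulate_study


def _config(seed, slope):
    return SimulationConfig(seed=seed, n_contigs=1, contig_length_bp=900_000,
                            n_control_clones=0, n_exposed_clones=1,
                            background_burden=0, exposure_burden=8000,
                            dbs_fraction=0, indel_fraction=0,
                            n_genes=100, gene_length_bp=4_000,
                            expression_rate_slope=slope)


# --- part 1: enrichment calls under the uniform null, one planted gene
study = simulate_study(_config(4, None))
muts = study.all_records()
genes = study.genes
observed = count_gene_mutations(muts, genes)
expected_per_gene = len(muts) * genes[0].footprint_bp / study.genome.total_length
observed["gene0001"] = int(10 * expected_per_gene)  # planted hot gene

results = gene_enrichment_test(
    observed,
    total_mutations=len(muts),
    footprints={g.name: g.footprint_bp for g in genes},
    effective_genome_bp=study.genome.total_length,
)
table = enrichment_table(results)
print(table[table.call != "consistent"].to_string(index=False))
n_cons = (table.call == "consistent").sum()
print(f"{n_cons}/{len(table)} genes consistent with uniform random placement")

# --- part 2: expression-coupled simulation, rate-vs-expression slope
coupled = simulate_study(_config(5, 0.012))
res = expression_rate_regression(
    coupled.all_records(), coupled.genes, n_bins=10, x_mode="mean_expression"
)
print(
    f"\nrate vs expression: slope={res.slope:.1f} mutations/Mb per expression "
    f"unit (se {res.slope_stderr:.1f}), p={res.p_value:.2e}, R^2={res.r_squared:.3f}"
)
print(
    "\nOnly the planted gene should be called overmutated (q<0.05, "
    "Benjamini-Hochberg within the one-sided family); all other genes "
    "match their footprint-proportional expectation. The positive slope "
    "in part 2 reflects the simulated coupling between expression and "
    "local mutation rate."
)
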