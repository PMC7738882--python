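"""Call differentially expressed genes by the digital-count rule.

A gene is a DEG when |log2-ratio| >= 1 (two-fold after depth
normalization) and the Audic-Claverie diverge probability >= 0.8.
"""

from gahd import (
    SimulationConfig,
    call_degs,
    diverge_probability,
    log2_ratio,
    simulate_counts,
    simulate_gahd_tracks,
    simulate_genome,
)

config = SimulationConfig(seed=1)
genome = simulate_genome(config)
_, truth = simulate_gahd_tracks(config, genome)
table = simulate_counts(config, genome, truth)

records, summary = call_degs(table)
print(
    f"{summary['n_up']} up, {summary['n_down']} down, "
    f"{summary['n_unchanged']} unchanged of {len(table.gene_ids)} genes "
    f"(planted: {len(truth.deg_up_ids)} up, {len(truth.deg_down_ids)} down)"
)

# The two statistics for one gene:
gid = truth.deg_up_ids[0]
i = table.gene_ids.index(gid)
a, b = int(table.counts_a[i]), int(table.counts_b[i])
lr = log2_ratio(a, b, table.library_size_a, table.library_size_b)
dp = diverge_probability(a, b, table.library_size_a, table.library_size_b)
print(
    f"{gid}: counts {a} -> {b}, log2-ratio {lr:.2f}, diverge probability {dp:.3f}"
)
# log2-ratio measures the fold change; the diverge probability is how
# incompatible the two counts are under a shared expression level.
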