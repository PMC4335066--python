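"""Find condition-specific hubs by contrasting strong-edge connectivity.

Simulates 200 genes with gene g00199 hubbed to 30 targets only in the
wild-type-like condition, counts PCIT-retained edges with |r| >= 0.90 per
gene and condition, and ranks genes by dh = k_A - k_B.
"""

from conetdiff import (
    PlantedHub,
    SimulationDesign,
    correlation_matrix,
    differential_hubbing,
    hub_counts,
    pcit_significant_edges,
    ranked_hub_table,
    simulate_expression,
)

design = SimulationDesign(
    n_genes=200, n_per_condition=20,
    hub=PlantedHub(hub=199, targets=tuple(range(30)), condition="A", loading=0.9),
    seed=19,
)
matrix, truth = simulate_expression(design)

lab_a, lab_b = matrix.conditions
net_a = pcit_significant_edges(correlation_matrix(matrix, lab_a))
net_b = pcit_significant_edges(correlation_matrix(matrix, lab_b))
table = ranked_hub_table(
    differential_hubbing(hub_counts(net_a, 0.90), hub_counts(net_b, 0.90))
)

print("top 5 differentially hubbed genes (k = strong retained edges):")
print(table.head(5))
print()
print(f"planted hub: {truth.hub_id} — many strong correlates in {lab_a}, "
      f"none in {lab_b}.")
print("A large |dh| flags a regulator even when its own mean expression is flat.")
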