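"""Quantify the SUMO pool equilibrium and SUMO2 chain topology.

The enrichment captures the SUMO2/3 C-terminus whether conjugated or free,
so summed evidence intensities partition the total SUMO pool into
conjugated sub-classes (chains, E1/E2/E3 enzymes, other targets), free
mature SUMO and immature precursors.  Chain topology distributes the
SUMO-on-SUMO signal over the lysines of SUMO2.
"""

from sumosite import chain_topology, equilibrium_fractions
from sumosite.synthetic import (
    PROTEIN_NAMES, GeneratorConfig, generate_evidence, generate_proteome,
)

config = GeneratorConfig(seed=1, replicates=3)
proteome = generate_proteome(config)
rows, design, truth = generate_evidence(config, proteome)

result = equilibrium_fractions(rows, design, protein_names=PROTEIN_NAMES)
print("pool fractions (control, mean ± SD over 3 replicates):")
for label, (mean, sd, n) in result.summary["control"].items():
    print(f"  {label:16s} {100 * mean:6.2f}% ± {100 * sd:5.2f}  "
          f"(truth {100 * truth.pool_fractions[label]:.2f}%)")

profile = chain_topology(rows, design, "SUMO2", proteome[0])
print("\nSUMO2 chain linkage usage (control):")
for lysine, (mean, sd, n) in profile.summary["control"].items():
    print(f"  K{lysine:<3d} {100 * mean:5.1f}% ± {100 * sd:4.1f}  "
          f"(truth {100 * truth.chain_profile['SUMO2'][lysine]:.0f}%)")

# With the cell-culture-like defaults ~93% of SUMO is conjugated and K11
# carries ~35% of chain linkages; the recovered fractions match the
# generator's ground truth to within sampling noise.
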