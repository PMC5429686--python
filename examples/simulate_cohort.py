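"""Generate a synthetic tumor cohort and summarize its mutation burden.

The generator plants 3 subtypes whose driver genes sit in separate network
modules; most mutations are sparse background noise, and a small
hypermutator fraction carries an inflated background rate.
"""

import numpy as np

import netstrat as ns

spec = ns.SyntheticSpec(n_patients=120, seed=1)
cohort = ns.generate(spec)

burden = cohort.mutation_matrix.patient_burden()
rates = ns.mutation_rate_per_mb(cohort.mutation_matrix)
frac, recurrent = ns.gene_mutation_fraction(cohort.mutation_matrix, threshold=0.05)

print(f"patients: {cohort.mutation_matrix.n_patients}, "
      f"mutated genes: {cohort.mutation_matrix.n_genes}")
print(f"network: {cohort.network.n_nodes} genes, {cohort.network.n_edges} interactions")
print(f"burden per patient: min {burden.min()}, median {np.median(burden):.0f}, "
      f"max {burden.max()}")
print(f"burden per Mb (simplified 30 Mb exome): {rates.min():.3f} to {rates.max():.3f}")
print(f"genes mutated in >5% of patients: {len(recurrent)}")
print("planted subtype sizes:", np.bincount(cohort.true_labels).tolist())
# the max/min burden ratio shows the hypermutator tail the pipeline must tolerate
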