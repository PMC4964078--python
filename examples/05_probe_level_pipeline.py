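"""Full probe-level preprocessing: HER2 calling, cohort filtering, collapse.

A probe layer (1-3 probes per gene plus two designated HER2 probes with a
planted overexpressing subpopulation) is expanded from a gene-keyed cohort.
HER2 status is called from the probes by a two-component Gaussian mixture,
HER2+ tumours are removed, the matrix is Z-standardized, and probes are
collapsed back to gene symbols.
"""

import nodesig as ns
from nodesig.synthetic_data import SimulationConfig

syn = ns.simulate_cohort(SimulationConfig(n_samples=300, seed=5))
layer = ns.make_probe_layer(syn, probes_per_gene=3, seed=5,
                            her2_positive_fraction=0.1)

calls = ns.classify_her2(layer.matrix, layer.her2_probe_ids, random_state=0)
clinical = syn.cohort.df.copy()
clinical["her2_status"] = clinical["sample_id"].map(calls)
cohort = ns.CohortTable(clinical)

filtered, cohort, report = ns.filter_cohort(layer.matrix, cohort)
zmat, zreport = ns.z_standardize(filtered)
collapsed, creport = ns.collapse_probes(zmat, layer.probe_to_gene)

planted = set(layer.planted_her2_positive)
called = set(calls.index[calls == "positive"])
print(f"planted HER2+ samples: {len(planted)}; called positive: {len(called)}; "
      f"recovered: {len(planted & called)}")
print(f"filter report: {report}")
print(f"probes: {layer.matrix.n_genes} -> genes after collapse: {collapsed.n_genes}"
      f" (zero-variance rows dropped: {zreport['n_dropped']})")
print("\nThe HER2-overexpressing subpopulation is detected from probe "
      "intensities alone and removed before any scoring, mimicking cohort "
      "curation from array data.")
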