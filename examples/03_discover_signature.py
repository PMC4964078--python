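"""Discover a directional signature by nearest shrunken centroids and
validate it on an independent cohort.

Training samples are classed by 10-year distant-metastasis outcome; the
shrinkage threshold is chosen by stratified 10-fold CV (1-SE rule); surviving
genes are labelled good/poor by their event-class centroid and combined into
a mean-Z index, scored on a second, held-out synthetic cohort.
"""

import nodesig as ns
from nodesig.synthetic_data import SimulationConfig
from nodesig.workbench import discover_and_validate

train = ns.simulate_cohort(SimulationConfig(n_samples=600, seed=7))
test = ns.simulate_cohort(SimulationConfig(n_samples=400, seed=1007))

res = discover_and_validate(train, test, seed=7)
sig = res["signature"]
print(f"CV-chosen shrinkage delta: {res['model'].delta:.2f} "
      f"({len(sig.genes)} surviving genes)")
print("good:", sorted(g.symbol for g in sig.genes if g.direction == "good"))
print("poor:", sorted(g.symbol for g in sig.genes if g.direction == "poor"))
print()
for fit in res["validation_fits"]:
    print(f"held-out {fit.stratum}: C={fit.concordance:.3f}, "
          f"HR={fit.hr:.2f} [{fit.ci_lower:.2f}, {fit.ci_upper:.2f}], p={fit.p:.2g}")
print("\nGenes from the planted adverse programs should surface as 'poor' and "
      "immune-program genes as 'good'; held-out concordance above 0.5 shows "
      "the discovered index transfers across cohorts.")
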