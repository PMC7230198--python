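"""Differential expression and detoxification-gene-class enrichment.

Simulates negative-binomial expression counts for two rearing conditions
with planted differential expression concentrated in a labelled cytochrome
P450 class, filters on counts per million, runs the two-group contrast and
tests the class for over-representation among DE genes — both from full
class membership and from the (observed, expected) pair alone.
"""

import numpy as np
import pandas as pd

from hostadapt import expression, simdata

rng = np.random.default_rng(21)
n_genes = 4000
genes = [f"g{i}" for i in range(n_genes)]
p450 = rng.choice(n_genes, 80, replace=False)  # 2% of genes are P450s
de_true = np.concatenate([rng.choice(p450, 25, replace=False),
                          rng.choice(np.setdiff1d(np.arange(n_genes), p450),
                                     50, replace=False)])
truth = simdata.SimTruth(de_genes=de_true,
                         de_lfc=rng.choice([-2.0, 2.0], de_true.size))
sim = simdata.simulate_expression(n_genes, 5, 2e6, 0.1, truth, seed=22)

cm = expression.CountMatrix(counts=pd.DataFrame(sim["counts"], index=genes))
filtered = expression.cpm_filter(cm, threshold=0.5, min_samples=2)
print(f"genes retained by CPM filter: {len(filtered.counts)} of {n_genes}")

de = expression.de_contrast(filtered, sim["groups"], fdr=0.05)
de_set = set(de.table.index[de.table["significant"]])
print(f"differentially expressed genes at FDR 0.05: {len(de_set)}")

universe = set(filtered.counts.index)
cls = {genes[i] for i in p450} & universe
res = expression.class_enrichment(de_set, cls, universe, class_name="P450")
print(f"P450 enrichment: observed {res.observed}, expected {res.expected:.2f}, "
      f"{res.tail}-tail P = {res.p:.2g}")

# the same test when only the observed and expected counts are available
p = expression.class_enrichment_from_expected(res.observed, res.expected)
print(f"Poisson large-universe approximation: P = {p:.2g} "
      "(small P: P450s are over-represented among DE genes)")
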