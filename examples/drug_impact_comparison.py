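"""Compare two kinase-activity ranking methods against drug-efficacy data.

The kinase impact score at list length N sums, over the top-N kinases and
the drugs targeting them, normalized activity x normalized potency (logIC50
median-centered, negated, scaled to [-1, 1]).  A method whose top ranks
attract potent drugs scores higher.  Methods are compared per length
(2..40) with a paired Wilcoxon test over cell lines, summarized by the
median p-value.
"""

import numpy as np
import pandas as pd

from inka import compare_methods, generate_drug_tables, normalize_efficacy, normalize_kas

rng = np.random.default_rng(0)
efficacy_table, targets = generate_drug_tables(n_cell_lines=6, n_drugs=15, seed=0)

efficacy = {
    line: normalize_efficacy(block.set_index("drug")["log_ic50"])
    for line, block in efficacy_table.groupby("cell_line")
}
kinases = sorted(targets["kinase"].unique())

# method A ranks drug-targeted kinases high; method B is a random shuffle
method_a, method_b = {}, {}
for line in efficacy:
    potency = {k: sum(efficacy[line].get(d, 0) for d, kk in zip(targets["drug"], targets["kinase"]) if kk == k)
               for k in kinases}
    informed = pd.Series({k: 1.0 + max(potency[k], 0) * 5 + rng.uniform(0, 0.1) for k in kinases})
    method_a[line] = normalize_kas(informed)
    method_b[line] = normalize_kas(pd.Series(rng.uniform(0.5, 2.0, len(kinases)), index=kinases))

result = compare_methods(method_a, method_b, efficacy, targets, labels=("informed", "random"))
print(result.per_length.head(6).round(4).to_string(index=False))
print(f"\nmedian p over lengths 2..40: {result.median_p:.4g}")
# A small median p says the informed ranking concentrates potent-drug
# targets at its top more than the random one, consistently across lengths.
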