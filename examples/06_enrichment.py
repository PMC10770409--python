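"""Hypergeometric over-representation analysis of a gene list.

Tests a query list against gene sets with the upper-tail hypergeometric
probability; sets need >= 5 overlapping genes (>= 2 for queries smaller
than 100 genes) to enter BH correction.
"""

import numpy as np

from circatx.enrich import ora

rng = np.random.default_rng(6)
universe = [f"g{i:04d}" for i in range(2000)]
sets = {
    "lipid_metabolism": universe[0:120],
    "cholesterol_transport": universe[100:180],
    "clock_output": universe[500:560],
    "unrelated": list(rng.choice(universe, 150, replace=False)),
}
# a query enriched for the first two sets
query = universe[0:60] + list(rng.choice(universe[600:], 40, replace=False))

res = ora(query, sets, universe)
print(res.to_string(index=False,
                    formatters={"p": "{:.3g}".format, "q": "{:.3g}".format}))

# 'overlap' is the number of query genes inside the set; only admitted sets
# (gene-count rule satisfied) receive a BH q-value.
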