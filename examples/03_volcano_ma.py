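"""Volcano and MA plots of a synthetic differential-expression table.

Generates a seeded DESeq2-shaped results table, draws both plots under the
MAD scale, and prints the significance tally plus a few display positions.
"""

import matplotlib
matplotlib.use("Agg")

from collections import Counter

from madfc.plot_builders import ma_plot, volcano
from madfc.synthetic_data import gen_de_results

table = gen_de_results(n_genes=2000, frac_null=0.8, seed=42)

fig, spec = volcano(table, "madfc", padj_max=0.1, lfc_min=1.0)
print("significance classes:", dict(Counter(spec.class_labels)))
# Up/Down need adjusted p < 0.1 AND |log2 FC| > 1; everything else is NS.

x = spec.point_positions["x"]
print("first 5 display positions (fold-change units):", x[:5].round(3))
print("axis tick labels:", spec.tick_spec.labels)
fig.savefig("example_volcano.png", dpi=120)

fig2, mspec = ma_plot(table, "madfc")
print("MA plot classes match volcano:", mspec.class_labels == spec.class_labels)
fig2.savefig("example_ma.png", dpi=120)
print("wrote example_volcano.png, example_ma.png")
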