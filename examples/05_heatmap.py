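"""Heatmap with MAD color normalization.

Colors are proportional to fold-change units and symmetric about no
change: FC = 1 sits at the white midpoint of the diverging palette, and a
fold change and its reciprocal get complementary colors.
"""

import matplotlib
matplotlib.use("Agg")
import numpy as np
import pandas as pd

from madfc.color_norm import ColorNormSpec, normalize
from madfc.plot_builders import heatmap

matrix = pd.DataFrame(
    [[4.0, 2.0, 1.0],
     [1 / 4, 1 / 2, 1.0],
     [1.0, 3.0, 1 / 3]],
    index=["protein A", "protein B", "protein C"],
    columns=["mono", "tetra", "hexa"],
)

spec_in = ColorNormSpec(transform="madfc", vmin_fc=1 / 4, vmax_fc=4.0,
                        symmetric=True)
fig, spec = heatmap(matrix, spec_in)
print("normalized colors:\n", np.round(spec.point_positions["normalized"], 3))
print("FC 1 maps to:", normalize(1.0, spec_in), "(palette midpoint)")
print("FC 4 and 1/4 sum to:",
      normalize(4.0, spec_in) + normalize(0.25, spec_in))
print("colorbar labels:", spec.tick_spec.labels)
fig.savefig("example_heatmap.png", dpi=120)
print("wrote example_heatmap.png")
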