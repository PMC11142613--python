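"""A labeled MAD axis: data in MAD coordinates, tick labels in raw fold change.

Sets the registered "madfc" matplotlib scale on an axis spanning raw fold
changes 1/6..6 and shows that the axis occupies display coordinates -5..5
while its tick labels read 1/6, 1/5, ..., 1/2, 1, 2, ..., 6.
"""

import numpy as np
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from madfc import make_ticks
from madfc.synthetic_data import gen_fcu_span

fc = gen_fcu_span(-5, 5)
fig, ax = plt.subplots()
ax.set_yscale("madfc", max_ticks=11)
ax.plot(np.arange(len(fc)), fc, "o")
ax.set_ylim(1 / 6, 6)
fig.canvas.draw()

tr = ax.yaxis.get_transform()
print("data range:", (round(fc.min(), 4), fc.max()))
print("display range:", tr.transform(np.array([1 / 6, 6])))
print("tick labels:", [t.get_text() for t in ax.get_yticklabels()])
# The labels are raw fold changes: the value of any point can be read
# straight off the axis even though spacing is linear in fold-change units.

spec = make_ticks(-5, 5, max_ticks=11, style="fraction")
print("tick positions:", spec.positions)
print("anchor (no change) at index:", spec.anchor_index)

fig.savefig("example_labeled_axis.png", dpi=120)
print("wrote example_labeled_axis.png")
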