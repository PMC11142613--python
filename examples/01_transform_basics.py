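"""Fold-change units and the MAD-FC transform on a handful of values.

The MAD-FC transform mirrors sub-unit fold changes onto a negative branch
(-1/x) and contracts both branches one unit toward zero; the result equals
the fold-change-unit encoding: x-1 above no change, 1-1/x below it.
"""

import numpy as np

from madfc import fold_change_units, madfc_forward, madfc_inverse

raw = np.array([2.0, 0.5, 3.0, 1 / 3, 1.0, 1 / 6, 6.0])
fcu = fold_change_units(raw)
print("raw fold change :", np.round(raw, 4))
print("fold-change units:", fcu)
# 2 and 1/2 land at +1 and -1: one doubling away from no change in either
# direction, equidistant on the MAD axis.

composed = madfc_forward(raw)
print("MAD-FC (mirror+contract):", composed)
print("identical to FCU encoding:", np.allclose(composed, fcu))

back = madfc_inverse(composed)
print("round trip recovers raw:", np.allclose(back, raw))
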