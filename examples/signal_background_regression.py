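"""Compare the split-reporter system against a full-length fusion per cell.

Simulates array-carrying populations with either a full-length fluorophore
fusion or the split system, computes each cell's signal (mean of brightest
10% of pixels) and background (mean of dimmest 50%), and regresses background
on signal.  A steep slope means brighter cells drag their own background up
(unbound fluorescent protein); a flat slope is the signature of a
low-background system.
"""

import numpy as np

from bifcros.population import regress_signal_vs_background
from bifcros.regimes import quantify_regime, regime

for label, construct in (("full-length fusion", "full_length"), ("split system", "split")):
    _, quants = quantify_regime(regime(construct, n_arrays=1), n_cells=200, seed=11)
    fit = regress_signal_vs_background(quants)
    ratios = [q.ratio for q in quants]
    print(f"{label:>18}: slope {fit.slope:6.3f}  (n={fit.n_points}, "
          f"median signal/background ratio {np.median(ratios):5.1f})")
print("-> the split system's regression is much flatter: focus brightness "
      "grows without raising the in-cell background")
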