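"""Granule-cell-mediated synchronization of a middle tufted cell pair.

Runs the two-cell microcircuit (two principal cells + two granule cells)
under weak ~3 Hz drive in three wirings and prints the pairwise spike-time
synchrony (sigma = 5 ms reliability). Shared GC inhibition - either through
reciprocal dendrodendritic contacts or through common external excitation
of the GCs - synchronizes mTC burst clusters; tonically firing MCs are
unaffected by the same manipulations.
"""

import numpy as np

from bulbnet.experiments import exp_two_cell_sync

for cell_type in ("mTC", "MC"):
    print(f"--- {cell_type} pairs (mean over 3 seeds)")
    base = None
    for wiring in ("separate", "reciprocal", "common_external"):
        vals = [exp_two_cell_sync(cell_type, wiring, seed)["synchrony"]
                for seed in range(3)]
        m = float(np.mean(vals))
        if wiring == "separate":
            base = m
            print(f"  {wiring:16s} synchrony {m:.2f}  (baseline)")
        else:
            print(f"  {wiring:16s} synchrony {m:.2f}  (gain {m - base:+.2f})")

# For mTCs the wired configurations should exceed the baseline by >= 0.3;
# MC synchrony barely moves: only the burster's slow-K rebound dynamics let
# shared inhibition act as a synchronizing reset.
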