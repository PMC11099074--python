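"""LLC-ROE versus classical ROE transfer as tumbling slows down.

Sweeps the rotational correlation time for the default three-spin geometry
(K at 2.5 A from S and 3.6 A from I) and locates the tau_c at which the
maximum LLC-to-K transfer overtakes the classical transfer.
"""

import numpy as np

from llcroe.propagation import crossover_tauc, max_transfer_vs_tauc
from llcroe.synthetic_data import default_three_spin_system

system = default_three_spin_system()
grid = np.array([0.1, 0.5, 1, 2, 5, 10, 20, 50, 100]) * 1e-9
tau_c, llc, ref = max_transfer_vs_tauc(system, grid, b0_T=22.3,
                                       cw_amplitude_hz=4000.0)

print("tau_c (ns)   max |LLC->K|   max |REF->K|   LLC/REF")
for tc, a, b in zip(tau_c, llc, ref):
    print(f"{tc * 1e9:9.1f}   {a:12.5f}   {b:12.5f}   {a / b:7.3f}")

tc_star = crossover_tauc(system, b0_T=22.3, cw_amplitude_hz=4000.0)
print(f"\ncrossover: tau_c* = {tc_star * 1e9:.1f} ns")
print(
    "Classical ROE transfer saturates once its source decays as fast as\n"
    "it pumps; the LLC source decays far more slowly, so its transfer\n"
    "keeps growing with molecular size and overtakes the classical route\n"
    "in the slow-tumbling regime of folded proteins."
)
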