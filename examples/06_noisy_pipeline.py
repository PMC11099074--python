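"""End-to-end synthetic pipeline: generate, add noise, fit, compare.

Simulates LLC and REF build-up curves for the default three-spin geometry
on the experiment's 64 x 1 ms mixing grid, adds 1% Gaussian noise, and
recovers sign, kinetics and the LLC/REF transfer ratio by curve fitting.
"""

import numpy as np

from llcroe import RelaxationModel
from llcroe.buildup_analysis import fit_buildup, transfer_ratio
from llcroe.synthetic_data import default_three_spin_system, gen_buildup

system = default_three_spin_system()
model = RelaxationModel(tau_c_s=10e-9, b0_T=22.3)

curves = {
    state: gen_buildup(system, model, state, noise_sigma=0.01, seed=42)
    for state in ("LLC", "REF")
}

for state, curve in curves.items():
    fit = fit_buildup(curve)
    print(
        f"{state}: sign {fit.sign:+d}, extremum {fit.max_amplitude:+.4f} at "
        f"{fit.time_of_max_s * 1e3:.0f} ms, rise {fit.rise_time_s * 1e3:.1f} ms"
    )

ratio = transfer_ratio(curves["LLC"], curves["REF"])
print(f"\nLLC/REF transfer ratio: {ratio.ratio:.2f} +/- {ratio.stderr:.2f}")
print(
    "The LLC curve is positive (K sits on the H-alpha-3 side) while the\n"
    "classical REF build-up is negative; their magnitude ratio measures\n"
    "how much of the classical transfer the LLC route delivers at this\n"
    "tumbling time."
)
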