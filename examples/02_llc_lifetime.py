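"""Lifetime advantage of the long-lived coherence for a protein-like pair.

Compares the decay of the spin-locked LLC (Ix - Sx, sampled at 1/J
intervals) with spin-locked transverse magnetisation (Ix + Sx) for an
isolated glycine proton pair tumbling with tau_c = 10 ns at 22.3 T.
"""

from llcroe import RelaxationModel, SpinSystem
from llcroe.propagation import llc_decay_constant, ref_decay_constant

pair = SpinSystem(
    labels=("I", "S"),
    offsets_hz=(70.0, -70.0),
    j_couplings_hz={("I", "S"): 17.5},
    coordinates_angstrom=((0.0, 0.0, 0.0), (0.0, 0.0, 1.77)),
    b0_T=22.3,
)
model = RelaxationModel(tau_c_s=10e-9, b0_T=22.3)

fit_llc = llc_decay_constant(pair, model, cw_amplitude_hz=4000.0)
fit_ref = ref_decay_constant(pair, model, cw_amplitude_hz=4000.0)

print(f"T_LLC  = {fit_llc.time_constant_s * 1e3:7.1f} ms")
print(f"T_1rho = {fit_ref.time_constant_s * 1e3:7.1f} ms")
print(f"ratio  = {fit_llc.time_constant_s / fit_ref.time_constant_s:.2f}")
print(
    "\nIntra-pair dipolar relaxation cannot mix the singlet with the\n"
    "triplet manifold, so the singlet-triplet coherence outlives the\n"
    "classical transverse coherence severalfold; experimentally, external\n"
    "protons and local motions reduce the advantage to about a factor 2."
)
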