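"""Stereospecific sign mapping on a synthetic multi-model structure.

Generates a 50-model ensemble around one glycine, extracts (phi, distance)
polar coordinates and mirror-plane sides for each neighbour proton, and
cross-checks the geometric sign prediction against a full LLC-ROE
simulation of the same geometry.
"""

import tempfile
from pathlib import Path

import numpy as np

from llcroe import RelaxationModel
from llcroe.propagation import roe_buildup
from llcroe.stereo_geometry import ensemble_stats, geometry_records, read_structure
from llcroe.synthetic_data import gen_toy_structure
from llcroe.spin_core import SpinSystem

workdir = Path(tempfile.mkdtemp())
pdb = workdir / "ensemble.pdb"
spec = [
    {"phi_deg": 60.0, "distance_angstrom": 3.0, "side": "closer-to-S"},
    {"phi_deg": 115.0, "distance_angstrom": 3.4, "side": "closer-to-I"},
]
gen_toy_structure(50, spec, seed=7, jitter_angstrom=0.15, path=pdb)

frame = read_structure(pdb)
records = geometry_records(frame, gly_res_seq=1)
stats = ensemble_stats(records)
print(stats[["neighbour", "n_models", "phi_mean_deg", "phi_circstd_deg",
             "distance_mean_angstrom", "consensus_sign"]].to_string(index=False))

# simulate the first neighbour's build-up sign for the mean geometry
row = stats.iloc[0]
gly = frame[(frame.res_name == "GLY") & (frame.model == "1")]
i_xyz = gly[gly.atom_name == "HA2"][["x", "y", "z"]].to_numpy()[0]
s_xyz = gly[gly.atom_name == "HA3"][["x", "y", "z"]].to_numpy()[0]
k_xyz = frame[(frame.model == "1") & (frame.res_seq == 2)][["x", "y", "z"]].to_numpy()[0]
system = SpinSystem(
    labels=("I", "S", "K"), offsets_hz=(70.0, -70.0, 300.0),
    j_couplings_hz={("I", "S"): 17.5},
    coordinates_angstrom=(tuple(i_xyz), tuple(s_xyz), tuple(k_xyz)), b0_T=22.3,
)
curve = roe_buildup(system, RelaxationModel(tau_c_s=10e-9, b0_T=22.3), 4000.0,
                    initial="LLC", times=np.arange(0.0, 0.06, 2e-3))
simulated = int(np.sign(curve.values[np.argmax(np.abs(curve.values))]))
print(f"\nneighbour {row.neighbour}: geometric sign {row.consensus_sign:+d}, "
      f"simulated LLC build-up sign {simulated:+d}")
print(
    "Neighbours on the H-alpha-3 side of the glycine mirror plane build up\n"
    "with the sign opposite to the classical ROE; the sign read from the\n"
    "structure matches the sign produced by the spin simulation."
)
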