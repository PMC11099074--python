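"""Seeded generators for every input the pipeline consumes.

Nothing here is downloaded: glycine-like spin systems (J ~ 17 Hz, shift
differences of 50-250 Hz at 950 MHz, H-H distance 1.77 A, H-C-H angle of
about 107 degrees from standard methylene stereochemistry), noisy build-up
curves (simulator truth plus additive Gaussian noise, sigma expressed
relative to the source signal at tau = 0), and toy multi-model PDB
structures with controlled neighbour placements.  Every generator is a pure
function of (parameters, seed) and writes its ground truth alongside, so
downstream fits can be checked against what was actually generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .buildup_analysis import BuildupCurve
from .relaxation import RelaxationModel
from .spin_core import SpinSystem

__all__ = [
    "GLYCINE_R_IS_ANGSTROM",
    "GLYCINE_HCH_ANGLE_DEG",
    "gen_spin_system",
    "gen_buildup",
    "gen_toy_structure",
    "default_three_spin_system",
]

#: methylene H-H distance (A) used throughout; standard glycine geometry
GLYCINE_R_IS_ANGSTROM = 1.77
#: methylene H-C-H angle (degrees)
GLYCINE_HCH_ANGLE_DEG = 107.0


def default_three_spin_system(
    b0_T: float = 22.3,
    j_is_hz: float = 17.5,
    dnu_hz: float = 140.0,
    k_offset_hz: float = 300.0,
) -> SpinSystem:
    """The documented default three-spin geometry: r_IS = 1.77 A, K in the
    IS plane at 2.5 A from S and 3.6 A from I (off the mirror plane)."""
    r_is = GLYCINE_R_IS_ANGSTROM
    r_ik, r_sk = 3.6, 2.5
    z = (r_ik**2 - r_sk**2 + r_is**2) / (2.0 * r_is)
    x = float(np.sqrt(r_ik**2 - z**2))
    return SpinSystem(
        labels=("I", "S", "K"),
        offsets_hz=(dnu_hz / 2.0, -dnu_hz / 2.0, k_offset_hz),
        j_couplings_hz={("I", "S"): j_is_hz},
        coordinates_angstrom=((0.0, 0.0, 0.0), (0.0, 0.0, r_is), (x, 0.0, z)),
        b0_T=b0_T,
    )


def gen_spin_system(
    preset: str = "glycine-like",
    seed: int = 0,
    n_spins: int = 3,
    b0_T: float = 22.3,
    path=None,
) -> SpinSystem:
    """Draw a random glycine-like spin system.

    The glycine-like preset samples the shift difference uniformly in
    [50, 250] Hz and J_IS in [16.5, 18] Hz (the glycine pairs of Lysozyme
    cluster around 17 Hz); the methylene geometry is fixed at
    r_IS = 1.77 A and neighbour spins are placed off the mirror plane at
    2.2-4.0 A from the pair midpoint.  Only J_IS is non-zero.  With ``path``
    the system is also written as a YAML configuration.
    """
    if preset not in ("glycine-like", "custom"):
        raise ValueError(f"unknown preset {preset!r}")
    if not 2 <= n_spins <= 4:
        raise ValueError("n_spins must be 2-4")
    rng = np.random.default_rng(seed)
    dnu = float(rng.uniform(50.0, 250.0))
    j_is = float(rng.uniform(16.5, 18.0))
    r_is = GLYCINE_R_IS_ANGSTROM
    coords = [(0.0, 0.0, 0.0), (0.0, 0.0, r_is)]
    offsets = [dnu / 2.0, -dnu / 2.0]
    labels = ["I", "S", "K", "R"][:n_spins]
    mid = np.array([0.0, 0.0, r_is / 2.0])
    axis = np.array([0.0, 0.0, 1.0])  # I -> S direction
    for extra in range(n_spins - 2):
        while True:
            d = float(rng.uniform(2.2, 4.0))
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = mid + d * v
            # off-plane: asymmetry along the IS axis above the in-plane band
            if abs(np.dot(pos - mid, axis)) < 0.2:
                continue
            if all(np.linalg.norm(pos - np.asarray(c)) > 1.8 for c in coords):
                break
        coords.append(tuple(float(x) for x in pos))
        offsets.append(float(rng.uniform(-400.0, 400.0)))
    system = SpinSystem(
        labels=tuple(labels),
        offsets_hz=tuple(offsets),
        j_couplings_hz={("I", "S"): j_is},
        coordinates_angstrom=tuple(coords),
        b0_T=b0_T,
    )
    if path is not None:
        with open(path, "w") as fh:
            yaml.safe_dump({"spin_system": system.to_dict(), "seed": int(seed)}, fh)
    return system


def gen_buildup(
    system: SpinSystem,
    model: RelaxationModel,
    state_label: str = "LLC",
    noise_sigma: float = 0.02,
    seed: int = 0,
    cw_amplitude_hz: float = 4000.0,
    times: Sequence[float] | None = None,
    target: str = "K",
) -> BuildupCurve:
    """Simulated ROE build-up plus i.i.d. Gaussian noise.

    ``noise_sigma`` is relative to the source signal at tau = 0 (which is 1
    in projection units), so it is also the absolute noise level of the
    curve.  The seed is recorded in the curve metadata; sigma = 0
    reproduces the simulator output exactly.  The default mixing-time grid
    is the experiment's pseudo-2D one: 64 increments of 1 ms.
    """
    from .propagation import roe_buildup

    if times is None:
        times = np.arange(64) * 1e-3
    truth = roe_buildup(
        system, model, cw_amplitude_hz, initial=state_label, times=times,
        target=target,
    )
    rng = np.random.default_rng(seed)
    noisy = truth.values + (
        rng.normal(scale=noise_sigma, size=truth.values.shape)
        if noise_sigma > 0
        else 0.0
    )
    meta = dict(truth.meta)
    meta.update({"seed": int(seed), "generator": "gen_buildup"})
    return BuildupCurve(
        times_s=truth.times_s,
        values=noisy,
        state_label=state_label,
        target=target,
        noise_sigma=float(noise_sigma),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# toy structures


def _glycine_backbone() -> dict[str, np.ndarray]:
    """Idealised glycine fragment: CA at origin, backbone N and C in the
    x-y plane, the two alpha protons symmetric about it."""
    ch = 1.09
    half = np.radians(GLYCINE_HCH_ANGLE_DEG / 2.0)
    n = np.array([1.45 * np.cos(np.radians(55.0)), 1.45 * np.sin(np.radians(55.0)), 0.0])
    c = np.array([1.52 * np.cos(np.radians(-55.0)), 1.52 * np.sin(np.radians(-55.0)), 0.0])
    bisector = np.array([-1.0, 0.0, 0.0])
    normal = np.array([0.0, 0.0, 1.0])
    ha2 = ch * (np.cos(half) * bisector + np.sin(half) * normal)
    ha3 = ch * (np.cos(half) * bisector - np.sin(half) * normal)
    return {"N": n, "CA": np.zeros(3), "C": c, "HA2": ha2, "HA3": ha3}


def gen_toy_structure(
    n_models: int,
    neighbour_spec: Sequence[Mapping],
    seed: int = 0,
    jitter_angstrom: float = 0.0,
    path=None,
    truth_path=None,
) -> tuple["gemmi.Structure", pd.DataFrame]:
    """Multi-model toy PDB with one glycine and controlled neighbours.

    ``neighbour_spec`` entries are mappings with keys ``res_name`` (default
    ALA), ``atom_name`` (default HA), ``phi_deg``, ``distance_angstrom``
    and ``side`` ("closer-to-I" | "closer-to-S" | "in-plane").  Neighbours
    are placed in the plane spanned by the median and the IS axis, so the
    requested (phi, distance, side) are reproduced exactly at zero jitter;
    per-model Gaussian jitter of the stated sigma emulates an NMR-style
    ensemble.  The ground-truth table is returned and optionally written.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    backbone = _glycine_backbone()
    mid = 0.5 * (backbone["HA2"] + backbone["HA3"])
    median = mid - backbone["CA"]
    median /= np.linalg.norm(median)
    axis = backbone["HA3"] - backbone["HA2"]
    axis /= np.linalg.norm(axis)

    truth_rows = []
    positions = []
    for i, spec in enumerate(neighbour_spec):
        phi = float(spec["phi_deg"])
        dist = float(spec["distance_angstrom"])
        side = spec.get("side", "closer-to-S")
        res_name = spec.get("res_name", "ALA")
        atom_name = spec.get("atom_name", "HA")
        s = {"closer-to-S": 1.0, "closer-to-I": -1.0, "in-plane": 0.0}[side]
        if side == "in-plane" and abs(np.sin(np.radians(phi))) * dist > 1e-9:
            # fold onto the mirror plane: keep phi by using the in-plane
            # component only when phi is 0 or 180, otherwise place K on the
            # median plane normal to the IS axis
            direction = np.cos(np.radians(phi)) * median + np.sin(
                np.radians(phi)
            ) * np.cross(median, axis)
        else:
            direction = np.cos(np.radians(phi)) * median + s * np.sin(
                np.radians(phi)
            ) * axis
        pos = mid + dist * direction
        positions.append((res_name, i + 2, atom_name, pos))
        truth_rows.append(
            {
                "neighbour": f"{res_name}{i + 2}-{atom_name}",
                "phi_deg": phi,
                "distance_angstrom": dist,
                "side": side,
                "predicted_sign": int(s),
            }
        )
    truth = pd.DataFrame(truth_rows)

    st = gemmi.Structure()
    st.name = "synthetic glycine neighbourhood"
    for im in range(n_models):
        model = gemmi.Model(str(im + 1))
        chain = gemmi.Chain("A")
        gly = gemmi.Residue()
        gly.name = "GLY"
        gly.seqid = gemmi.SeqId(1, " ")
        for name, xyz in backbone.items():
            jit = rng.normal(scale=jitter_angstrom, size=3) if jitter_angstrom else 0.0
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element("H" if name.startswith("H") else name[0])
            p = np.asarray(xyz) + jit
            atom.pos = gemmi.Position(*p)
            gly.add_atom(atom)
        chain.add_residue(gly)
        for res_name, seqid, atom_name, xyz in positions:
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(seqid, " ")
            jit = rng.normal(scale=jitter_angstrom, size=3) if jitter_angstrom else 0.0
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("H")
            p = np.asarray(xyz) + jit
            atom.pos = gemmi.Position(*p)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    if path is not None:
        st.write_pdb(str(path))
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    return st, truth
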