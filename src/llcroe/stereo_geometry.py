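"""Stereospecific geometry around a glycine methylene pair.

Each neighbour proton K is described in polar coordinates relative to the
glycine H-alpha-2 / H-alpha-3 pair (spins I and S): the radius is the
distance from K to the midpoint of the IS segment, and the angle phi is
measured between the median (the unit vector from the alpha carbon through
that midpoint) and the midpoint-to-K vector.  The glycine mirror plane
sigma_h interchanges the two protons; the side of that plane on which K
sits is read from the sign of (K - midpoint).(S - I) and determines the
sign of the LLC-ROE build-up: neighbours closer to H-alpha-2 (I) build up
with the same (negative) sign as the classical ROE reference, neighbours
closer to H-alpha-3 (S) with the opposite (positive) sign.

The prochiral naming of glycine H-alpha protons varies between PDB
depositions (HA2/HA3 vs 1HA/2HA); both spellings are accepted and the
binding H-alpha-2 -> I, H-alpha-3 -> S is fixed and logged on request.
No protons are ever built silently: an X-ray file without glycine
hydrogens raises an error naming the residues (an explicitly-labelled
ideal-geometry builder is available for modelling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "GeometryRecord",
    "SignConvention",
    "read_structure",
    "glycine_pairs",
    "phi_and_distance",
    "predict_sign",
    "geometry_records",
    "ensemble_stats",
    "place_ideal_methylene_protons",
    "IN_PLANE_TOL_ANGSTROM",
]

logger = logging.getLogger(__name__)

#: projected asymmetry below which a neighbour counts as in-plane (A)
IN_PLANE_TOL_ANGSTROM = 0.05

# PDB version-2 spellings of the glycine alpha protons
_HA2_NAMES = ("HA2", "1HA")
_HA3_NAMES = ("HA3", "2HA")


@dataclass(frozen=True)
class SignConvention:
    """Binding of the prochiral proton names to the simulator's I/S labels.

    ``predict_sign`` uses: closer to H-alpha-2 (bound to I) -> -1, closer to
    H-alpha-3 (bound to S) -> +1, in-plane -> 0, matching the raw
    rotating-frame sign of the simulated LLC build-up.
    """

    halpha2_spin: str = "I"
    halpha3_spin: str = "S"


@dataclass(frozen=True)
class GeometryRecord:
    """Polar coordinates and side assignment of one neighbour in one model."""

    neighbour: str
    model: str
    distance_angstrom: float
    phi_deg: float
    signed_phi_deg: float
    side: str  # "closer-to-I" | "closer-to-S" | "in-plane"
    predicted_sign: int

    def __post_init__(self) -> None:
        if not self.distance_angstrom > 0:
            raise ValueError("distance must be positive")
        if not 0.0 <= self.phi_deg <= 180.0:
            raise ValueError("phi must be folded to [0, 180] degrees")
        expected = {"closer-to-I": -1, "closer-to-S": 1, "in-plane": 0}[self.side]
        if self.predicted_sign != expected:
            raise ValueError("predicted_sign inconsistent with side")


# ---------------------------------------------------------------------------
# structure reading


def read_structure(path, require_glycine_protons: bool = True) -> pd.DataFrame:
    """Read a (multi-model) PDB file into an atom table.

    Columns: model, chain, res_name, res_seq, atom_name, element, x, y, z.
    Residue numbering is 1-based as in the source file.  With
    ``require_glycine_protons`` (default) every glycine must carry both
    alpha protons; offenders are listed in the raised error.
    """
    st = gemmi.read_structure(str(path))
    rows = []
    for model in st:
        model_id = getattr(model, "name", None) or getattr(model, "num", "1")
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append(
                        (
                            str(model_id),
                            chain.name,
                            res.name,
                            res.seqid.num,
                            atom.name,
                            atom.element.name,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
    if not rows:
        raise ValueError(f"no atoms found in {path}")
    frame = pd.DataFrame(
        rows,
        columns=[
            "model", "chain", "res_name", "res_seq", "atom_name", "element",
            "x", "y", "z",
        ],
    )
    if require_glycine_protons:
        missing = []
        for (model, chain, seq), grp in frame[frame.res_name == "GLY"].groupby(
            ["model", "chain", "res_seq"]
        ):
            names = set(grp.atom_name)
            if not names.intersection(_HA2_NAMES) or not names.intersection(
                _HA3_NAMES
            ):
                missing.append(f"{chain}/GLY{seq} (model {model})")
        if missing:
            raise ValueError(
                "glycine residues lacking H-alpha-2/H-alpha-3 protons "
                "(no protons are built silently): " + ", ".join(missing)
            )
    return frame


def _atom_xyz(group: pd.DataFrame, names: Iterable[str]) -> np.ndarray:
    sel = group[group.atom_name.isin(list(names))]
    if sel.empty:
        raise KeyError(f"atom {tuple(names)} not found")
    return sel[["x", "y", "z"]].to_numpy(dtype=float)[0]


def glycine_pairs(frame: pd.DataFrame) -> pd.DataFrame:
    """One row per glycine per model: CA, H-alpha-2 and H-alpha-3 positions."""
    rows = []
    for (model, chain, seq), grp in frame[frame.res_name == "GLY"].groupby(
        ["model", "chain", "res_seq"]
    ):
        rows.append(
            {
                "model": model,
                "chain": chain,
                "res_seq": seq,
                "ca": _atom_xyz(grp, ("CA",)),
                "halpha2": _atom_xyz(grp, _HA2_NAMES),
                "halpha3": _atom_xyz(grp, _HA3_NAMES),
            }
        )
    if not rows:
        raise ValueError("no glycine residues in structure")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# core geometry


def phi_and_distance(
    i_xyz, s_xyz, ca_xyz, k_xyz, in_plane_tol: float = IN_PLANE_TOL_ANGSTROM
) -> tuple[float, float, str]:
    """Polar coordinates (phi in degrees, distance in Angstrom) and side.

    The median direction is the unit vector from the alpha carbon through
    the midpoint of IS; phi is the angle between that direction and the
    midpoint-to-K vector, folded to [0, 180]; the side is read from the
    projection of (K - midpoint) on the IS axis with ``in_plane_tol``
    deciding the degenerate in-plane band.
    """
    i_xyz, s_xyz, ca_xyz, k_xyz = (
        np.asarray(v, dtype=float) for v in (i_xyz, s_xyz, ca_xyz, k_xyz)
    )
    if np.linalg.norm(s_xyz - i_xyz) < 1e-6:
        raise ValueError("I and S positions coincide")
    mid = 0.5 * (i_xyz + s_xyz)
    median = mid - ca_xyz
    norm_median = np.linalg.norm(median)
    if norm_median < 1e-6:
        raise ValueError("CA coincides with the IS midpoint (degenerate median)")
    median /= norm_median
    vk = k_xyz - mid
    dist = float(np.linalg.norm(vk))
    if dist < 1e-6:
        raise ValueError("K coincides with the IS midpoint")
    cosphi = float(np.clip(np.dot(median, vk) / dist, -1.0, 1.0))
    phi = float(np.degrees(np.arccos(cosphi)))
    axis = (s_xyz - i_xyz) / np.linalg.norm(s_xyz - i_xyz)
    proj = float(np.dot(vk, axis))
    if abs(proj) < in_plane_tol:
        side = "in-plane"
    elif proj > 0:
        side = "closer-to-S"
    else:
        side = "closer-to-I"
    return phi, dist, side


def predict_sign(
    side_or_record: str | GeometryRecord,
    convention: SignConvention = SignConvention(),
) -> int:
    """LLC-ROE build-up sign from the mirror-plane side.

    Closer to H-alpha-2 (spin I) -> -1 (same sign as the classical ROE
    reference), closer to H-alpha-3 (spin S) -> +1, in-plane -> 0.
    """
    side = (
        side_or_record.side
        if isinstance(side_or_record, GeometryRecord)
        else side_or_record
    )
    logger.debug(
        "sign convention: H-alpha-2 -> %s, H-alpha-3 -> %s",
        convention.halpha2_spin,
        convention.halpha3_spin,
    )
    return {"closer-to-I": -1, "closer-to-S": 1, "in-plane": 0}[side]


def geometry_records(
    frame: pd.DataFrame,
    gly_res_seq: int,
    neighbours: Sequence[tuple[str, int, str]] | None = None,
    max_distance_angstrom: float = 5.0,
    chain: str | None = None,
    convention: SignConvention = SignConvention(),
) -> list[GeometryRecord]:
    """GeometryRecords for neighbour protons of one glycine, per model.

    ``neighbours`` is a list of (res_name, res_seq, atom_name) triples; by
    default every hydrogen outside the glycine within
    ``max_distance_angstrom`` of the IS midpoint is used.
    """
    pairs = glycine_pairs(frame)
    pairs = pairs[pairs.res_seq == gly_res_seq]
    if chain is not None:
        pairs = pairs[pairs.chain == chain]
    if pairs.empty:
        raise ValueError(f"no glycine with residue number {gly_res_seq}")
    records: list[GeometryRecord] = []
    for _, row in pairs.iterrows():
        model_frame = frame[frame.model == row.model]
        if neighbours is None:
            cand = model_frame[
                (model_frame.element == "H")
                & ~(
                    (model_frame.res_seq == gly_res_seq)
                    & (model_frame.chain == row.chain)
                )
            ]
        else:
            keys = set(neighbours)
            cand = model_frame[
                model_frame.apply(
                    lambda r: (r.res_name, r.res_seq, r.atom_name) in keys, axis=1
                )
            ]
        mid = 0.5 * (row.halpha2 + row.halpha3)
        for _, at in cand.iterrows():
            k = np.array([at.x, at.y, at.z])
            if neighbours is None and np.linalg.norm(k - mid) > max_distance_angstrom:
                continue
            phi, dist, side = phi_and_distance(row.halpha2, row.halpha3, row.ca, k)
            axis = row.halpha3 - row.halpha2
            proj = float(np.dot(k - mid, axis / np.linalg.norm(axis)))
            records.append(
                GeometryRecord(
                    neighbour=f"{at.res_name}{at.res_seq}-{at.atom_name}",
                    model=str(row.model),
                    distance_angstrom=dist,
                    phi_deg=phi,
                    signed_phi_deg=float(np.sign(proj) * phi) if side != "in-plane" else phi,
                    side=side,
                    predicted_sign=predict_sign(side, convention),
                )
            )
    if not records:
        raise ValueError("no neighbour atoms matched")
    return records


def _circular_mean_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean and circular std (degrees)."""
    rad = np.radians(angles_deg)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    mean = float(np.degrees(np.arctan2(s, c))) % 360.0
    r = float(np.hypot(c, s))
    std = float(np.degrees(np.sqrt(max(-2.0 * np.log(max(r, 1e-300)), 0.0))))
    return mean, std


def ensemble_stats(records: Sequence[GeometryRecord]) -> pd.DataFrame:
    """Per-neighbour ensemble statistics over structure models.

    Circular mean/std for phi, arithmetic mean/std for the distance; a
    neighbour whose models straddle the mirror plane is flagged
    ``sign_ambiguous`` and its consensus sign set to 0.
    """
    if not records:
        raise ValueError("empty record set")
    frame = pd.DataFrame([r.__dict__ for r in records])
    out = []
    for nb, grp in frame.groupby("neighbour"):
        phi_mean, phi_std = _circular_mean_deg(grp.phi_deg.to_numpy())
        signs = set(grp.predicted_sign)
        ambiguous = len(signs - {0}) > 1
        out.append(
            {
                "neighbour": nb,
                "n_models": len(grp),
                "phi_mean_deg": phi_mean,
                "phi_circstd_deg": phi_std,
                "distance_mean_angstrom": float(grp.distance_angstrom.mean()),
                "distance_std_angstrom": float(grp.distance_angstrom.std(ddof=0)),
                "consensus_sign": 0 if ambiguous else int(
                    max(signs, key=lambda s: (grp.predicted_sign == s).sum())
                ),
                "sign_ambiguous": ambiguous,
                "models": ",".join(grp.model),
            }
        )
    return pd.DataFrame(out)


def place_ideal_methylene_protons(
    n_xyz, ca_xyz, c_xyz, ch_bond_angstrom: float = 1.09, hch_angle_deg: float = 107.0
) -> tuple[np.ndarray, np.ndarray]:
    """MODELLING helper: ideal glycine H-alpha-2/H-alpha-3 positions.

    Builds the two methylene protons from the backbone N-CA-C geometry with
    a standard C-H bond length and H-C-H angle.  This is explicit
    model-building, never invoked automatically: structures lacking protons
    raise instead.  Returns (H-alpha-2, H-alpha-3); H-alpha-2 is placed on
    the side given by the right-handed N x C normal.
    """
    n_xyz, ca_xyz, c_xyz = (np.asarray(v, float) for v in (n_xyz, ca_xyz, c_xyz))
    b1 = n_xyz - ca_xyz
    b2 = c_xyz - ca_xyz
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    bisector = -(b1 + b2)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(b1, b2)
    normal /= np.linalg.norm(normal)
    half = np.radians(hch_angle_deg / 2.0)
    h2 = ca_xyz + ch_bond_angstrom * (np.cos(half) * bisector + np.sin(half) * normal)
    h3 = ca_xyz + ch_bond_angstrom * (np.cos(half) * bisector - np.sin(half) * normal)
    return h2, h3
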