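"""Exact product-operator algebra for small systems of spin-1/2 nuclei.

Everything downstream (relaxation, propagation, pulse simulation) is built on
the matrices produced here.  Conventions, fixed once for the whole package:

* Zeeman product basis with |alpha> = |m=+1/2> first, ordered
  ``|aa>, |ab>, |ba>, |bb>`` for two spins and the analogous Kronecker
  ordering (first declared spin = leftmost factor) for three or four spins.
* Cartesian single-spin operators are half Pauli matrices, so
  ``Tr[Ix Ix] = 2**n / 4`` for an n-spin system.
* The singlet/triplet pair states are
  ``S0 = (|ab> - |ba>)/sqrt(2)``, ``T0 = (|ab> + |ba>)/sqrt(2)``,
  ``T+1 = |aa>``, ``T-1 = |bb>``, quantized either along z (lab frame) or
  along x (the CW spin-lock frame); the x-frame states are obtained from the
  z-frame ones by the global rotation ``exp(-i (pi/2) sum_k Iky)`` which maps
  z onto x.
* The long-lived coherence operator is ``Q = |S0><T0| + |T0><S0| +
  i(|S0><T0| - |T0><S0|)``; in the x frame its real part equals ``Ix - Sx``
  and its imaginary part ``2IzSy - 2IySz``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GAMMA_H",
    "SpinSystem",
    "StateOperator",
    "SpinKet",
    "single_spin_op",
    "build_operator",
    "permutation_operator",
    "singlet_triplet_basis",
    "llc_operator",
    "project",
]

#: Proton gyromagnetic ratio (rad s^-1 T^-1), CODATA.
GAMMA_H = 267.522187_08e6

_PAULI = {
    "x": np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex),
    "y": np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex),
    "z": np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex),
    "+": np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex),
    "-": np.array([[0.0, 0.0], [1.0, 0.0]], dtype=complex),
}

_MIN_DISTANCE_ANGSTROM = 0.5


def _normalise_j_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SpinSystem:
    """A system of 2-4 like (1H by default) spin-1/2 nuclei.

    Parameters
    ----------
    labels:
        Spin identifiers, conventionally ``("I", "S")`` for the glycine
        methylene pair plus optional neighbours ``"K"`` and ``"R"``.
    offsets_hz:
        Resonance offset of each spin from the CW carrier, in Hz.
    j_couplings_hz:
        Scalar couplings in Hz, keyed by unordered label pairs.  By default
        only J(I,S) is non-zero, mirroring a glycine pair whose neighbours
        couple only through space.
    coordinates_angstrom:
        One 3-vector per spin, used for dipolar couplings.
    gamma_rad_per_s_per_T:
        Gyromagnetic ratio per spin (all 1H unless stated otherwise).
    b0_T:
        Static field; only used to derive the Larmor frequency.
    """

    labels: tuple[str, ...]
    offsets_hz: tuple[float, ...]
    j_couplings_hz: Mapping[tuple[str, str], float]
    coordinates_angstrom: tuple[tuple[float, float, float], ...]
    gamma_rad_per_s_per_T: tuple[float, ...] = ()
    b0_T: float = 22.3

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if not 2 <= len(labels) <= 4:
            raise ValueError(f"need 2-4 spins, got {len(labels)}")
        if len(set(labels)) != len(labels):
            raise ValueError("spin labels must be unique")
        offsets = tuple(float(v) for v in self.offsets_hz)
        if len(offsets) != len(labels) or not all(np.isfinite(offsets)):
            raise ValueError("offsets_hz must be finite, one per spin")
        coords = np.asarray(self.coordinates_angstrom, dtype=float)
        if coords.shape != (len(labels), 3):
            raise ValueError("coordinates_angstrom must be (n_spins, 3)")
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d <= _MIN_DISTANCE_ANGSTROM:
                    raise ValueError(
                        f"spins {labels[i]},{labels[j]} closer than "
                        f"{_MIN_DISTANCE_ANGSTROM} A (d={d:.3f} A)"
                    )
        gammas = tuple(float(g) for g in self.gamma_rad_per_s_per_T) or (
            (GAMMA_H,) * len(labels)
        )
        if len(gammas) != len(labels):
            raise ValueError("one gyromagnetic ratio per spin required")
        jmap: dict[tuple[str, str], float] = {}
        for key, value in dict(self.j_couplings_hz).items():
            a, b = key
            if a == b:
                raise ValueError("J coupling requires two distinct spins")
            if a not in labels or b not in labels:
                raise ValueError(f"J coupling references unknown spin in {key}")
            jmap[_normalise_j_key(a, b)] = float(value)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "offsets_hz", offsets)
        object.__setattr__(self, "gamma_rad_per_s_per_T", gammas)
        object.__setattr__(self, "j_couplings_hz", jmap)
        object.__setattr__(
            self,
            "coordinates_angstrom",
            tuple(tuple(float(x) for x in row) for row in coords),
        )
        if not self.b0_T > 0:
            raise ValueError("b0_T must be positive")

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_spins(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    @property
    def larmor_hz(self) -> float:
        """Proton Larmor frequency nu0 = gamma B0 / 2pi (Hz, magnitude)."""
        return abs(self.gamma_rad_per_s_per_T[0]) * self.b0_T / (2.0 * np.pi)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown spin label {label!r}") from None

    def j_hz(self, a: str, b: str) -> float:
        return self.j_couplings_hz.get(_normalise_j_key(a, b), 0.0)

    def coords(self) -> np.ndarray:
        return np.asarray(self.coordinates_angstrom, dtype=float)

    def distance_angstrom(self, a: str, b: str) -> float:
        c = self.coords()
        return float(np.linalg.norm(c[self.index(a)] - c[self.index(b)]))

    # -- config I/O -------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SpinSystem":
        """Build from the documented YAML/JSON configuration mapping.

        Schema (all frequencies Hz, coordinates Angstrom)::

            labels: [I, S, K]
            offsets_hz: [70.0, -70.0, 0.0]
            j_couplings_hz: {"I,S": 17.5}
            coordinates_angstrom: [[...], [...], [...]]
            b0_T: 22.3            # or larmor_mhz: 950.0
        """
        labels = tuple(cfg["labels"])
        j_raw = cfg.get("j_couplings_hz", {}) or {}
        jmap = {}
        for key, value in j_raw.items():
            if isinstance(key, str):
                parts = [p.strip() for p in re.split(r"[,\-]", key) if p.strip()]
            else:
                parts = list(key)
            if len(parts) != 2:
                raise ValueError(f"bad J-coupling key {key!r}")
            jmap[(parts[0], parts[1])] = float(value)
        if "b0_T" in cfg:
            b0 = float(cfg["b0_T"])
        elif "larmor_mhz" in cfg:
            b0 = float(cfg["larmor_mhz"]) * 1e6 * 2.0 * np.pi / GAMMA_H
        else:
            b0 = 22.3
        return cls(
            labels=labels,
            offsets_hz=tuple(float(v) for v in cfg["offsets_hz"]),
            j_couplings_hz=jmap,
            coordinates_angstrom=tuple(
                tuple(float(x) for x in row) for row in cfg["coordinates_angstrom"]
            ),
            gamma_rad_per_s_per_T=tuple(
                float(g) for g in cfg.get("gamma_rad_per_s_per_T", ())
            ),
            b0_T=b0,
        )

    @classmethod
    def from_yaml(cls, path) -> "SpinSystem":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg.get("spin_system", cfg))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "offsets_hz": list(self.offsets_hz),
            "j_couplings_hz": {
                f"{a},{b}": v for (a, b), v in sorted(self.j_couplings_hz.items())
            },
            "coordinates_angstrom": [list(row) for row in self.coordinates_angstrom],
            "gamma_rad_per_s_per_T": list(self.gamma_rad_per_s_per_T),
            "b0_T": self.b0_T,
        }


@dataclass
class StateOperator:
    """A density/detection operator in the fixed Zeeman product basis."""

    matrix: np.ndarray
    label: str = ""
    basis: str = "zeeman"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("StateOperator matrix must be square")
        n = int(round(np.log2(m.shape[0])))
        if 2 ** n != m.shape[0]:
            raise ValueError("dimension must be a power of two")
        self.matrix = m

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.conj().T, atol=tol))

    def dagger(self) -> "StateOperator":
        return StateOperator(self.matrix.conj().T, label=f"({self.label})+")

    def norm(self) -> float:
        """Frobenius norm."""
        return float(np.linalg.norm(self.matrix))

    def normalised(self) -> "StateOperator":
        n = self.norm()
        if n == 0:
            raise ValueError("cannot normalise the zero operator")
        return StateOperator(self.matrix / n, label=self.label, basis=self.basis)


@dataclass
class SpinKet:
    """A pure state vector in the fixed Zeeman product basis."""

    vector: np.ndarray
    label: str = ""
    basis: str = "zeeman"

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=complex).reshape(-1)
        n = int(round(np.log2(v.size)))
        if 2 ** n != v.size:
            raise ValueError("ket dimension must be a power of two")
        self.vector = v

    def outer(self, other: "SpinKet") -> np.ndarray:
        """|self><other|."""
        return np.outer(self.vector, other.vector.conj())


def single_spin_op(n_spins: int, index: int, axis: str) -> np.ndarray:
    """Matrix of a single-spin operator (axis in x, y, z, +, -) embedded in
    the n-spin product space."""
    if axis not in _PAULI:
        raise ValueError(f"unknown axis {axis!r}")
    if not 0 <= index < n_spins:
        raise ValueError("spin index out of range")
    op = np.array([[1.0]], dtype=complex)
    for k in range(n_spins):
        op = np.kron(op, _PAULI[axis] if k == index else np.eye(2, dtype=complex))
    return op


# ---------------------------------------------------------------------------
# product-operator expression mini-language


_NUMBER_RE = re.compile(r"\d+(?:\.\d*)?(?:[eE][+-]?\d+)?")


def _tokenize_term(term: str, labels: Sequence[str], original: str):
    """Split one additive term into (coefficient, [(label, axis), ...])."""
    pos = 0
    coeff = 1.0
    factors: list[tuple[str, str]] = []
    term = term.strip()
    m = _NUMBER_RE.match(term)
    if m:
        coeff = float(m.group(0))
        pos = m.end()
    by_length = sorted(labels, key=len, reverse=True)
    while pos < len(term):
        ch = term[pos]
        if ch in " *":
            pos += 1
            continue
        matched = None
        for lab in by_length:
            if term.startswith(lab, pos):
                matched = lab
                break
        if matched is None:
            raise ValueError(
                f"cannot parse {original!r}: unknown spin label at {term[pos:]!r}"
            )
        pos += len(matched)
        if pos >= len(term) or term[pos] not in "xyz+-":
            raise ValueError(
                f"cannot parse {original!r}: spin {matched!r} lacks an axis "
                "(one of x, y, z, +, -)"
            )
        factors.append((matched, term[pos]))
        pos += 1
    if not factors:
        raise ValueError(f"cannot parse {original!r}: empty term {term!r}")
    return coeff, factors


def _split_terms(expr: str):
    """Split on +/- that act as term separators.

    A ``+``/``-`` immediately after a spin *label* is a raising/lowering axis;
    after a complete factor (label+axis), a number, or at the start it
    separates terms.
    """
    out = []
    sign = 1.0
    buf = ""
    prev_is_label_char = False  # last non-space char could still need an axis
    pending_term = False  # a separator was seen and awaits its term
    i = 0
    while i < len(expr):
        ch = expr[i]
        if ch in "+-" and not prev_is_label_char:
            if buf.strip():
                out.append((sign, buf))
                buf = ""
            sign = 1.0 if ch == "+" else -1.0
            pending_term = True
        else:
            buf += ch
            if not ch.isspace():
                # heuristic: an alphabetic char that is not an axis letter
                # leaves the factor open, so a following +/- is an axis
                prev_is_label_char = ch.isalpha() and ch not in "xyz"
        if ch in "+-" and prev_is_label_char:
            prev_is_label_char = False
        i += 1
    if buf.strip():
        out.append((sign, buf))
    elif pending_term:
        out.append((sign, ""))  # trailing separator: force a parse error
    return out


def build_operator(system: SpinSystem, expression: str) -> StateOperator:
    """Build the matrix of a product-operator expression.

    The expression language covers sums of scalar-weighted products of
    single-spin operators, e.g. ``"Ix-Sx"``, ``"2IzSy-2IySz"``,
    ``"0.5I+S-"`` or ``"identity"``.  Unicode minus is accepted.
    """
    expr = expression.replace("−", "-").replace("–", "-").strip()
    if not expr:
        raise ValueError("empty operator expression")
    n = system.n_spins
    if expr.lower() in {"identity", "e", "1"}:
        return StateOperator(np.eye(system.dim, dtype=complex), label="identity")
    total = np.zeros((system.dim, system.dim), dtype=complex)
    for sign, term in _split_terms(expr):
        coeff, factors = _tokenize_term(term, system.labels, expression)
        mat = np.eye(system.dim, dtype=complex)
        for lab, axis in factors:
            mat = mat @ single_spin_op(n, system.index(lab), axis)
        total += sign * coeff * mat
    return StateOperator(total, label=expression)


def permutation_operator(system: SpinSystem, pair: Sequence[str]) -> np.ndarray:
    """SWAP operator exchanging the two spins of ``pair`` (identity on the
    rest); realises the glycine mirror symmetry sigma_h on spin space."""
    if len(pair) != 2:
        raise ValueError("pair must contain exactly two labels")
    i, j = (system.index(p) for p in pair)
    # SWAP = 1/2 (identity + 4 I.S) for the pair
    dot = sum(
        single_spin_op(system.n_spins, i, ax) @ single_spin_op(system.n_spins, j, ax)
        for ax in "xyz"
    )
    return 0.5 * np.eye(system.dim, dtype=complex) + 2.0 * dot


def _rotation_z_to_x(system: SpinSystem) -> np.ndarray:
    """Global unitary exp(-i (pi/2) sum_k Iky), rotating z onto x."""
    jy = sum(
        single_spin_op(system.n_spins, k, "y") for k in range(system.n_spins)
    )
    from scipy.linalg import expm

    return expm(-1j * (np.pi / 2.0) * jy)


def singlet_triplet_basis(
    system: SpinSystem, pair: Sequence[str] = ("I", "S"), quantization_axis: str = "z"
):
    """Return the four pair kets ``(S0, T+1, T0, T-1)`` as StateOperators.

    The kets live in the full Hilbert space only for a two-spin system; for
    larger systems they are returned in the two-spin subspace of the pair
    (column vectors of length 4, ordering |aa>, |ab>, |ba>, |bb> of the pair).
    """
    if len(pair) != 2:
        raise ValueError("pair must contain exactly two labels")
    for p in pair:
        system.index(p)  # raises on unknown labels
    if quantization_axis not in ("x", "z"):
        raise ValueError("quantization_axis must be 'x' or 'z'")
    aa = np.array([1, 0, 0, 0], dtype=complex)
    ab = np.array([0, 1, 0, 0], dtype=complex)
    ba = np.array([0, 0, 1, 0], dtype=complex)
    bb = np.array([0, 0, 0, 1], dtype=complex)
    rt2 = 2.0 ** -0.5
    kets = {
        "S0": rt2 * (ab - ba),
        "T+1": aa,
        "T0": rt2 * (ab + ba),
        "T-1": bb,
    }
    if quantization_axis == "x":
        pair_system = SpinSystem(
            labels=tuple(pair),
            offsets_hz=(0.0, 0.0),
            j_couplings_hz={},
            coordinates_angstrom=((0.0, 0.0, 0.0), (1.77, 0.0, 0.0)),
        )
        u = _rotation_z_to_x(pair_system)
        kets = {k: u @ v for k, v in kets.items()}
    return tuple(
        SpinKet(v, label=f"|{name}>_{quantization_axis}")
        for name, v in (
            ("S0", kets["S0"]),
            ("T+1", kets["T+1"]),
            ("T0", kets["T0"]),
            ("T-1", kets["T-1"]),
        )
    )


def llc_operator(
    system: SpinSystem, pair: Sequence[str] = ("I", "S"), quantization_axis: str = "x"
) -> StateOperator:
    """Long-lived coherence operator Q = Qpar + i Qperp for the pair.

    In the spin-lock (x) frame ``Qpar = Ix - Sx`` and
    ``Qperp = 2IzSy - 2IySz``; the z-frame variant is the 90-degree
    y-rotation of that, with real part ``Iz - Sz``.  Q connects the singlet
    with the central triplet state, so it is traceless and changes sign
    under spin permutation.
    """
    if len(pair) != 2:
        raise ValueError("pair must contain exactly two labels")
    a, b = pair
    qpar = build_operator(system, f"{a}x-{b}x").matrix
    qperp = build_operator(system, f"2{a}z{b}y-2{a}y{b}z").matrix
    q = qpar + 1j * qperp
    if quantization_axis == "x":
        return StateOperator(q, label=f"Q_LLC({a},{b})_x")
    if quantization_axis == "z":
        u = _rotation_z_to_x(system)
        # x-frame operators are the z-frame ones conjugated by u; invert it
        return StateOperator(u.conj().T @ q @ u, label=f"Q_LLC({a},{b})_z")
    raise ValueError("quantization_axis must be 'x' or 'z'")


def project(rho: StateOperator | np.ndarray, op: StateOperator | np.ndarray) -> float:
    """Normalised overlap Tr[rho op] / Tr[op op] (real part).

    With this normalisation the projection of an operator onto itself is 1,
    which fixes the amplitude scale of all reported trajectories.
    """
    r = rho.matrix if isinstance(rho, StateOperator) else np.asarray(rho)
    o = op.matrix if isinstance(op, StateOperator) else np.asarray(op)
    if r.shape != o.shape:
        raise ValueError(f"dimension mismatch {r.shape} vs {o.shape}")
    denom = np.trace(o @ o)
    if abs(denom) == 0:
        raise ValueError("projection target has zero norm")
    return float(np.real(np.trace(r @ o) / denom))
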