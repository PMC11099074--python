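"""Dipole-dipole Redfield relaxation for rigid, isotropically tumbling spins.

The fluctuating Hamiltonian is the sum over spin pairs (i, j) of

    H_D(t) = b_ij * sum_q F_2q(Omega_ij(t)) T_2q^(ij)

with b_ij = -(mu0/4pi) gamma_i gamma_j hbar / r_ij^3 the dipolar coupling
constant and T_2q the unit-Frobenius-norm rank-2 spin tensor operators of the
pair.  For isotropic rotational diffusion with correlation time tau_c the
orientation functions decay mono-exponentially and the relaxation
superoperator takes the double-commutator form

    Gamma(rho) = -(3/4) sum_{p,p'} b_p b_p' P2(cos theta_pp') *
                 sum_q J(q w0) [T_2q^(p), [T_2q^(p')+, rho]]

(symmetrised in p <-> p'), where J(w) = (2/5) tau_c / (1 + w^2 tau_c^2),
P2 is the second Legendre polynomial of the angle between the two
internuclear vectors (auto terms have P2 = 1) and w0 is the Larmor
frequency.  The overall factor 3/4 is pinned by requiring that the isolated
like-spin pair reproduce the Solomon longitudinal rate
R1 = (3/4) b^2 [J(w0) + 4 J(2w0)]; the same convention then fixes every
other rate in the package.

Because all spins are protons, every lab-frame eigenfrequency difference
produced by a q-quantum dipolar term equals q*w0 up to offsets of a few
hundred Hz, i.e. to a relative accuracy of ~1e-7; the superoperator is
therefore built with spectral densities at 0, w0 and 2w0 and is *not*
secularised with respect to the rotating-frame Hamiltonian (offsets, J, CW
irradiation), which is treated exactly by the propagation module.  This is
the standard treatment for spin-locked relaxation when w1 tau_c << 1.

Dipole-dipole relaxation between equivalent spins cannot mix states of
different permutation symmetry: the singlet population of an isolated pair
is immune, and the singlet-triplet coherence (the LLC) decays up to three
times more slowly than in-phase transverse magnetisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.constants import hbar, mu_0

from .spin_core import SpinSystem, single_spin_op

__all__ = [
    "RelaxationModel",
    "dipolar_coupling",
    "spectral_density",
    "redfield_superoperator",
    "llc_and_transverse_rates",
    "solomon_longitudinal_rate",
    "solomon_transverse_rate",
]


@dataclass(frozen=True)
class RelaxationModel:
    """Isotropic rigid-rotor relaxation model.

    Parameters
    ----------
    tau_c_s:
        Rotational correlation time in seconds (10 ns is typical for a
        ~14 kDa protein at room temperature).
    b0_T:
        Static magnetic field in tesla (22.3 T <-> 950 MHz protons).
    mechanisms:
        Only ``("dipolar",)`` is supported; CSA, anisotropic diffusion and
        internal motion are out of scope.
    """

    tau_c_s: float
    b0_T: float = 22.3
    mechanisms: tuple[str, ...] = ("dipolar",)
    spectral_density_convention: str = "reduced-2/5"

    def __post_init__(self) -> None:
        if not self.tau_c_s > 0:
            raise ValueError("tau_c_s must be positive")
        if not self.b0_T > 0:
            raise ValueError("b0_T must be positive")
        for mech in self.mechanisms:
            if mech != "dipolar":
                raise ValueError(f"unsupported relaxation mechanism {mech!r}")

    def larmor_rad_per_s(self, gamma: float) -> float:
        return gamma * self.b0_T


def dipolar_coupling(r_angstrom: float, gamma1: float, gamma2: float) -> float:
    """Dipolar coupling constant b = -(mu0/4pi) gamma1 gamma2 hbar / r^3.

    Returned in rad/s; negative for two like-sign gyromagnetic ratios.
    Two protons at 1.78 A give b/2pi of about -21.3 kHz.
    """
    if not r_angstrom > 0:
        raise ValueError("distance must be positive")
    if r_angstrom < 0.5:
        raise ValueError(f"distance {r_angstrom} A below the 0.5 A sanity bound")
    r = r_angstrom * 1e-10
    return -(mu_0 / (4.0 * np.pi)) * gamma1 * gamma2 * hbar / r**3


def spectral_density(omega_rad_per_s: float | np.ndarray, model: RelaxationModel):
    """Reduced spectral density J(w) = (2/5) tau_c / (1 + w^2 tau_c^2) in s."""
    tc = model.tau_c_s
    w = np.asarray(omega_rad_per_s, dtype=float)
    out = 0.4 * tc / (1.0 + (w * tc) ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rank-2 spin tensors and the superoperator


def _pair_tensors(system: SpinSystem, i: int, j: int) -> dict[int, np.ndarray]:
    """Unit-norm rank-2 tensor operators T_2q for spins (i, j), q = -2..2."""
    n = system.n_spins

    def op(idx, ax):
        return single_spin_op(n, idx, ax)

    ip, im, iz = op(i, "+"), op(i, "-"), op(i, "z")
    sp, sm, sz = op(j, "+"), op(j, "-"), op(j, "z")
    t22 = ip @ sp
    t21 = -(iz @ sp + ip @ sz)
    t20 = (4.0 * iz @ sz - ip @ sm - im @ sp) / np.sqrt(6.0)
    t2m1 = iz @ sm + im @ sz
    t2m2 = im @ sm
    # unit Frobenius norm in the pair subspace; embedding in a larger system
    # tensors the identity on spectator spins and must NOT be rescaled
    return {q: t for q, t in ((2, t22), (1, t21), (0, t20), (-1, t2m1), (-2, t2m2))}


def _commutator_superop(a: np.ndarray) -> np.ndarray:
    """Superoperator of rho -> [a, rho] for row-major vectorised rho."""
    d = a.shape[0]
    eye = np.eye(d, dtype=complex)
    return np.kron(a, eye) - np.kron(eye, a.T)


def redfield_superoperator(system: SpinSystem, model: RelaxationModel) -> np.ndarray:
    """Full dipolar Redfield superoperator Gamma (dimension 4^n x 4^n).

    Acts on row-major vectorised density operators; includes every pair
    auto-correlation and every pair-pair cross-correlation weighted by
    P2(cos theta) of the inter-vector angle.  Gamma annihilates the
    identity and preserves Hermiticity.
    """
    if tuple(model.mechanisms) != ("dipolar",):
        raise ValueError("only dipolar relaxation is implemented")
    coords = system.coords()
    if coords.shape[0] != system.n_spins:
        raise ValueError("coordinates required for every spin")
    n = system.n_spins
    d = system.dim
    gamma_ratios = system.gamma_rad_per_s_per_T
    w0 = abs(gamma_ratios[0]) * model.b0_T

    pairs = list(combinations(range(n), 2))
    b_const = {}
    unit_vec = {}
    tensors = {}
    for (i, j) in pairs:
        rij = coords[j] - coords[i]
        r = float(np.linalg.norm(rij))
        b_const[(i, j)] = dipolar_coupling(r, gamma_ratios[i], gamma_ratios[j])
        unit_vec[(i, j)] = rij / r
        tensors[(i, j)] = _pair_tensors(system, i, j)

    jq = {q: spectral_density(q * w0, model) for q in (0, 1, 2)}

    gamma = np.zeros((d * d, d * d), dtype=complex)
    for p in pairs:
        for pp in pairs:
            cos_t = float(np.dot(unit_vec[p], unit_vec[pp]))
            p2 = 0.5 * (3.0 * cos_t**2 - 1.0)
            weight = b_const[p] * b_const[pp] * p2
            if weight == 0.0:
                continue
            for q in (-2, -1, 0, 1, 2):
                a = tensors[p][q]
                b = tensors[pp][q]
                dc = _commutator_superop(a) @ _commutator_superop(b.conj().T)
                if pp != p:
                    dc = 0.5 * (
                        dc
                        + _commutator_superop(b) @ _commutator_superop(a.conj().T)
                    )
                gamma -= 0.75 * weight * jq[abs(q)] * dc
    return gamma


# ---------------------------------------------------------------------------
# analytic Solomon closed forms (isolated like-spin pair)


def solomon_longitudinal_rate(b: float, tau_c_s: float, omega0: float) -> float:
    """R1 of an isolated like-spin pair: (3/4) b^2 [J(w0) + 4 J(2w0)]."""
    model = RelaxationModel(tau_c_s=tau_c_s, b0_T=1.0)
    jw = spectral_density(omega0, model)
    j2w = spectral_density(2.0 * omega0, model)
    return 0.75 * b * b * (jw + 4.0 * j2w)


def solomon_transverse_rate(b: float, tau_c_s: float, omega0: float) -> float:
    """R2 of an isolated like-spin pair: (3/8) b^2 [3J(0) + 5J(w0) + 2J(2w0)]."""
    model = RelaxationModel(tau_c_s=tau_c_s, b0_T=1.0)
    j0 = spectral_density(0.0, model)
    jw = spectral_density(omega0, model)
    j2w = spectral_density(2.0 * omega0, model)
    return 0.375 * b * b * (3.0 * j0 + 5.0 * jw + 2.0 * j2w)


# ---------------------------------------------------------------------------
# LLC and spin-locked transverse rates


def llc_and_transverse_rates(
    system: SpinSystem,
    model: RelaxationModel,
    cw_amplitude_hz: float,
    pair: Sequence[str] = ("I", "S"),
) -> tuple[float, float]:
    """Decay rates (R_LLC, R_1rho) in 1/s from the full Liouvillian.

    Evolves Q_par = Ix - Sx (sampled at multiples of 1/J so that the
    coherent J oscillation is at its maxima) and Ix + Sx under the
    rotating-frame Hamiltonian plus Gamma, and extracts mono-exponential
    rates by a log-linear fit.  Warns if the CW amplitude is below five
    times the offset difference, where the magnetic-equivalence regime is
    not established.
    """
    import warnings

    from .propagation import llc_decay_constant, ref_decay_constant

    a, bl = pair
    dnu = abs(system.offsets_hz[system.index(a)] - system.offsets_hz[system.index(bl)])
    if cw_amplitude_hz < 5.0 * dnu:
        warnings.warn(
            "CW amplitude below 5x the I-S offset difference; LLC regime "
            "not established",
            stacklevel=2,
        )
    fit_llc = llc_decay_constant(system, model, cw_amplitude_hz, pair=pair)
    fit_ref = ref_decay_constant(system, model, cw_amplitude_hz, pair=pair)
    return fit_llc.rate_per_s, fit_ref.rate_per_s
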