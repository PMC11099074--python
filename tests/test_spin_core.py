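"""Product-operator algebra against a brute-force Kronecker oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from llcroe.spin_core import (
    SpinSystem,
    build_operator,
    llc_operator,
    permutation_operator,
    project,
    singlet_triplet_basis,
)

SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
SP = np.array([[0, 1], [0, 0]], dtype=complex)
SM = np.array([[0, 0], [1, 0]], dtype=complex)
PAULI = {"x": SX, "y": SY, "z": SZ, "+": SP, "-": SM}


def kron_oracle(n, factors):
    """Independent embedding: explicit Kronecker product of 2x2 blocks."""
    mats = [np.eye(2, dtype=complex)] * n
    out = np.eye(2**n, dtype=complex)
    for idx, axis in factors:
        m = [np.eye(2, dtype=complex)] * n
        m[idx] = PAULI[axis]
        full = m[0]
        for b in m[1:]:
            full = np.kron(full, b)
        out = out @ full
    return out


@pytest.fixture(scope="module")
def pair():
    return SpinSystem(
        labels=("I", "S"),
        offsets_hz=(70.0, -70.0),
        j_couplings_hz={("I", "S"): 17.5},
        coordinates_angstrom=((0, 0, 0), (0, 0, 1.77)),
    )


@pytest.fixture(scope="module")
def triple():
    return SpinSystem(
        labels=("I", "S", "K"),
        offsets_hz=(70.0, -70.0, 300.0),
        j_couplings_hz={("I", "S"): 17.5},
        coordinates_angstrom=((0, 0, 0), (0, 0, 1.77), (2.5, 0, 1.0)),
    )


@pytest.mark.parametrize(
    "expr, factors",
    [
        ("Ix-Sx", [("-", None)]),  # handled specially below
        ("Ix+Sx", None),
        ("2IzSy-2IySz", None),
        ("0.5I+S-", None),
        ("IzSz", None),
        ("2IxSx+2IySy", None),
    ],
)
def test_build_operator_matches_kron_oracle(pair, expr, factors):
    """Every expression used in the package equals its explicit Kronecker
    construction."""
    oracles = {
        "Ix-Sx": kron_oracle(2, [(0, "x")]) - kron_oracle(2, [(1, "x")]),
        "Ix+Sx": kron_oracle(2, [(0, "x")]) + kron_oracle(2, [(1, "x")]),
        "2IzSy-2IySz": 2 * kron_oracle(2, [(0, "z"), (1, "y")])
        - 2 * kron_oracle(2, [(0, "y"), (1, "z")]),
        "0.5I+S-": 0.5 * kron_oracle(2, [(0, "+"), (1, "-")]),
        "IzSz": kron_oracle(2, [(0, "z"), (1, "z")]),
        "2IxSx+2IySy": 2 * kron_oracle(2, [(0, "x"), (1, "x")])
        + 2 * kron_oracle(2, [(0, "y"), (1, "y")]),
    }
    got = build_operator(pair, expr).matrix
    assert np.allclose(got, oracles[expr], atol=1e-14)


def test_qpar_norm_and_hermiticity(pair):
    """Ix - Sx is a traceless Hermitian 4x4 operator with Tr[(Ix-Sx)^2] = 2."""
    q = build_operator(pair, "Ix-Sx")
    assert q.matrix.shape == (4, 4)
    assert q.is_hermitian()
    assert abs(np.trace(q.matrix)) < 1e-14
    assert np.isclose(np.trace(q.matrix @ q.matrix).real, 2.0)


def test_identity_expression(pair, triple):
    for system in (pair, triple):
        e = build_operator(system, "identity")
        assert np.allclose(e.matrix, np.eye(system.dim))


def test_unicode_minus_accepted(pair):
    a = build_operator(pair, "Ix−Sx").matrix
    b = build_operator(pair, "Ix-Sx").matrix
    assert np.allclose(a, b)


@pytest.mark.parametrize(
    "expr, msg",
    [
        ("Qx", "unknown spin label"),
        ("I", "lacks an axis"),
        ("Ix-", "empty term"),
        ("", "empty"),
    ],
)
def test_parse_errors_name_offending_token(pair, expr, msg):
    with pytest.raises(ValueError, match=msg):
        build_operator(pair, expr)


@settings(max_examples=30, deadline=None)
@given(
    a=st.floats(-5, 5, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
    b=st.floats(-5, 5, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
)
def test_expression_linearity(a, b):
    """build_operator is linear in the expression coefficients."""
    system = SpinSystem(
        labels=("I", "S"),
        offsets_hz=(0.0, 0.0),
        j_couplings_hz={},
        coordinates_angstrom=((0, 0, 0), (0, 0, 1.77)),
    )
    combined = build_operator(system, f"{a}IxSz+{b}Sy").matrix
    part = a * build_operator(system, "IxSz").matrix + b * build_operator(
        system, "Sy"
    ).matrix
    assert np.allclose(combined, part, atol=1e-10)


class TestSingletTripletBasis:
    def test_orthonormal_and_symmetry(self, pair):
        kets = singlet_triplet_basis(pair, ("I", "S"), "z")
        vecs = [k.vector for k in kets]
        gram = np.array([[np.vdot(u, v) for v in vecs] for u in vecs])
        assert np.allclose(gram, np.eye(4), atol=1e-12)
        # permutation: S0 antisymmetric, T's symmetric
        swap = np.zeros((4, 4))
        swap[0, 0] = swap[3, 3] = swap[1, 2] = swap[2, 1] = 1.0
        s0, tp, t0, tm = vecs
        assert np.allclose(swap @ s0, -s0)
        for t in (tp, t0, tm):
            assert np.allclose(swap @ t, t)

    def test_z_outer_product_equals_iz_minus_sz(self, pair):
        s0, _, t0, _ = singlet_triplet_basis(pair, ("I", "S"), "z")
        outer = s0.outer(t0) + t0.outer(s0)
        assert np.allclose(outer, build_operator(pair, "Iz-Sz").matrix, atol=1e-12)

    def test_x_outer_product_equals_ix_minus_sx(self, pair):
        """The x-quantized singlet/triplet coherence is the 90-degree
        y-rotation of the z-frame result and equals Ix - Sx."""
        s0, _, t0, _ = singlet_triplet_basis(pair, ("I", "S"), "x")
        outer = s0.outer(t0) + t0.outer(s0)
        assert np.allclose(outer, build_operator(pair, "Ix-Sx").matrix, atol=1e-12)

    def test_pair_size_validated(self, pair):
        with pytest.raises(ValueError):
            singlet_triplet_basis(pair, ("I",), "z")


class TestLLCOperator:
    def test_hermitian_components_are_qpar_and_qperp(self, pair):
        """Q = Qpar + i Qperp with both components Hermitian: the real
        (Hermitian) part is Ix - Sx and the imaginary part 2IzSy - 2IySz."""
        q = llc_operator(pair, ("I", "S"), "x").matrix
        herm = 0.5 * (q + q.conj().T)
        anti = (q - q.conj().T) / 2j
        assert np.allclose(herm, build_operator(pair, "Ix-Sx").matrix, atol=1e-12)
        assert np.allclose(anti, build_operator(pair, "2IzSy-2IySz").matrix,
                           atol=1e-12)

    def test_traceless(self, pair):
        for axis in ("x", "z"):
            assert abs(np.trace(llc_operator(pair, ("I", "S"), axis).matrix)) < 1e-12

    def test_zero_diagonal_in_singlet_triplet_basis(self, pair):
        kets = singlet_triplet_basis(pair, ("I", "S"), "x")
        q = llc_operator(pair, ("I", "S"), "x").matrix
        for k in kets:
            assert abs(np.vdot(k.vector, q @ k.vector)) < 1e-12

    def test_permutation_antisymmetry(self, pair):
        p = permutation_operator(pair, ("I", "S"))
        qpar = build_operator(pair, "Ix-Sx").matrix
        ref = build_operator(pair, "Ix+Sx").matrix
        assert np.allclose(p @ qpar @ p, -qpar, atol=1e-12)
        assert np.allclose(p @ ref @ p, ref, atol=1e-12)

    def test_frames_related_by_rotation(self, pair):
        from scipy.linalg import expm

        from llcroe.spin_core import single_spin_op

        jy = single_spin_op(2, 0, "y") + single_spin_op(2, 1, "y")
        u = expm(-1j * (np.pi / 2) * jy)
        qz = llc_operator(pair, ("I", "S"), "z").matrix
        qx = llc_operator(pair, ("I", "S"), "x").matrix
        assert np.allclose(u @ qz @ u.conj().T, qx, atol=1e-12)


class TestProject:
    def test_self_projection(self, pair):
        q = build_operator(pair, "Ix-Sx")
        assert np.isclose(project(q, q), 1.0)

    def test_symmetric_antisymmetric_orthogonal(self, pair):
        a = build_operator(pair, "Ix+Sx")
        b = build_operator(pair, "Ix-Sx")
        assert abs(project(a, b)) < 1e-14

    def test_linearity_and_decomposition(self, pair):
        qpar = build_operator(pair, "Ix-Sx")
        qperp = build_operator(pair, "2IzSy-2IySz")
        rho = 0.3 * qpar.matrix + 0.7 * qperp.matrix
        assert np.isclose(project(rho, qpar), 0.3)
        assert np.isclose(project(rho, qperp), 0.7)

    def test_dimension_mismatch(self, pair, triple):
        with pytest.raises(ValueError, match="mismatch"):
            project(build_operator(pair, "Ix"), build_operator(triple, "Ix"))


class TestSpinSystemValidation:
    def test_spin_count_bounds(self):
        with pytest.raises(ValueError):
            SpinSystem(labels=("I",), offsets_hz=(0.0,), j_couplings_hz={},
                       coordinates_angstrom=((0, 0, 0),))

    def test_min_distance(self):
        with pytest.raises(ValueError, match="closer than"):
            SpinSystem(labels=("I", "S"), offsets_hz=(0.0, 0.0),
                       j_couplings_hz={},
                       coordinates_angstrom=((0, 0, 0), (0, 0, 0.3)))

    def test_j_key_validation(self):
        with pytest.raises(ValueError, match="unknown spin"):
            SpinSystem(labels=("I", "S"), offsets_hz=(0.0, 0.0),
                       j_couplings_hz={("I", "X"): 7.0},
                       coordinates_angstrom=((0, 0, 0), (0, 0, 1.77)))

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        system = SpinSystem(
            labels=("I", "S", "K"),
            offsets_hz=(70.0, -70.0, 300.0),
            j_couplings_hz={("I", "S"): 17.5},
            coordinates_angstrom=((0, 0, 0), (0, 0, 1.77), (2.5, 0, 1.0)),
            b0_T=22.3,
        )
        path = tmp_path / "system.yaml"
        path.write_text(yaml.safe_dump({"spin_system": system.to_dict()}))
        assert SpinSystem.from_yaml(path) == system
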