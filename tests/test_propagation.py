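"""Coherent + relaxing evolution: LLC oscillation, decays, ROE transfer."""

import numpy as np
import pytest

from llcroe.buildup_analysis import FitError
from llcroe.propagation import (
    crossover_tauc,
    evolve,
    hamiltonian,
    llc_decay_constant,
    llc_observables,
    max_transfer_vs_tauc,
    pseudo_2d_frequency,
    ref_decay_constant,
    roe_buildup,
)
from llcroe.relaxation import RelaxationModel
from llcroe.spin_core import SpinSystem, build_operator, permutation_operator

from conftest import R_IS, make_three_spin


class TestHamiltonian:
    def test_zeeman_diagonal_case(self, gly117_pair):
        """With no CW and no J the eigenvalues are the Zeeman sums of the
        offsets (in Hz, up to the global rotation-sense sign)."""
        system = SpinSystem(
            labels=("I", "S"), offsets_hz=(70.0, -70.0), j_couplings_hz={},
            coordinates_angstrom=((0, 0, 0), (0, 0, R_IS)),
        )
        h = hamiltonian(system, 0.0).matrix
        eig = np.sort(np.linalg.eigvalsh(h).real / (2 * np.pi))
        expected = np.sort([(si * 70.0 - ss * 70.0) / 2.0
                            for si in (1, -1) for ss in (1, -1)])
        assert np.allclose(eig, expected, atol=1e-9)

    def test_hermitian(self, three_spin):
        h = hamiltonian(three_spin, 4000.0, cw_phase_rad=0.7)
        assert h.is_hermitian()

    def test_permutation_commutator_vanishes_with_strong_lock(self, gly117_pair):
        """H commutes with the I<->S permutation only at equivalence or in
        the CW-dominated limit."""
        p = permutation_operator(gly117_pair, ("I", "S"))

        def comm_norm(cw):
            h = hamiltonian(gly117_pair, cw).matrix
            rel = np.linalg.norm(h @ p - p @ h) / np.linalg.norm(h)
            return rel

        assert comm_norm(0.0) > 0.1
        assert comm_norm(4000.0) < 0.05
        assert comm_norm(8000.0) < comm_norm(4000.0)
        equivalent = SpinSystem(
            labels=("I", "S"), offsets_hz=(0.0, 0.0),
            j_couplings_hz={("I", "S"): 17.5},
            coordinates_angstrom=((0, 0, 0), (0, 0, R_IS)),
        )
        h0 = hamiltonian(equivalent, 0.0).matrix
        assert np.linalg.norm(h0 @ p - p @ h0) < 1e-12

    def test_effective_field_tilt_about_one_degree(self):
        """A 4 kHz lock over +/-70 Hz offsets tilts the effective field by
        arctan(70/4000), i.e. about one degree."""
        assert np.degrees(np.arctan(70.0 / 4000.0)) < 1.1


class TestCoherentLLCEvolution:
    def test_equivalent_pair_free_evolution_exact(self, equivalent_pair):
        """At magnetic equivalence the LLC interconversion
        Qpar cos(2 pi J t) + Qperp sin(2 pi J t) is exact."""
        j = 17.5
        times = np.linspace(0.0, 10 / j, 301)
        obs = {
            "Qpar": build_operator(equivalent_pair, "Ix-Sx").matrix,
            "Qperp": build_operator(equivalent_pair, "2IzSy-2IySz").matrix,
        }
        traj = evolve(build_operator(equivalent_pair, "Ix-Sx"), equivalent_pair,
                      None, 0.0, times, observables=obs)
        assert np.allclose(traj.observables["Qpar"], np.cos(2 * np.pi * j * times),
                           atol=1e-10)
        assert np.allclose(traj.observables["Qperp"], np.sin(2 * np.pi * j * times),
                           atol=1e-10)

    def test_quarter_period_is_pure_qperp(self, gly117_pair):
        """tau = 1/(4J) converts Ix - Sx fully into 2IzSy - 2IySz."""
        j = 17.5
        obs = llc_observables(gly117_pair, 4000.0)
        traj = evolve(build_operator(gly117_pair, "Ix-Sx"), gly117_pair, None,
                      4000.0, [0.0, 1 / (4 * j)], observables=obs)
        assert abs(traj.observables["Qpar"][-1]) < 1e-3
        assert abs(traj.observables["Qperp"][-1] - 1.0) < 1e-3

    def test_half_period_inverts_qpar(self, gly117_pair):
        j = 17.5
        obs = llc_observables(gly117_pair, 4000.0)
        traj = evolve(build_operator(gly117_pair, "Ix-Sx"), gly117_pair, None,
                      4000.0, [0.0, 1 / (2 * j)], observables=obs)
        assert np.isclose(traj.observables["Qpar"][-1], -1.0, atol=2e-3)

    def test_waveform_matches_cos_sin_at_effective_frequency(self, gly117_pair):
        """Under the lock the tilted-frame projections follow the cos/sin
        interconversion at nu_LLC = J(1 - theta^2) to ~theta^2 accuracy."""
        times = np.arange(0.0, 10 / 17.5, 1e-3)
        obs = llc_observables(gly117_pair, 4000.0)
        traj = evolve(build_operator(gly117_pair, "Ix-Sx"), gly117_pair, None,
                      4000.0, times, observables=obs)
        nu = pseudo_2d_frequency(traj, "Qpar")
        assert abs(nu / 17.5 - 1.0) < 0.01
        assert np.max(np.abs(traj.observables["Qpar"]
                             - np.cos(2 * np.pi * nu * times))) < 1e-3
        assert np.max(np.abs(traj.observables["Qperp"]
                             - np.sin(2 * np.pi * nu * times))) < 1e-3

    def test_unitary_invariants(self, gly117_pair):
        """Without relaxation both Tr(rho) and Tr(rho^2) are conserved."""
        rho0 = build_operator(gly117_pair, "Ix-Sx")
        shift = rho0.matrix + 0.5 * np.eye(4)
        from llcroe.spin_core import StateOperator

        traj_times = np.linspace(0.0, 0.2, 11)
        from llcroe.propagation import liouvillian, _propagate_series
        h = hamiltonian(gly117_pair, 4000.0).matrix
        lv = liouvillian(h, None)
        rhos = _propagate_series(lv, shift, traj_times)
        purities = [np.trace(r @ r).real for r in rhos]
        traces = [np.trace(r).real for r in rhos]
        assert np.allclose(purities, purities[0], atol=1e-10)
        assert np.allclose(traces, traces[0], atol=1e-10)

    def test_oscillation_frequency_invariant_to_offset(self):
        """nu_LLC stays within 1% of J for shift differences up to 200 Hz
        under a 4 kHz lock."""
        for dnu in (0.0, 100.0, 200.0):
            system = SpinSystem(
                labels=("I", "S"), offsets_hz=(dnu / 2, -dnu / 2),
                j_couplings_hz={("I", "S"): 17.5},
                coordinates_angstrom=((0, 0, 0), (0, 0, R_IS)),
            )
            times = np.arange(0.0, 0.5, 1e-3)
            obs = llc_observables(system, 4000.0)
            traj = evolve(build_operator(system, "Ix-Sx"), system, None, 4000.0,
                          times, observables=obs)
            assert abs(pseudo_2d_frequency(traj, "Qpar") / 17.5 - 1.0) < 0.01


class TestDecayConstants:
    def test_no_relaxation_zero_rate(self, gly117_pair):
        fit = llc_decay_constant(gly117_pair, None, 4000.0)
        assert fit.rate_per_s < 1e-6
        fit = ref_decay_constant(gly117_pair, None, 4000.0)
        assert fit.rate_per_s < 1e-6

    def test_rate_ordering_protein_regime(self, gly117_pair, model_10ns):
        """T_LLC exceeds twice T_1rho for the isolated pair at 10 ns."""
        t_llc = llc_decay_constant(gly117_pair, model_10ns, 4000.0).time_constant_s
        t_ref = ref_decay_constant(gly117_pair, model_10ns, 4000.0).time_constant_s
        assert t_llc / t_ref >= 2.0

    def test_halving_tau_c_halves_rate_in_extreme_narrowing(self, gly117_pair):
        r1 = llc_decay_constant(
            gly117_pair, RelaxationModel(tau_c_s=2e-12, b0_T=22.3), 4000.0
        ).rate_per_s
        r2 = llc_decay_constant(
            gly117_pair, RelaxationModel(tau_c_s=1e-12, b0_T=22.3), 4000.0
        ).rate_per_s
        assert np.isclose(r1 / r2, 2.0, rtol=2e-2)


class TestROEBuildup:
    def test_mirror_plane_target_gives_zero_llc_transfer(self, model_10ns):
        """K equidistant from I and S sits in the glycine mirror plane: the
        permutation-antisymmetric LLC cannot transfer to it.  The null is
        exact at restored magnetic equivalence; with a 140 Hz shift
        difference under the 4 kHz lock the residual leakage is suppressed
        to below 1e-4."""
        equivalent = make_three_spin((2.5, 0.0, R_IS / 2.0), dnu_hz=0.0)
        curve = roe_buildup(equivalent, model_10ns, 4000.0, initial="LLC",
                            times=np.arange(0.0, 0.05, 2e-3))
        assert np.max(np.abs(curve.values)) < 1e-8
        shifted = make_three_spin((2.5, 0.0, R_IS / 2.0), dnu_hz=140.0)
        curve = roe_buildup(shifted, model_10ns, 4000.0, initial="LLC",
                            times=np.arange(0.0, 0.05, 2e-3))
        assert np.max(np.abs(curve.values)) < 1e-4

    def test_swap_negates_llc_preserves_ref(self, model_10ns):
        """Exchanging the I and S coordinates flips the LLC build-up sign
        (antisymmetric source) and leaves the REF build-up unchanged."""
        times = np.arange(0.0, 0.06, 2e-3)
        k = (2.29, 0.0, 2.78)
        sys_a = make_three_spin(k, dnu_hz=0.0)
        sys_b = SpinSystem(
            labels=("I", "S", "K"), offsets_hz=(0.0, 0.0, 300.0),
            j_couplings_hz={("I", "S"): 17.5},
            coordinates_angstrom=((0, 0, R_IS), (0, 0, 0), k), b0_T=22.3,
        )
        llc_a = roe_buildup(sys_a, model_10ns, 4000.0, "LLC", times).values
        llc_b = roe_buildup(sys_b, model_10ns, 4000.0, "LLC", times).values
        ref_a = roe_buildup(sys_a, model_10ns, 4000.0, "REF", times).values
        ref_b = roe_buildup(sys_b, model_10ns, 4000.0, "REF", times).values
        assert np.allclose(llc_a, -llc_b, atol=1e-8)
        assert np.allclose(ref_a, ref_b, atol=1e-8)
        # with resolved shifts the same relations hold to the lock-
        # suppression level
        sys_c = make_three_spin(k, dnu_hz=140.0)
        sys_d = SpinSystem(
            labels=("I", "S", "K"), offsets_hz=(70.0, -70.0, 300.0),
            j_couplings_hz={("I", "S"): 17.5},
            coordinates_angstrom=((0, 0, R_IS), (0, 0, 0), k), b0_T=22.3,
        )
        llc_c = roe_buildup(sys_c, model_10ns, 4000.0, "LLC", times).values
        llc_d = roe_buildup(sys_d, model_10ns, 4000.0, "LLC", times).values
        assert np.allclose(llc_c, -llc_d, atol=1e-4)

    def test_side_determines_sign(self, model_10ns):
        """Targets closer to S build up with the opposite sign to targets
        closer to I (stereospecific sign rule)."""
        times = np.arange(0.0, 0.06, 2e-3)
        closer_s = make_three_spin((2.29, 0.0, 2.78))  # r_SK=2.5 < r_IK=3.6
        closer_i = make_three_spin((2.29, 0.0, R_IS - 2.78))
        val_s = roe_buildup(closer_s, model_10ns, 4000.0, "LLC", times).values
        val_i = roe_buildup(closer_i, model_10ns, 4000.0, "LLC", times).values
        ext_s = val_s[np.argmax(np.abs(val_s))]
        ext_i = val_i[np.argmax(np.abs(val_i))]
        assert np.sign(ext_s) == -np.sign(ext_i)
        assert np.sign(ext_s) > 0  # closer to S: positive

    def test_ref_buildup_is_negative(self, three_spin, model_10ns):
        """Classical (REF) ROE build-ups are negative in the package's raw
        rotating-frame sign convention."""
        curve = roe_buildup(three_spin, model_10ns, 4000.0, "REF",
                            np.arange(0.0, 0.06, 2e-3))
        assert curve.values[np.argmax(np.abs(curve.values))] < 0

    def test_passivity(self, three_spin, model_10ns):
        """The transferred K amplitude never exceeds the initial source
        norm (projection units: source = 1 at tau = 0)."""
        curve = roe_buildup(three_spin, model_10ns, 4000.0, "LLC",
                            np.arange(0.0, 0.3, 5e-3))
        assert np.max(np.abs(curve.values)) <= 1.0

    def test_missing_target_spin(self, gly117_pair, model_10ns):
        with pytest.raises(KeyError, match="target"):
            roe_buildup(gly117_pair, model_10ns, 4000.0, "LLC")


class TestTransferSweep:
    def test_ref_wins_fast_llc_wins_slow(self, three_spin):
        """Extreme narrowing favours the classical transfer; slow tumbling
        favours the LLC route (the curves cross in between)."""
        grid, llc, ref = max_transfer_vs_tauc(
            three_spin, [0.1e-9, 30e-9], 22.3, 4000.0
        )
        assert ref[0] > llc[0]
        assert llc[1] > ref[1]

    def test_crossover_bracketing_and_tolerance(self, three_spin):
        tc = crossover_tauc(three_spin, 22.3, 4000.0, rel_tol=5e-2)
        assert 1e-9 < tc < 100e-9
        # crossing verified by the sweep on either side
        _, llc, ref = max_transfer_vs_tauc(
            three_spin, [tc / 2.0, tc * 2.0], 22.3, 4000.0
        )
        assert llc[0] < ref[0]
        assert llc[1] > ref[1]

    def test_mirror_plane_geometry_has_no_crossover(self, model_10ns):
        system = make_three_spin((2.5, 0.0, R_IS / 2.0))
        with pytest.raises(ValueError, match="no LLC/REF crossover"):
            crossover_tauc(system, 22.3, 4000.0, tau_c_bracket_s=(1e-10, 3e-8))


class TestPseudo2DFrequency:
    def test_flat_trajectory_returns_zero(self, gly117_pair):
        system = SpinSystem(
            labels=("I", "S"), offsets_hz=(0.0, 0.0), j_couplings_hz={},
            coordinates_angstrom=((0, 0, 0), (0, 0, R_IS)),
        )
        times = np.arange(0.0, 0.5, 1e-3)
        obs = {"Qpar": build_operator(system, "Ix-Sx").matrix}
        traj = evolve(build_operator(system, "Ix-Sx"), system, None, 0.0, times,
                      observables=obs)
        assert pseudo_2d_frequency(traj, "Qpar") == 0.0

    def test_too_few_periods_raises(self, equivalent_pair):
        times = np.arange(0.0, 0.08, 1e-3)  # ~1.4 periods of 17.5 Hz
        obs = {"Qpar": build_operator(equivalent_pair, "Ix-Sx").matrix}
        traj = evolve(build_operator(equivalent_pair, "Ix-Sx"), equivalent_pair,
                      None, 0.0, times, observables=obs)
        with pytest.raises(FitError, match="periods"):
            pseudo_2d_frequency(traj, "Qpar")

    def test_free_equivalent_pair_frequency(self, equivalent_pair):
        times = np.arange(0.0, 0.5, 1e-3)
        obs = {"Qpar": build_operator(equivalent_pair, "Ix-Sx").matrix}
        traj = evolve(build_operator(equivalent_pair, "Ix-Sx"), equivalent_pair,
                      None, 0.0, times, observables=obs)
        assert np.isclose(pseudo_2d_frequency(traj, "Qpar"), 17.5, rtol=1e-6)
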