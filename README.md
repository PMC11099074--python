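# llcroe

Spin-dynamics toolkit for **long-lived coherences (LLCs)** in glycine
methylene proton pairs of proteins: excitation by dual-frequency shaped
pulses, CW-sustained evolution under dipolar Redfield relaxation,
through-space **LLC-ROE** magnetisation transfer to neighbouring protons,
and the stereospecific geometry analysis that maps build-up signs onto
protein structure.

## The science

The two alpha protons of a glycine residue, **I** (H&alpha;2) and **S**
(H&alpha;3), form a J-coupled pair (J<sub>IS</sub> &asymp; 17 Hz) whose
singlet state S&#8320; = (|&alpha;&beta;&rang; &minus; |&beta;&alpha;&rang;)/&radic;2
is antisymmetric under spin permutation.  Intra-pair dipole-dipole
relaxation is permutation-symmetric, so it cannot mix S&#8320; with the
triplet manifold.  The **long-lived coherence** is the superposition of
S&#8320; with the central triplet T&#8320;; in the spin-lock frame its
Cartesian components are

    Q_par  = Ix - Sx          (excited by the antiphase dual-band pulse)
    Q_perp = 2IzSy - 2IySz

and during a strong on-resonance CW lock it evolves coherently as

    rho(tau) = Q_par cos(2 pi J_IS tau) + Q_perp sin(2 pi J_IS tau),

oscillating at &nu; = J<sub>IS</sub> while decaying with a time constant
T<sub>LLC</sub> that exceeds the spin-locked transverse lifetime
T<sub>1&rho;</sub> severalfold (the dipole-dipole-only Redfield limit in
slow tumbling is a factor 9; proteins show &ge; 2 experimentally).  Because
the LLC source is long-lived, its rotating-frame Overhauser transfer to a
nearby proton K keeps growing with the rotational correlation time
&tau;<sub>C</sub> and overtakes the classical ROE route for slowly tumbling
molecules.  And because Q_par is permutation-*antisymmetric*, the sign of
the transferred signal tells which side of the glycine mirror plane K
occupies: neighbours closer to H&alpha;2 build up with the classical
(negative) ROE sign, neighbours closer to H&alpha;3 with the opposite
(positive) sign &mdash; a stereospecific structural constraint readable
directly from a 1D experiment.

The relaxation engine is a full (non-secular in the rotating frame)
dipolar Redfield superoperator for rigid isotropic tumbling with all
pair-pair cross-correlations, using J(&omega;) = (2/5)&tau;<sub>C</sub>/(1+&omega;&sup2;&tau;<sub>C</sub>&sup2;)
and b = &minus;(&mu;&#8320;/4&pi;)&gamma;&sup2;&#8463;/r&sup3;; it reproduces
the analytic Solomon rates for an isolated pair to machine precision.
Evolution is by exact matrix exponentials of the constant Liouvillian
(2-4 spins), never by time stepping.

## Worked example

```python
from llcroe import RelaxationModel, SpinSystem
from llcroe.propagation import llc_decay_constant, ref_decay_constant, crossover_tauc
from llcroe.synthetic_data import default_three_spin_system

pair = SpinSystem(labels=("I", "S"), offsets_hz=(70.0, -70.0),
                  j_couplings_hz={("I", "S"): 17.5},
                  coordinates_angstrom=((0, 0, 0), (0, 0, 1.77)), b0_T=22.3)
model = RelaxationModel(tau_c_s=10e-9, b0_T=22.3)
t_llc = llc_decay_constant(pair, model, cw_amplitude_hz=4000.0).time_constant_s
t_ref = ref_decay_constant(pair, model, cw_amplitude_hz=4000.0).time_constant_s
print(t_llc, t_ref)                      # 0.1079 s vs 0.0120 s  -> ratio 8.99
print(crossover_tauc(default_three_spin_system(), 22.3, 4000.0))  # 1.433e-08 s
```

For an isolated glycine-like pair at &tau;<sub>C</sub> = 10 ns and 22.3 T
the locked LLC lives 107.9 ms against 12.0 ms for classical transverse
magnetisation (ratio 8.99, the near-ceiling of pure intra-pair dipolar
relaxation).  For the default three-spin geometry (K at 2.5 &Aring; from S,
3.6 &Aring; from I) the maximum LLC-ROE transfer overtakes the classical
ROE at &tau;<sub>C</sub>* &asymp; 14.3 ns &mdash; the molecular-size regime
of folded proteins.

The `examples/` directory holds one short narrative script per capability
(oscillation, lifetimes, transfer crossover, shaped-pulse excitation,
stereospecific geometry, noisy-data pipeline); each prints the numbers it
computes and a line on what they mean.  A thin CLI wires the same stages
for shell use:

```bash
llcroe synth spin-system --seed 1 --out run/
llcroe simulate decay --config run/spin_system.yaml --out run/
llcroe geometry stats --pdb ensemble.pdb --gly 117 --out run/
```

Every CLI run writes a JSON manifest with the package version, all
resolved defaults, seeds and input/output hashes.

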