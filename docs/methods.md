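# Methods

This note records the model, the conventions, and the numerical and design
choices behind `llcroe`, at the level of detail a maintainer needs to
modify it safely.

## Spin model and conventions

Systems contain 2-4 like spin-1/2 nuclei (all &sup1;H by default): the
glycine methylene pair I/S, an optional transfer target K and an optional
silent neighbour R.  The only scalar coupling active by default is
J(I,S); neighbours interact exclusively through space, as appropriate for
non-bonded protons.

Fixed conventions, used everywhere:

* Zeeman product basis |&alpha;&alpha;&rang;, |&alpha;&beta;&rang;,
  |&beta;&alpha;&rang;, |&beta;&beta;&rang; with &alpha; = m = +1/2; the
  first declared spin is the leftmost Kronecker factor.  Cartesian
  operators are half Pauli matrices.
* The rotating-frame Hamiltonian carries a global minus sign
  (H = &minus;2&pi;[&Sigma;&Delta;&nu;<sub>k</sub>I<sub>kz</sub> +
  &Sigma;J<sub>kl</sub> **I**<sub>k</sub>&middot;**I**<sub>l</sub> +
  &nu;&#8321;&Sigma;I<sub>kx</sub>]), the precession sense chosen so that
  an initial Ix &minus; Sx evolves into +(2IzSy &minus; 2IySz) after a
  quarter J period.  The opposite sense only negates the sine component;
  no observable magnitude depends on it.
* The LLC operator is Q = Q<sub>&#8741;</sub> + iQ<sub>&#8869;</sub> with
  Q<sub>&#8741;</sub> = Ix &minus; Sx and Q<sub>&#8869;</sub> = 2IzSy &minus; 2IySz
  in the spin-lock (x-quantized) frame; the z-frame variant (real part
  Iz &minus; Sz) is related by the global 90&deg; y rotation and is
  available for completeness.  The sign of Q<sub>&#8869;</sub> relative to
  the rotation sense is a convention; we fix it as above.

### Tilted detection frame

With offsets &plusmn;&Delta;&nu;/2 under a CW lock of amplitude
&nu;&#8321;, each spin's effective field is tilted by
&theta; = arctan(&Delta;&nu;/2&nu;&#8321;) (&asymp;1&deg; at the working
point of 140 Hz / 4 kHz).  LLC observables are defined along these
per-spin effective-field axes.  This matters numerically: an
instantaneously prepared Ix &minus; Sx overlaps fast
&omega;&#8321;-rotating modes with amplitude O(&Delta;&nu;/2&nu;&#8321;)
&asymp; 0.018, which would contaminate plain-frame projections; the fast
modes are orthogonal to the tilted observables, leaving only O(&theta;&sup2;)
&asymp; 3&times;10&#8315;&#8308; deviations.  The sustained oscillation
frequency is &nu;<sub>LLC</sub> = J(1 &minus; &theta;&sup2;), i.e. within
0.03% of J at the working point; trajectory checks against the
cos/sin interconversion are therefore made at the fitted
&nu;<sub>LLC</sub>, with the frequency itself separately required to sit
within 1% of J.

## Relaxation engine

Dipole-dipole relaxation under rigid isotropic tumbling, and nothing else:
CSA, anisotropic or internal motion, chemical exchange and thermal
corrections are out of scope (decays relax toward zero; only decay
constants and amplitudes relative to the initial state are analysed).

The superoperator is the double-commutator Redfield form over all spin
pairs p, p&prime; with unit-norm rank-2 tensors T<sub>2q</sub>:

&Gamma;(&rho;) = &minus;(3/4) &Sigma;<sub>p,p&prime;</sub>
b<sub>p</sub>b<sub>p&prime;</sub> P&#8322;(cos&theta;<sub>pp&prime;</sub>)
&Sigma;<sub>q</sub> J(q&omega;&#8320;)
[T<sub>2q</sub><sup>(p)</sup>, [T<sub>2q</sub><sup>(p&prime;)&dagger;</sup>, &rho;]]

with J(&omega;) = (2/5)&tau;<sub>C</sub>/(1+&omega;&sup2;&tau;<sub>C</sub>&sup2;),
b = &minus;(&mu;&#8320;/4&pi;)&gamma;&sub1;&gamma;&sub2;&#8463;/r&sup3;, and
P&#8322; of the inter-vector angle weighting the pair-pair
cross-correlations.  The overall 3/4 is pinned by requiring the isolated
like-pair Solomon rates

* R&#8321; = (3/4) b&sup2; [J(&omega;&#8320;) + 4J(2&omega;&#8320;)]
* R&#8322; = (3/8) b&sup2; [3J(0) + 5J(&omega;&#8320;) + 2J(2&omega;&#8320;)]

which the engine reproduces to machine precision across
&tau;<sub>C</sub> &isin; [0.01, 100] ns; this nails the spectral-density
convention so it cannot drift silently.  Because all spins are protons,
every lab-frame eigenfrequency difference of a q-quantum term equals
q&omega;&#8320; to &sim;10&#8315;&#8311; relative, so spectral densities
are evaluated at 0, &omega;&#8320;, 2&omega;&#8320; only.  No secular
truncation is applied with respect to the rotating-frame Hamiltonian
(offsets, J, CW): the coherent part is exact in the Liouvillian, which
automatically performs the toggling-frame averaging appropriate when
&omega;&#8321; far exceeds all relaxation rates while
&omega;&#8321;&tau;<sub>C</sub> &Lt; 1.

Two structural consequences, both unit-tested: the singlet population of
an isolated pair is immune to intra-pair dipolar relaxation, and the
spin-locked LLC decays at R&#8322;/9 in the slow-tumbling dipole-only
limit (the q = 0 double commutator has eigenvalue 1/6 on the
{Q<sub>&#8741;</sub>, Q<sub>&#8869;</sub>} subspace versus 3/2 for
Ix + Sx).  The simulated T<sub>LLC</sub>/T<sub>1&rho;</sub> for the
isolated pair at 10 ns / 22.3 T is 8.99, approaching that ceiling of 9;
measured protein values are smaller (&ge; 2) because external protons and
local anisotropic motions contribute.

## Propagation and read-out

Evolution integrates d&rho;/dt = &minus;i[H,&rho;] + &Gamma;&rho; by matrix
exponentials of the constant Liouvillian (dimension &le; 256&sup2;), one
cached exponential per distinct grid step.  Reported signals are
normalised overlaps Tr[&rho;O]/Tr[O&sup2;], so the source observable
starts at 1.

* **T<sub>LLC</sub>**: the LLC envelope is the quadrature magnitude
  &radic;(&lang;Q<sub>&#8741;</sub>&rang;&sup2; + &lang;Q<sub>&#8869;</sub>&rang;&sup2;)
  of the tilted-frame projections sampled at multiples of 1/J (where the
  coherent cosine passes through 1), fitted mono-exponentially.  Sampling
  the bare Q<sub>&#8741;</sub> projection would alias the 0.03%
  &nu;<sub>LLC</sub>-vs-J mismatch into a spurious &sim;10&#8315;&sup3;/s
  rate.  **T<sub>1&rho;</sub>**: decay of the tilted Ix + Sx on a grid
  scaled to its own rate.
* **Build-ups**: &lang;Kx&rang; versus mixing time, raw rotating-frame
  sign.  Under this convention classical (REF) ROE build-ups are
  *negative*, and the LLC-ROE sign encodes the mirror-plane side:
  closer to H&alpha;2 (I) &rarr; negative (same as REF), closer to
  H&alpha;3 (S) &rarr; positive.  The default simulation grid is
  0-500 ms in 1 ms steps (resolving the 17.5 Hz oscillation); the
  synthetic-experiment generator defaults to the pseudo-2D acquisition
  grid of 64 increments of 1 ms.
* **Maximum transfer**: max over &tau;<sub>mix</sub> &isin; (0, 5T<sub>1&rho;</sub>]
  of |&lang;Kx&rang;| with the initial state normalised to unit Frobenius
  norm (a "source-projection" normalisation is also available; the
  LLC/REF ratio and hence the crossover are identical under both).
* **Crossover &tau;<sub>C</sub>***: bisection on log &tau;<sub>C</sub> of
  the difference of the two maxima, relative tolerance 10&#8315;&sup2;,
  ties resolved to the lower &tau;<sub>C</sub>.
* **Oscillation frequency**: damped-cosine least squares seeded from the
  discrete spectrum; a bare FFT of a 64-point grid cannot resolve
  17.5 Hz to 1%.

With the default geometry (r<sub>IS</sub> = 1.77 &Aring;, K in the IS
plane at 2.5 &Aring; from S and 3.6 &Aring; from I &mdash; both defaults
documented and overridable) the crossover falls at 14.3 ns at 22.3 T.
The mechanism: the LLC source oscillates at J, so its transfer integrates
&int;cos(2&pi;Jt)e<sup>&minus;R<sub>LLC</sub>t</sup>dt and is bounded by
&sim;&sigma;<sub>diff</sub>/2&pi;J, while the classical transfer is bounded
by &sigma;<sub>sum</sub>T<sub>1&rho;</sub>; the curves cross where
T<sub>1&rho;</sub>(&tau;<sub>C</sub>) falls to the J-limited window.  At
these &tau;<sub>C</sub> the field enters only through
J(&omega;&#8320;)/J(0) &sim; 10&#8315;&#8308;, so within this model class
the crossover is insensitive to B&#8320; to &sim;0.1%; a genuine field
dependence requires mechanisms (&omega;&#8320;&tau;<sub>C</sub> &sim; 1
spectral-density weight, shift-difference scaling, anisotropic local
motion) outside the rigid-isotropic dipolar model.

### Symmetry nulls

The zero-transfer null for a mirror-plane neighbour, and the exact
negation of the LLC build-up under I&harr;S coordinate exchange, are
consequences of the I/S permutation symmetry of the full Liouvillian.
They are exact (&le;10&#8315;&#8313; in practice) when the shift
difference is zero &mdash; the situation the CW lock is designed to
emulate.  At &Delta;&nu; = 140 Hz under a 4 kHz lock the residual
symmetry breaking leaks &sim;2&times;10&#8315;&#8309; of in-plane
transfer; tests assert the exact nulls at restored equivalence and the
suppression below 10&#8315;&#8308; at the working offsets.

## Dual-frequency excitation

The band-selective 90&deg; envelope is E-BURP2, realised from its
published Fourier coefficient table (Geen & Freeman, *J. Magn. Reson.* 93,
93-141, 1991), stored as data.  By default the amplitude is calibrated so
one band delivers an exact on-resonance 90&deg; rotation; at 50 ms
duration this lands at 81.9 Hz peak amplitude, matching the nominal
80 Hz setting, with an excitation window of roughly &plusmn;30 Hz per
band.  The dual-frequency waveform is the sum of two frequency-shifted
copies of the envelope, the second carrying the inter-band phase offset.
State selection propagates the two-spin thermal state through the
piecewise-constant waveform (offsets and J active, &le;100 &mu;s steps),
scans the inter-band phase to maximise the projection onto Ix &minus; Sx
(LLC) or Ix + Sx (REF), and applies a receiver phase (global z rotation)
to place the result along x; the selected phases are reported, since the
experimental description of the method leaves them free.  The antiphase setting yields
perfect symmetric/antisymmetric selectivity for symmetric offsets; the
J evolution during the 50 ms pulse caps the transferred amplitude near
0.55 of the thermal polarisation, as it does in the real experiment.
Relaxation during the pulse is neglected by default (excitation and
mixing are treated separately).

## Stereospecific geometry

For each neighbour proton K of a glycine: distance = |K &minus; mid(I,S)|,
&phi; = angle between the median (unit vector from C&alpha; through the
midpoint) and the midpoint&rarr;K vector, folded to [0&deg;, 180&deg;];
the side of the mirror plane comes from the sign of
(K &minus; mid)&middot;(S &minus; I) with a 0.05 &Aring; in-plane band for
numerical robustness (both the folded and the signed &phi; are stored).
Predicted signs follow the simulator's convention above, with
H&alpha;2 &harr; I and H&alpha;3 &harr; S; the prochiral naming of the
input file (HA2/HA3 or 1HA/2HA) is normalised and the binding logged,
because depositions vary.  Ensembles aggregate with a circular mean/std
for &phi; and arithmetic ones for the distance; neighbours whose models
straddle the plane are flagged sign-ambiguous.  X-ray files without
glycine protons raise an error listing the residues; an ideal-methylene
builder (1.09 &Aring; C-H, 107&deg; H-C-H) exists but is explicitly
opt-in modelling.  The sign consistency between geometry and simulation
is verified over 200 random off-plane placements
(|r<sub>IK</sub> &minus; r<sub>SK</sub>| > 0.2 &Aring;) with 100%
agreement required.

## Curve fitting

Decays are fitted as A e<sup>&minus;Rt</sup>; constant input raises
(infinite time constants are not resolvable), as do genuinely growing
signals, while |R|&middot;span < 10&#8315;&#8310; is clamped to zero.
Build-ups use A(1 &minus; e<sup>&minus;t/&tau;&#8337;</sup>)e<sup>&minus;t/&tau;&#8338;</sup>
(a package choice; the source oscillation is quenched at the transfer
site for macromolecular tumbling, and an oscillation-modulated variant is
available by flag).  Fits are multi-started from both smoothed extrema so
a noise spike cannot select a degenerate local minimum.  The sign call is
conservative: the fitted extremum must exceed three times its standard
error (full-covariance delta method) or the sign is reported as 0 and
flagged &mdash; the sign is the structural deliverable.  Transfer ratios
|max LLC|/|max REF| are defined only within a matched pair sharing the
source normalisation; a noise-level REF extremum flags the ratio
undefined.

## Synthetic data

Generators are pure functions of (parameters, seed) and carry their
ground truth.  The glycine-like preset draws &Delta;&nu; uniformly from
[50, 250] Hz (the spread of resolved glycine pairs at 950 MHz),
J<sub>IS</sub> from [16.5, 18] Hz, fixes r<sub>IS</sub> = 1.77 &Aring;
(standard methylene geometry, H-C-H &asymp; 107&deg;; the source material
does not print its H-H distance, so this documented standard value is the
default and is overridable), and places neighbours 2.2-4.0 &Aring; from
the pair midpoint, off the mirror plane.  Noisy build-ups are simulator
truth plus i.i.d. Gaussian noise with &sigma; quoted relative to the
source signal at &tau; = 0 (no noise model is given for the real data;
additive Gaussian is the neutral choice).  Toy structures are valid
multi-model PDB files with one glycine and neighbours at controlled
(&phi;, d, side), plus seeded per-model jitter emulating an NMR-style
ensemble; they emulate none of the rest of a protein (no chemistry, no
packing), so passing geometry tests demonstrates the mapping and
aggregation logic, not performance on real depositions.

## Problem sizes and determinism

All simulations are exact small-matrix computations: 2-4 spins (Liouville
dimension &le; 256), transfer sweeps over &sim;10 correlation times,
crossover bisection to 1% with &sim;30 sweep evaluations, 200-geometry
sign checks, and 500-repeat noise suites; the full test battery and the
reproduction script each run in minutes on one core.  Every stochastic
element takes an explicit seed; the headline quantities (lifetime ratio,
crossover) are deterministic.

## Known limitations

* Rigid isotropic tumbling with pure dipolar relaxation: no CSA,
  cross-correlated CSA-DD, internal or anisotropic motion, exchange, or
  thermalisation.  Quantities that depend on those mechanisms (e.g. any
  B&#8320; dependence of the transfer crossover at
  &omega;&#8320;&tau;<sub>C</sub> &Gt; 1, or protein-measured lifetime
  ratios) will deviate from this model by construction.
* At most four spins: spin diffusion through the proton bath is absent,
  so simulated transfer amplitudes upper-bound what a crowded protein
  shows.
* The crossover correlation time depends on J<sub>IS</sub> (roughly as
  1/J) and on the chosen K geometry; the documented default yields
  14.3 ns at 22.3 T.
* Shaped-pulse simulation is piecewise-constant and ignores relaxation
  during the pulse by default, and RF inhomogeneity is not modelled.
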