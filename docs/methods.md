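# Methods

This note documents the model assumptions, default parameters, numerical
choices and known limitations of the package. Quantities quoted as code
output are computed by the test suite or `scripts/acceptance.py`.

## Solvent model

Bulk water enters through its relative mass density
d_w(T) = exp[−α_w(T−T_o) − ½β_w(T−T_o)²] about T_o = 298.15 K. α_w
(2.5×10⁻⁴ K⁻¹) is the thermal expansivity at T_o and β_w (9.8×10⁻⁶ K⁻²)
its first temperature derivative; refitting the two parameters to Kell's
1-atm density formula over 5–45 °C reproduces these defaults and stays
within 2×10⁻⁴ of Kell everywhere in that window. The X-ray scattering
length density ρ₀(T) = r_e n_e,w ρ_m,w° N_A d_w(T)/M_w is 9.39×10⁻⁶ Å⁻²
at 25 °C. The dielectric constant uses the Malmberg–Maryott polynomial
(87.740 − 0.40008 t + 9.398×10⁻⁴ t² − 1.410×10⁻⁶ t³, t in °C), a
documented, replaceable choice.

Electrolyte screening uses the standard ionic-strength definition
I = I_S + ½ Σ z²C over microions: the monovalent counterions released by
the nanostars (C′ = |Z| c d_w/M_DNA by electroneutrality) contribute C′/2,
and the macroions themselves are excluded. This convention is forced by
the physics it must reproduce: with it, the screened-Coulomb
contact u_C(2R) is ≈300 kJ/mol at both sample conditions, the pair
potential minima are a few to ~10 kJ/mol deep, and the dense-sample RPA
state is stable; counting counterions at full weight would make the dense
sample unphysically attractive (RPA-unstable).

M_DNA defaults to 64 700 g/mol, the sodium-salt mass of the assembled
four-strand construct; `molecular_weight()` computes free-acid or Na-salt
masses from any sequence set.

## Coarse-grained ensembles

The default sequences are a synthetic four-strand design with the layout
20 (section A) + 1 junction base + 20 (section B = reverse complement of
the next strand's A) + 2 spacers + CGATCG, i.e. 4 × 49 = 196 residues.
`build_topology` validates length, alphabet, the palindromic overhang and
the section-pairing bijection for any user design.

The builder emulates an equilibrated coarse-grained trajectory
geometrically, not energetically:

* arms are rigid ideal duplexes (rise 3.4 Å/bp, twist 36°/bp) starting
  12 Å from the centre, their directions drawn about tetrahedral axes
  with angular spread 0.25 rad (the junction-flexibility knob);
* united-atom sites sit at the coarse-grained interaction-site radii —
  backbone 6.3 Å and base 1.8 Å from the duplex axis, the same convention
  the oxDNA reader produces (±0.4 length units about the nucleotide
  centre of mass). The 10 Å figure usually quoted for B-DNA is the duplex
  *envelope*; placing point scatterers at the atomistic phosphate radius
  (8.9 Å) instead would shift the ensemble Kratky peak from ≈0.20 down to
  ≈0.145 Å⁻¹ and is not what a coarse-grained trajectory provides;
* the two spacer bases and the 6-base overhang continue past each arm tip
  as a freely jointed 6 Å/step walk (single-stranded DNA has a
  sub-nanometre persistence length); self-overlapping draws are rejected
  and resampled.

Typical realizations have a uniform-site radius of gyration of 52–57 Å
and a maximum reach of ~90–120 Å from the centre, consistent with an
effective interaction radius of 42–53 Å and a fully extended arm length
of about 90 Å. Because the builder is deterministic given a seed, every
ensemble is exactly reproducible.

What the builder does not emulate: sequence-dependent elasticity, duplex
breathing, junction stacking, inter-arm hybridization, and any
temperature dependence of the conformations. Passing tests therefore
validate the scattering machinery on realistic mass distributions, not
the conformational statistics of real nanostars.

## Form factor (united atoms + hydration shell)

Atomic amplitudes use the International Tables 4-Gaussian parameterization
(pluggable table, verified against an independent crystallographic
library in the tests); displaced solvent uses the spherical-Gaussian
g_a(q) = ν_a exp(−q²ν_a^{2/3}/4π) with the Fraser–MacRae–Suzuki van der
Waals volumes (H 5.15, C 16.44, N 2.49, O 9.13, P 5.73 Å³). Group excess
lengths b_j(q) are Debye sums over idealized residue geometries shipped
as a small PDB fixture (curated in-chain compositions: backbone C₅H₈O₅P,
adenin-9-yl C₅H₄N₅, guanin-9-yl C₅H₄N₅O, cytosin-1-yl C₄H₄N₃O,
thymin-1-yl C₅H₅N₂O₂). b_j is a non-negative scalar (square root of an
orientational average): the group's internal phase is deliberately
discarded, which is part of the united-atom approximation itself.

The hydration shell packs dummy waters (ν_w = 29.9 ų, hard core 2.8 Å)
at contact with the group spheres on deterministic Fibonacci lattices
with greedy exclusion; a 196-nucleotide star acquires ≈1800–2600 shell
waters, and the count moves by <5% when the acceptance order is
randomized. A shell water carries the excess length (d_h − 1) ρ₀ g_w(q),
so the shell vanishes identically at d_h = 1.

Orientational averages are computed by expanding both amplitudes in
complex spherical harmonics about the excess-scattering-length-weighted
centroid (weights at q = 0, shell excluded, so the origin does not move
with d_h). Truncation order Lmax defaults to 30 and should be raised to
⌈q_max R_max⌉ (≈36 for hydrated stars on q ≤ 0.3 Å⁻¹); a warning is
emitted below that bound. Against the brute-force Debye double sum the
multipole path agrees to ~10⁻⁵ relative at the recommended order. The
shell enters linearly in (d_h − 1), so P(q; d_h) is cached exactly as a
quadratic A + (d_h−1)B + (d_h−1)²C and d_h can be scanned or fitted
without re-expansion.

β(q) squares the ensemble-mean amplitude (β = |⟨F⟩|²/⟨|F|²⟩ with both
averages over orientations *and* configurations); the alternative —
averaging per-configuration β — would not vanish for a conformationally
heterogeneous ensemble and is not used. For the default ensemble β falls
below 0.05 by q ≈ 0.12–0.13 Å⁻¹, so only the first structure-factor peak
survives in S_M.

## Structure factor (HSDY, PY + RPA)

The repulsive amplitude is standard DLVO,
B_C = Z²λ_B/(1+κR)² (k_BT·Å), with λ_B the Bjerrum length and κ from the
total ionic strength; the attraction has B_A = −2RJ and κ_A = 1/d so that
u_A(2R) = −J exactly. The Yukawa-tail transform restricted to r > 2R has
the closed form ũ(q) = (4πB/q)·Im[e^{2iqR}/(κ−iq)] (q→0 limit
4πB(1+2κR)/κ²), verified against adaptive quadrature to 10⁻⁸ (scaled).
The Percus–Yevick kernel is Wertheim's analytic solution; below x = 2qR =
0.1 the trigonometric limbs switch to series to avoid cancellation, and
the closed form matches numerical Fourier inversion of the PY direct
correlation function to 10⁻¹⁰.

The PY volume fraction defaults to the self-consistent effective-R
convention φ = n(4/3)πR³ (≈0.093 for the dense sample at R = 51 Å); a
dry-volume convention (partial specific volume 0.55 cm³/g, φ ≈ 0.01 at
18 g/L — the "<0.02" figure usually quoted) is selectable. PY validity is
enforced as φ < 0.25.

RPA divides S₀ by 1 + nS₀ũ/k_BT and **raises** (naming the offending q)
when the denominator is non-positive: with two sharp-cutoff Yukawa tails
of ~300 kJ/mol contact scale, stability requires the integrated repulsion
and attraction to nearly cancel — which is exactly where the physical
system sits. Temperature enters via ε(T), d_w(T) (through n, κ and C′)
and the explicit k_BT; J and d carry no intrinsic T-dependence within one
evaluation.

## Synthetic batches and the global fit

`synthesize_batch` emulates the experimental protocol: a 5–45 °C ramp
(5 °C steps outside 20–30 °C, 2 °C inside; 12 curves per direction),
q = 0.014–0.3 Å⁻¹, absolute intensities, heteroscedastic noise
σ(q) = noise_level·I(q)·(1 + q/q_max) with noise_level = 0.02 by default.
The generating trajectories are sigmoids centred at 25 °C (the overhang
melting region): R grows 41→43.5 Å (1 g/L batch) or 49→53 Å (18 g/L),
while J falls 280→276 kJ/mol and d 14.5→13.5 Å. d_h° is 1.001 (dilute)
or 1.0505 (dense) with α_h = 0.

The merit function is χ̄² + αL with L the sum of squared *relative*
neighbour differences of the per-curve parameters, normalized by each
parameter's batch mean — a scale-free form chosen because R, J and d have
incommensurate units, letting one scalar α weight all three. When α is
not supplied it is set by the ≈10%-rule at the good-fit scale: against a
roughness prior of one 1% step per parameter per neighbour pair,
α = 0.1/[3(N_m−1)·10⁻⁴], i.e. α ≈ 30 for a 12-curve batch, which keeps
αL at a few percent of the merit for physical trajectories. Over- or
under-riding α is a one-argument change; fits report χ̄², L and α
separately so the decomposition is always auditable.

Optimization is two-stage bounded trust-region least squares
(`scipy.optimize.least_squares`): first a collapsed 5-parameter fit
(d_h°, α_h and one shared (R, J, d)) from multiple deterministic starts,
then the full per-curve fit from the collapsed optimum. The initial
(R, J, d) is physics-based and computable from the sample conditions
alone: J₀ equals the contact repulsion u_C(2R₀) (the charge-balance
point, near which the RPA is stable) and d₀ the Debye length. Curve sets
that wander into RPA-unstable territory contribute large flat residuals,
steering the optimizer back. Uncertainties are 1σ Gauss–Newton estimates
at the optimum; they capture local curvature only, not the valley
structure discussed next.

### Identifiability at the default noise level

Noise-free batches are recovered exactly (parameters to <10⁻⁴ relative,
merit → 0). At 2% noise the model has a genuinely sloppy direction —
simultaneous changes of J (up), R (down) and d (down) leave I(q) almost
unchanged. A linearized Cramér–Rao analysis at the generating parameters
(all curves pooled) bounds the attainable precision at roughly
R 0.3%, J 0.8%, d 0.2% for the dense batch, but R 4%, J 11%, d 2% for
the dilute batch, whose structure-factor signal is ~30× weaker. Dense
recoveries typically land within ~1% (R, d) and 1–3% (J, with a small
positive bias because the truth sits near the RPA stability wall, which
rectifies noise); dilute J recoveries scatter by ~10–16% however good the
optimizer, so dilute attraction parameters at this noise level should be
read as order-of-magnitude. Real measurements averaging many exposures
have several-fold smaller errors, which is what makes the dilute fit
informative in practice.

## Numerical conventions

q = 4π sin θ/λ in Å⁻¹ everywhere (nm⁻¹ input converted on read); lengths
in Å; intensities absolute (cm⁻¹); energies k_BT internally, kJ/mol at
interfaces; all constants in `constants.py`, exportable as JSON for
audit. Outputs embed seeds, never timestamps, so identical invocations
are byte-identical.

## Known limitations

* The builder's conformational statistics are geometric; temperature does
  not change the ensemble (only d_h(T) and the structure factor carry T).
* The isotropic HSDY potential is a radial average of an intrinsically
  anisotropic, bond-mediated attraction; with β(q) damping, other S(q)
  models could fit equally well.
* RPA with sharp-cutoff Yukawa tails oscillates in ũ(q) and has a narrow
  stability corridor at gel-path densities; states beyond it raise rather
  than extrapolate.
* No instrument resolution smearing, no arbitrary-scale fitting by
  default, single-concentration fits only (no sharing of (J, d) across
  batches).
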