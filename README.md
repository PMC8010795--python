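# nanostar-saxs

Modelling of small-angle X-ray scattering (SAXS) from solutions of
tetravalent DNA nanostars — four-armed constructs self-assembled from four
49-base strands whose palindromic CGATCG overhangs provide temperature-
controlled tip-to-tip bonding. The package is written for scattering
practitioners who want to go from coarse-grained nanostar configurations
and measured (or simulated) SAXS curves to effective interaction
parameters across the gas-like and gel states.

The macroscopic differential scattering cross section is assembled as

    I(q) = n(T) · P(q; d_h) · S_M(q)        [cm⁻¹]

with three model layers:

* **Form factor P(q)** — each nucleotide is represented by two united
  atoms (backbone = phosphate + deoxyribose, and base), with q-dependent
  excess scattering lengths b_j(q) computed from idealized atomic
  geometries by the Debye formula, δb_a(q) = f_a(q) r_e − ρ₀ g_a(q). A
  first hydration shell of dummy waters with relative density d_h is
  packed at contact with the united atoms. Amplitudes are expanded in
  spherical harmonics about the scattering-weighted centroid, giving the
  exact orientational averages ⟨F⟩(q) and P(q) = ⟨|F|²⟩(q) for an ensemble
  of configurations, and the coupling function β(q) = |⟨F⟩|²/P(q) of the
  decoupling approximation.
* **Structure factor S(q)** — hard spheres of effective radius R with two
  Yukawa tails u_j(r) = B_j e^{−κ_j(r−2R)}/r: a DLVO screened-Coulomb
  repulsion (charge Z = 196, Debye screening from the total ionic
  strength) and an attraction of depth J at contact and range d. S(q) is
  the random-phase-approximation perturbation of the analytic
  Percus–Yevick solution; the measured structure factor is
  S_M(q) = 1 + β(q)[S(q) − 1].
* **Global fit** — a temperature batch of curves is fitted jointly with
  common parameters (d_h°, α_h: the hydration density and its thermal
  expansivity) and per-curve parameters (R, J, d), minimizing
  χ̄² + αL where L penalizes parameter jumps between neighbouring
  temperatures.

Ensembles come from a geometric builder (rigid B-form arms, flexible
junction, random-walk overhangs — a synthetic stand-in for a
molecular-dynamics trajectory) or from oxDNA configuration/topology files.

## Worked example

```python
import numpy as np
import nanostar_saxs as ns

# 29 synthetic configurations of the four-strand 196-residue design
ens = ns.build_ensemble(n_configurations=29, seed=1)

# hydrated ensemble form factor on the experimental q-window
solvent = ns.solvent_state(298.15)
q = np.linspace(0.014, 0.3, 72)
ff = ns.ensemble_form_factor(ens, solvent, q, d_h=1.05, Lmax=36)
print("Kratky peak at q = %.3f 1/A" % q[np.argmax(q**2 * ff.P)])
print("beta(0.10) = %.3f" % ff.beta[np.argmin(abs(q - 0.10))])

# structure factor of the dense sample (18 g/L, 22 mM added salt, 25 °C)
params = ns.HSDYParams.from_conditions(
    R=51.0, J=278.0, d=14.0, concentration=18.0, I_S=0.022, T=298.15)
sf = ns.rpa_structure_factor(params, np.linspace(0.002, 0.3, 1500))
print("S(q) first peak at q* = %.4f 1/A, S(q*) = %.2f" % sf.first_peak)
```

prints

```
Kratky peak at q = 0.203 1/A
beta(0.10) = 0.127
S(q) first peak at q* = 0.0441 1/A, S(q*) = 1.55
```

i.e. the Kratky plot of the hydrated star peaks near 0.2 Å⁻¹ (a compact
particle with ~30 Å internal correlations), the coupling function has
essentially decayed by q ≈ 0.1 Å⁻¹ (so only the first S(q) peak survives
in S_M), and the dense-sample structure factor peaks near 0.05 Å⁻¹,
corresponding to a nearest-neighbour spacing of roughly 140 Å.

A complete simulate-and-refit round trip:

```sh
nanostar-saxs simulate-batch --conc 18 --salt 0.022 --dh0 1.0505 \
    --noise 0.02 --seed 1 --outdir scratch/batch
nanostar-saxs fit --manifest scratch/batch/manifest.yaml --seed 1 \
    --report scratch/report.json
```

The JSON report contains the recovered d_h°, the per-curve (R, J, d)
trajectories with 1σ estimates, and the merit decomposition
(χ̄², L, α).

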