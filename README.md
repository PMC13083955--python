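# stigroove

Coarse-grained conformational ensembles of multidomain proteins with
intrinsically disordered regions (IDRs), and the analyses that connect those
ensembles to solution experiments.

Ubiquitin-binding shuttle proteins such as yeast Dsk2 combine folded domains
(UBL, STI1, UBA) with long disordered linkers that harbour transient
amphipathic helices. Whether and how often those helices visit the
hydrophobic groove of the STI1 domain is not directly observable; it can be
quantified from single-chain simulations, provided the apparent occupancy is
corrected for what chain connectivity and sterics alone would produce. This
package implements that workflow end to end for anyone studying
tethered-domain interactions in multidomain/IDR proteins:

* a **residue-bead model**: one bead per residue at the residue centre of
  mass, with per-residue stickiness λ, diameter σ, charge and mass (a
  bundled, overridable CSV of the CALVADOS-family hydropathy scale);
  harmonic backbone bonds; an elastic network restraining folded domains;
  Langevin dynamics (BAOAB) in the standard nm/ps/Da/kJ·mol⁻¹ unit system;
* the **groove-occupancy classifier**: per frame, a disordered residue is
  "in the groove" iff it is (1) closer to the groove centre than the
  furthest interior residue, (2) closer to an interior than to any exterior
  residue, and (3) within the interior group's envelope around its dominant
  principal axis;
* the **excluded-volume null model**: the same chain with all λ and charges
  set to zero; excess probability = occupancy / null-model occupancy, i.e.
  the fold enrichment attributable to chemical interactions;
* **ensemble metrics**: mass-weighted radius of gyration
  R_g = √(Σmᵢ|rᵢ−r_com|²/Σmᵢ) with replica statistics, the tethered-domain
  effective concentration c_eff = P(shell)/(4πd²w·N_A) from the inter-domain
  distance distribution, and the self-consistent Guinier fit
  ln I(q) = ln I₀ − q²R_g²/3 over q·R_g ≤ 1.3;
* **NMR observables** from picked peak lists: chemical-shift perturbations
  Δδ = [(ΔδH)² + (ΔδN/5)²]^½, concentration-normalised intensity ratios
  I/I₀ with explicit absent-peak states, secondary shifts Δδ(Cα−Cβ),
  mono-exponential relaxation fits I(t) = I₀e^(−Rt) with Monte-Carlo rate
  errors (500 trials), and hetNOE = I_sat/I_ref with propagated uncertainty.

Synthetic-data generators with analytically known ground truth (toy groove
geometries, planted-occupancy trajectories, ideal decays and scattering
profiles, a 60-residue two-domain test chain) make every stage testable
without downloads.

## Worked example

```python
import numpy as np
import stigroove as sg

# groove occupancy on a planted toy system
system = sg.make_toy_groove_system(n_interior=8, n_exterior=8,
                                   groove_radius=6.0, seed=1)
planted = sg.make_planted_occupancy_trajectory(system, [16],
                                               target_occupancy=0.25,
                                               n_frames=10_000, seed=7)
profile = sg.occupancy_profile([planted.frames], planted.groove,
                               planted.probe_indices)
print(f"planted 0.25 -> recovered {profile.probability[0]:.4f}")

# Guinier fit of a noisy synthetic scattering profile
q = np.linspace(0.011, 0.08, 120)
prof = sg.make_guinier_profile(rg=37.9, i0=100.0, q_grid=q,
                               noise_sd=0.4, seed=41)
fit = sg.guinier_fit(prof, qrg_max=1.3)
print(f"Guinier Rg = {fit.rg_A:.2f} +/- {fit.rg_err_A:.2f} A "
      f"over {fit.n_points} points")

# relaxation fit with Monte-Carlo errors
series = sg.make_relaxation_series(rate=2.0, amplitude=100.0,
                                   delays_s=[0.004, 0.004, 0.6, 0.6, 1.0, 1.0],
                                   noise_sd=1.0, seed=21)
fit_r = sg.fit_monoexponential(series, mc_trials=500, seed=5)
print(f"R = {fit_r.rate:.3f} +/- {fit_r.rate_sd:.3f} s^-1")
```

prints

```
planted 0.25 -> recovered 0.2500
Guinier Rg = 37.85 +/- 0.11 A over 41 points
R = 2.027 +/- 0.033 s^-1
```

The recovered occupancy matches the planted Bernoulli probability to
binomial precision; the Guinier fit recovers the generator's radius of
gyration within its own fit error over the self-consistent q·R_g ≤ 1.3
window; the relaxation rate lands within one Monte-Carlo standard deviation
of the planted 2.0 s⁻¹.

A full study (topology variants → replica simulations → occupancy, excess
enrichment, R_g, effective concentration, TSV/JSON reports) runs from one
YAML config:

```bash
stigroove run-study --config study.yaml --out results/ --seed 1000
```

with `chain: toy` usable out of the box; see
`stigroove --help` for the per-stage subcommands (`simulate`, `occupancy`,
`rg`, `ceff`, `guinier`).

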