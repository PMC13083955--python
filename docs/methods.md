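# Methods

## The coarse-grained model

Each residue is a single bead placed at the residue centre of mass. Beads
carry four parameters: a hydropathy/stickiness λ ∈ [0, 1], a van der Waals
diameter σ (nm), a charge valence at the reference pH (e), and the average
residue mass (Da). The bundled table (`data/residue_params.csv`,
`table_version 1`) carries the CALVADOS-family stickiness scale; it is data,
not code — any CSV with the same header can be substituted, and the version
string is recorded in every run manifest.

Nonbonded pairs interact through two terms:

* a hydropathy-scaled 12-6 potential (Ashbaugh–Hatch form). With
  L(r) = 4ε[(σ/r)¹² − (σ/r)⁶] the energy is L(r) + (1−λ)ε for
  r ≤ 2^{1/6}σ and λ·L(r) beyond, truncated at 2.0 nm. The two branches
  meet at −λε, so the potential is continuous for every (λ, σ, ε);
  ε defaults to 0.8368 kJ/mol. By default the potential is truncated
  without an energy shift (the tail at 2 nm is ≤ 10⁻³ kJ/mol); a `shift`
  flag switches to truncate-and-shift.
* Debye–Hückel screened electrostatics B(ε_r)·q_iq_j·e^{−κr}/r with
  B = 138.935/ε_r kJ·nm/mol/e², truncated at 4.0 nm. The relative
  permittivity follows the standard empirical temperature fit for water
  (≈ 78.4 at 298.15 K); κ comes from the ionic strength treated as a 1:1
  electrolyte (κ⁻¹ ≈ 0.65 nm at 0.22 M).

Charges: Asp/Glu −1, Lys/Arg +1, His by Henderson–Hasselbalch
1/(1+10^{pH−pK_a}) with pK_a = 6.0 (at the default pH 6.8 this gives
+0.137), and ±1 on the chain termini by default. All of pH, pK_a and the
termini flag are arguments.

Consecutive beads are bonded harmonically (r₀ = 0.38 nm,
k = 8033 kJ/mol/nm²). Folded domains are annotated as 1-based inclusive
residue spans with a restraint group; every non-bonded pair (|i−j| ≥ 2)
within one group whose reference-structure distance is below the
elastic-network cutoff (default 0.9 nm) is restrained harmonically at
k = 700 kJ/mol/nm² with the reference distance as equilibrium length.
Restrained and bonded pairs are excluded from the nonbonded sum. Reference
bead positions are the heavy-atom centres of mass of each residue in the
input structure (hydrogens excluded when absent).

Two topology variants are derived from the base model:

* **excluded-volume (EV) null model** — all λ and all charges set to zero;
  bonds and elastic restraints unchanged. This is the baseline for the
  excess-probability normalisation: it measures how often a disordered
  residue would sit in the groove from connectivity and sterics alone.
  Zeroing charges along with λ is a deliberate choice (flag
  `keep_charges=True` retains them): the null model is meant to contain no
  chemistry at all.
* **bound-complex variant** — the elastic network over a chosen set of
  restraint groups is rebuilt from a bound-pose coordinate set, so pairs
  across the domain interface that are close in the bound pose become
  restrained and the domains stay associated throughout the run. Intra-group
  restraints are preserved whenever the bound pose moves each domain
  rigidly.

A helper rescales the stickiness of buried folded-domain residues (relative
Shrake–Rupley accessibility below 0.2 → λ scaled by 0.7, both knobs
exposed): buried side chains should not contribute full hydropathy to
surface contacts. The rule is a simple threshold approximation of the
buried-residue treatment used with centre-of-mass bead models.

## Dynamics

Langevin dynamics with the BAOAB splitting; friction 0.01 ps⁻¹, timestep
10 fs, temperature 298.15 K by default. Initial velocities are
Maxwell–Boltzmann draws from the run seed; every run uses a single private
`numpy` Generator, so trajectories are bit-reproducible per (topology,
config, seed, platform). Frame k of a saved trajectory holds the
coordinates at time k·Δ (Δ = save interval), so a run of duration T yields
⌊T/Δ⌋ frames covering [0, T), and discarding an equilibration span t_eq
leaves ⌊(T−t_eq)/Δ⌋ frames. The save interval defaults to 0.5 ps — the
unique value under this convention that reconciles a 70 ns production run
and a 3.5 ns discard with 133,000 production frames. Replicas differ in
their thermal-noise seed and in a small Gaussian jitter (0.02 nm) applied
to linker beads of the starting conformation; folded domains start at their
reference geometry. Forces are evaluated over a dense O(n²) pair list,
appropriate for single chains of a few hundred beads; integration aborts
with the offending step index if coordinates or energy become non-finite.

No periodic box is used: the model targets a single dilute chain. No
enhanced sampling, no multi-chain systems.

## Groove occupancy

The groove is defined by an explicit interior/exterior labeling of the
groove-domain residues (a YAML/CSV input; ≥ 4 interior residues are
required for a defined principal axis). A helper proposes interior residues
as those whose local outward normal points back toward the domain centroid
(concave face), but its output is advisory — the explicit list is the
source of truth.

Per frame, a candidate residue is occupied iff all three hold:

1. its distance to the groove centre (arithmetic mean of interior bead
   positions, recomputed per frame) is strictly smaller than the largest
   interior-bead distance to that centre;
2. its minimum distance to an interior bead is strictly smaller than its
   minimum distance to an exterior bead;
3. its perpendicular distance to the dominant principal axis of the
   interior beads (the line through the groove centre along the top
   eigenvector of their covariance) is at most the maximum perpendicular
   distance of the interior beads themselves, scaled by the alignment
   threshold.

Design notes: the axis criterion is the package's concrete reading of
"account for the groove's curvature" — a single interpretable knob
(default 1.0 = the interior group's own envelope) recorded in the run
manifest. Ties break against occupancy in steps 1–2 (strict inequalities);
step 3 uses ≤ so that the threshold 1.0 includes the envelope boundary.
The furthest-interior radius is recomputed per frame rather than frozen
from the reference structure; with restrained domains the difference is
small, and per-frame recomputation keeps the criterion exactly
rigid-motion invariant. All criteria are distance- or axis-relative, so
classification is invariant under global rotation and translation (a
property test checks this).

Per-residue occupancy is the replica mean of (occupied frames / frames),
with the across-replica standard deviation as spread. The excess profile
divides observed by EV-baseline probabilities per residue: 0/0 is flagged
undefined (excluded from region means), x/0 with x > 0 is flagged infinite;
no pseudo-count is applied. Region enrichment is the arithmetic mean of
defined per-residue enrichments within a named 1-based span.

## Ensemble metrics

* **R_g** — mass-weighted, about the centre of mass; computed in nm and
  reported in Å (conversion only at the reporting boundary). Replica
  ensembles report per-replica means, the grand mean, and the SEM across
  replicas (0 for a single replica).
* **Effective concentration** — the distance between two tethered groups
  (centre-of-mass distance by default; minimum inter-bead distance as an
  option) is collected over frames; c_eff = f/(4πd²w) · (1 molecule/nm³ →
  1.6606 M), where f is the fraction of frames with distance in
  (d − w/2, d + w/2), d the contact distance, w the shell width
  (default 0.2 nm). Contact distance should be taken from the bound-pose
  domain separation of the system under study; both are config knobs and
  logged. An empty shell reports 0 with a warning flag. This is the
  standard shell-density estimator for tethered-ligand effective
  concentrations.
* **Guinier fit** — weighted linear fit of ln I vs q², iterated to a
  self-consistent low-q window with q·R_g ≤ 1.3 (configurable), capped at
  20 rounds with ties resolved toward the smaller window; ≥ 5 points
  required; R_g = √(−3·slope) with its error from the slope covariance.
  Profiles with non-negative slope are rejected. The three-column
  whitespace `.dat` dialect (with `#` comments and non-numeric header
  lines) is accepted.

## NMR observables

* CSP: Δδ = √(ΔδH² + (ΔδN/w)²), nitrogen weight w = 5 by default (a
  parameter). Residues missing from either list are flagged absent, never
  treated as zero.
* Intensity ratios I/I₀ divide each intensity by its sample concentration
  when normalisation is on; a missing test peak is an explicit absent
  state (the "no observable peak" class), a zero reference intensity is a
  per-residue flag.
* Secondary shifts: (Cα_obs − Cα_rc) − (Cβ_obs − Cβ_rc). The random-coil
  table is an input file — such values are generated by external, versioned
  predictors for specific pH/temperature, so the package ships no table of
  record. Glycine (no Cβ) uses the Cα term alone and is flagged.
* Relaxation: untransformed nonlinear least squares of I(t) = I₀e^{−Rt}
  (log-linearisation would distort additive noise), initial guess from the
  two-point log slope. Rate uncertainty is the SD of rates refit on 500
  replicas of the best-fit curve perturbed with Gaussian noise at the
  stored spectral noise level. Duplicate delays are retained as independent
  observations (configurable by averaging upstream); non-convergent
  residues are flagged, not fatal.
* hetNOE: I_sat/I_ref with error |v|·√((σ_s/I_s)² + (σ_r/I_r)²); exact
  first-order propagation (verified against a finite-difference oracle).

## Synthetic data

The generators produce fixtures whose ground truth is known in closed form:
hemicylindrical toy grooves (interior beads on the concave half-arc,
exterior on the convex back, small seeded jitter; an unambiguous labeling
and a well-defined principal axis), planted-occupancy trajectories (probes
at the groove centroid with Bernoulli probability p, else at 3.5× the
furthest-interior radius — guaranteed to fail test 1), exact
mono-exponential decays and Guinier profiles with optional Gaussian noise,
and random peak lists with a perturbation helper. Each call uses one
explicit-seed RNG stream; noiseless outputs are exact evaluations of the
stated closed forms.

The bundled 60-residue test chain has two folded domains: a hydrophobic
hairpin (residues 1–21) whose 1.4 nm open channel serves as the groove — a
probe bead in the channel sits near the pair-potential minimum of both
strands — and a helical partner domain (49–60), joined by Ala/Ser linkers
with one Trp/Phe sticky segment (35–40) standing in for a transient helix.
Its reference geometry is bondable (consecutive beads ≈ 0.38 nm), so bonds
and the elastic network do not fight; the hairpin needs an elastic-network
cutoff of 1.6 nm to restrain the channel width.

What the synthetic conditions do **not** emulate: real spectral artifacts
(phase errors, peak overlap), SAXS buffer subtraction and instrument
smearing, sequence-specific helicity (the bead model assigns none), or the
size and timescales of a real 373-residue multidomain protein. Passing
tests therefore demonstrate that the algorithms are implemented correctly
and recover planted truth — not that the force field reproduces any
particular protein's ensemble.

## Problem sizes

The test suite samples the toy chain with 2 replicas × 0.4 ns per variant;
the acceptance script uses 3 replicas × 1.5 ns for the interacting chain
and 3 × 2.5 ns for the EV null model (the null baseline is set by rare
steric passages and needs more sampling — the same reason full-protocol EV
runs are conventionally an order of magnitude longer). These sizes give
stable orderings and finite baselines for a 60-bead chain while keeping a
full run in minutes on one CPU; they are scaled-down study conditions, not
converged ensembles, and the reported toy quantities carry the replica SEM
accordingly. In the acceptance summary the fold-enrichment baseline is
floored at one count when the EV ensemble records no passage, making the
reported ratio a lower bound.

## Known limitations

* The integrator is plain numpy; it is comfortable for ≤ a few hundred
  beads but not tuned for the multi-microsecond, 400-residue regime.
* The elastic network uses a single force constant and cutoff per build;
  no distance-dependent stiffness.
* The EV variant's zeroed electrostatics is a modelling decision (see
  above); enable `keep_charges` to test the alternative reading.
* Guinier analysis only — no full scattering-curve prediction from
  coordinates, and no molecular-weight analysis.
* The interior/exterior helper is geometric and advisory; for real domains
  the labeling should come from structural inspection.
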