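# Methods

## Scope and model

`fretforge` models a fluorescent-protein-flanked PDI-b'a' fusion as a chain
of Cα beads and asks one question: how does the redox-dependent domain
arrangement of the b'a' fragment translate into ensemble FRET efficiency?
The two redox states are represented by two independent single-basin
structure-based models — one built from an open (oxidized-like) reference,
one from a closed (reduced-like) reference — rather than by a multi-basin
potential. This mirrors how the states are prepared experimentally (two
separately equilibrated species) and keeps each topology a pure Gō model.

### Potential

For bead coordinates x, with native values taken from the reference
structure:

    E = Σ k_b (r − r₀)²                       bonds (consecutive beads)
      + Σ k_θ (θ − θ₀)²                       angles
      + Σ S·k_φ [1 − cos(φ − φ₀)]             dihedrals (switched, see below)
      + Σ ε [5 (r₀/r)¹² − 6 (r₀/r)¹⁰]         native contacts
      + Σ ε_ev [(σ/r)¹² − (σ/r_c)¹²]          excluded volume, r < r_c

Native contacts join residue pairs with |i − j| ≥ 4 whose minimum
heavy-atom distance is below 4.5 Å (all-atom references) or whose Cα–Cα
distance is below 6.5 Å (Cα-only references, including all synthetic
structures); the contact r₀ is always the native Cα–Cα distance. Linker
residues and residues placed by the assembler (missing-residue completion)
carry bonded terms only — they have no native reference geometry. Contacts
spanning the b'/a' boundary are flagged interdomain and their ε is
multiplied by `interdomain_scale`; the oxidized model defaults to 0 (the
open-form crystal contacts are lattice artifacts, so the domains should
rearrange freely) and the reduced model to 1. Scaled-to-zero contacts stay
excluded from the excluded-volume sum, so `interdomain_scale = 0` removes
them from the energy exactly.

Excluded volume applies to every non-bonded, non-contact pair with
|i − j| ≥ 2, truncated at r_c = 2.5 σ and shifted to zero there so the
energy is continuous; a Verlet neighbor list with a 1.5× cutoff skin,
rebuilt every 20 steps, accelerates it.

### Units

Lengths are Å. Energies are reduced units with k_B·300 K ≡ 1 (one unit is
therefore ≈ 0.596 kcal/mol; the conversion is documented, not enforced).
Bead mass is uniform (1), and time is the reduced unit implied by these
choices. Temperatures are specified in kelvin and converted internally via
k_B = 1/300 per K.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| k_b | 100 Å⁻² | stiff backbone; bond sd ≈ 0.07 Å at 300 K |
| k_θ | 20 rad⁻² | standard Cα-model bending stiffness |
| k_φ | 1 | soft torsions; contacts dominate folding |
| ε (contact) | 1.0 | calibrated for native stability, see below |
| ε_ev, σ | 0.2, 4.0 Å | standard CG excluded-volume scale |
| timestep | 0.01 | dt·ω ≈ 0.2 for the stiffest (bond) mode |
| friction γ | 0.25 | underdamped, CafeMol-like sampling regime |
| snapshot interval | 10³ steps | ~10³–10⁴ analysis frames per run |
| equilibration fraction | 0.1 | discards the relaxation transient |
| R₀ | 53 Å | CFP/YFP Förster distance, random orientation |
| efficiency threshold | 0.5 | the headline ensemble statistic |

The uniform contact energy replaces a heterogeneous, database-tuned
parameterization; a surrogate this simple has one scale to set, and ε is
calibrated against the requirement that a contact-dense reference domain
stay native: at ε = 0.3–0.6 the lattice stand-ins melt (FP RMSD ≈ 10 Å
over 10⁵ steps), while ε = 1.0 (≈ 1 k_BT per contact, in the range used
throughout the Gō-model literature) holds them at RMSD ≈ 0.7 Å mean /
1.5 Å max. ε remains configurable per call.

### Numerical regularizations

Cα chains can pass through locally collinear geometries where the exact
gradients of angle and torsion terms diverge. Two standard regularizations
keep the dynamics stable:

* the angle force coefficient 2k_θ(θ−θ₀)/sin θ is capped at 100·k_θ
  (exact wherever the force is moderate; only truly near-singular
  configurations are capped);
* every dihedral is multiplied by a smooth cubic switch
  S(sin²θ₁)·S(sin²θ₂) of its flanking bending angles (off below
  sin²θ = 0.01, fully on above 0.09), with the switch gradient included in
  the forces; torsions thus vanish smoothly where φ is ill-defined.

Near-coincident nonbonded pairs are distance-clamped at 0.5 Å with a
warning, so pathological inputs give large-but-finite energies. Analytic
forces match central-difference gradients to better than 1e-5 relative on
randomized chains (this is enforced by the test suite).

### Integrator

BAOAB splitting of Langevin dynamics, with the thermal-noise stream drawn
chunk-wise from a seeded PCG64 generator — runs are bitwise reproducible
for a given seed. `noise_scale` multiplies only the noise amplitude (not
the friction) and exists for fluctuation–dissipation checks: scaling it by
c samples temperature c²·T. Velocities are recorded with each snapshot so
the kinetic temperature can be validated by equipartition. Energies beyond
a configurable threshold abort with the offending step number. The
full-scale preset (`SimulationParams.paper_scale()`) is 10⁷ steps at
300 K; tests and the acceptance script use desk-scale runs of 10⁵–10⁶
steps, which suffice for the qualitative open/closed contrast and the
thermostat checks at the precision asserted.

## FRET estimation

Each FP's transition dipole is the unit vector from its chromophore
Tyr/Trp Cα bead to its Ser147-equivalent Cα bead; r is the distance
between the two chromophore beads (the dipole origins — the simplest
reading of "distance of the dipoles"). κ² = (d̂·â − 3(d̂·R̂)(â·R̂))² ∈ [0, 4]
averages 2/3 isotropically; α = κ²/(2/3) rescales relative to the random
orientation already embedded in R₀ = 53 Å. κ² = 0 returns E = 0 directly
rather than guarding a singularity. Efficiencies are per-snapshot (no
sub-snapshot averaging). Histograms use 50 uniform bins on [0, 1]. The
`superpose_on_domain` utility Kabsch-aligns all frames on a chosen segment
(e.g. the b' domain) for visualization; r, κ² and E are rigid-motion
invariant, so scoring is unaffected, and this is asserted to 1e-10.

## Redox titration model

The a' active-site dithiol/disulfide couple equilibrates with glutathione,
ox + 2 GSH ⇌ red + GSSG, so with x = [GSH]²/[GSSG] (molar) the oxidized
fraction is f_ox = K_eq/(K_eq + x) and the observed ratiometric efficiency
is R(x) = R_red + (R_ox − R_red)·f_ox. The fit estimates
(log₁₀K_eq, R_ox, R_red) by Levenberg–Marquardt least squares on the
ratios, initialized from the extreme ratios and the interpolated half-way
crossing on the log₁₀x axis; it requires ≥ 4 points spanning ≥ 2 decades.
When the fitted two-state model fails to explain at least 80% of the
variance beyond a constant response — a redox-insensitive construct — the
fit reports the flat solution (R_ox = R_red = mean) and flags K_eq
unidentifiable. The optional bootstrap resamples points nonparametrically
(1000 resamples customary, seeded) for 95% percentile intervals. Peak
intensities are read at fixed 475/530 nm with linear interpolation, not by
peak finding. Time courses are normalized by the mean of the
pre-stimulation baseline window, making the operation idempotent.

## Synthetic data: what it emulates and what it does not

The generators provide every input with known ground truth:

* **Dumbbells.** FP stand-ins and core domains are boustrophedon walks on
  a 3.8 Å cubic lattice — compact, contact-dense, hence rigid under the
  potential — joined by circular-arc bridges with exact 3.8 Å bead
  spacing. The *open* arrangement separates the two core blocks by a
  configurable gap (30 Å default; no intercore contacts) and folds the
  chain back so both FPs sit adjacent (chromophores ≈ 20 Å apart). The
  *closed* arrangement merges the cores into one block — the reduced form
  behaves as a single particle — with the FPs at opposite ends
  (chromophores ≈ 90 Å apart, beyond E > 0.5 for any κ²). Which
  arrangement is high-FRET is therefore fixed by generated geometry, not
  by any label in the scoring code. Linker lengths (2 and 4) match the
  reference construct.
* **Trajectories.** Bernoulli mixtures of the two templates with isotropic
  Gaussian bead jitter and returned state labels.
* **Spectra.** Two Gaussians (475/530 nm) whose acceptor amplitude solves
  the closed form so the noiseless I(530)/I(475) is exact; additive noise
  afterwards.
* **Titrations and time courses.** Generated from the same closed forms
  the analysis fits, with multiplicative noise; GSH is back-solved from
  each x at fixed [GSSG] (1 mM). Default conditions: K_eq = 1e-6 M,
  R_ox = 1.2, R_red = 0.6, 5% noise, 12 points log-spaced over
  x ∈ [1e-8, 1e-4] M.

These stand-ins capture geometry, rigidity and connectivity — what the
pipeline actually consumes — but not real protein energetics, β-barrel
architecture, chromophore photophysics, or heterogeneous contact
strengths. Tests passing on them demonstrate that the pipeline's
machinery (assembly, integration, scoring, fitting) is correct under
known ground truth, not that the force field reproduces any particular
protein's ensemble.

## Problem sizes and precision of the shipped checks

The test suite and `scripts/acceptance.py` use: 10⁶ Monte-Carlo
orientation pairs for the isotropic κ² mean (±1%); a 10⁶-step, friction-2
two-bead run against the Boltzmann quadrature oracle (temperature within
3%, bond-length variance within 5% — the higher friction decorrelates
samples so the estimator noise is well below the asserted bands); two
10⁵-step, 206-bead ensembles for the open/closed contrast (≥ 10× in the
fraction of snapshots with E > 0.5); and 200 titration replicates for the
parameter-recovery rate (≥ 95% within 0.3 of log₁₀K_eq). The
zero-temperature descent check runs at friction 50, above twice the
stiffest mode frequency, where the energy decreases monotonically.

## Known limitations

* The uniform-ε contact model has no sequence specificity; relative
  open/closed populations of a real construct are outside its reach — only
  the geometric ordering of the FRET statistic is claimed.
* Torsions are switched off near backbone collinearity (see above), so
  nearly-straight linkers are held by bending terms alone.
* The excluded-volume background is active at lattice-native distances
  (3.8 Å < σ), so synthetic native states are stationary points of the
  reference-based terms but feel a small outward pressure from the
  background; contact strength is calibrated with this included.
* Circular permutants are supported as sequence/offset bookkeeping only;
  no photophysical consequences are modeled.
* Reading real structures requires a PDB file per component (core and
  FPs) plus user-supplied FP sequences and chromophore offsets; homology
  modeling of the reduced-form core is out of scope — that reference is
  accepted as input or generated synthetically.
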