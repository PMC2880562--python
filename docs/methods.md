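# Methods

`quatdyn` analyses the quaternary dynamics of two-trimer (hexameric)
protein assemblies from coordinate trajectories.  The package was built
around the arginine-repressor C-terminal domain (ArgRC): six identical
subunits, chains A–F, stacked as two trimers on a shared 3-fold axis,
whose dominant collective motion is a rigid rotation of one trimer
relative to the other.  Every analysis below runs equally on real
multi-model PDB / DCD / XTC input and on the package's synthetic
generator, which provides analytic ground truth.

## Units and conventions

Coordinates in Å, times in ps, masses in amu, energies in kJ/mol,
entropies in kJ/(mol·K), temperatures in K — fixed package-wide.
Physical constants come from `scipy.constants` and are centralized in
`quatdyn.constants`.  RMSD/RMSF and covariances divide by the number of
points/frames (population normalization).  Frame windows are half-open
index ranges `[start, stop)`.  Residue numbering is the deposited PDB
numbering; altloc groups resolve to the highest-occupancy conformer
(ties go to altloc 'A'); insertion codes are part of residue identity.

## Superposition

Weighted Kabsch superposition (SVD with reflection exclusion) underlies
every fitted quantity.  Alignment defaults to mass weights where the
physics calls for them (entropy, covariance) and uniform weights for
Cα-level reporting.  Rank-deficient (collinear) point sets are rejected
rather than silently resolved.

## Covariance referencing

The 3N×3N displacement covariance C_ij = ⟨(x_i − x̄_i)(x_j − x̄_j)⟩ is
computed after per-frame rigid-body fitting, and collapses to the N×N
atom-pair map C_xx + C_yy + C_zz.  Two referencing modes are exposed
because they answer different questions:

* **hexamer_mean** — fit on the whole selection, deviations from the
  window mean.  Rigid inter-trimer motion is largely absorbed by the
  fit and the map shows internal motions only.
* **trimer_fit_initial** — fit on one trimer's Cα set only, deviations
  from the *initial* (reference) structure.  A rigid rotation of the
  opposite trimer then appears as a coherent, strongly positive block
  over that trimer's atom pairs.  This is the package's operational
  definition of "trimer referencing"; the contrast between the two
  modes is quantified (in tests and the acceptance script) as the mean
  absolute map value over cross-chain pairs within the mobile trimer,
  which exceeds the hexamer-mode value by two orders of magnitude for a
  pure oscillation.

The window is always an explicit parameter: different observables are
legitimately computed over different trajectory segments, and a silent
default would hide that choice.

PCA diagonalizes the covariance; eigenvector signs follow the
largest-magnitude-component-positive convention, and extreme
conformations are reconstructed as reference ± (quantile of
|projection|)·eigenvector.

## Quasi-harmonic entropy

The Schlitter bound, S ≤ (k_B/2)·ln det[1 + (k_B T e²/ħ²)·σ] with σ the
mass-weighted covariance (e is Euler's number), is evaluated as a sum
of eigenvalue logarithms for stability.  Frames are aligned to a
reference by a mass-weighted whole-selection fit, which removes overall
translation/rotation but deliberately not internal collective motion
such as trimer rotation.  The corrected variant (`qh_corrected`)
additionally projects the six rigid-body directions of the reference
geometry (mass-weighted, Gram–Schmidt orthonormalized) out of σ before
evaluation, removing the Cartesian singularity; both variants are
reported because published "improved" procedures differ in detail.
Entropy differences use ΔS = (k_B/2)·ln(det σ_a′/det σ_b′) on the
regularized matrices σ′ = 1 + const·σ — the difference formula is
occasionally printed without the logarithm, which is dimensionally
impossible, so the log form is implemented.

Convergence caveat: the sampled log-determinant is biased low by
roughly d(d+1)/(2F) nats for d degrees of freedom and F frames.
Selections should therefore be sized to the available frames
(single-subunit selections converge to <1% at a few thousand frames;
full-hexamer selections need tens of thousands).  Tests and the
acceptance script use problem sizes chosen on that basis.

## Inter-trimer rotation

Domain-decomposition algorithms are unnecessary here: the moving
domains are known a priori to be the trimers, so the package measures a
fixed-partition rotation.  Each frame is fitted to the reference on the
fixed trimer's Cα atoms, then the Kabsch rotation of the mobile
trimer's Cα set onto its reference position is converted to angle-axis
form.  The sign convention — positive = clockwise viewed down the
3-fold axis from the DEF (top) side — is made unambiguous by fixing the
viewpoint; "clockwise" alone is viewpoint-dependent.  The 3-fold axis
is the principal inertia axis of the Cα set closest to the inter-trimer
COM vector.  Only the stored per-frame axis is sign-flipped for series
continuity; the signed angle is left to the convention, so ensembles
that rotate in both directions retain both signs.

Oscillation statistics report the mean, two amplitude estimators
(std·√2, exact for a sinusoid, and (max−min)/2), and a cycle time from
the dominant periodogram peak.  The cycle time is flagged undefined
unless the peak exceeds 3× the spectral median **and** carries ≥5% of
total spectral power; the median test alone cannot reject white noise,
whose spectral maximum is ~ln(N) medians.  A zero-crossing estimate is
reported alongside as a cross-check.

## Hydrogen bonds and salt bridges

Detection is donor/acceptor (N donates; N/O accept) so heavy-atom-only
models work.  Criteria (all configurable): donor–acceptor distance
≤ 3.5 Å; with explicit hydrogens, D–H···A within 30° of linear; without
hydrogens, a donor-antecedent angle ≥ 90° when an antecedent heavy atom
exists.  Salt bridges pair Arg/Lys/His sidechain nitrogens with Asp/Glu
carboxylate oxygens at N–O ≤ 4.0 Å and are reported even when hydrogen-
bond geometry fails — the electrostatic contact persists at distances
where directional bonding is lost, which is exactly the distinction the
quaternary analysis needs.  Persistence is the per-pair occupancy
fraction over a window; "persistent" means strictly >50% of frames.
Occupancy is evaluated per stored frame with no intermittency
smoothing.  Inter-trimer censuses come in the three standard variants:
persistent-only, total excluding ligand-mediated bonds, and total
including them.

## Interface metrics

Six Cα–Cα distances spanning the interface diagonally across the
ligand pockets (Gly103 to Asp128 of the diagonally opposite subunit)
quantify the quaternary state.  Δδ subtracts a reference distance —
canonically the ligand-bound crystal value, 9.8 Å — so the histogram
center measures the mean quaternary shift and the breadth measures
oscillation.  Histograms use half-open 0.1 Å bins (negative deviations
fall in negative-index bins); sampling stride and window are explicit
parameters.  Distances are frame-internal (no fitting), hence exactly
invariant under rigid-body motion.  The chain pairing of the six
diagonals in a real deposition is configuration; the default pairing
(A↔D, B↔E, C↔F in deposition order, both directions) matches the
synthetic generator.  Dihedral series use circular statistics, since
sidechain spreads of tens of degrees routinely cross ±180°.

## LIE energetics

ΔG = α·Δ⟨V_LJ⟩ + β·Δ⟨V_elec⟩ between bound and free ligand–environment
averages, with α = 0.18 and β = 0.50 (the standard values for small
charged ligands) and free-L-arg-in-SPC-water reference means of
−4.63 kJ/mol (LJ) and −453.458 kJ/mol (electrostatic) as defaults.
Binding enthalpy is the nonbonded interaction-energy difference
⟨V(protein·ligand)⟩ + ⟨V(ligand·water)_bound⟩ − ⟨V(ligand·water)_free⟩.
The bundled Coulomb + Lennard-Jones evaluator (plain cutoff,
Lorentz–Berthelot combining, Coulomb prefactor N_A·e²/4πε₀ ≈
138.935458 kJ·mol⁻¹·nm·e⁻²) exists to generate energy series for
synthetic systems; it is not a force field and makes no claim to
PME-quality electrostatics.

## Reaction coordinate

Per-ligation-state records (entropy ± replica sd, the three bond
counts, per-ligand ΔH and ΔG, a relative free-energy level) are ordered
apo basin → binding-competent state → the +1 manifold (sub-states keep
separate coordinates) → +2 → … → +6.  Levels for n = 3–5 are linear
interpolations between the n = 2 and n = 6 anchors; an anchor that is
itself an estimate carries an "unconstrained" flag that propagates.
Combining entropies, bond counts, and per-ligand energetics into one
level is an estimate by construction, so levels are assembled as
anchor + per-ligand ΔG increments and labelled estimated, with the
entropy and bond-count panels displayed alongside rather than folded
in.  A level the inputs cannot pin down is stored as an interval, never
imputed.  The energy zero sits at the apo-basin minimum.  Report
generation is deterministic for fixed inputs.

## The synthetic generator

Pseudo-monomers are rigid bodies (a deterministic 50-residue Cα spiral
plus marker atoms) with independent per-atom Gaussian jitter — no
internal normal modes, which suffices for every observable the pipeline
measures.  Defaults are the study conditions the package is exercised
under: rotation mean 13°, amplitude 3°, period 250 ps (sinusoid; an
exactly discretized Ornstein–Uhlenbeck process and a two-state switch
are alternatives), monomer COMs 18 Å from the axis and trimer planes
18 Å apart, jitter σ from 0.17 Å (core) to 0.6 Å (surface) — bracketing
the 0.3–1.5 Å RMSF range typical of compact domains — pocket rest
distance 9.8 Å opening by 1.6 Å at the rotated mean, and gate angle 13°.

Marker placement is solved in closed form: a pair at radius r and axial
gap dz with azimuthal stagger ψ has separation d(θ)² =
2r²(1−cos(ψ+θ)) + dz², so the pocket markers hit exactly 9.8 Å at θ = 0
and 11.4 Å at θ = 13°, and the hydrogen-bond markers cross the 3.5 Å
detection cutoff exactly at the gate angle (2.9 Å at θ = 0).  The same
geometry keeps the N–O distance inside the 4.0 Å salt-bridge cutoff
across the whole oscillation range, reproducing the
"hydrogen-bond-broken but electrostatically intact" regime.  The
ground-truth object carries the realized θ series, the analytic
pocket-distance map, the analytic bond-open fraction per process, the
per-atom jitter σ, and a closed-form Schlitter entropy of the jitter
(optionally with the six rigid-body modes projected out, mirroring what
per-frame alignment removes).

Bound ligands (up to six three-atom arginine stand-ins, chain L) each
contribute one hydrogen bond on the static-trimer side, and the "ligand
brake" multiplies rotation mean and amplitude by brake_factor^n_ligands
(default 0.05), so a single ligand effectively arrests the oscillation.

What the generator does **not** emulate: internal protein flexibility
(loops, secondary-structure breathing), solvent, force-field energetics
beyond Gaussian series with prescribed means, and coupling between
jitter and rotation.  Passing tests therefore demonstrate that the
analysis machinery recovers known collective motion, contact gating,
and energetics from trajectories with realistic noise — not that it
reproduces any particular protein's MD.

## Numerical choices

Kabsch degeneracy threshold: second singular value < 1e-10 of the
first.  Covariance matrices are explicitly symmetrized; eigenvalues
below −1e-8·max are an error, small negatives are clipped.  Degenerate
PCA eigenvalues are ordered by the eigensolver with the sign convention
applied afterwards.  Exact zeros in the rotation series are not counted
as sign changes by the zero-crossing estimator.  Histogram bins are
half-open so boundary values land in the upper bin.  All generator and
test randomness flows through seeded `numpy` Generators.

## Problem sizes

Tests and the acceptance script use 10³–10⁴-frame synthetic
trajectories (~340 atoms), 10⁵-sample Gaussian draws for entropy
closed-form checks, and ≤1200-frame covariance contrasts; these sizes
were chosen so that each statistical tolerance (binomial bounds, CLT
bounds, log-det bias) is comfortably met while the whole suite runs in
well under a minute per module.
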