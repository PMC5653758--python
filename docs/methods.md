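# Methods

## Model

The system is a coarse-grained stand-in for the IgG1-Fc/FcγRIIIa complex:
one bead per monosaccharide residue and one bead per protein-surrogate
site, in vacuum with implicit solvent. It is not an all-atom force field
and does not attempt force-field energetics; it exists so that the
sampling machinery (restrained Langevin dynamics, temperature replica
exchange) and the analysis chain operate on data with the same structure
as a production study, at a size where closed-form checks are possible.

Potential energy terms (units: Å, kcal·mol⁻¹, amu, fs/ps, K;
k_B = 1.987204259×10⁻³ kcal·mol⁻¹·K⁻¹):

* bonds k_b(d − b₀)², default k_b = 50 kcal·mol⁻¹·Å⁻², b₀ = 5 Å between
  linked sugar beads (b₀ is the built distance for scaffold/anchor bonds);
* angles k_a(θ − θ₀)², k_a = 5 kcal·mol⁻¹·rad⁻², θ₀ at the built geometry
  for every bonded triple, so the build is a bonded-term minimum;
* Lennard-Jones 12-6 with ε = 0.2 kcal·mol⁻¹, σ = 5 Å
  (Lorentz–Berthelot mixing), truncated at 10 Å, 1-2/1-3 pairs excluded;
* positional restraints E = k(r − r₀)², k = 10 kcal·mol⁻¹·Å⁻².

The restraint formula is used verbatim **without** the conventional ½, so
the effective spring constant is 2k: a restrained bead in equilibrium has
per-coordinate variance k_B·T/(2k) = 0.0298 Å² at 300 K for k = 10. Every
closed-form target in the tests carries this factor.

Bead parameters (masses from monosaccharide residue masses, the ε/σ/k
values above) are invented for stability at dt = 2 fs; they are stand-ins,
not fitted quantities.

### Toy-complex layout

Three chains (Fc A, Fc B, receptor) each contribute four restrained
scaffold beads; each glycosylation site (Fc-A/Fc-B Asn297, receptor Asn45
and Asn162) contributes an unrestrained anchor bead, mirroring a protocol
that restrains the protein backbone except around the sequons. Glycans are
the canonical biantennary tree — core GlcNAc1-GlcNAc2-Man3, α1-3 arm
Man4-GlcNAc5-Gal6, α1-6 arm Man4'-GlcNAc5'-Gal6', optional core fucose on
GlcNAc1. The receptor glycans always carry their own fucose; the
`fc_fucosylated` flag toggles it on the two Fc glycans, and the Fc-A fucose
is built pointing into the inter-glycan space near the Asn162 glycan core.
The geometry places the Fc-A and Asn162 glycans face to face across the
interface, emulating the crystallographic arrangement at bead resolution.

## Dynamics and replica exchange

Langevin dynamics uses the BAOAB splitting, chosen for its superior
configurational accuracy at large time steps; the default collision
frequency is 1 ps⁻¹ and the default step 2 fs (the fastest bond period in
the toy systems is ≈ 700 fs, so dt is far below stability limits). No
constraint algorithm is needed (no hydrogens), and there is no periodic
box, Ewald electrostatics or barostat: constant-pressure equilibration is
out of scope by design.

The REMD engine distributes n temperatures geometrically,
T_i = T_min (T_max/T_min)^(i/(n−1)) — near-uniform acceptance when heat
capacity varies weakly with T. Neighbor swaps use the Metropolis
criterion p = min(1, exp[(β_i − β_j)(E_i − E_j)]) with parity alternating
between (0,1),(2,3),… and (1,2),(3,4),… on successive attempts, so all
pairs are exercised; with 64 replicas an even sweep tries exactly 32
pairs. Accepted swaps exchange configurations between temperature slots
and rescale velocities by √(T_new/T_old). Frames are recorded per
temperature slot, i.e. already demultiplexed, and the leading
`burn_in_fraction` (default 0.5) is discarded before analysis. One seed
determines everything: a single stream drives the batched dynamics of all
replicas and an independently derived stream drives swap decisions. (This
is a deliberate simplification of per-replica independent streams: the
batched draw is equivalent for reproducibility purposes and vectorizes.)

The full-scale reference protocol — 64 replicas spanning 300–400 K, 30 ns
per replica at dt = 2 fs, swaps every 1000 steps, first half discarded —
is kept as `STUDY_PROTOCOL` for protocol arithmetic (1.92 μs aggregate);
it is far beyond desk scale and is never run here.

## Analyses

* **RMSF** ρ_i = √⟨(r_i − ⟨r_i⟩)²⟩ over production frames with uniform
  weight. No superposition is applied by default because the simulations
  restrain the frame of reference; an optional least-squares fit to a
  reference supports unrestrained inputs. Per-glycan values are unweighted
  means over the glycan's particle RMSFs (the aggregation rule is a
  package choice; reasonable alternatives differ only through the
  particle-count weighting).
* **PCA**: frames are iteratively fitted to their average coordinate (2
  rounds), deviations are mass-weighted (√m_i), and the 3N×3N covariance
  is diagonalized; projections Φ_p = V_p·R. Mass weighting is the default;
  the unweighted toggle gives identical results up to scale for
  uniform-mass bead systems. Eigenvalues are floored at −10⁻¹⁰λ₁ to
  absorb numerical negatives.
* **Free-energy landscape** ΔG = −k_B T ln P over (Φ₁, Φ₂) histograms,
  shifted so the global minimum is 0. Default binning: 50×50 spanning the
  sample range padded by one bin each side; empty bins are NaN
  (undefined), never 0, for serialization safety. Aligning landscapes
  across systems requires passing shared bin edges.
* **Distances**: group centers are mass-weighted centers of non-hydrogen
  members; histograms are density-normalized.
* **χ1 dihedrals** via the standard atan2 construction, signed per the
  IUPAC convention (validated against MDAnalysis during development),
  reported in (−180, 180] with −180 mapped to +180. A rotamer printed as
  186° in a 0–360 convention appears here as −174°.
* **B-factor conversion** B = (8π²/3)ρ², the isotropic Debye–Waller
  relation; used to compare simulated fluctuation profiles with
  crystallographic B-factors, with unobserved template residues assigned
  a sentinel (default 200 Å²).

## Structure layer

PDB read/write is delegated to gemmi (classic fixed-column dialect). Alt
locations resolve to the highest occupancy, first listed on ties;
hydrogens are kept and flagged. Residue names longer than 3 characters are
rejected at write time — the classic dialect has no room for the
remediated 4-character carbohydrate codes, and silent truncation would be
worse than an error. Glycosidic bonds are inferred from anomeric-carbon to
exocyclic-oxygen distances below 1.8 Å (covalent C–O ≈ 1.4 Å, next-nearest
contacts > 2.4 Å); trees root at the residue bonded to an Asn ND2, and
nomenclature labels are assigned by traversal using the linkage oxygen
(O3 child of Man3 → Man4 arm, O6 child → Man4' arm). Carbohydrate
fragments with no resolvable parent are reported as orphans. The
recognized carbohydrate code set is configurable because PDB carbohydrate
codes changed across remediation. Superposition is the SVD-based Kabsch
fit with reflections excluded; an independent quaternion-eigenvalue oracle
cross-checks it in the tests. Sequence-matched Cα pairing (same chain id
and author residue number in both models) defines the superposition set
for comparing deposited structures; the checks against the deposited
entries require the user to supply the coordinate files, since the package
performs no remote fetching.

## Synthetic data

Generators produce trajectories with attached truth records (all recovery
tests read truth from the data, never from test constants): isotropic
Gaussian jitter (truth RMSF σ√3), two-basin mixtures (truth
ΔΔG = −k_B T ln((1−p)/p), with a warning recorded when basins are closer
than 2σ), exact Boltzmann draws for harmonic wells (truth variance
k_B T/(2k)), labeled toy glycan trees, and PDB fixtures whose covalent
geometry is consistent with the bond-inference cutoff. Frames are i.i.d.
across time by design, which makes binomial/χ² standard-error formulas
exact when setting test tolerances; autocorrelated generators are future
work. What these generators deliberately do not emulate: force-field
energetics, ring puckering, autocorrelation, and anisotropic fluctuation —
so passing recovery tests demonstrates estimator correctness, not realism
of the dynamics.

## Problem sizes and what the desk-scale runs show

The sampling-correctness checks use 12 independent harmonic beads, 8
replicas and 2×10⁵ steps per replica with γ = 5 ps⁻¹ and m = 100 amu —
chosen once so per-coordinate statistics pool over 36 i.i.d. coordinates
and position autocorrelation decays in a few hundred steps, giving
standard errors of ~1% against the 5% band. The end-to-end toy pipeline
uses 8 replicas × 20,000 steps (0.32 ns aggregate per system). At that
length the per-glycan RMSF differences between glycoforms are dominated by
sampling noise: the pipeline checks are structural (all four glycan groups
populated, bit-for-bit determinism per seed, Boltzmann-correct rungs), and
no directional claim about the fucosylation effect is made or tested at
desk scale. Full-scale per-glycan RMSF values and the fucosylation-induced
increase for the Asn162 glycan are properties of μs-scale all-atom
ensembles and are out of reach of the toy model by construction.

## Numerical choices and edge cases

* Minimization is steepest descent with backtracking; exhausting the line
  search near a flat minimum terminates normally (stalled), while a stall
  with max-gradient > 1 kcal·mol⁻¹·Å⁻¹ raises a divergence error.
* `superpose` refuses < 3 pairs and collinear point sets (second singular
  value ≤ 10⁻¹⁰ of the first).
* Single-bin landscapes are valid (ΔG = 0 in the occupied bin);
  out-of-range references in `landscape_locate` are flagged, not clamped.
* Empty atom selections warn and return empty lists; empty RMSF groups
  report NaN (missing), never 0.
* Exchange attempts with zero recorded attempts produce an empty mixing
  report rather than a division error.
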