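# Methods

## Scope and data model

The package analyses the collective domain motions of elongated two-domain
dimers: elastic-network normal modes, essential dynamics (PCA) of
trajectories, cross-system mode comparison, rigid-fit mobility statistics,
and active-site geometry scans for near-attack conformations (NAC).
Structures are ordered atom lists (names, residues, chains, coordinates in
Å, masses in amu from the IUPAC standard atomic weights of the element
symbol); the atom order as read is the canonical index space for every
matrix and vector.  Trajectories are frame stacks bound to a structure
with times in ps.  PDB is the native format (multi-model PDB for
trajectories; DCD/XTC optionally through MDAnalysis); dense text matrices
carry imported Hessians; CSV/TSV carry series and spectra.

Time windows are half-open `[a, b)` by default with a `closed` flag,
because both conventions occur in trajectory bookkeeping: a 100-ns window
sampled at 1 ps holds 100 001 conformations when closed, while a 7-ns
window at the same spacing holds 7000 snapshots half-open.  A 120-ns
trajectory subsampled at 2 ns gives 60 snapshots when t = 0 is excluded
(the closed window `[2, 120]` ns); the exclusive-of-origin convention is
what makes 120/2 = 60 come out exactly, and both conventions remain
available.

## Elastic-network normal modes

The Hessian is the standard anisotropic network model: for every atom pair
within a cutoff (default 13 Å on Cα, uniform force constant k = 1
kJ mol⁻¹ Å⁻²) the off-diagonal 3×3 superelement is `−k r̂ r̂ᵀ`, and
diagonal blocks are the negated row sums, which makes uniform translations
exact zero modes by construction.  An elastic network stands in for a
force-field Hessian deliberately: it preserves the low-frequency mode
shapes that drive domain motion while avoiding a minimisation engine.  The
consequence is that absolute frequencies depend on k and are **not**
physically meaningful; mode shapes, mode ordering and the entire
comparison pipeline are.

Mass weighting applies `H′ = M^{−1/2} H M^{−1/2}` element-wise
(`/√(m_i m_j)`), flagged so it cannot be applied twice.  Eigenanalysis is
a full symmetric decomposition (`scipy.linalg.eigh`), eigenvalues
ascending, eigenvector signs normalised so the largest-magnitude component
is positive (solver signs are arbitrary).  Frequencies are
`ν_i = √λ_i / 2π`; with k in kJ mol⁻¹ Å⁻² and masses in amu,
`√(1 kJ mol⁻¹ amu⁻¹ Å⁻²)` equals exactly 10¹³ rad s⁻¹ (CODATA), so the
wavenumber conversion is `ν̃ = √λ · 10¹³ / (2π c)` ≈ 53.088 √λ cm⁻¹.
Eigenvalues below −10⁻⁶ of the spectrum maximum are rejected (the matrix
does not describe a minimum); smaller negatives are clamped to zero.

The six lowest modes are removed as trivial, but not silently: the removed
modes are projected onto an exactly constructed orthonormal rigid-body
basis (3 translations, 3 rotations about the centre, mass-weighted when
the modes are), and the per-mode overlap is reported.  On a connected
structure all six overlaps are 1.0 to machine precision; anything less
signals a disconnected network (isolated atoms are also warned about at
Hessian build time).

Two generators turn modes into coordinates.  Harmonic trajectories sample
one full period of `x(t) = x_ref + A sin(2πt/T) d` for visualisation.
Thermal ensembles draw per-mode amplitudes `c_i ~ N(0, k_B T/λ_i)` in
mass-weighted coordinates and map back through `M^{−1/2}` — classical
equipartition, chosen over quasi-harmonic conventions because it makes the
per-mode variance analytically checkable (`k_B` = R/1000 =
8.314462×10⁻³ kJ mol⁻¹ K⁻¹, consistent with the force-constant unit).
Trivial modes have λ = 0 and are rejected, not skipped.

## Essential dynamics

Frames restricted to the analysis atom set (all Cα by default) are
rigid-fitted to the first frame of the analysis window — the reference
convention throughout — before the 3n×3n covariance is accumulated.
Normalisation is 1/F (population; the time average as written), with
`ddof=1` available.  PCA returns descending eigenvalues (variances, Å²)
and unit eigenvectors; projections, extreme conformations (the actual
frames attaining extreme projections, never synthetic extrapolations),
variance spectra (cumulative percentages) and porcupine fields
(`scale·√λ·d` per atom, NMD export) follow.  Two exact internal
identities are enforced by tests: the variance of the PC-i projection
equals λ_i, and Σ(per-atom RMSF²) = Σλ = trace C when RMSF is computed
with the same single-reference alignment (RMSF's default, by contrast, is
a 2-pass iterative fit to the evolving mean, the usual convention for
fluctuations about mean positions).

## Mode comparison across systems

Systems differing in bound ligands have Hessians of different dimension,
so mode vectors cannot be compared directly.  The protocol: for each
system and mode, generate a 5000-conformation thermal ensemble at 300 K
along that single mode; reduce each conformation to the atoms all systems
share (the main-chain N, CA, C, O selection); run PCA on the reduced
ensemble; PC1 is the recovered mode on the common atom set.  For a
single-mode ensemble only the first eigenvalue is significant — λ₂/λ₁ is
reported as a purity diagnostic and warns above 0.05.  Similarity is the
absolute inner product `|a·b|` (the reported scale is [0, 1] and
eigenvector signs are arbitrary, so the sign is dropped).  Modes are
matched across systems by index after frequency ordering; no assignment
optimisation is performed — a permutation showing up off-diagonal is a
finding, not something to optimise away.

## Superposition and mobility

Kabsch superposition via SVD with the determinant correction, so a
reflection is never returned; collinear or coincident point sets leave the
rotation underdetermined and raise.  Weighted fits are supported but mass
weighting is off by default (Cα sets are fitted geometrically).  RMSD
series fit each frame on one atom set and measure on another, which
isolates inter-domain motion (e.g. L-domain RMSD after fitting the K
domain).  Mobile regions are contiguous residue runs with RMSF above a
threshold (default mean + 1 SD of the profile), merging runs separated by
fewer than `gap_merge` (default 2) residues; there is no universal numeric
criterion for "high mobility", so the rule is explicit and configurable
and region counts are not treated as ground truth.

## NAC geometry

A site definition carries atom indices for: a closure pair (one marker
atom per domain — e.g. an ATP-coordinating Mg²⁺ in the L domain and the
Nε2 of the triose-anchoring histidine in the K domain), the γ-phosphorus,
the bridging (leaving) oxygen of the scissile P–O bond, and the
chemically equivalent nucleophile hydroxyl oxygens, each tracked
separately.  Site definitions are user-supplied selections (a builtin
helper encodes the synthetic dimer's markers), never hard-coded residue
numbers.  The O···P–O angle is measured at the P vertex between the
vectors P→O_nucleophile and P→O_leaving — 180° is a perfect in-line
attack; the convention is fixed here because the notation alone does not
pin down the vertex.  The NAC filter passes frames with distance
strictly < 3.5 Å and angle strictly > 155° (both thresholds
configurable); passing frames with distance ≤ 3.3 Å (the P 1.9 Å + O
1.4 Å van der Waals sum) are annotated as van der Waals contacts.  The
filter is monotone in both thresholds by construction.

## Synthetic generator

`make_toy_dimer` builds each domain as a uniform-density point cloud
(125 Å³ per residue) centred on the L2-K1-K2-L1 axis; adjacent domain
centres sit at 0.75·(R_K + R_L) (≈30 Å at the reference size of 575
residues per subunit, K domain 340 residues), which keeps the elastic
network connected at any scale.  Residue counts, the histidine position
(221/575) and the K/L split scale proportionally when a smaller system is
requested.  Each site's markers are placed so the closure pair starts
≈14 Å apart (the open state) and the nucleophile-to-phosphorus baseline
is >10 Å.  Output is bit-identical for a fixed seed.

`make_hinge_trajectory` plants the three universal bilobate motions —
hinge-bend, twist, wobble — as linearised rigid rotations of the terminal
L domains (mirrored between subunits), projected out of the rigid-body
subspace and Gram-Schmidt orthonormalised, supported on the Cα atoms.
Frames are `x_ref + Σ a_i(t) d_i + noise` with `a_i ~ N(0, √v_i)` and
isotropic jitter σ (default 0.1 Å per coordinate) on the protein atoms.
Because the fields are fixed displacement fields, the planted motion is
exactly rank-k and PCA-recoverable; the price is that large amplitudes are
not true rotations, and a warning fires when the 3σ displacement exceeds
half the domain spacing.  Default variances solve
`(V + 3σ²)/(V + 3nσ²) = 0.68` — the condition that the first three
principal components carry 68% of the total variance — at the system's
own Cα count, split 60/25/15 between hinge, twist and wobble.  What the
generator does **not** emulate: real backbone connectivity, secondary
structure, anharmonic wells, slow drift, or correlated noise — so passing
tests validate the estimators and the pipeline's bookkeeping, not the
biology of any particular protein.

`plant_nac_episode` steers a chosen nucleophile oxygen along the in-line
direction during specified time windows.  With `n_pass` given, a centred
block of exactly that many frames gets geometry strictly inside the filter
(edges at 3.49 Å / 155.5°, centre at the episode's extremes, default
3.16 Å and 178.45°), making the census an exact ground truth; without it,
a smooth squared-sine approach is used and the count is emergent.  The
default episode set reproduces the reference phenomenology: three
distance-only approaches of one oxygen (angles stay far from in-line) and
one 7-ns window (105–112 ns) in which the other oxygen achieves 395
genuinely passing snapshots.

## Problem sizes in tests and acceptance

Counting identities (1150 Cα, 4600 main-chain atoms, 3450-dim covariance,
5000-conformation ensembles, 60/7000-snapshot windows) are computed at
full size — they are cheap.  Statistical checks use the sizes at which
their convergence is already decisive: ensemble protocols at 30–60
residues per subunit with 5000 conformations, planted-spectrum recovery at
100–150 residues per subunit with 4000 frames (the top-3 fraction is then
determined to a fraction of a percentage point), the full-size
essential-dynamics stage in the acceptance script at 4000 frames.  These
sizes are the package's own choices for decisive-yet-quick validation;
all tolerances (5% equipartition, ±2 points cumulative variance, 10⁻⁸
spectral identities, 10⁻⁶ oracle agreement, exact NAC counts) are stated
in the tests themselves.

## Known limitations

* The elastic network reproduces mode shapes, not absolute frequencies;
  wavenumbers printed for ENM spectra are in "spring units".
* Linearised planted rotations are only locally rotation-like; variance
  recovery is exact, physical curvature is not modelled.
* Rigid-fit alignment before covariance slightly couples rotation removal
  with large internal motions (a universal property of the procedure, not
  of this implementation); the planted-recovery tests bound the effect.
* The selection grammar is deliberately small (name / resname / resid /
  chain / element conjunctions); it covers the analyses here, not general
  structural queries.
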