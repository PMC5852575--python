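# Methods

## Overlap-volume statistic

The quantity at the centre of the package measures how strongly an
apo-protein conformer intrudes into the space its RNA partner occupies in
a bound reference complex. Each ensemble frame is rigid-body fitted onto
the complex; protein and RNA atoms are then treated as van der Waals
spheres and the intersection volume is summed over all protein–RNA pairs.
For radii r₁, r₂ at centre distance d the pair term is

- 0 for d ≥ r₁ + r₂ (disjoint),
- (4/3)π·min(r₁, r₂)³ for d ≤ |r₁ − r₂| (containment),
- π (r₁+r₂−d)² (d² + 2d(r₁+r₂) − 3(r₁−r₂)²) / (12d) otherwise
  (spherical lens).

The analytic form is exact and is validated in the test suite against a
Monte-Carlo integration oracle (uniform sampling in a tight bounding box
of the intersection region; the box's radial extent is the maximum of the
lower envelope of the two circle profiles, attained at x = 0, x = d or the
crossing plane).

**Pairwise-sum semantics.** The statistic is the sum of *per-pair*
overlaps. Where three or more spheres overlap the same region it is
counted once per pair, so the value is not the volume of the geometric
union and can exceed it. This is intentional: the quantity is a steric
clash score whose distribution is compared *between variants computed the
same way*, where the over-counting cancels in the comparison. An
inclusion–exclusion union volume is explicitly out of scope.

**Frozen RNA.** The RNA coordinates come from the reference complex and
never move. The metric asks how much of the *bound-pose* RNA volume a free
protein conformer invades — using relaxed or re-docked RNA would answer a
different question.

**Neighbour search.** Pairs are pruned with a KD-tree at cutoff
max(r_protein) + max(r_RNA). Every discarded pair has exactly zero
overlap, so the pruned sum equals the brute-force all-pairs sum to
floating-point accuracy (asserted to 1e-9 ų in tests on seeded systems).

**Radii.** The choice of radius set is a free parameter of any such
analysis; the shipped default is Bondi's compilation (C 1.70, N 1.55,
O 1.52, P 1.80, S 1.80, Zn 1.39 Å, …) with a 1.50 Å fallback for unknown
elements (logged). Tables load from two-column CSV, so alternative sets
are drop-in. Likewise, whether hydrogens enter the protein set (MD frames
have them; crystal references usually do not) is a flag
(`include_hydrogens`, default on), and the catalytic Zn²⁺ is excluded by
default but includable (`include_zinc`), since such analyses are
meaningful both with and without the ion.

## Superposition

Kabsch least-squares with equal weights: centre both point sets, SVD of
the cross-covariance, and a sign flip of the smallest singular pair
whenever the determinant would be −1, so a proper rotation is always
returned (verified on mirrored near-planar inputs). Atom correspondence is
exact matching on (chain, residue key, atom name) — ensemble and reference
are assumed to derive from the same model, so no sequence alignment is
attempted. The default fit selection is protein backbone N/CA/C;
fits on fewer than three or (near-)collinear points are rejected rather
than silently returning an arbitrary rotation. Per-frame RMSD before and
after fitting is reported, and after ≤ before is enforced as an invariant.

## RMSF

RMSF_i = √(mean_f |x_{i,f} − x̄_i|²) with x̄ the time mean. When a fit
selection is supplied, one fit-to-mean refinement pass runs first (fit all
frames to the raw mean, recompute the mean, measure fluctuations);
fitting to an external reference is available through the superposition
module. Per-residue values aggregate atoms by root mean square, not plain
mean, so they remain RMS displacements. For isotropic per-axis Gaussian
displacements of width σ the closed form RMSF = √3·σ holds, which the
tests use for parameter recovery (σ = 0.5 Å, 2000 frames, 5% tolerance);
an independent cross-check against MDAnalysis' RMSF implementation is also
in the suite.

## Hydrogen bonds

Geometric criterion in the GROMACS convention: donor–acceptor distance
≤ 3.5 Å and hydrogen–donor–acceptor angle ≤ 30°, donors and acceptors N/O.
Both cutoffs are configurable (`HBondCriteria`). Donor hydrogens are
identified by covalent distance (≤ 1.25 Å), since multi-model PDB
ensembles rarely carry CONECT records. Structures without hydrogens fall
back to the distance-only criterion with a logged warning and a flag on
the output; such bonds are undirected and are de-duplicated by atom pair,
whereas explicit-hydrogen bonds are identified by their D–H–A triplet.
Time averages count bonds in both donation directions between a residue
and the RNA selection, per frame, and divide by the frame count; the
summary table is residue rows × variant columns. Time averages computed
from real MD trajectories of specific systems are properties of those
trajectories; the module reproduces the *computation*, not any particular
published table.

## Quantification ratios

Editing level = 100·G/(A+G) from pre-integrated Sanger peak areas;
cassette inclusion = 100·long/(long+short) from band molarities.
Chromatogram parsing and peak integration are out of scope — commercial
software performs the integration in practice, and inventing a peak caller
would add nothing to the stated formulas. The ratio is computed as
100·(G/total) so the result never exceeds 100 by rounding. Replicate
summaries use SEM = s/√n with the sample (n−1) standard deviation; SEM is
undefined (NaN) for n = 1.

## Synthetic data: what it emulates and what it does not

The generators produce inputs with the statistical structure the analysis
assumes, so every stage is testable without downloading any structure.

- **Harmonic ensembles**: frames are mean + iid Gaussian per-axis noise of
  width σ, with no net rigid motion injected. This gives closed-form RMSF
  and exact seed-determinism. Real MD ensembles are anharmonic, correlated
  in time, and drift rigidly — passing tests on harmonic data validates
  the *statistics*, not force-field realism.
- **Variant pair** (the study conditions for the two-isoform comparison):
  a 60-atom Cα core on a 3.8 Å cubic lattice, a 21-atom pseudo-RNA chain
  of P spheres spaced 5 Å at 9 Å from the core centre, and in variant B a
  10-atom loop placed 3.0 Å from the pseudo-RNA centroid (contact distance
  C+P = 3.5 Å), all fluctuated with σ = 0.3 Å over 200 frames. The odd RNA
  atom count puts the chain centroid on its central atom, making the loop
  offset a true centre-to-atom distance; 10 loop atoms mirror a ten-residue
  isoform insertion; σ = 0.3 Å is a typical well-ordered-region amplitude;
  200 frames give the rank-sum test high power for the built-in effect
  while keeping runs fast. Setting `loop_atoms=0` (or a large offset)
  yields an exact null, used for false-positive control. The pseudo-RNA is
  a bare sphere chain — the occlusion metric consumes only centres and
  radii, so base-pair geometry would be decoration.
- **Hydrogen-bond fixtures**: exact requested distance/angle geometries.
- **Peak-area tables**: per-site edited fractions true_fraction +
  N(0, noise_sd²) clipped to [0, 1]; the clip introduces negligible bias
  at the small noise levels used.

## Numerical and design choices

- Units are Å / ų / degrees everywhere; mixing nm-based trajectory
  conventions with Å structures is a classic source of silent 10³ volume
  errors, so conversion happens nowhere downstream of I/O.
- PDB I/O is delegated to biotite; altloc duplicates collapse to the
  highest-occupancy conformer (ties to first in file order, i.e. 'A'),
  elements missing from the element column are inferred from atom names,
  HETATM records are kept and flagged, insertion codes become a residue-key
  suffix. Files with MODEL records always parse as ensembles, even with a
  single model. Written files end with an END record; coordinates outside
  the fixed PDB columns (|x| ≥ 10⁴ Å) are rejected.
- Distributions default to Freedman–Diaconis binning with a 10-bin
  fallback for degenerate IQR (e.g. constant series, padded ±0.5 ų).
  A histogram rather than a KDE is the default density estimate: it is
  assumption-free and exactly normalised; a KDE would introduce a
  bandwidth choice the comparison does not need.
- The two-variant comparison uses the tie-corrected two-sided Mann–Whitney
  test plus plain mean/median differences; when every pooled value is
  identical the test is short-circuited to p = 1 (the tie-corrected
  variance vanishes).
- The degenerate-geometry threshold for Kabsch is s₂ ≤ 1e-10·scale on the
  singular values, rejecting collinear clouds while accepting planar ones
  (where the reflection guard does the work).

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
systems — ≤ 200-atom overlap systems, 200-frame variant ensembles,
2000-frame RMSF recovery, 10⁷-sample Monte-Carlo sphere checks — sizes at
which every oracle (brute force, closed form, simulation) is itself cheap
and trustworthy. The implementation has no intrinsic size limit; cost
scales linearly in frames and near-linearly in atoms via the KD-tree.

## Known limitations

- The pairwise sum over-counts multi-sphere intersections (documented
  above; by design).
- No union/SES volumes, no per-residue decomposition of the overlap beyond
  per-atom contributions, no trajectory formats beyond multi-model PDB
  (XTC/DCD readers belong to trajectory libraries), no mmCIF.
- Hydrogen-bond analysis has no energy term, water bridges or lifetime
  statistics; it is the plain geometric count.
- Atom correspondence requires identical naming between ensemble and
  reference; structures from different numbering schemes must be
  renumbered upstream.
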