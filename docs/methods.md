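# Methods

This note records the models implemented, the defaults chosen where the
underlying conventions admit alternatives, and what the synthetic test
beds do and do not establish.

Units are AMBER conventions throughout: Å, kcal/mol, amu, ps, elementary
charges; k_B = 0.0019872041 kcal/(mol·K), Coulomb constant
k_c = 332.0636 kcal·Å/(mol·e²). No unit auto-detection is performed.

## PMF by thermodynamic integration along a steering path

The estimator treats the 3n coordinates of n steered centers as the
reaction coordinates. For each displacement window the centers are held
fixed and the force the rest of the system exerts on them is sampled;
the PMF difference between windows is the line integral of minus the
mean force along the recorded center path, with forces from all centers
concatenated into a single 3n-vector before the dot product. Because the
PMF is a state function, any path connecting the end states is valid;
the path increments du are taken from the recorded center positions, not
re-idealised to a straight line.

Choices and their rationale:

- **Window schedule.** Graded spacing — 0.1 Å on [0, 5], 0.2 Å on
  [5, 13], 0.4 Å beyond — reflects that the PMF is steepest near the
  bound state. When the total displacement is not a whole multiple of
  the final spacing, a short terminal step is appended so the grid lands
  exactly on the total.
- **Quadrature.** Trapezoidal rule between consecutive windows. It is
  exact for linear mean-force profiles (hence the harmonic recovery test
  is exact to round-off) and O(h²) otherwise; the quartic double-well
  barrier is recovered to 0.25% at 0.1 Å spacing, within the 1% the
  package's acceptance suite demands.
- **Uncertainty.** Each window's force samples are collected in four
  contiguous segments; the standard error is sd(segment means)/√4, which
  absorbs autocorrelation on scales shorter than a segment. Propagation
  to the PMF uses the exact trapezoid coefficients — window i enters the
  cumulative integral with weight (Δu_before + Δu_after)/2 — and treats
  windows as independent. That independence is an approximation
  (separately equilibrated windows); it is the same approximation a
  per-window steered protocol makes.
- **No Jacobian/entropic correction** is applied for the multi-center
  restraint geometry, and no work-based (Jarzynski/Crooks) or
  umbrella/WHAM machinery is included: the estimator is the mean-force
  line integral, nothing else.
- **Convergence.** `compare_runs` re-anchors repeat profiles at zero and
  reports the maximum absolute deviation and per-point z-scores against
  pooled sigma; the convergence flag uses a user tolerance (default
  1 kcal/mol).

## Langevin sampling of constraint forces (synthetic data)

The synthetic steering records emulate the constrained-sampling protocol
over analytically tractable potentials. Free coordinates evolve by a
BAOAB-split Langevin integrator (deterministic half-kicks and drifts
around an exact Ornstein–Uhlenbeck velocity update), chosen for its
configurational accuracy at modest timesteps; any integrator passing the
equipartition check (variance k_BT/k for a harmonic degree of freedom
within 3 standard errors) would serve. Defaults: 300 K, friction 5 ps⁻¹,
timestep 0.002 ps, masses 12 amu, forces sampled every 4 steps.

Each window starts from the local energy minimum of the free
coordinates (L-BFGS), then discards an equilibration fraction —
default 20% of the total sampled length — before the four collection
segments. The underlying protocol equilibrates each window for a fixed
time but does not state the discard split, so the fraction is an exposed
parameter, not a constant. Per-window random streams derive from one
explicit seed by a fixed counter scheme (`default_rng([seed, window])`),
making every record bit-reproducible.

The reference stochastic test system is one steered center coupled
through a chain of springs to two free particles: integrating the free
particles out leaves an exactly harmonic PMF with k_eff = (Σ 1/k_i)⁻¹,
so both the mean forces and the reconstructed PMF have closed forms to
recover. Recovery within 3 propagated sigma at every grid point, and
two-run convergence, are checked at 26 windows × 2000 samples (a few
seconds of compute); these sizes are the package's test conditions, and
the same machinery runs unchanged at finer schedules.

## Generalized Born / surface-area decomposition

- **Electrostatics and Lennard-Jones.** Plain Coulomb q_iq_j·k_c/r and
  12-6 LJ in the Rmin/2 convention with Lorentz–Berthelot combination
  (Rmin/2 add, ε geometric), summed over all cross pairs with no cutoff —
  a post-processing convention; dynamics cutoffs belong to the engine
  that generated the trajectory, not to this analysis.
- **GB flavor.** The polar term uses pairwise-descreening effective Born
  radii with OBC-II rescaling (α = 1.0, β = 0.8, γ = 4.85), a 0.09 Å
  radius offset, element-wise descreening scale factors (H 0.85, C 0.72,
  N 0.79, O 0.85, S 0.96, P 0.86, else 0.8), interior dielectric 1.0 and
  exterior 78.5, no salt screening. The flavor and radii set are
  declared assumptions — common defaults for this kind of
  decomposition — surfaced in the configuration and logs; the pairwise
  descreening integral was derived by shell integration and is verified
  against direct numerical quadrature in the tests. The interaction part
  uses the single-trajectory convention: unbound terms are evaluated on
  the complex geometry with radii recomputed per group.
- **Nonpolar term.** ΔG_nonpol = γ·SASA + β with γ = 0.005
  kcal/(mol·Å²) and β = 0. β is a per-state constant that cancels in the
  interaction difference and is therefore not spread over residues. The
  surface area is LCPO: per-atom linear combination of the isolated-atom
  area, pairwise buried-cap areas, and the neighbor-pair correction
  terms, on probe-expanded (1.4 Å) spheres; hydrogens carry zero area.
- **Per-residue assignment.** Two modes. `half` splits every pair term
  half/half between the two residues (GB self terms to their own atom),
  making the table conserve: rows over **both** sides sum exactly to the
  directly computed interface total of each term, which is the
  conservation identity the acceptance suite checks to 1e-6 kcal/mol.
  `full` assigns cross pairs at full weight to the focal residue — the
  residue-to-whole-partner energy conventionally quoted with the
  |ΔG| ≥ 5 kcal/mol key-residue filter — and double-counts across sides
  by construction; for ΔG_pol it keeps only cross terms at complex
  radii, omitting intra-group radii-relaxation, so no conservation is
  claimed for it.
- **Snapshot policy.** N evenly spaced frames, default 150.

The LCPO oracle test compares against a 10,000-point Shrake–Rupley
evaluation on random clusters generated with pairwise but no triple
sphere overlaps, using the geometrically exact coefficients P1 = 1,
P2 = −1, P3 = P4 = 0. In that regime the pairwise-overlap treatment is
exact up to the oracle's discretisation, which is what makes a 5% bound
meaningful for arbitrary random geometry; fitted per-atom-type
coefficient tables encode chemistry (bonded neighbors) that random
sphere clusters do not have. The P3/P4 triple-overlap machinery is
implemented and exercised through the same code path.

## Trajectory statistics

- **RMSD.** Unweighted Kabsch fit on the stated fit selection, RMSD
  measured on the measure selection; the reference is a frame or an
  external structure.
- **PCA.** Frames are superposed onto their average structure, iterated
  twice (fit → re-average → fit), before the 3m × 3m covariance is
  diagonalised; for frames with no rigid-body component (i.i.d.
  fluctuations about a fixed mean, as the Gaussian generator produces)
  superposition can be disabled, which is how the known-covariance
  recovery test avoids the small bias that removing six rigid-body
  degrees of freedom would introduce.
- **Clustering.** Pairwise best-fit RMSD (each frame pair superposed
  independently, batched 3×3 SVD), average-linkage agglomeration on
  every sieve-th frame, remaining frames assigned to the nearest cluster
  medoid under the same metric with ties to the lower cluster index;
  clusters relabelled by decreasing population. Sieve 1 therefore equals
  clustering without sieving.
- **Hydrogen bonds.** Donors are N/O with at least one bonded hydrogen
  (bond list from CONECT records or construction); acceptors are N/O.
  A bond exists in a frame when the acceptor–donor distance is strictly
  below 3.5 Å **and** the acceptor···H–donor angle (at the hydrogen) is
  strictly above 120°. Both boundaries are exclusive; the tests pin this
  convention at the exact floating-point boundary.
- **Native contacts.** The native pair list comes from the reference
  structure: residue pairs across the interface with any heavy-atom
  distance strictly below 3.5 Å. A frame retains a contact under the
  same single criterion (no relaxed "breaking" cutoff). Qb is the
  retained fraction; per-pair boolean timelines support
  contact-by-contact unbinding narratives, and `contact_map` gives
  residue×residue maps with their intersection across representative
  frames. Heavy atom means element ≠ H.

## Synthetic test beds: scope and limits

The generators plant the exact feature each statistic estimates:
contact-break schedules (Qb ground truth to the frame), hydrogen-bond
geometry switched on/off per frame, well-separated conformers with
sub-noise jitter, Gaussian coordinate fluctuations with a prescribed
covariance, and harmonic-chain force records with closed-form mean
forces. Passing these tests establishes the estimators' correctness —
that each computes the quantity it defines, at its stated tolerance —
on inputs where the answer is known. It does not establish anything
about real trajectories: synthetic beads have no force-field chemistry,
no correlated solvent motions, no conformational heterogeneity beyond
what is planted, and sample sizes are desk-scale. Applying the package
to production data exercises exactly the same code paths but inherits
all the usual sampling caveats of the data itself.

## Degenerate inputs and tie-breaks

Empty selections, fewer than 3 fit atoms, single-frame PCA, a reference
with no native contacts, non-PSD covariances, missing force-field or
LCPO parameters, overlapping atoms (r < 1e-6 Å), non-finite Born radii
and diverging Langevin trajectories all raise informative errors rather
than propagating NaNs. Cluster-assignment ties go to the lower cluster
index; equal-population clusters keep their agglomeration order
(stable sort). PMF profiles are anchored at W(0) = 0; comparisons
re-anchor both operands first.

## Known limitations

- GB radii-relaxation cross-talk means the `full` per-residue polar
  values are a reporting convention, not an exact partition (see above).
- Window-independence in the PMF error bars underestimates uncertainty
  if windows are seeded from each other's final states with short
  equilibration.
- LCPO inherits its accuracy from the coefficient table supplied; with
  fitted biomolecular coefficient sets its error against numeric SASA is
  a property of that fit, not of this implementation.
- The PDB reader targets ordinary ATOM/HETATM/MODEL/TER/CONECT records;
  insertion codes are not modelled (residue identity is chain + id), and
  altloc handling keeps the first location.
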