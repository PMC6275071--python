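# unbindkit

Tools for characterising how a biomolecular complex holds together and
comes apart: reconstruction of the potential of mean force (PMF) along a
multi-center steering path, per-residue implicit-solvent interaction
free-energy decomposition across a binding interface, and the trajectory
statistics (RMSD, radius of gyration, covariance PCA, clustering,
hydrogen-bond occupancy, native binding contacts) used to describe
binding and unbinding — together with a synthetic-data layer that
generates every input with analytically known ground truth, so each
estimator is testable end to end.

It is written for structural/computational biophysicists post-processing
steered and equilibrium simulations of protein–RNA or protein–protein
complexes, where the raw trajectories come from an external MD engine and
what remains is the estimation problem.

## The methods

**PMF by thermodynamic integration in 3n dimensions.** When n centers
(e.g. three Cα or C1′ atoms fixing a molecule's position and orientation)
are dragged along a path u(λ) through their 3n-dimensional configuration
space, the PMF is a state function whose change is the line integral of
the mean constraint force:

```
W(u_b) − W(u_a) = −∫ ⟨F⟩ · du
```

where ⟨F⟩ is the ensemble-average force the rest of the system exerts on
the clamped centers. The path is divided into displacement windows (by
default every 0.1 Å near the bound state, 0.2 Å and then 0.4 Å further
out); each window is equilibrated and then sampled in four segments, whose
spread gives the per-window standard error; trapezoidal quadrature with
full error propagation yields W(d) ± σ(d), and independent repeat runs are
compared point by point for convergence.

**Interface free-energy decomposition.** The interaction energy between
groups A and B is split per residue into

```
ΔG = ΔE_ele + ΔE_vdw + ΔG_pol + ΔG_nonpol
```

with Coulomb and 12-6 Lennard-Jones cross sums (no cutoff), generalized
Born polar solvation (OBC-II effective radii, Still interaction function)
in the single-trajectory convention, and γ·SASA + β nonpolar solvation
(γ = 0.005 kcal/(mol·Å²), β = 0) with LCPO surface areas. The half-pair
table conserves — rows sum exactly to the directly computed interface
totals — while the full-pair mode reports the conventional
residue-to-whole-partner energies for key-residue ranking.

**Trajectory statistics.** Kabsch-superposed RMSD, (mass-weighted) radius
of gyration, PCA of the positional covariance with cumulative variance
fractions, average-linkage agglomerative clustering on pairwise best-fit
RMSD with sieving, geometric hydrogen-bond occupancy (acceptor–donor
< 3.5 Å and acceptor···H–donor angle > 120°, strict inequalities),
group mass-center distances, the fraction of native binding contacts Qb
(residue pairs with any heavy-atom distance < 3.5 Å in the reference),
and residue contact maps with their intersection across representatives.

## Worked example

`examples/01_pmf_reconstruction.py` drags a steered center through a chain
of harmonic springs (k = 4, 6, 8 kcal/mol/Å², so the exact PMF is
harmonic with k_eff = (1/4 + 1/6 + 1/8)⁻¹ ≈ 1.846), samples constraint
forces by Langevin dynamics in 26 windows of four segments each, and
reconstructs:

```
windows: 26, samples/window: 2000 (4 segments)
PMF at 5.0 Å: 23.046 ± 0.053 kcal/mol   (exact: 23.077)
max |ΔPMF| between the two runs: 0.0577 kcal/mol -> convergent: True
```

The reconstructed well depth matches the closed form within one
propagated standard error, and two independent-seed runs agree — the
convergence evidence a steered study reports. The other examples follow
the same pattern: `02` prints a per-residue decomposition table whose row
sums equal the directly computed interface totals, `03` recovers planted
contact schedules (Qb stepping 1.0 → 0.0 exactly as planted), covariance
eigenvalues (4.005, 1.011 for planted 4, 1), conformer clusters and a 0.7
hydrogen-bond occupancy, and `04` runs the whole pipeline with a hashed
manifest.

A thin CLI wraps the same entry points
(`unbindkit run|synth|pmf|decompose|analyze`).

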