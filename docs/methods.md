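# Methods

## Scope and model

`edchiro` covers the analysis that sits between a finished MD simulation
of a solvated, ligand-protected nanocluster and its ensemble-averaged
electronic circular dichroism: essential-dynamics reduction, free-energy
landscapes by Boltzmann inversion, conformer and solvation-shell
extraction, structural descriptors, Boltzmann-weighted Lorentzian spectral
averaging, and chirality quantification. It does not run MD and does not
compute electronic structure; stick spectra (energies, rotatory strengths,
optional fragment labels) are consumed as data.

## Essential dynamics

The covariance of the atomic Cartesian coordinates is taken over the
solute subset, unweighted. Frames are first superposed (Kabsch,
unweighted, proper rotation) onto an iteratively refined mean: frame 0
seeds the reference, two refinement passes re-fit all frames to the
running mean, and a final pass fits to the returned mean so that the
stored mean and the fitted frames are exactly consistent — projections of
the model's own trajectory then equal the SVD scores to round-off, and
the full-mode reconstruction identity (mean + Σ_j c_j v_j = aligned
frame) holds to < 1e-8 nm. Fitting to the mean rather than to frame 0 is
the default because the mean is the structure the covariance is taken
about; frame-0 fitting is available through the same superposition
primitives.

With n_frames ≪ 3·n_atoms the eigensystem comes from an SVD of the
centred data matrix rather than from the explicit 3n × 3n covariance;
eigenvalues below zero by round-off are clipped, and each eigenvector's
first non-negligible component is made positive so projections are
reproducible across runs and BLAS builds. Mass-weighting is deliberately
absent everywhere (superposition, covariance, projection); the RMSD
primitive documents the same choice.

## Free-energy landscape and basins

ΔG°(i) = −RT ln(P(i)/P_ref) with R = 8.314 J mol⁻¹ K⁻¹, T defaulting to
300 K, P_ref the maximum bin probability; the reference bin therefore sits
exactly at 0 and unoccupied bins carry +inf (a rendering ceiling, never
0). ΔG° is invariant under uniform rescaling of counts by construction.

Basins are 4-neighbour connected components of occupied bins with
ΔG° below a cutoff (2.5 kJ/mol for the bare solute, 1.0 kJ/mol for
solvated-cluster landscapes; 8-neighbour adjacency is available).
Labels B1, B2, … follow ascending minimum ΔG°, ties broken by larger
probability mass. Note that lowering the cutoff shrinks the basin mask
monotonically but can *split* a component in two; the nesting of basin
bins, not the component count, is the monotone quantity.

Bin count: the production default is 50 × 50 over the data range padded
by 2%. For desk-scale trajectories the pipeline's "auto" rule instead
takes ⌈√(n_frames/20)⌉ bins per axis (bounded to [10, 50]), i.e. ≈ 20
frames per bin per axis — at 5000 frames that gives 16 bins, which puts
one bin at roughly one basin width for the synthetic conditions below and
keeps occupied-bin counts in the tens.

Inter-basin free energies read off single peak bins are Poisson-noisy
(relative error ≈ 1/√count per peak). `inter_basin_free_energy` therefore
averages the top-5 bins of each basin before inverting; for basins of
comparable width the inter-basin ratio is unbiased and the noise drops by
≈ √5. The `Basin.min_delta_g` field keeps the raw single-bin minimum.

## Conformer extraction

Per basin, the representative is the frame nearest (Euclidean, essential
plane) to the basin's probability-weighted centroid — a deterministic
rule, ties broken by lowest frame index. Additional density peaks of the
same basin contribute extra representatives only when their fitted RMSD
to every already-retained representative exceeds the threshold (default
0.17 nm), reproducing the situation where one landscape region holds two
structurally distinct conformers (labelled -A, -B). Conformer ΔG° is the
basin minimum; conformer probabilities are the normalized Boltzmann
weights of those ΔG° values.

## Solvation shell

The solute's ellipsoid is fitted from its (optionally mass-weighted)
gyration tensor with semi-axes √(5 λ_k) — exact for a uniform solid
ellipsoid. The squared ellipsoidal distance d² = Σ_k ((x−c)·û_k/a_k)²
is 1 on the surface and reduces to |x−c|²/r² for a sphere. The ellipsoid
is fitted once per constrained trajectory (the solute is frozen there)
and reused for every frame. Waters are ranked by their *oxygen's* d² and
selected whole — molecules are never split across the shell boundary;
ties break on molecule id, and growing N strictly nests the selection.
The default N = 126 comes from the site-counting heuristic
(sites per ligand − intramolecular sites) × n_ligands = (9 − 2) × 18,
with the per-ligand counts exposed as inputs rather than hard-coded.

Descriptors: Rg is the mass-weighted RMS distance from the centre of
mass. SASA is Shrake–Rupley with probe 0.14 nm and a deterministic
Fibonacci-lattice sphere mesh (default 960 points/atom; fewer than 16 is
refused); determinism means repeated runs agree bit-for-bit. Hydrogen
bonds use the de facto geometric criterion: donor–acceptor distance
≤ 0.35 nm and H–donor–acceptor angle ≤ 30°, scoped to intra-solute,
solute–water or water–water pairs; same-molecule pairs never count.

## Spectra

Broadening uses a unit-area Lorentzian per line,
I(E) = Σ_k R_k (ε/π)/((E−E_k)² + ε²), HWHM ε = 0.15 eV by default. The
unit-area convention (not peak-height-1) is chosen so the integral of the
spectrum equals the summed rotatory strengths and broadening commutes
exactly with linear combination — ensemble averaging before or after
broadening is identical to round-off, and a with/without-solvent
difference spectrum equals the broadened stick difference. Rotatory
strengths are carried in their input units (typically 10⁻⁴⁰ cgs) and
never converted to molar Δε; intensities are "strength units per eV".

Boltzmann weights use the max-shift trick and are invariant under a
constant ΔG° shift. Restricting to a conformer subset *re-derives* the
weights from the stored ΔG° values (it does not rescale old
probabilities) — the two are algebraically identical here but the ΔG°
route is the contract. The bundled 13-conformer reference table
reproduces its published probability column at two significant figures;
one entry (B1-2, computed 0.0905) sits half a printed ulp from its
published 0.090, so table comparisons use one-unit-in-the-last-digit
tolerance.

## Hausdorff chirality measure

HCM = min over proper rotations (after centroid alignment) of the
Hausdorff distance between the point set and its mirror image, divided by
the set diameter; values lie in [0, 1) and vanish for achiral (e.g.
planar) sets. Minimization is a vectorized z-y-z Euler grid at 15° steps
followed by Nelder-Mead refinement of the best grid point. Mirroring uses
the z-reflection; any other improper operation differs from it by a
proper rotation, which the search covers. The measure is invariant under
rigid motion, uniform scaling, and enantiomer exchange. A 2°-grid
brute-force search (independent rotation-matrix construction) agrees with
the coarse-plus-refine route to < 1e-3 on a fixed chiral fixture.

## Synthetic data: what it does and does not emulate

`make_planted_trajectory` builds frames as reference + Σ_k c_k(t)·mode_k
+ isotropic Gaussian noise, with mode amplitudes drawn from a Gaussian
basin mixture. The planted modes are random orthonormal 3n-vectors
projected out of the 6-dimensional rigid-body subspace, so they are
genuine internal motions and survive superposition. Ground truth (modes,
per-frame basin assignment, exact −RT ln occupancy-ratio ΔG°) is returned
alongside. Default desk-scale conditions: 30 atoms, 5000 frames, two
modes, basins at 0 and 0.5 nm along mode 1 with width 0.06 nm and
occupancies 0.8/0.2, noise 1e-6 nm². These trajectories have no
anharmonic coupling, no solvent degrees of freedom and no kinetics —
passing recovery tests shows the estimator chain is correct, not that a
250 ns production trajectory would be converged.

`make_solvated_frame` places rigid 3-site waters with oxygens at exact
assigned ellipsoidal distances around a solute sampled uniformly inside
the requested ellipsoid; the construction itself is the selection oracle.
Water geometry beyond the O–H bond length is not physical.
`make_stick_spectra` draws line energies uniformly and strengths from a
zero-mean Gaussian with random fragment labels; a solvent-free variant
drops all water-labelled lines. All generators are pure functions of
(spec, seed).

## Problem sizes and tolerances

Recovery suites run 10 fixed seeds at 5000 frames; basin count is exact,
inter-basin ΔG° within 0.5 kJ/mol (top-5 estimator), essential-plane
subspace angle < 5°. Spectral identities hold to 1e-12 (linearity) or 1%
(quadrature over a wide grid). I/O round-trips are asserted at each
format's declared precision: XYZ 1e-8 nm (9 printed decimals), GRO
6e-4 nm (3 decimals in nm), PDB 6e-5 nm (3 decimals in Å).

## Known limitations

- Landscapes are strictly 2-D; no ≥3-mode histograms or kinetic
  (rate/transition) analysis.
- The ellipsoid convention (gyration tensor, √5 scaling) is one declared
  choice; surface-distance metrics would rank waters slightly
  differently near the poles of elongated solutes. The convention is
  isolated behind `EllipsoidModel`.
- Periodic-boundary re-imaging is a minimal whole-molecule shift pass and
  assumes orthorhombic boxes; frames are expected pre-imaged.
- HCM's grid-plus-refine search is not a certified global optimum;
  the dense-grid cross-check bounds the error on small point sets only.
- No plotting; exports are delimited text and JSON that plot directly.
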