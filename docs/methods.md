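# Methods

This note documents the models implemented in `crypticpocket`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the protocol left the
design open.

## Ensemble representation and superposition

A `ConformationalEnsemble` is an F × A × 3 coordinate array in Å plus a
per-atom table (serial, name, element, residue, chain, insertion code,
heavy-atom flag) and per-frame provenance (replica id, time in ns, source).
Multi-model PDB files are read through biotite with alternate locations
resolved to the highest-occupancy conformer (ties by altLoc label order);
insertion codes are kept and treated as distinct residues; hydrogens are
retained if present. Any trajectory reader that yields per-frame A × 3
arrays can feed the same container via
`ConformationalEnsemble.from_frames`. Residue numbering is 1-based as in
the PDB; internal atom indices are 0-based. An atom is "heavy" when its
element is not H/D, decided by the element column with an atom-name
fallback for files with a blank element field.

Frames are superposed by least-squares rigid-body fitting (Kabsch, SVD with
determinant correction so reflections are never applied), batched as one
3 × 3 SVD per frame. The fitting reference is an **iterative mean
structure**: seed with frame 0, superpose all frames, recompute the mean,
repeat until the mean moves less than 1e-4 Å RMSD (max 50 iterations). The
protocol this implements does not fix a reference; the iterative mean is
the standard unbiased choice for a subsequent coordinate PCA, and the
result is deterministic given frame order. The mean is defined only up to a
global rigid motion, which is irrelevant downstream because PCA centers the
coordinates. Fits with fewer than three non-collinear atoms are rejected as
degenerate.

## Loop-atom PCA

PCA operates on the 3N coordinate vector of the selected loop heavy atoms,
mass-unweighted and unscaled, with **population (1/F) covariance
normalization** — at trajectory-scale frame counts the 1/F vs 1/(F−1)
distinction is immaterial but a convention is required. The decomposition
is computed through the thin SVD of the centered frame matrix (equivalent
to diagonalizing the 3N × 3N covariance, stable for large F); modes with
numerically zero variance (below 1e-12 of the total) are dropped.
Eigenvector sign is fixed by making each mode's largest-magnitude component
positive, so outputs are bit-reproducible. Pooling frames across replicas
or starting structures is plain concatenation. A subsampling stride is the
caller's responsibility; nothing in the math assumes a particular frame
density.

## Free-energy surface and watershed clustering

The PC1/PC2 projections are histogrammed on a default 100 × 100 grid whose
edges span the data range padded by one bin per side. The raw histogram is
regularized with a small Gaussian kernel (**σ = 2 bins** by default) before
normalization: a finite sample scatters shot noise across thousands of
bins, and without regularization that noise carves spurious minima into the
inverted surface. The kernel width is far below the bin-space footprint of
any metastable state at these grid sizes and never zeroes an occupied bin,
so every frame stays assignable; σ = 0 disables smoothing.

Boltzmann inversion sets G = −kT ln(p/p_max), so the global minimum is at
G = 0; kT defaults to 300 K in kcal/mol (0.5962). Empty bins carry a finite
sentinel, max finite G + 3 kT, never NaN.

Watershed flooding processes occupied bins in order of increasing (G,
row-major index). A bin with no already-assigned 8-neighbour seeds a new
basin (it is a local minimum under that total order); otherwise it joins
the basin of its lowest-G assigned neighbour, ties again broken by
row-major index. This is provably equivalent to steepest-descent
assignment with the same tie rule (the test suite checks the equivalence
exhaustively on small grids), and is independent of frame order.

Two merge rules clean the raw flood, both deterministic:

* **Barrier persistence** (default 1 kT): a basin whose lowest pass to a
  neighbour, minus its own minimum, is below the threshold is absorbed into
  that neighbour. Sub-kT corrugation of a sampled surface is noise, not
  metastability.
* **Minimum population** (default 0, i.e. off): basins holding fewer than
  the given fraction of frames merge into the neighbour with the lowest
  shared-boundary pass; island basins with no occupied-bin adjacency merge
  into the nearest basin in bin space.

Basin populations are fractions of assigned frames; each basin reports its
minimum bin and a **medoid representative** — the frame minimizing the
summed squared PC-space distance to its basin mates (equivalently the frame
nearest the basin centroid; ties go to the lowest frame id). Second-stage
subclustering re-superposes one family's frames onto their own iterative
mean, refits the PCA, and reruns density → inversion → watershed in the
refit subspace. How the original protocol clustered within conformational
families is not fully specified; the refit-PC-subspace watershed
implemented here is one committed interpretation.

## Grid volumetrics

Cavity measurement follows the Epock-style protocol: a regular grid of
spacing 0.5 Å spans the bounding box of an **including sphere** (default
radius 6.0 Å) and is registered so the sphere center lies on a grid point,
making volumes translation-reproducible. A point is *free* iff it is inside
the including sphere, outside every excluding sphere, and farther than
(vdW radius + probe) from every atom center. Radii are the Bondi set
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å …), probe radius defaults to 0 to
mirror a default-parameter cavity run; both are configurable. The pocket is
the contiguous component of free points reachable from a seed (default: the
including-sphere center, falling back to the nearest free point within the
cutoff), where contiguity means "within the 4 Å contiguous cutoff",
computed as connected components of the distance graph so the result is
order-independent. Volume is exactly n_points × spacing³. The published
wording of the contiguous-cutoff parameter is ambiguous between a
contiguity radius and an atom-distance bound; the contiguity reading is
implemented. Molecular (ligand) volumes use the same occupancy grid over
the union of vdW spheres, registered on the first atom so an isolated
sphere is sampled symmetrically. Pocket lining residues are those with at
least one heavy atom within 4.5 Å of the component.

The independent check for all of this is a deliberately plain fine-grid
oracle (0.1 Å spacing, single nearest-neighbour query, uniform radii) that
lives with the synthetic fixtures, not with the production code.

## Druggability score

Descriptors of a pocket component: volume (Å³); apolar fraction of lining
heavy atoms (element C or S); polar lining atoms (N/O) per 100 Å³;
enclosure, the fraction of 146 quasi-uniform rays (Fibonacci sphere) from
the component centroid that hit a protein atom's vdW sphere within 8 Å; and
the fraction of lining residues in the apolar class
{Ala, Val, Leu, Ile, Pro, Phe, Met, Trp, Cys}. Atom polarity is decided by
element rather than partial charge — simpler and directly testable.

The score is a logistic,

    score = σ(−9.5 + 4.0·apolar + 3.0·enclosure + 1.0·ln(1+V) − 0.6·polar_density),

strictly inside (0, 1), increasing in apolar fraction and enclosure,
decreasing in polar density. The reference druggability model this emulates
does not publish coefficients, so these were fit once, by hand, to four
synthetic calibration descriptor fixtures — a hydrophobic enclosed pocket
(score ≥ 0.8), a shallow all-polar groove (≤ 0.1), a mixed medium pocket
(0.5 ± 0.15) and a tiny pocket (≤ 0.2) — and frozen as the default
configuration. Scores are comparative, not absolute affinities.

## Trajectory metrics

RMSD profiles over replica sets report, per time point, the mean over
replicas of each frame's RMSD to the reference and the RMSD of the
across-replica average structure; convexity guarantees the second never
exceeds the first, and the spread between them distinguishes ensemble
diversity from collective drift. Hydrogen bonds are scored as heavy-atom
donor–acceptor distances (default cutoff 3.5 Å, no angle term, since only
distances are reported upstream); salt bridges as charged-group minimum
distances (default 4.0 Å). Inter-group distances aggregate as the minimum
heavy-atom pair distance by default (center-of-geometry mode available);
where published "contact distance" aggregation rules are unstated, minimum
distance is the committed interpretation. Occupancy is the fraction of
window frames at or below the cutoff, the window defaulting to the final
40 % of frames; motif occupancies are counted on frames satisfying all
member cutoffs simultaneously, never multiplied from marginals.

## Synthetic generators

All generators are pure functions of (spec, seed), using numpy's PCG64.

* **Two-state loop ensembles** ride on a deterministic ~50-residue
  three-loop scaffold (three heavy atoms plus one hydrogen per residue, so
  heavy-only selections like "8–14" are meaningful). Frame states are
  i.i.d. Bernoulli(π_out); the *out* state adds a smooth, tapered per-atom
  displacement field (default 3 Å peak, matching a loop-opening scale that
  clearly separates states); isotropic Gaussian noise (default 0.3 Å per
  coordinate) models intra-state fluctuation; optional extra collective
  modes add Gaussian-amplitude motions. I.i.d. frames are the right null
  for an analysis that pools frames across many independent replicas; a
  Markov-switching variant is deliberately out of scope of the validation
  contract.
* **Cavity fixtures**: an empty including sphere (analytic volume), a solid
  atom lattice (spacing 1.0 Å ≤ 1.2 Å, radius 1.5 Å; zero cavity), and a
  hollow shell with a carved spherical cavity whose reference volume comes
  from the 0.1 Å fine-grid oracle. Shells thinner than one atom diameter
  are rejected as leaky.
* **Contact series** draw each frame from a bound or unbound Gaussian
  (defaults N(2.9, 0.15) and N(6.0, 0.8) Å, a hydrogen-bond-like contrast)
  per a Bernoulli(occupancy) label, truncated positive.

What the generators do *not* emulate: physics. There is no force field, no
solvent, no kinetics, no anharmonicity beyond the state mixture, and no
correlation between frames. Passing tests therefore demonstrate that the
analysis recovers the statistical structure it assumes — populations,
displacement geometry, cavity volumes, occupancies — not that any
particular real protein has a cryptic pocket.

## Problem sizes and determinism

The validation suite runs at deliberately desk-sized scales: 10³–2 × 10⁴
frames, ≤ 200 selected atoms, 100 × 100 free-energy grids, 0.1–0.5 Å
volumetric grids. These sizes are where the statistical contracts (binomial
and multinomial bounds, ±0.02–0.03 population tolerances) are meaningful
and the oracles exhaustively checkable; every routine scales to larger
ensembles without modification. All randomness flows through explicit
seeds; the pipeline writes its full parameter set to the run log and
reproduces `summary.json` byte-identically on rerun.

## Known limitations

* Free-energy surfaces live in the PC1/PC2 subspace only; slow motions
  orthogonal to the leading modes fold into basin breadth.
* Basin counts depend on histogram granularity, smoothing and the merge
  thresholds; populations are robust to these choices but cluster counts on
  real data should be read as resolution-dependent.
* Grid volumes carry ±(half-cell × surface area) discretization
  sensitivity near boundaries; halving the spacing changes fixture volumes
  by under 3 %.
* The druggability coefficients are a committed reconstruction calibrated
  on synthetic fixtures; rank order is meaningful, absolute values are not
  transferable to other scoring programs.
* No solvent-excluded-surface volumes, no alpha-sphere pocket detection,
  no secondary-structure assignment, no docking and no kinetic modelling.
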