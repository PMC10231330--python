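# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic studies do and do not demonstrate.

## Coordinate and unit conventions

Coordinates are Ångström internally. Nanometres appear at reporting
boundaries: PCA projections and eigenvalues, free-energy-landscape axes,
SAXS momentum transfer q (nm⁻¹) and radii of gyration. Residue numbering is
1-based with inclusive intervals, following the deposited numbering of the
tandem SH2 construct: N-SH2 = residues 3–104, linker = 105–111, C-SH2 =
112–216, PCA/clustering atom set = Cα of 12–215 (flexible termini
excluded). Structures from accessions with different numbering are
reconciled by an explicit residue-offset configuration, not by sequence
alignment.

## Geometry

Superposition is Kabsch least squares with the standard determinant
correction (the sign of the smallest singular vector is flipped when the
optimal orthogonal matrix would be a reflection); inputs with fewer than
three non-collinear point pairs raise a degenerate-fit error. RMSD and PCA
use unweighted Cα coordinates; gyration tensors are mass-weighted by
default. The gyration summary reports the square roots of the sorted
eigenvalues of the gyration tensor (so rg² equals the sum of squared
components exactly); the per-axis ("about-axis") components used by common
MD tooling are recovered as √(rg² − λᵢ), and it is in that convention that
a prolate particle shows one small and two large components.

## Essential dynamics

PCA fits all conformers to the running mean iteratively (default
tolerance 10⁻⁶ nm shift, maximum 10 iterations) before accumulating the
population covariance of the flattened Cα coordinates; eigenvalues are
reported in nm² together with cumulative fluctuation fractions. Projection
of an external structure superposes it onto the stored mean over the fit
selection first, making projections invariant under rigid motion of the
input. The free-energy landscape is g = −kT ln(n/n_max) over a 2-D
histogram of (PC1, PC2), with empty bins masked and the most populated bin
at exactly zero; kT defaults to 2.494 kJ/mol (300 K). Clustering is the
GROMOS neighbour-counting algorithm with a configurable fit-RMSD cutoff
(default 0.3 nm): ties in neighbour count break to the lowest conformer
index, and cluster ids are assigned in order of decreasing population. The
all-pairs fit-RMSD matrix is computed with a batched Kabsch
(singular-value) formula.

## RDC model

A coupling is D = D_max · eᵀ S e with S the traceless symmetric Saupe
matrix. D_max is computed from physical constants with effective bond
lengths r(N–H) = 1.041 Å, r(N–C′) = 1.329 Å, r(C′–Cα) = 1.525 Å; the
two-bond H–C′ distance is measured per structure by default (fixed 2.05 Å
optional). N–C′ and H–C′ couple residue i's amide to residue i−1's
carbonyl. Missing amide protons are constructed in the C′(i−1)–N(i)–Cα(i)
plane opposite the bisector; prolines never carry amide-proton couplings.
Fits solve the M×5 (or block M×5N) design by SVD; the multi-tensor scheme
uses truncated SVD with a relative singular-value cutoff (default 10⁻⁶) and
reports the effective rank. Weights over template structures are uniform
unless given; 1/σ² weighting of records is optional and off by default.

An identifiability caveat discovered during development: for ensembles
whose conformers are built from the *same two rigid domains* (as the
synthetic generator does), the ensemble-averaged couplings determine only
the two domain-frame-averaged tensors Σᵢ wᵢ GᵢᵀSᵢGᵢ — ten numbers in total
regardless of ensemble size — so per-conformer tensors carry gauge freedom
and the truncated-SVD solution is the minimum-norm representative. The fit
quality and the frame-averaged tensors are well-defined and are what the
tests assert. Real ensembles (and MD frames) have per-conformer internal
geometry differences that break this degeneracy.

## SAXS

The predictor is a deliberately coarse one-bead-per-residue Debye model:
beads sit on Cα positions and carry the residue's electron count, with a
shared Gaussian form-factor decay exp(−(qσ_bead)²/2), σ_bead = 3 Å by
default. Solvent-excluded volume and the hydration layer are not modelled,
so absolute agreement with measured curves (e.g. the depth of scattering
minima) is outside the model's scope; internal consistency is exact and is
what the tests check: the vectorized pair sum equals a naive double loop to
10⁻¹⁰ relative, I(0) = (Σfᵢ)² exactly, rigid motions leave I(q) unchanged,
and the Guinier radius of a point-bead curve matches the bead-cloud
gyration radius (a Gaussian bead width σ adds 3σ² to the apparent Rg²,
which the tests account for). The Guinier window is determined
self-consistently (fit, recompute the q·Rg ≤ 1.3 bound, refit, ≤20
iterations). χ² is reduced by default with a fitted scale and an optional
offset; the calculated curve is interpolated onto the experimental grid
with no extrapolation.

## Linkage screening

Peptide-bound single-domain templates are superposed onto each tandem
conformation over the Cα atoms of shared residues (minimum support 20
atoms). The head-to-tail distance is the distance from the backbone C of
the N-domain-bound peptide's +6 residue to the backbone N of the
C-domain-bound peptide's −4 residue (pY = 0 numbering); tail-to-head swaps
the roles. Threshold fractions (default 40 Å) come with Wilson 95%
intervals. The linker-clash test samples the straight anchor–anchor
segment every 0.5 Å and flags samples within 2 Å of a heavy atom — a
declared simplification standing in for an unspecified published
procedure, so Yes/No clash labels for specific crystal structures are
heuristic-dependent. Steric openness counts N-SH2 heavy atoms within a
cutoff (default 2.5 Å) of catalytic-domain atoms after C-SH2 anchoring on a
full-length reference.

## Synthetic ensembles and their ground truth

Pseudo-domains are compact self-avoiding Cα walks (3.8 Å spacing,
non-adjacent pairs ≥ 3 Å, radius target 2.4·n^⅓ Å) decorated with
idealised backbone N, C′, O and amide-H positions — geometrically sane and
orientationally diverse, but not Ramachandran-derived folds. The tandem is
assembled from two such domains joined by a 7-residue Cα-only linker trace
(constrained random bridge). Pose distributions are explicit basin lists
(axis–angle rotation, translation, Gaussian spreads, weights); the default
constructor solves each basin's translation so the linker can close and the
mean pose is clash-free, emulating a free-energy landscape with a few broad
interdomain-orientation minima and a conserved prolate overall shape (the
study conditions use 2–3 basins with 10–12° angular and 1.5 Å translational
spreads). The basin label is drawn per conformer *before* rejection
sampling of the pose within the basin, so planted basin weights are
preserved exactly.

Surrogate alignment tensors take their principal axes from the conformer's
gyration tensor and their eigenvalues from (magnitude, rhombicity), with
the axial magnitude scaled by the relative shape anisotropy by default —
steric alignment is stronger for more elongated particles, and the scaling
makes per-conformer tensors genuinely distinct. This is a stand-in with the
right covariance behaviour, not a physical alignment prediction. Simulated
observables are ensemble averages plus Gaussian noise (RDCs: additive, in
Hz; SAXS: multiplicative with relative s.d. a + b·q).

What passing tests therefore show: the *analysis machinery* is correct
(exact oracles, covariances, parameter recovery under the generator's own
forward models). What they do not show: agreement with any experimental
dataset, absolute SAXS features, or the numerical values that depend on
long MD trajectories (mode fractions near 90%/60%, Rg ≈ 2.2 nm, the
11%/0.2%/21%/27% linkage fractions, correlations against measured
couplings). Those are reported by the pipeline when such data are supplied,
never asserted.

## Restrained refinement

The refinement is rigid-body Metropolis Monte Carlo over the pose of one
domain relative to the other, one replica per starting conformer, with the
restraint energy on the replica-averaged couplings (k calibrated so the
initial energy per coupling is ~1 when not set). Moves combine a rotation
about the mobile domain's centroid (≤8° by default, with a 10% admixture of
large rotations up to 180° that lets replicas hop between pose basins) and
a translation (≤1.5 Å); proposals that overstretch the linker span
([3.8, 30.4] Å) or bring interdomain Cα pairs closer than 4 Å are rejected
outright. The Metropolis temperature can be annealed geometrically
(the recovery studies use 0.5 → 0.005 over 2×10⁴ steps).

Tensor handling has two modes. The data-driven mode (default) refits each
replica's tensor to the observed couplings by SVD at a fixed interval and
freezes it in between — the protocol appropriate for experimental data.
Because a fitted tensor absorbs any rigid rotation of the whole replica
(covariance), this mode can rate even badly wrong starting poses at
r ≈ 0.9, which makes it insensitive as a recovery benchmark. The
parameter-recovery studies therefore use the geometric mode: the tensor is
recomputed from the replica's current shape (the same surrogate model the
generator used) inside every move, making the energy a consistent function
of the coordinates and closing the generative loop. Under those conditions
an 8-replica refinement started from 70–110° pose perturbations rises from
r ≈ 0.3–0.8 to r > 0.99 in 2×10⁴ steps (~20 s), while intra-domain
geometry is preserved exactly — rigid moves make the domain-integrity
check an identity rather than an approximation. Because refinement moves
only the domain pose, the linker Cα trace is rebuilt between the final
anchors for output.

The default replica count is 24 (matching the published protocol size);
the scaled-down studies use 8 replicas so the recovery run completes in
seconds — problem sizes throughout (16–100 conformers, ~800 couplings,
2×10⁴ MC steps) were chosen as the smallest at which the statistical
assertions are stable across seeds.

## Degenerate inputs and tie-breaks

Sphere-like conformers (relative gyration anisotropy < 0.05) are rejected
by the surrogate-tensor constructor as having undefined axes. Collinear
point sets raise degenerate-fit errors. Clustering and greedy sub-ensemble
selection break ties deterministically by lowest conformer index. All
generators and the refinement are bitwise reproducible under a fixed seed.
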