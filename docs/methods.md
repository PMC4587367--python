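# Methods

`mdtop` reimplements, as a tested pipeline over synthetic data, a "top-down"
comparative analysis of molecular-dynamics ensembles: several related systems
(a wild-type enzyme and point mutants of one residue) are sub-sampled into a
single concatenated "artificial trajectory", clustered jointly in pairwise-RMSD
space, and then compared in finer detail through collective motions,
fluctuations, solvation structure, hydrogen-bond networks and access tunnels.
This note records the models, conventions and numerical choices; every number
quoted here is computed by the test suite or the analysis drivers, not assumed.

## The synthetic study design

No real trajectories ship with the package; the `synthetic` module generates
ground-truth-labelled stand-ins for every analysis stage.

**Conformational ensembles.** A toy peptide topology (per residue: N, H, CA,
CB, O; one Cys-like SG start-point atom, charged side-chain tags on the
terminal residues) is simulated *statistically*: each frame is the reference
conformation of the currently scheduled conformational basin plus i.i.d.
Gaussian displacement of width σ per coordinate. Hydrogens ride rigidly on
their donor's displacement so donor–H bonds (< 1.2 Å) survive the noise; the
clustering selections (Cα/Cβ) are unaffected. Restart runs reuse the basin
active at their branch time with a fresh random stream, emulating re-seeded
velocities. This is an emulator, not MD: there is no force field, no inertia,
no kinetics — frames are exchangeable within a basin. Consequently passing
tests demonstrate correctness of the *analysis machinery* on data with the
assumed statistical structure (compact, well-separated conformational
basins), not robustness to slow drift, anharmonicity or correlated solvent
motion found in real trajectories.

**The five-system design.** The canonical layout has systems WT, F429A,
F429E, F429H, F429L (in that fixed concatenation order): WT and F429L occupy
private basins, the other three share one. Defaults: one 150 ns long run plus
two 10 ns restarts (branching at 60 and 130 ns) per system, frames every
20 ps, σ = 0.7 Å, basin separation 2.9 Å. The width and separation place the
intra-basin pairwise-RMSD mode near 0.17 nm (for isotropic per-coordinate σ
the pairwise RMSD concentrates near σ√6) and the inter-basin mode near
0.29 nm — the two histogram modes that motivate the 0.22 nm clustering
cutoff. Basin references are built from orthonormalised random displacement
fields arranged as a regular simplex in displacement space, with a single
global scale calibrated by fixed-point iteration so the mean pairwise
superposition-RMSD between references equals the requested separation; this
makes all basins mutually roughly equidistant, so validation indices are not
biased toward merging any particular pair.

**Channel bodies.** Tunnel fixtures are spheres of radius 1.5 Å on a jittered
cubic lattice (pitch 2.0 Å, jitter ±0.15 Å) filling a ball. Channel tubes and
a spherical start cavity (free radius 3 Å) are carved out and then *lined*
with explicit wall-sphere rings at the profile radius, so the free radius
along the axis equals the requested profile within the jitter rather than
being quantised by the lattice. The truth record carries the exact profile
minimum (bottleneck), the body radius (length) and the jitter (tolerance).

**Solvent.** Solvent centres are a homogeneous spatial Poisson process at the
bulk water number density (0.0334 Å⁻³ by default) thinned by radial shell
multipliers around a target atom — the exact construction of an inhomogeneous
Poisson process. Each frame is an independent draw, so solvent counts vary
per frame and the container is a dedicated `SolvatedFrames` object rather
than a fixed-atom-count trajectory.

**Hydrogen-bond series.** Scheduled donor–acceptor pairs are formed in a
Bernoulli(target-occupancy) subset of frames by repositioning the acceptor
relative to the frozen donor–H geometry (formed: 2.9 Å, 10° off-axis;
broken: 5.5 Å, 60°), giving exact per-frame truth.

## Artificial trajectories

A trajectory is divided into equal time chunks of one stride (defaults 80 ps
for scans, 40 ps for the final analysis set); one frame is drawn uniformly
from each chunk, excluding frames within 10% of the stride of either chunk
boundary (4 ps at 40 ps stride). Long runs first lose their initial 30 ns
relaxation prefix; restarts are sampled whole. Chunk counts use
floor(retained duration / stride), dropping a partial trailing chunk — this
floor convention reproduces the design's exact totals (five systems ×
[120 ns long + 2 × 10 ns restarts]: 8750 frames at 80 ps, 17500 at 40 ps,
7500 for long-runs-only at 80 ps). Provenance (system, source, original
time, truth basin) accompanies every concatenated frame.

## Superposition metrics

RMSD is the least-squares residual after optimal rigid superposition with a
proper rotation enforced; the core solve is scipy's `Rotation.align_vectors`
(Kabsch), cross-checked in the tests against a nested rotation-grid search.
Pairwise matrices use the closed-form residual from a batched 3×3 SVD of
cross-covariances. RMSF and PCA share one mean-structure convention: two
passes of superposition onto the running mean, then a final alignment onto
the converged mean (so projecting the fitting frames reproduces the fitted
deviations exactly). RMSF is √⟨|Δr|²⟩ per atom — for isotropic
per-coordinate σ this converges to σ√3. Internal units are Å; RMSD/RMSF are
reported in nm only at the output boundary.

The similarity-score centroid of a frame set maximises Σ_j exp(−rms_ij/σ)
with σ the population standard deviation of the off-diagonal upper triangle
of the RMSD matrix (the matrix has no other free scale; an unscaled
exponential variant would pick the same frame only when σ = 1). Ties break
to the lowest frame index.

## Clustering and validation

* **k-medoids (PAM):** seeded random initial medoids, assignment to the
  nearest medoid, then best-improving single swaps until the medoid set is
  stable; the objective is the within-cluster sum of *squared*
  member→medoid distances (variance-like, consistent with the WSS elbow);
  best of 10 restarts. Ties break to the lowest (medoid, candidate) pair.
* **GROMOS peeling:** the frame with most neighbours at `distance < cutoff`
  (strict, GROMACS-like) seeds a cluster and is removed with its neighbours;
  repeat; singletons allowed; ties to the lowest frame index.
* **Average linkage:** scipy agglomerative clustering cut at the distance
  threshold; cluster representatives are medoids (minimum summed distance).

Validation over a cluster-count scan: WSS (elbow), Dunn index = (minimum
inter-medoid separation) / (maximum intra-cluster diameter), maximal at the
best count, and Davies–Bouldin index = mean over clusters of the worst
(d_i + d_j)/d_ij with d_i the mean member→medoid distance and d_ij the
medoid–medoid distance, minimal at the best count. Since only the distance
matrix is available, every "centroid" is a medoid; coincident medoids make
DBI undefined and raise. Degenerate Dunn cases (all zero diameters with
positive separation) report +inf, i.e. perfectly separated.

Contingency tables count frames per (system, cluster); transitions are
counted only between time-consecutive frames of the same (system, source) —
never across concatenation boundaries.

## PCA

Mass-unweighted covariance of the 3n Cartesian Cα coordinates after shared
superposition, eigendecomposed with `eigh`; eigenvalues clipped of −1e−10
round-off, spectra below machine scale flushed to exactly zero (identical
frames are flagged degenerate rather than failing). Eigenvector signs are
fixed by making each vector's largest-magnitude component positive.
Projection re-superposes each frame onto the stored mean, so the per-frame
second moment of the scores equals the eigenvalue exactly.

## Solvation

g(r) uses the sphere-local normalisation: shell density of B around centres
A divided by the mean density of B *within the r_max sphere* (not the global
box density), averaged over frames and centres. This is exact for the
ideal-gas fixture and keeps g(r) defined for non-periodic neighbourhoods.
Defaults: bin width 0.1 Å, r_max 12 Å; periodic minimum-image convention
when a box is present, with r_max capped at half the smallest box edge.
Coordination numbers are direct counts within the cutoff (7 Å default),
averaged over frames; the rounded integer is reported alongside the mean
because the rounding convention of published integer counts is a
presentation choice.

## Hydrogen bonds and salt bridges

A pair is bonded when d(D,A) < 3.5 Å (strict) and the deviation angle
≤ 30° (inclusive). The default angle convention ("hda") is the angle at the
donor between the D→H and D→A directions — the deviation of the acceptor
from the donor–hydrogen axis, the GROMACS-style criterion; a literal
donor–hydrogen–acceptor angle of ≤ 30° is geometrically impossible for a
hydrogen bond, so the alternative "dha_deviation" convention (180° minus the
D–H···A angle) is provided behind a flag instead. Intra-residue pairs are
excluded; with several hydrogens per donor the minimum-angle hydrogen
represents the pair each frame. Occupancy is the detected-frame fraction;
lifetime filtering keeps bonds strictly above the threshold fraction (0.5
default, 0.6 exposed as the stricter reporting variant). Network diffs
compare above-threshold bond sets keyed by residue-level labels and require
both tables to share one labelling. Salt bridges use opposite-charge tagged
side-chain N/O atoms within 4.0 Å — a geometric stand-in, since charge tags
live in the topology, not in chemical perception.

## Tunnels

A regular grid (0.5 Å default spacing) covers the structure plus a 3 Å
margin. Free radius per node = distance to the nearest atom centre minus
that atom's vdW radius (clipped at 0); nodes at or above the probe radius
(0.7 Å proximal-type, 1.3 Å distal-type searches) are admissible. Exits are
admissible nodes outside the convex hull of the atom centres; in the
directed search graph exit nodes have no outgoing edges, so every shortest
path terminates at its *first* node outside the molecular hull — tunnel
lengths therefore measure start-to-surface, not start-to-grid-edge. Edge
cost is length / min(free radius at endpoints)^2 over 26-connected
neighbours (the exponent is configurable; 2 makes cost length- and
narrowness-sensitive), solved by sparse Dijkstra. Throughput is e^(−cost) ∈
(0, 1]. Multiple tunnels per frame come from accepting exits cheapest-first
with a 5 Å mutual separation. A start node below the probe raises a
distinct blocked-start error rather than reporting mere absence.

Tunnels across frames become pathways by average-linkage clustering of
path polylines resampled to 20 equidistant points (mean pointwise distance;
3–4 Å cutoff), ranked by mean throughput of the cheapest member tunnel per
frame. Bottleneck-lining residues are those whose vdW surface lies within a
1 Å shell of the bottleneck sphere surface.

vdW radii are the Bondi set, shipped as a literal for bit-reproducibility.

## Problem sizes and determinism

The analysis drivers and the test suite run the five-system design at
4 ns + 2 × 0.6 ns per system (≈ 250–550 sampled frames per frame set) —
large enough that all three clustering routes, the index scan, the PCA
silhouette and the RMSF contrasts resolve the planted structure with wide
margins, while the whole suite stays under a minute. The acceptance script
generates the *full* durations, since the frame-count identities are exact
and cheap at any size. Every random draw flows from named seeds through
`numpy` `SeedSequence` spawning; identical (spec, seed) inputs give
bit-identical outputs, and the pipeline writes byte-identical tables on
rerun.

## Known limitations

* The emulator has no kinetics: transition counts test bookkeeping, not
  rates; restart runs are statistically, not dynamically, branched.
* The tunnel search is a grid heuristic, not a Voronoi computation: radii
  and lengths are accurate to about one grid spacing, and the cost function
  is a documented package choice rather than a published constant.
* The free radius uses the nearest-centre convention (distance to nearest
  atom centre minus that atom's radius), which can overestimate clearance
  when a slightly farther atom has a much larger radius; with the
  near-uniform radii used here the effect is below the grid resolution.
* Occupancy statistics treat frames as exchangeable; autocorrelation in
  real trajectories would widen the binomial error bars used in the tests.
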