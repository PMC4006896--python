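# Methods

This note documents the models, algorithms and numerical choices behind
`spherecon`, the assumptions each one makes, and what the synthetic phantoms
do and do not demonstrate about real data.

## Equal-area sphere parcellation

Nodes are defined by dividing the unit sphere into *N* regions of equal area
and using the region centers as node reference points. We use a recursive
zonal scheme: a north and south polar cap whose spherical area is exactly
4π/N, and between them latitudinal collars, each cut into equal-angle
longitude cells. The number of collars follows from the ideal cell angle
√(4π/N); ideal per-collar cell counts are rounded while carrying the
rounding remainder so the total is exactly N, and the collar boundaries are
then recomputed so that *every* cell has area exactly 4π/N by construction
(band area is proportional to the difference of boundary-colatitude
cosines). Cell centers are the spherical centroids of the cells (the
centroid height z is the mean of the boundary cosines, projected back to the
sphere); cap centers are the poles. The construction is deterministic in N.

`SpherePartition.region_of` classifies points against these exact
boundaries (after undoing any applied rotation), which is what the
Monte-Carlo uniformity checks in the test suite sample. Rotations are
composed as Rz(θz)·Ry(θy)·Rx(θx) in degrees, applied to the centers and
tracked as a net rotation matrix.

**Scaling to an individual surface.** The literature behind this scheme
says only that the sphere is "scaled to the brain surface". We scale each
region center per axis by the surface's half-ranges ((max−min)/2 per
coordinate) and translate by the bounding-box midpoint. The midpoint is
used rather than the point mean because it makes the scaling exact for any
surface with a symmetric bounding box (a sampled sphere maps reference
points onto the partition centers themselves), independent of how the
surface points happen to be distributed. A PCA-aligned scaling could be
swapped in; we deliberately interpret no orientation metadata, since the
whole framework de-emphasizes anatomical location.

**Assignment.** Every surface point gets the label of the nearest scaled
reference point (Euclidean; ties broken toward the lowest node index for
determinism). Empty nodes are retained as isolated network nodes — the
optimal-N rule depends on seeing them.

## Network construction

Streamlines below a minimum length are discarded first; the thresholds that
make sense are acquisition-dependent (5 mm for neonates, 10 mm for
6-month-olds, 15 mm for adults; the adult value is the package default).
The dense connectome maps each streamline endpoint to the nearest surface
point within `endpoint_radius_mm` (default 2.0 mm, about a voxel). Only the
two endpoints are used, never interior passage; streamlines with an
unmapped endpoint or with both endpoints on the same surface point are
skipped and tallied. Downscaling sums dense counts over node pairs,
discards intra-node pairs (zero diagonal), and binarizes at one streamline.
Streamline counts are carried as optional weights for inspection, but all
downstream analysis is binary: with small or developing brains the total
streamline count varies so strongly across subjects that weighted alignment
is not meaningful.

## Optimal node count

For candidates N ∈ {10, 50, 90, 95, 100, 105, 110, 150, 300, 500, 1000,
3000} (configurable), the rule selects the largest N at which *every*
subject's N-node network is a single connected component spanning all N
nodes. The only assumption is that no brain region is structurally
isolated; an isolated node at some N means the parcellation has become too
fine for the streamline density. A "none" outcome (no candidate qualifies)
is a valid result, not an error.

## Normalized global metrics

C is the mean local clustering coefficient with the convention that nodes
of degree < 2 contribute 0. L is the mean shortest-path length over all
node pairs and is only defined for connected graphs; callers holding a
disconnected network must explicitly restrict to the giant component
(`giant_subnetwork`), and the API refuses to guess. Q is the best Louvain
modularity over 20 seeded restarts (networkx implementation).

The null ensemble consists of degree-preserving Maslov–Sneppen
randomizations: each of `n_random` networks receives
`rewires_per_edge × |E|` accepted double-edge swaps (protocol values 100
networks × 1000 rewires per edge; tests use smaller ensembles, which only
widens Monte-Carlo noise, not bias). Degree sequences are preserved
exactly. Cr = C/C_rand and Lr = L/L_rand use ensemble means; swi = Cr/Lr is
computed from those same numbers, so the identity holds to machine
precision. For a randomized network that falls apart, L is evaluated on its
giant component. On graphs where no swap is possible (e.g. complete
graphs), the randomization is the identity and Cr = Lr = 1, as it should
be.

Metrics depend systematically on the parcellation scale N; the test suite
demonstrates this on a phantom (different Cr at N = 50 vs N = 95). Compare
metrics only at a common N.

## Network alignment

Two same-size binary adjacency matrices are aligned by finding a node
permutation p of the moving matrix B minimizing cost(p) = Σᵢⱼ |A −
B[p,p]|ᵢⱼ (full-matrix sum; for symmetric inputs this is twice the
lower-triangle sum, and for binary matrices minimizing it is equivalent to
maximizing the Pearson correlation). The optimizer is Metropolis simulated
annealing over transpositions:

- initial temperature T₀ = cost/ln 2, so a cost-doubling move starts out
  50% acceptable;
- one sweep = N proposed transpositions, each evaluated in O(N) by updating
  only the two affected rows/columns;
- geometric cooling chosen so the temperature reaches the floor 10⁻⁴·T₀ on
  the final sweep regardless of the configured sweep count. A fixed
  per-sweep factor like 0.995 is also supported, but as a default it is a
  trap: over 200 sweeps it only reaches 0.37·T₀, so the walk never leaves
  the high-temperature regime and large-N alignments do not converge;
- best-of-`restarts` (default 100, the protocol's "run 100 times, keep the
  lowest cost"), tracking the best permutation *visited*, not the final
  one;
- the identity permutation and a degree-matched pre-alignment (stable
  argsort of degree sequences) are always evaluated as candidates. The
  identity guarantees r_after ≥ r_before; the degree match is the package's
  pre-alignment heuristic and makes recovery of permuted copies of
  networks with distinctive degree sequences essentially immediate.

All randomness flows from a single master seed through spawned
`SeedSequence` children, so results are bit-reproducible. The reported
correlation is that of the lowest-cost run (not an average over runs). The
aligner is practical up to roughly 100 nodes; beyond that the permutation
space outgrows the schedule.

Pair-wise group alignment stores r(i→j) for subject j aligned to fixed
reference i. The matrix is not symmetric because alignment is directional;
reference selection therefore averages over rows (candidate-as-reference).
The subject with the highest mean off-diagonal row value becomes the cohort
reference (ties to the lowest index), and the sum network adds the aligned
binary adjacencies of everyone else to the reference's own.

**Rotation analysis.** To expose node-discretization error, the reference
sphere is rotated about each axis (±10° by default — about half a node
width at N = 95), networks are rebuilt from the same dense connectome, and
each rotated network is aligned back to the 0° baseline. When the rotated
network disconnects, its correlation is still reported but flagged
(`connected = False`), since alignment across different giant components is
not properly comparable; metrics rows are then computed on the giant
component. The mechanism being measured: a coherent streamline bundle
falling on a node boundary produces two binary connections to a common
neighbor where an interior bundle produces one.

## Edge-wise group statistics

Tests operate on the N(N−1)/2 sub-diagonal edge values of subjects aligned
to a common reference. The edge-wise test is a pooled-variance two-sample
t-test. Binary data with small groups frequently yields zero pooled
variance: such edges get t = 0, p = 1 when the group means agree and a
signed sentinel (±10¹²) with p ≈ 0 when they differ; inside NBS the
permutation machinery handles these cases without special treatment.
Benjamini–Hochberg FDR (statsmodels) is the generic multiplicity
correction.

NBS: edges with |t| ≥ threshold (two-sided contrast) form a graph whose
connected components are measured in edge count; K full label permutations
(without replacement, labels restored each time) build the null
distribution of the maximal component size, and each observed component
gets corrected p = (1 + #{null ≥ size})/(K + 1), which cannot drop below
1/(K+1). The primary threshold is a free parameter of the method and is a
required argument — there is no principled default. NBS is uninformative
when the true contrast does not form a connected component.

## Synthetic phantoms

`phantom` generates subjects with known answers: surfaces sampled uniformly
per unit area on an ellipsoid (rejection sampling on the area element;
default half-axes 60 × 80 × 55 mm, brain scale), planted-partition
ground-truth networks (contiguous modules, p_in/p_out defaults 0.7/0.1,
connectivity repaired by a flagged ring when a draw is disconnected), and
streamlines whose endpoints are surface points of the correct nodes, arced
through an interior waypoint so their lengths (~90 mm at brain scale)
clear any realistic length threshold. With zero endpoint jitter the
pipeline recovers the planted adjacency exactly; with jitter comparable to
node spacing, recovery degrades — the same discretization mechanism the
rotation analysis measures. Cohorts are noisy copies of one ground truth
(Bernoulli edge flips at 5% by default, matching the scale of
within-cohort variability the alignment step must tolerate) with recorded
node permutations; the two-group generator plants a connected 6-edge
contrast for power testing.

What the phantoms do *not* emulate: tractography biases (crossing fibers,
length-dependent seeding, gyral bias), spatially correlated noise, partial
voluming, or any relationship between module structure and geometry beyond
node assignment. Passing round-trip tests therefore validates the
*bookkeeping* of the pipeline (geometry → dense connectome → parcellation →
network → alignment), not the fidelity of tractography itself.

## Problem sizes in the tests

The test suite and acceptance script favor sizes that keep every check
sharp: exhaustive-permutation cross-checks at N = 7 (5040 permutations),
permutation recovery at N ≤ 30, randomization ensembles of 20–50 networks
with 10–20 rewires per edge, NBS calibration with 200 null simulations of
K = 200 permutations at N = 20, and 10⁶-sample Monte-Carlo checks of
partition areas. The protocol-scale defaults (100 restarts, 100 random
networks, 1000 rewires per edge, K = 1000) remain the library defaults.

## Known limitations

- Alignment quality degrades beyond ~100 nodes; no spectral or
  graph-edit-distance alternative is provided.
- L is restricted to connected graphs / giant components by design; there
  is no harmonic-mean (efficiency) fallback.
- Only binary analysis is supported downstream; weights are carried but
  never drive alignment or metrics.
- TRK reading requires nibabel and maps coordinates as stored; no header
  transform is applied.
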