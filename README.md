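# spherecon

Atlas-free construction and connection-wise comparison of diffusion-MRI
structural connectomes.

## The problem

Standard connectome pipelines define network nodes by registering every brain
to an anatomical atlas. That breaks down exactly where connectomics is most
interesting — neonates, infants, reorganized brains after injury — because
inter-subject anatomical variability (or outright absence of adult landmarks)
makes the registration unreliable. `spherecon` implements an alternative that
needs no atlas at all:

1. **Parcellation.** A unit sphere is divided into *N* regions of exactly
   equal area (recursive zonal partitioning: polar caps plus latitudinal
   collars cut into equal-area cells). The sphere is scaled to each
   individual brain surface and every surface point is assigned to the
   nearest region center, giving *N* nodes of similar size on each brain
   separately — no template, no co-registration.
2. **Network construction.** Streamlines from whole-brain tractography are
   length-thresholded, their endpoints mapped to surface points (the "dense
   connectome"), and entries combined per node pair. Networks are binarized
   at a threshold of one streamline: `A[i,j] = 1` iff at least one streamline
   connects nodes *i* and *j*.
3. **Optimal *N*.** Assuming no part of the brain is structurally isolated,
   the optimal parcellation is the finest one at which every subject's
   network still forms a single connected component spanning all nodes.
4. **Metrics.** Global measures are normalized against degree-preserving
   random networks (Maslov–Sneppen rewiring): `Cr = C/C_rand`,
   `Lr = L/L_rand`, small-world index `swi = Cr/Lr`, plus maximized
   modularity *Q* (Louvain, best of seeded restarts).
5. **Alignment.** Because nodes carry no anatomical labels, two subjects are
   compared by *network alignment*: simulated annealing reorders the nodes of
   one adjacency matrix to minimize `Σ|A − B_permuted|` (best of many
   restarts; the identity and a degree-matched pre-alignment are always
   evaluated). Agreement is the Pearson correlation over the N(N−1)/2
   sub-diagonal entries.
6. **Group analysis.** The most typical subject (highest mean post-alignment
   correlation) becomes the cohort reference; aligned networks are summed
   into a template, and two groups can be contrasted edge-wise with
   Benjamini–Hochberg FDR or the network-based statistic (NBS) permutation
   procedure.

Because no real MRI data ships with the package, a phantom module generates
synthetic subjects (ellipsoidal surfaces, planted-partition ground-truth
networks, streamlines realizing them) with known structure; jitter-free
phantoms round-trip the whole construction exactly.

## Worked example

```python
import spherecon as sc
from spherecon.phantom import PhantomSpec, make_subject
from spherecon.builder import build_dense_connectome

# a synthetic subject: 30-node modular ground truth on an ellipsoid surface
sub = make_subject(PhantomSpec(n_true=30, n_modules=3, p_in=0.8, p_out=0.1,
                               n_surface_points=1500, seed=30))

# rebuild its network from the streamlines, at the ground-truth resolution
dense = build_dense_connectome(sub.streamlines, sub.surface, 2.0)
net = sc.downscale(dense, sub.assignment)
print("recovered exactly:",
      (net.adjacency == sub.ground_truth.adjacency).all())

gm = sc.global_metrics(net, n_random=50, rewires_per_edge=20, seed=1)
print(f"Cr={gm.Cr:.2f} Lr={gm.Lr:.2f} Q={gm.Q:.2f} swi={gm.swi:.2f}")

# align a node-shuffled copy back onto the original
import numpy as np
perm = np.random.default_rng(2).permutation(30)
moved = sc.BinaryNetwork(adjacency=net.adjacency[np.ix_(perm, perm)])
res = sc.sa_align(net, moved, restarts=50, iterations=200, seed=3)
print(f"r_before={res.r_before:.4f} r_after={res.r_after:.4f} "
      f"cost={res.cost:.0f}")
```

Output:

```
recovered exactly: True
Cr=2.21 Lr=1.11 Q=0.49 swi=2.00
r_before=0.0592 r_after=1.0000 cost=0
```

The jitter-free phantom reconstructs its planted network exactly; the
network clusters ~2.2× more than its degree-matched null at near
random-graph path length (small-world organization, swi > 1); and the
annealing aligner undoes the node shuffle completely (post-alignment
correlation 1, absolute-difference cost 0).

The same steps are available from the shell:

```bash
spherecon simulate --spec phantom.json --out-dir phantom/
spherecon parcellate --n 95 --surface phantom/surface.tsv --out labels.tsv
spherecon build --streamlines phantom/streamlines.tsv \
    --surface phantom/surface.tsv --labels labels.tsv --out net.csv
spherecon align --ref a.csv --moving b.csv --restarts 100 --seed 7 --out r.json
spherecon run --cohort cohort.json --out-dir out/   # full six-step pipeline
```

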