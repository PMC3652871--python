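# tractnet

Template-free structural brain networks from diffusion tractography.

Mapping the connectome of rapidly developing (e.g. neonatal) brains is hard
to do with anatomical atlases: landmarks shift, myelination is incomplete,
and atlas registration biases the nodes. `tractnet` implements the
alternative: define the network nodes *without any template* by partitioning
a sphere into N regions of exactly equal area and projecting them radially
onto a surface shell extracted 4–6 mm below the cortex from the non-zero
support of a fractional-anisotropy (FA) map. Streamlines from whole-brain
tractography then connect the nodes, and the resulting binary network is
analysed for integration, segregation and modular structure.

It is aimed at researchers in MRI connectomics / network neuroscience who
want an auditable, fully seeded reimplementation of this workflow, plus
phantom generators that make every stage testable without subject data.

## The model

For a binary network A on the N′ non-empty nodes:

* edge density `2|E| / (N′(N′−1))`,
* clustering `C = ⟨C_i⟩`, `C_i = 2T_i / (k_i(k_i−1))` (segregation),
* characteristic path length `L` = mean shortest path over connected pairs
  (integration),
* scaled metrics against degree-preserving rewired surrogates
  (1000 attempted double-edge swaps per edge, 100 surrogate networks):
  `γ = C/C_rand`, `λ = L/L_rand`, small-world index `σ = γ/λ`,
* physical connection lengths: Euclidean centroid distance per edge,
* modularity `Q = Σ_c (e_cc − a_c²)` maximised by Newman's
  leading-eigenvector spectral bisection with Kernighan–Lin refinement;
  the optimal module count is the K of that partition, and a fixed-K
  variant (K = 5) constrains the count by greedy merges / forced splits,
* connectivity matrices are displayed after a seeded stochastic search for
  the node order minimising total edge bandwidth `Σ_(i,j)∈E |π(i)−π(j)|`
  (10⁶ attempts).

Node-count selection is network-driven: the optimal N is the finest
parcellation whose giant component still contains every non-empty node.

## Worked example: the phantom study

The repository is organised as an analysis project; the numbered scripts
under `analysis/` run the whole study on a synthetic phantom (an
ellipsoidal FA volume plus a tractogram with five planted, spatially
contiguous endpoint modules and 10% sub-threshold noise streamlines):

```bash
python analysis/01_generate_phantom.py
python analysis/02_build_network.py
python analysis/03_graph_metrics.py
python analysis/04_modules.py
```

which prints (seed 0):

```
length filter (5.0 mm): 5000 -> 4500 streamlines
optimal node number over [25, 50, 75, 100, 150]: 150 (finest whole-brain parcellation)
connectivity matrix: 1683 edges among 100 non-empty nodes (density 0.340); giant component 100/100
density 0.340, C 0.470, L 1.660
gamma 1.401, lambda 1.000, sigma 1.401 (100 surrogates, 1000 rewires/edge)
modularity Q 0.351 at K_opt=5
reordering: bandwidth 57795 -> 34446 after 1,000,000 attempts
spectral detection : K=5, Q=0.351, ARI vs planted 1.000
fixed K=5        : Q=0.351, ARI vs planted 1.000
module volume      : 94.1% of voxels agree with their neighbourhood majority (spatial contiguity)
```

Reading this: the length filter removed exactly the 500 planted noise
streamlines; every candidate parcellation was spanned by its giant
component, so the finest candidate wins; γ > 1 with λ ≈ 1 means the phantom
network is more clustered than its degree-matched random surrogates at the
same integration level (σ > 1, "small world"); and spectral community
detection recovers the five planted modules exactly (adjusted Rand
index 1.0), mapping back onto the phantom cortex as five contiguous
sectors. Tables land in `results/`, volumes in `scratch/`.

The same pipeline runs on real data via the library driver:

```python
import tractnet as tn
config = tn.RunConfig.preset("term", n_nodes=100, seed=7)
report = tn.run_pipeline(config, "fa.nii.gz", "tracks.trk", "out/")
```

which writes the parcellation and module-label volumes (NIfTI), the
connectivity matrix and edge list (CSV), and a full metrics report plus
manifest (JSON); reruns with the same seed are byte-identical. Length
threshold presets: preterm/term 5 mm, infant6mo 10 mm, adult 15 mm.

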