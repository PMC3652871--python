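# Methods

`tractnet` implements a template-free structural-connectome workflow: from a
fractional-anisotropy (FA) volume and a whole-brain streamline set it builds
a binary brain network on equal-area surface nodes, quantifies the network's
integration and segregation against degree-preserving random surrogates, and
segments the cortex into network-driven modules. Because no subject data
accompany the package, a phantom generator supplies inputs with known ground
truth; this note records the model, the defaults, and the choices made where
the design was genuinely open.

## Network construction

**Brain mask and surface shell.** The brain mask is the non-zero support of
the FA map. It is closed once (6-connected dilation + erosion) to fill
pinholes, then eroded to a metric depth `depth_mm` (default 5 mm, valid
range 4–6 mm) using the anisotropy-aware Euclidean distance transform —
equivalent to erosion by a Euclidean ball of radius `depth_mm`, so the shell
sits at the same physical depth in every direction regardless of voxel
anisotropy. We deliberately use metric erosion rather than iterated
structuring-element erosion: k passes of a 6-connected cross erode to an L1
(diamond) depth, which under-erodes along body diagonals by a factor up to
√3 and would place the "5 mm deep" shell at ~2.9 mm depth in diagonal
directions. The node surface is the one-voxel skin of the eroded mask
(eroded minus one further 6-connected erosion). Protrusions such as the
cerebellum are not removed. Erosion that empties the mask raises an error.

**Equal-area nodes.** The unit sphere is partitioned into N regions of
exactly equal area by the recursive zonal construction: two polar caps of
area 4π/N plus latitudinal collars, each collar holding an integer number of
equal-area cells; collar boundaries are placed by inverting the cap-area
function at cumulative region counts, so all areas are equal *analytically*
(tested to 1e-9 relative). Each surface voxel is mapped to the sphere by
normalising its offset from the surface centroid (radial projection; the
polar axis is the volume z-axis) and labelled with the containing region.
This sphere-to-surface correspondence is the package's own choice — the
simplest rotation-equivariant mapping consistent with the equal-area intent;
no ellipsoidal normalisation precedes projection. Nodes that receive no
voxel stay in the matrix with degree 0 so N is comparable across subjects;
they are excluded from all averages.

**Node count selection.** For candidate N (default grid 10–300 by 10s) the
network is built and the giant component computed; the selected N is the
largest for which the giant component contains every non-empty node — the
finest parcellation that still represents the whole brain. If no candidate
qualifies, the candidate with the highest giant-component fraction is
returned and flagged. N = 100 is the default working resolution.

**Streamline filtering and connectivity.** Streamlines shorter (arc length,
inclusive bound) than `min_length_mm` are removed as likely noise; presets
are 5 mm for preterm/term neonates, 10 mm for six-month infants, 15 mm for
adults. Each surviving streamline is resampled at half the minimum voxel
spacing (so a one-voxel shell cannot be jumped over), points are mapped to
voxels by flooring the continuous grid index (half-open voxel boxes), and
every unordered pair of distinct touched node labels increments the weight
matrix. A track touching k > 2 nodes therefore contributes all C(k,2)
pairs; an endpoints-only mode exists for sensitivity analysis. The analysed
network is the binarization `weights >= 1` (configurable threshold).

## Network analysis

Density is 2|E|/(N′(N′−1)) over the N′ non-empty nodes. Clustering uses
C_i = 2T_i/(k_i(k_i−1)), with C_i = 0 for degree < 2 and such nodes kept in
the average. Path length L averages shortest paths over connected ordered
pairs; unreachable pairs are excluded and counted (surrogates can fragment,
so this convention is applied identically to real and null networks).

**Null ensemble.** Each surrogate starts from the observed network and
undergoes R×|E| attempted double-edge swaps (R = 1000 "rewires per edge";
proposals creating self-loops, multi-edges or sharing a vertex are rejected
but still count as attempts), exactly preserving every node's degree.
C_rand and L_rand are means over 100 surrogates. Scaled metrics are
γ = C/C_rand, λ = L/L_rand and the small-world index σ = γ/λ. Graphs with no
swappable edge pair (e.g. stars) return surrogates equal to the input with
a warning; σ is undefined (error) when C_rand = 0. The swap loop is a
numba kernel fed with pre-drawn Generator streams, so ensembles are
bit-reproducible for a given seed.

**Physical connection lengths.** One Euclidean centroid-to-centroid
distance per edge — a deliberate straight-line approximation to fibre
length — binned at 10 mm by default.

**Matrix reordering.** To display the community structure, a node order
minimising the total edge bandwidth Σ_(i,j)∈E |π(i)−π(j)| is sought by
10⁶ random transpositions accepted whenever the objective does not increase
(plain greedy descent; a simulated-annealing acceptance is not provided —
on the ~100-node matrices used here greedy already attains the exhaustive
optimum on small test cases). The objective trace is non-increasing by
construction.

**Modules.** Community detection is the leading-eigenvector method:
recursive bisection by the top eigenvector of the (generalized) modularity
matrix, with Kernighan–Lin single-node fine-tuning after each split and
stopping when no split increases Q. Eigenvectors come from a dense
symmetric solver (networks here are ≤ a few hundred nodes), so runs are
deterministic; sign ties break toward the first module; the fine-tuning
pass accepts only strictly, exactly recomputed improvements (the
incremental gains drift at float precision and a naive loop can cycle).
The data-driven module count is the K of that partition. The fixed-K
variant (study design: K = 5) constrains the count by greedily merging the
Q-maximising module pair while too many, or forcibly bisecting the module
whose best split yields the highest Q (ΔQ ≤ 0 allowed, median/index split
as fallback for indivisible groups) while too few; this constraint
procedure is our construction — only the target count is given by the
study design. Degree-0 nodes get label 0 and are excluded from Q. Module
labels are finally mapped back onto the surface voxels as a label volume.

## The phantom and what it does (not) show

The generator emulates exactly the features downstream stages consume:

* **FA volume** — a solid ellipsoid (default semi-axes 55/65/50 mm,
  1.5 mm voxels: brain-sized, coarse like neonatal DWI) with a smooth
  radial FA profile in (0, 0.8]; padding ≥ 8 mm so erosion never touches
  the array border. Radii below twice the voxel size are rejected as
  degenerate.
* **Planted modules** — five equal longitude sectors about the surface
  centroid, so modules are spatially contiguous wedges by construction.
* **Tractogram** — 5000 streamlines. Endpoint node pairs are drawn with
  relative weight 0.9 (same planted module) vs 0.05 (different modules);
  endpoints are random surface voxels of the sampled nodes, re-drawn until
  separated by more than the length threshold. Each streamline is the 1 mm
  resampled chord between its endpoints with interior points clamped, in
  ellipsoid-normalized coordinates, safely below the endpoint radius: only
  the two termini lie in the surface shell. This makes two invariants hold
  exactly — the length filter removes exactly the 10% planted noise
  (short random surface segments of 1 mm to threshold−0.5 mm), and with
  p_in = 1, p_out = 0 the binary network is block-diagonal under the
  planted ordering even under all-pairs track-node counting.

The phantom does **not** emulate gyral folding, curved fibre geometry,
partial-volume effects, scanner noise, or realistic streamline-count
distributions. Passing tests therefore certify the *network-construction
and analysis machinery* — not tractography robustness on real DWI. In
particular the phantom's edge density (~34%) is far above the 5–10% range
typical of subject networks, because a 100-node phantom with 4500 clean
chords is much better sampled than real tractography.

## Numerical choices and degenerate inputs

* All stochastic operations draw from `numpy.random.Generator` seeded via
  `SeedSequence`; identical seeds give byte-identical artifacts (CSV/JSON).
* Sphere assignment uses half-open colatitude/longitude intervals; the
  south pole and the 2π meridian fold into the last zone/cell, so every
  direction belongs to exactly one region. A voxel exactly at the surface
  centroid borrows the nearest voxel's direction (logged).
* Eigen-solver tolerance for "indivisible" is 1e-10 on the leading
  eigenvalue; ΔQ acceptance tolerance 1e-12.
* Empty tractograms, edgeless graphs, all-zero volumes, K exceeding the
  non-empty node count, and centroid-less edge endpoints raise explicit
  errors rather than propagating NaNs.
* User-facing files are 1-based (node ids, module ids); in-memory arrays
  are 0-based.

## Problem sizes used by the shipped analyses

The analysis scripts and the acceptance runner use the phantom defaults
above (100 nodes, 5000 streamlines, 100 surrogates × 1000 rewires/edge,
10⁶ reordering attempts) — the full stated conditions, chosen to run
comfortably on a single CPU. The statistical suites use 10⁶ Monte-Carlo
sphere points, 100 random oracle graphs (n ≤ 25), and 20-seed ensembles
for null-model calibration and community recovery.

## Known limitations

* The sphere-to-surface mapping assumes a star-shaped surface about its
  centroid; deeply folded cortices violate this and would alias distant
  patches onto one node.
* Fixed-K segmentation is a constrained variant of the spectral optimum,
  not a global K-constrained modularity maximiser.
* L's unreachable-pair exclusion (rather than giant-component restriction)
  is one convention among several; the exclusion count is reported so
  fragmentation is visible.
* Weighted-network metrics are out of scope: streamline counts are kept in
  the weight matrix but all analysis is binary.
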