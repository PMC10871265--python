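# Methods

This note records what `cryoclust` computes, the defaults and why, what
the synthetic data generator does and does not emulate, and the design
choices made where more than one reasonable reading existed.

## Problem setting

Input: a stack of *n* same-sized grayscale 2D projection images of a
mixture of particle species, optionally with ground-truth class labels
for a subset of species (used only for semi-supervised model
selection). Output: a partition of the images into per-particle groups,
with an explicit noise label allowed, plus evaluation reports.

## Synthetic data generator

`simulate.make_volume` renders six shape families (sphere, dumbbell,
cube, torus, rod, L-shape) as soft-edged indicator densities on a cubic
voxel grid (default 40³, soft edge ≈ 1 voxel). Classes beyond six are
seeded variants of a family: anisotropic coordinate rescaling (±35%)
plus 2–4 additive Gaussian lobes. These variants are a geometric
stand-in for distinct macromolecules — they are *not* derived from any
deposited structure, and nothing about their density statistics mimics
electron scattering.

`simulate.project_volume` computes line-integral projections by voxel
splatting: voxel-centre coordinates are rotated (centre convention
(N−1)/2 per axis) and each voxel's density is distributed bilinearly
over the image-plane pixel grid. Unlike resampling-based rotation this
conserves total mass exactly at every orientation, which anchors the
mass-conservation invariants used throughout the tests. Orientations
are uniform on SO(3) (normalised Gaussian quaternions).

`simulate.make_dataset` draws per-class projection counts uniformly
from an inclusive range — defaults follow the two study regimes: few
views (2–12 per class) and many views (13–20 per class) — renders on a
shared padded canvas, and rescales to 100×100 pixels.

The noise model adds, in order: (1) Gaussian noise whose mean and
variance equal the image's own pixel mean and variance — we read the
parameterisation literally, so the noise both brightens and grains the
image; `zero_mean=True` gives the variance-only alternative; and
(2) salt-and-pepper corruption of round(1% · H·W) pixels, half set to
the input image's maximum and half to its minimum. Both steps are
deterministic under a seed. What passing tests on these data show is
that the pipeline separates geometrically distinct particles under
heavy additive noise; they do not show robustness to CTF effects,
off-centring, or junk particles, none of which the generator emulates.

## Common-line graph

Line projections use the same exact splatting idea in 2D: pixel-centre
coordinates are rotated and intensities binned linearly, at angles
[0°, 175°] in 5° steps (36 angles). Signals live on a padded bin grid
(length N + 2·pad with pad ≈ N(√2−1)/2 + 1, parity preserving) so no
mass is clipped at any angle; at 0° the central N bins equal the
column sums exactly. Padding is what makes every signal sum to the
image's total intensity — on an unpadded grid diagonal projections of
boundary mass would be lost, and the mass-conservation invariant could
not hold for arbitrary images.

Pair scoring evaluates the measure on all 36×36 signal pairs and keeps
the optimum (minimum for L1/L2/Wasserstein, maximum for
cosine/correlation), with exact ties broken to the lexicographically
smallest angle pair. Zero-variance signals under correlation (or
zero-norm under cosine) score similarity 0 and are skipped for the
optimum, with a log entry. The 1D Wasserstein distance is computed
after shifting each signal by its minimum and normalising to unit mass
(zero-mass signals are an error), as the L1 distance between CDFs.
Images are assumed centred; `shift_search=w` optionally compares
signals over integer relative shifts in [−w, w].

Graph construction Z-scores each source node's n−1 candidate scores
(a `global_zscore` flag Z-scores over the whole matrix instead — both
readings of "relative to all edge scores" are available; per-node is
the default). Distance measures are negated after Z-scoring so larger
weight always means more similar. `top_k` keeps the k = 5 largest
weights per node (directed); `top_m_edges` keeps the m = 3000 largest
globally. Symmetrisation keeps edge {u,v} iff either direction exists,
with the maximum weight.

Z-scored weights can be negative. Every consumer that needs a valid
probability distribution or Laplacian (node2vec walks, GraphWave, DGI,
walktrap, modularity, label propagation) applies the shift
w → w − min + ε (ε = 10⁻⁶), which preserves the similarity ranking.
Edge betweenness uses the unweighted topology: igraph treats edge
weights as traversal costs there, which would invert their meaning as
similarities.

## Node embeddings

Defaults (the similarity-graph literature gives no canonical values;
these are the common published defaults, all exposed in config):

* **Node2Vec** — p = q = 1, 10 walks/node, walk length 80, window 10,
  dim 128, 5 negatives; walks respect edge direction on directed
  graphs. The skip-gram with negative sampling is a compact numpy
  implementation: 3 epochs over the (centre, context) pairs, linearly
  decaying learning rate from 0.025, noise distribution ∝ count^0.75,
  logits clipped to ±10. Batched updates normalise the accumulated
  gradient by each node's multiplicity within the batch, so a node
  repeated in a batch still takes an O(lr) step (without this the
  optimisation diverges on small graphs). Nodes never visited by any
  walk are embedded as zero vectors with a warning.
* **GraphWave** — two heat scales chosen from the Laplacian spectrum
  (−ln η / √(λ₂·λ_max) for η ∈ {0.95, 0.70}, the method's own
  adaptive heuristic; fixed scales large relative to the spectrum make
  every wavelet collapse onto the constant eigenvector and the
  embedding degenerate on weighted graphs), 50 characteristic-function
  sample points evenly in [0, 100]; output dim = 2 × 50 × |scales|.
  An explicit scale list overrides the heuristic.  Computed by exact
  eigendecomposition of the unnormalised Laplacian of the symmetrised
  graph, so structurally equivalent nodes get embeddings equal to
  numerical precision.
* **DGI-GCN** — one-layer GCN encoder over the symmetrised,
  self-looped, symmetrically degree-normalised adjacency; PReLU
  activation; bilinear discriminator against a sigmoid mean-pooled
  summary; corruption by row-shuffling the attribute matrix; 100
  epochs of Adam at 10⁻³ on analytic gradients; dim 128. Attributes
  are column-standardised before encoding.

A user-supplied callable `(graph, attrs, seed) → n×d matrix` plugs
into the pipeline unchanged.

## Image embeddings and triplet training

The `tiny-cnn` backbone (three 3×3 conv blocks, 8/16/32 channels, ReLU,
two 2×2 max-pools, global average pool) uses seeded He-initialised
random weights and is never trained; it exists so the package builds,
tests and runs fully offline. The named pretrained backbones (AlexNet,
VGG-11, DenseNet, ResNet-18, EfficientNet-B1/B7, ResNet-50) require
downloaded weights and raise an explicit error pointing at the
tiny-cnn fallback when unavailable. Images are min-max scaled to [0,1]
per image, replicated to three channels, and centred.

Triplet training freezes the whole conv backbone and trains only the
dense head (512, 256, 256; ReLU + batch-norm on the first two) — the
same frozen-backbone/trainable-head pattern used with large pretrained
encoders. Backbone features are standardised (train-set mean/variance)
before the head. Triples pair every unordered same-class pair with 10
uniformly drawn negatives (`per_class` mode: one negative per other
class); the triples split 80–20 into train/validation; training runs
Adam at 10⁻⁴ for 10 epochs at batch size 2 (32 for the split-training
regime), with per-epoch train/validation loss recorded. ‖·‖² in the
loss is the squared Euclidean distance (the FaceNet convention); an
unsquared variant is a flag. A NaN loss aborts with diagnostics.

Embeddings are not L2-normalised by default. For the
fine-tuning-benefit experiment in the acceptance suite we enable the
normalisation flag: with a frozen random backbone the unnormalised
head outputs have squared distances of order 10²–10³, so a margin of
0.5 is satisfied at initialisation and training stops before
reorganising the geometry; on the unit sphere the margin constrains
angles and training demonstrably tightens classes. With a pretrained
backbone whose feature scale is moderate, the unnormalised default is
serviceable.

The 70–30 train/test split is over *classes* (particle species), not
images: round(0.7 · n_classes) training classes, at least one on each
side, seeded.

## Fusion and reduction

Embedding blocks are column-standardised (zero-variance columns
dropped) before concatenation so one block's scale cannot dominate —
the natural default given embeddings of very different scales; a flag
disables it. Reduction uses PCA when the matrix is dense and uncentred
truncated SVD when more than half its entries are exactly zero.
Components with explained-variance ratio ≥ 2% are kept, minimum two;
the 2% rule is applied per component (the literal reading), not
cumulatively. Component signs are fixed (largest-magnitude loading
positive) for reproducibility. Fusion modes: concatenate-then-reduce,
reduce-then-concatenate, image-only, node-only.

## Clustering and model selection

The 22 candidate distance measures are Bray-Curtis, Canberra,
Chebyshev, city-block, Pearson correlation, cosine, Dice, Euclidean,
Hamming, Jaccard, Jensen-Shannon, Kulsinski, Mahalanobis, matching,
Minkowski, Rogers-Tanimoto, Russell-Rao, standardised Euclidean,
Sokal-Michener, Sokal-Sneath, squared Euclidean, and Yule. Binary
measures are evaluated on the nonzero-indicator pattern of the vectors
(logged as such); Kulsinski and Sokal-Michener follow the classic
scipy formulas (recent scipy removed them). Measures undefined on the
data — singular covariance for Mahalanobis, negative entries for
Jensen-Shannon, non-finite values anywhere — are skipped with a log
entry. The measure with the best ground-truth-class silhouette on the
training split wins; ties go to the first in the order above.

Hyperparameter grids: DBSCAN eps 0.25–3 step 0.25 × min_samples 2–10;
OPTICS max_eps 0.25–3 step 0.25 × min_samples 2–10; BIRCH threshold
0.1–1 step 0.1 × branching_factor 10–100 step 10; Affinity Propagation
damping 0.5–1 step 0.1. Every grid point fits on all points; the FMMF
of the induced partition restricted to training images picks the
winner; ties break by higher silhouette, then fewer clusters, then
first grid point. Notes: BIRCH's CF-tree is Euclidean by construction,
so the chosen measure does not apply to it; Affinity Propagation uses
the negated distance matrix as similarity, and non-convergence (or the
invalid damping = 1.0 grid edge) is treated as a failed grid point and
skipped. Density-based noise points count as singleton clusters during
evaluation (penalising precision); `drop_noise` excludes them instead.

Graph clustering: strongly/weakly connected components, walktrap
(4 steps, igraph), edge betweenness (igraph), greedy modularity,
k-clique (k = 3, the smallest nontrivial), and semi-synchronous /
asynchronous label propagation (networkx, seeded). Methods defined
only for undirected graphs symmetrise a directed input first, logged.
k-clique leaves non-members as singletons.

## Evaluation metrics

With overlap O = |P∩T|: F-similarity = harmonic mean of O/|P| and
O/|T|. FMMF computes a maximum-weight one-to-one matching on the
F-similarity matrix (Hungarian algorithm); precision divides the
matched weight by the number of predicted clusters, recall by true
clusters. CMMF averages each cluster's single best partner (no
one-to-one constraint), so CMMF ≥ FMMF always. The Qi et al. score
matches P to T when O²/(|P||T|) ≥ ω (default ω = 0.25, the common
choice in the complex-prediction literature; configurable). UnSPA =
√(Sn · PPV) with Sn = Σ_T max_P O / Σ_T |T| and the unbiased
PPV = Σ_P max_T O / Σ_P |P|; the Σ|P| denominator is our documented
reading of "unbiased". These formula fixations are package-level
decisions: the defining reference sits outside what the package can
cite, so each piece is configurable where ambiguous. For datasets with
junk (unlabelled) images, evaluation can run both with junk as its own
pseudo-class and with junk excluded.

## Determinism and numerical choices

Every stochastic component (volume perturbation, orientations, noise,
triples, walks, SGNS, DGI, label propagation, Affinity Propagation
tie-breaks, t-SNE) takes a seed; fitted results are bit-reproducible
for a fixed seed on one platform. t-SNE uses perplexity
min(30, (n−1)/3) under the selected distance. The AutoML driver fixes
one class split per run, tunes every combo on the training classes
only, ranks by training FMMF, and never uses test metrics for
selection. Intermediate artifacts (graphs, embeddings) are cached by
content hash within a run; caching is observationally transparent.

## Problem sizes used in the validation suite

The test and acceptance runs use desk-scale versions of the study
conditions chosen to exercise every code path: 20 random 8×8 images
for the scoring-oracle checks, 4 classes × 12 projections at 100×100
(clean and noisy) for end-to-end recovery, a 24-image 3-class texture
toy set for triplet training, and the 35-class / 13–20-projections
regime for the metric-identity target. These sizes are the package's
validation choices; the pipeline itself has no hard-coded scale.

## Known limitations

* No CTF simulation, micrograph-level picking, or junk-particle
  generation in the simulator.
* Common-line scoring assumes centred images of identical size; only
  integer-shift search is available for off-centre data.
* The tiny-cnn backbone is untrained; absolute embedding quality with
  it is far below a pretrained ResNet-50, and results on real
  micrograph data should use pretrained weights where available.
* Watch Your Step, Metapath2Vec, Attri2Vec, GraphSAGE and the
  GAT/APPNP/Cluster-GCN DGI encoders are not implemented; the node
  embedding interface accepts them as plug-in callables.
* Estimating the number of clusters a priori is out of scope by
  design — all clustering methods used operate without it.
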