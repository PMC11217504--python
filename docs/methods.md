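# Methods

`phenotrip` implements a machine-learnt phenomics pipeline for collections
of specimen photographs: a triplet-trained convolutional encoder places
every image in a Euclidean morphospace; centroid distances in that space
yield disparity and sexual-dimorphism statistics; and neighbour-joining
trees built from those distances are validated against gene-tree samples.
Because real museum collections are large and access-controlled, the
package ships a synthetic specimen simulator that generates ground-truthed
collections with the statistical structure the analysis assumes.  This note
records the models, the parameters that matter, and the design decisions
taken where more than one reasonable choice existed.

## Synthetic collections

**Species tree.** A pure-birth (Yule) process with per-lineage rate 1 is
run until the requested number of tips, plus one further waiting time so
the last pendant edges are positive; all branch lengths are then rescaled
to unit root depth.  This is the simplest ultrametric null and fixes the
time units for everything downstream: Brownian rates are variances per unit
root depth.

**Phenotypes.** Each species x sex cell carries a 10-dimensional latent
trait vector (fore/hindwing aspect, hindwing tail length, base and patch
hue, patch position and size, spot count, saturation).  Traits evolve
independently by Brownian motion along the tree, each sex with its own
rate; the increments of the two sexes are independent draws.  Sexual
dimorphism is a constant offset added to male traits, so every species is
dimorphic even at rate zero — matching taxa in which dimorphism is
universal while its *disparity* varies.  The offset direction is restricted
to colour and spot-count components: those render with the same pixel
sensitivity at both sexes' operating points, so the offset separates the
sexes without inflating either sex's image variance.  Structural traits
(tail length, patch size) are excluded from the offset for exactly that
reason.

The scenario defaults are the package's study conditions: 8 species, 12
images per species x sex x surface at 32 px, male rate 0.08 and female
rate 0.02 (the 4:1 male-divergent regime; swapping the rates gives the
female-divergent regime, equal rates the null), dimorphism offset 0.6,
pixel noise sd 0.02 on the 0..1 intensity scale, and per-specimen latent
jitter sd 0.02.  The rate magnitudes were chosen so that between-species
trait differences (sd ~ 0.3-0.5 latent units at typical patristic
distances) are clearly visible yet stay within the renderer's near-linear
range.

**Renderer.** Images are built analytically from the absolute horizontal
coordinate, so they are exactly bilaterally symmetric before noise; wings
are soft-edged ellipses, plus a forewing patch, hindwing spots (with a
fractional-alpha last spot so the map is continuous in the latent count)
and a dark body.  Two renderer properties matter for the statistics and
were engineered deliberately:

* *Monotone response.* Latent traits map to drawing parameters through
  `center + gain * tanh(t - center)`: near-linear over realistic Brownian
  excursions, softly saturating far out, never flat.  A hard clamp (or hue
  wrap-around) would truncate exactly the high-rate sex's extra variance
  and bias the disparity-difference statistic toward zero or even the wrong
  sign.
* *Balanced gains.* Per-trait gains are set so one latent unit of any trait
  moves the image by a comparable pixel norm (measured sensitivities span
  roughly 2-8 rather than 0-20 without balancing).  Without this, one or
  two traits dominate pixel distance and the effective trait dimension
  collapses, making the pipeline's sign recovery noisy.

The ventral surface is a deterministic muting of the dorsal parameters
(reduced saturation, lighter value, patch coordinates swapped, hues
shifted) — two correlated views of one phenotype.  The uniform background
colour is a module constant.

**Gene trees.** Each gene tree is the species tree with every branch length
multiplied by exp(N(0, jitter)) and, per internal edge with probability
1 - exp(-jitter), one nearest-neighbour interchange.  Default: 100 trees at
jitter 0.1.  This emulates the spread of a posterior sample of coalescent
species trees without running an MCMC; it does not model deep coalescence
explicitly.  The genetic distance matrix is the patristic matrix of the
true tree.

**What the simulator does not emulate.** Real photograph collections have
heterogeneous lighting, pose and wing damage, non-uniform image counts,
label noise, and phenotypes that are not low-dimensional smooth functions
of heritable traits.  Passing tests on synthetic data therefore show that
the *pipeline* recovers known structure under its stated model; they do not
certify performance on museum data.

## Embedding

The encoder is a compact stack of 3x3 stride-2 convolutions
(channels 8-16-32 by default for 32 px input), a flatten, and a linear head
to a 64-dimensional embedding, trained with the hinge triplet loss
max(0, ||a-p|| - ||a-n|| + margin), margin 0.2, on raw (un-normalised)
Euclidean distances.  Flattening rather than global average pooling is the
default because pooling discards the spatial arrangement that carries most
of the phylogenetic signal at these image sizes; `pool="gap"` is available.

Triplets are sampled species-uniformly: the "same" species is drawn with
equal probability from the species list (species with fewer than two
images are excluded from that role, with a warning), its two images drawn
uniformly without replacement, and the negative drawn from a uniformly
chosen different species.  This neutralises collection imbalance in the
inter-species distance distribution.  Two RNG streams make runs
reproducible: a data-order stream (default seed 12345) for triplet
sampling, and a training stream for weight initialisation and
augmentation.

An *epoch* is ceil(n_images / 3) triplets — one expected presentation of
each image — so epoch counts are comparable across dataset sizes.  The
optimiser is Adam at 3e-4 with batches of 32 triplets; the rate is set low
enough that the embedding's correlation with genetic distance rises over
the first tens of epochs rather than peaking immediately.  Random-affine
augmentation (translation up to 8% of each dimension, scale 0.9-1.1, shear
up to 5 degrees) is applied per batch with a bilinear warp; out-of-frame
samples take the image's background corner value.

Training logs the mean loss every epoch and, at a configurable interval
(default 10 epochs), the Pearson correlation between condensed
inter-species centroid distances in the current embedding and the genetic
distance matrix.  The loss and that correlation are deliberately different
quantities: the loss keeps improving long after the embedding's
evolutionary signal has peaked, so stopping time is an analysis choice,
not an optimisation fact.  Checkpoints at several epochs are the mechanism
for comparing stopping times; epoch 0 (the untrained encoder) is a valid
checkpoint.

For tree building, `ensemble_species_distance_matrix` averages the species
centroid-distance matrices of several short independent runs (default 3
runs to the configured epoch; run k offsets both seeds by 100k).  A single
run leaves run-specific distortion in the distances; the ensemble mean is a
steadier morphospace estimate and is the recommended NJ input.

## Disparity statistics

All statistics operate on subset centroids (mean embedding over the images
of a species, optionally filtered by sex and/or surface; the default pools
both surfaces).  The sexual disparity difference for a species pair is the
inter-male centroid distance minus the inter-female one; its mean over
unordered pairs summarises a clade.  The statistic is invariant under
global isometries of the embedding, and the mean over all species equals
mean(male condensed) - mean(female condensed) when the key sets match.
Species present in only one sex are dropped from both matrices (logged).
Rank-based tests are used throughout: Kruskal-Wallis for the male-female
location shift in condensed distances, Spearman for the association of the
disparity difference with one sex's inter-species distances.
Distinctiveness ranks species by their minimum or mean centroid distance to
all others; ties break lexicographically so rankings are deterministic.

## Phylogenetic validation

Neighbour joining (Saitou-Nei) is implemented exactly, with two policies
where the textbook algorithm is silent: Q-criterion ties break at the
smallest (row, column) pair under canonical (sorted-label) order, and a
negative branch-length estimate is clamped to zero with the deficit moved
to the co-joined branch, preserving the joined pair's distance.  On
additive matrices the output reproduces the input patristic distances to
1e-8.  Trees are rooted, when needed, at the midpoint of a designated
outgroup's pendant edge (idempotent; path lengths unchanged).

The branch-score (Euclidean branch-length) distance is computed over the
union of the two trees' bipartitions, encoded as normalised leaf bitmasks;
the two edges either side of a root contribute their summed length to one
split, so rooted and unrooted representations of the same tree compare
equal.  Clade depth is the maximum path length from a clade's MRCA to its
member terminals ("highest" read as furthest from the MRCA; the alternative
reading — height above the root — was rejected as it depends on rooting
depth rather than clade structure).

**Congruence.**  An embedding-space tree carries arbitrary units, while
gene trees are on a time or substitution scale, so congruence analysis
normalises every tree to unit total branch length by default — a shape-only
comparison (`normalize=None` restores raw scales).  The report comprises
(i) branch-score distances from the phenotypic tree to each gene tree,
(ii) distances among gene trees (all pairs up to 2000, else a seeded
subsample of at most 10,000), and (iii) distances from the phenotypic tree
to `n_random` random trees — uniform coalescent-style topologies with
branch lengths resampled from the pooled gene-tree edges, the null chosen
because it holds the branch-length distribution fixed while destroying
topology.  Two summaries matter: the Kruskal-Wallis test between (i) and
(iii), and whether the median of (i) lies within the range of (ii) — the
embedding agreeing with the genes about as well as the genes agree among
themselves.

## Pixel baseline

The deliberately simple comparator: Pearson correlation of overlying RGB
pixels between uniformly rescaled images (the first image sets the
dimensions; the second is rescaled to match; ventral images are flipped
horizontally first), pooled across channels by default (per-channel
correlation with channel-mean r is available).  Species-level distance is
1 - mean correlation over sampled cross-species image pairs; constant-image
comparisons contribute r = 0 with a logged count so means stay defined on
flat synthetic backgrounds.  The same NJ step turns the matrix into a
baseline tree, optionally after rescaling the matrix to a proportion of its
maximum.

## Numerical and testing choices

Image rescaling is bilinear with round-half-to-even widths (minimum 1) —
deterministic across platforms.  The encoder runs in float32; its gradients
are verified against central finite differences on a float64 copy.  Problem
sizes in the test suite follow the study conditions above (8 species, 12
images per cell, 150 epochs, 10 seeds per regime for the sign-recovery
checks; 3 x 10-epoch ensembles, 100 gene trees and 200 random trees for
congruence; 200 random matrices/triples for the NJ and tree-metric
property suites).  Stochastic pipeline guarantees are stated as seed
majorities (at least 9/10 for disparity sign, at least 8/10 for congruence)
rather than per-seed certainties: individual tree realisations can be
intrinsically hard — a species tree with short internal edges narrows the
gene-gene distance range below what any image-derived tree can reach.

## Known limitations

The renderer is a low-dimensional cartoon; it cannot test robustness to
photographic nuisance variation.  The gene-tree model jitters the species
tree rather than simulating coalescence, so gene-tree discordance is
symmetric and topologically local.  The congruence normalisation makes the
comparison shape-only; absolute rate information in the embedding is
deliberately discarded there.  Clade-depth values are in embedding units
and are comparable only within one embedding.
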