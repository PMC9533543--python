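# Methods

`karyoevo` re-implements, as one tested pipeline, the bespoke computations of
a eudicot karyotype-evolution analysis: reconstruction of an ancestral
karyotype from pairwise chromosome collinearity, projection of that
karyotype onto extant genomes with copy labelling, classification of
chromosome fusions and a shared-vs-independent fusion test, polyploidy
inference from syntenic-block Ks distributions and collinear gene trees, and
a per-node decomposition of gene-tree discordance into estimation error,
incomplete lineage sorting (ILS) and hybridization.  A genome-evolution
simulator supplies ground-truth inputs, so every stage is scored against a
known answer without external data.

## The simulator (`genome`, `clade`)

A genome is an ordered list of chromosomes, each an ordered list of genes
carrying a family label, an orientation, and the true ancestral chromosome
and index they descend from.  Coordinates are 0-based gene-order indices;
intervals are half-open.  Events:

* **WGD / WGT** — every chromosome gains one or two extra copies.
  Fractionation is per-family Bernoulli retention of the extra copies
  (scalar retention *r* keeps the pre-duplication copy always and each extra
  copy with probability *r*); a per-copy retention vector models
  subgenome-biased loss, with the guarantee that no family ever loses its
  last copy.  Copy *c* of gene *x* is renamed `x.c` (including `.0`), so a
  gene id encodes its full copy path through successive polyploidies — this
  is what dates paralog pairs for Ks emission.
* **EEJ** — concatenation of two whole chromosomes (tail-to-head by default;
  other end combinations reverse the joined partner).  **RTA** — reciprocal
  arm exchange at interior breakpoints `(bx, by)`, producing
  `X[0:bx]+Y[by:]` and `Y[0:by]+X[bx:]`.  **NCF** — insertion of all of Y
  into the interior of X.  **FISSION** and **INVERSION** as usual.  All
  events except fractionation preserve the gene multiset.

`simulate_clade` evolves the ancestor down a newick species tree under a
per-branch scenario.  Unspecified choices (which chromosomes fuse, where
breakpoints fall) are drawn from a single seeded generator in preorder, then
recorded explicitly, so replaying the event log reproduces every tip genome
byte-identically — the replay identity is a standing test.  Branch lengths
are ages in arbitrary time units; event ages default to even spacing along
their branch.

**Ks emission**: a pair of same-family genes whose lineages diverged at age
*a* receives a lognormal draw with median `a * ks_per_age` and coefficient
of variation `cv` (`sigma = sqrt(log(1 + cv^2))`; `cv = 0` degenerates to
the exact median).  Paralog divergence ages come from the copy paths,
ortholog ages from the species-tree node (or an older shared polyploidy).
This stands in for codon-level Ks estimation, which is out of scope: the
emitted values have the clustering-around-event-ages structure the peak
fitting assumes, not the rate heterogeneity of real Ks.

### The declared study scenario

The *moderate scenario* (in `scenarios`) fixes the simulation conditions all
recovery results refer to: a 7-chromosome ancestor with chromosome sizes
160/140/130/120/110/100/90 genes (850 families; unequal sizes make fusion
products dominated by one ancestral chromosome, as in real karyotypes); six
species on the tree `(((S1,S2),S3),((S4,S5),S6))`; one WGD per lineage
except a WGT in S3, duplicate retention 0.7; five fusions across lineages
(two EEJ, two RTA, one NCF); inversions with span at most 25% of the
chromosome (real inversions are sub-chromosomal; unbounded spans would also
make "order agreement with the ancestor" an ill-posed target for the
reconstruction, since the ancestral order would not survive in any
descendant).

What the generator does **not** emulate: tandem duplications and multi-copy
families predating the polyploidies, translocations smaller than an arm,
gene-order noise from annotation error, missing assemblies, and
rate-variable Ks.  Recovery results under the scenario therefore bound what
the method can do when its assumptions hold; they do not certify performance
on real genomes.

## Synteny (`synteny`)

Anchors are all same-family gene pairs between two chromosomes (all copy
combinations; a self-comparison excludes the trivial diagonal).  A block is
a chain of anchors strictly monotone in both genomes with at most `max_gap`
(default 25) intervening genes between consecutive anchors on either side
and at least `min_anchors` (default 5) anchors.  Chains are extracted
best-first by an O(n^2) dynamic program (both orientations), removing each
chain's anchors and repeating, so overlapping polyploidy-derived blocks on
one chromosome pair are all retained.  On small inputs the first chain is
tested against an exhaustive enumeration oracle.

The collinearity ratio is `x_ij = 2 CN_ij / (N_i + N_j)`, with `CN_ij` the
number of anchored gene pairs (each pair counted once across blocks) and
`N` the chromosomes' gene counts; identical chromosomes get exactly 1.  The
matrix spans every chromosome of every species, including intragenomic
pairs — post-polyploidy homologous copies attract each other into the same
cluster.  Rows are Z-transformed (`Zx_ij = (x_ij - mu_i) / sigma_i`, mean
and sample SD over row *i* excluding the diagonal; a zero-spread row is an
error naming the chromosome).  Row-wise normalisation is asymmetric, so the
matrix is symmetrised by arithmetic mean before clustering; distance is
`max(S) - S`; agglomerative clustering with average linkage; the cluster
count is user-fixed or selected by maximum mean silhouette over k in
[2, 12].  Under the moderate scenario the silhouette profile peaks sharply
at the true count (7), and fused chromosomes join the cluster of their
dominant ancestral component.

**Syntenic depth**: the genome is tiled into `window`-gene windows (default
20) and each window counts the distinct partner blocks that span it; the
modal count over covered windows, in each direction, is the depth ratio
(2:1 for one unshared WGD, 3:2 for WGT vs WGD, and so on).

## Ancestral-karyotype reconstruction (`aek`)

Per cluster, the member with the highest mean collinearity ratio to the
other members is the reference (ties: more genes, then lexicographic id).
Donors are processed in decreasing mean collinearity to the reference, so
the most reliable donor wins family collisions.  Within a single block,
for each pair of anchors adjacent in the block, donor genes strictly between
them — at most `max_intervening = 5` — whose families are not yet present
are inserted between the two reference anchors, preserving donor order
(reversed for orientation −1 blocks); anchor pairs whose reference families
have crossed (earlier insertions or duplications) are skipped and logged.
Family uniqueness within an ancestral chromosome is enforced throughout.
Ancestral chromosomes are numbered by descending family count.

**Projection** treats the reconstruction as a pseudo-genome (gene id =
family id) and re-runs block detection against the target.  An anchored
gene takes its best block's coordinates (score, then lower ancestral
chromosome/index); an unanchored gene flanked within 10 genes on both sides
by anchors of the same ancestral chromosome inherits it with a linearly
interpolated (fractional) index; everything else stays unassigned.

**Copy labelling** groups painted segments of one ancestral chromosome
greedily: the largest unused segment seeds a copy, and segments whose
covered ancestral positions overlap the copy's by less than 20% of their own
extent join it.  Copies are ranked by completeness (covered fraction of the
ancestral chromosome) and labelled A, B, C, … with deterministic tie-breaks
(target chromosome id, then position).  Segment-interleaving genuinely
under-determines copy delimitation; the 20% rule is one defensible
convention and is exposed as a flag.

## Fusion classification (`fusions`)

Paintings are condensed to segment strings: maximal same-(ancestral
chromosome, copy) runs, with runs shorter than `min_seg = 10` absorbed into
agreeing flanks or dropped.  Patterns: X–Y–X is an **NCF** candidate; X–Y on
one chromosome is an **EEJ** candidate when the joined extremities map
within `end_eps = 10` genes of the ancestral termini, and otherwise feeds an
exhaustive **RTA** pairing search for a second chromosome carrying the
complementary pieces (interval overlap at most `end_eps`).  Coverage
thresholds (`tau = 0.8`) are evaluated against the participating **copy's
genome-wide extent**, not the raw ancestral length: a whole 70%-retained
subgenome copy is a complete fusion participant, which keeps the classifier
working under realistic fractionation while coinciding with the
ancestral-length denominator in loss-free settings.  Junctions are the
inter-gene positions between adjacent segments, with flanking genes and
their ancestral coordinates.  Calls are invariant to copy relabelling and
to whole-chromosome reversal; unmatched multi-segment chromosomes are
reported UNCLASSIFIED rather than forced.

**Shared vs independent fusions.**  Two species' fusions of the same
ancestral pair are *shared* only if collinearity runs intact through the
fusion point: some single block between the two species must cross both
junctions, the block's unique crossing of each junction must skip at most
`window = 10` genes in both coordinate systems, and the two crossings must
be the same place in the chain (within `window` anchors).  The
same-chain-position requirement matters: with `max_gap = 25`, a chain can
"teleport" across a convergent junction by skipping up to 25 genes and
would otherwise fake continuity.  The test is evaluated in both directions
and is symmetric.  Convergent fusions closer than about `window` genes are
genuinely indistinguishable by this criterion, which is a property of the
method, not of the implementation.

## Polyploidy inference (`polyploidy`)

Blocks are summarised by their exact median Ks (NaNs skipped; empty blocks
omitted with a warning).  Peaks are fitted on log Ks — Ks peaks are
right-skewed, mixtures of Gaussians on the log scale fit them with fewer
components — inside a window of [0.01, 3], with 1..4 components, five
seeded initialisations each, and BIC model selection; at least 20 values are
required.  Modes are reported as exp(mean).

The **monophyly test** takes collinear gene trees whose leaves are labelled
`species|copy`.  Per tree (alternating which species roots, seeded), a
random copy of the rooting species is the outgroup; the tree supports
*independent* polyploidy when the other species' retained copies form a
monophyletic clade — checked directly on the unrooted splits (a clade under
leaf-rooting is a split isolating exactly those copies away from the root
leaf), which avoids any rerooting machinery.  Trees lacking a rootable copy
or two copies of the non-rooting species are skipped and tallied.

## Discordance decomposition (`discordance`)

* **Gene-tree support**: per internal species-tree bipartition, the
  percentage of gene trees (pruned to shared taxa) whose splits contain the
  restricted bipartition; trees uninformative for a bipartition leave its
  denominator.  A node whose outside is a single taxon (e.g. adjacent to a
  lone outgroup) is undefined rather than 100%.
* **Theta**: `theta = 2 m / d` from a branch's length in mutation units
  (substitutions/site) and coalescent units; with `d = t/2N` and
  `m = mu t`, this is `4 N mu`.  The constant 2 is a convention of this
  derivation and is kept explicit in the op.
* **MSC simulator**: structured coalescent down the species tree (rate
  k(k−1)/2 per branch, tips one lineage each by default) with optional
  introgression pulses that reroute recipient lineages to the donor branch
  with probability gamma.  Its oracle is the closed form
  `P(concordant) = 1 − (2/3) e^{−T}`, and it is cross-checked against an
  independent coalescent implementation in the tests.
* **Estimation error**: alignments are simulated under GTR on the species
  tree itself (gene tree ≡ species tree, so every failure is estimation
  error), with the rate matrix normalised to one expected substitution per
  unit branch length; trees are rebuilt by neighbour joining on
  Jukes–Cantor-corrected distances (saturated replicates are skipped and
  tallied).  NJ-on-corrected-distances replaces maximum likelihood: it
  preserves the construct — support loss from finite data — at desk scale.
  Defaults 200 alignments of 1500 bp.
* **Reticulation index**: under pure ILS the two minor topologies of any
  rooted triplet around a node are equally frequent; gene flow breaks the
  symmetry.  Per node, triplet combinations (one taxon per child subtree,
  one from outside, excluding the outgroup; capped at 200, seeded) are
  tested by a **two-sample** 2×2 chi-square of observed minor counts
  against the minors of ILS-only trees simulated on the same species tree —
  two-sample because the null calibration carries its own sampling noise; a
  one-sample test against the null point estimate rejects spuriously on
  short branches where minor counts are large.  Benjamini–Hochberg across a
  node's combinations at alpha = 0.05; the index is the rejected fraction,
  and the raw mean minor imbalance |m1−m2|/(m1+m2) is emitted alongside so
  either convention can be reported.
* **lmg**: each predictor's importance is the average over all orderings of
  its R² increment, computed via the subset-weight identity
  `sum_S |S|!(p−1−|S|)!/p! [R²(S∪j) − R²(S)]`; shares sum to the full-model
  R² to 1e−10 and the implementation is validated against an independently
  coded 6-ordering enumerator.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
The sizes used throughout — 850–1700-gene genomes, 2000 gene trees for
closed-form checks, 200–800 trees and 200 alignments for the discordance
stages — were chosen as the smallest at which the statistical targets are
comfortably inside their sampling error, and the full suite runs in about a
minute.  `scripts/acceptance.py` recomputes the two headline targets (the
seven-cluster recovery and the 2:1 syntenic depth) from scratch at any seed.

## Known limitations

* Clustering quality degrades when fusions outnumber intact chromosomes or
  when retention drops well below 0.5; the silhouette-selected k is then no
  longer anchored by pure-chromosome clusters.
* The augmentation order (most-collinear donor first) is a declared
  convention; collision handling between donors is otherwise
  under-determined.
* Copy delimitation with interleaved segments, the fusion-coverage
  threshold, and the shared-fusion window are conventions exposed as flags,
  not uniquely determined by the underlying method description.
* Ks values are emitted, not estimated from sequences; conclusions about
  peak-fitting robustness to codon-level estimation noise are out of reach.
* The theta recovery demonstrated in the tests reads both unit systems from
  distance-based re-estimates on simulated data; with real data both come
  from external inference (ML branch lengths, quartet-based coalescent
  lengths) whose biases are not modelled here.
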