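# Methods

## The simulation in one paragraph

`fedvar` studies cross-silo, horizontal federated learning for binary variant
pathogenicity classification: a small number of always-available institutional
clients share one feature space but hold disjoint samples. Each federated
round, the server broadcasts the global model to a sampled subset of clients,
every selected client runs 10 local epochs of mini-batch training on its own
variants, and the server combines the returned parameter vectors. The
package compares this against centralized training on the pooled data (CDS)
and against per-silo models, using AUC-ROC over repeated weight
initializations as the metric and the median as the cross-seed summary.

## Synthetic cohorts

Real multi-institutional variant collections cannot be redistributed, so the
generator emulates their structure rather than their content.

**What is emulated.** Skewed silo sizes (configurable per silo; the packaged
scenarios use 64.8%→3% for coding SNVs, 45.5%→2% for non-coding SNVs, and a
90%-dominant silo for CNVs); 1:1 class balance via per-silo downsampling of
the majority label; a temporal split (training records dated before the split
date, a later-submissions test pool after it); a second test pool attributed
to institutions absent from training; benign CNVs paired to pathogenic CNVs
by genomic length (greedy nearest neighbour on |Δ log length|, descending
pathogenic length, the matched benign record inheriting the pathogenic
record's submission date); and per-silo distribution shift.

**Generative model.** Continuous payload coordinates (35 conservation values
for SNVs; quantitative gene/region annotations for CNVs) follow class-
conditional Gaussians with shared unit variance. `class_separation` is the
standardized mean difference per informative coordinate and `n_informative`
confines the signal to the first *k* coordinates; bounded quantities
(coverage fractions, probabilities) are squashed/clipped after drawing, flags
are Bernoulli with a mild class tilt, CNV lengths are log-normal, and
chromosomes are uniform over the 23 symbols (1–22, X; Y is absent from the
study design). Silo-level non-IID structure comes in two forms:
`feature_shift` adds a constant (scalar or per-coordinate) offset to all of a
silo's records — a pure covariate shift — while `pathogenic_shift` offsets
only the pathogenic class, reproducing the empirically observed pattern of
pathogenic variants clustering by their client of origin. The clustered form
is the package's "strong non-IID" regime: a silo-constant covariate shift is
largely absorbed by the first-layer bias of an MLP and barely perturbs
federated averaging, whereas class-conditional clusters make each client's
locally optimal decision rule genuinely different.

**What is not emulated.** Real annotation pipelines (conservation tracks,
constraint scores and regulatory builds arrive as synthetic tables, not from
genome resources); linkage between chromosome and features; submission-date
dynamics beyond the before/after relation; label noise and database
re-classification. Consequently, passing tests demonstrate that the
*machinery* (encodings, optimizers, aggregation, evaluation designs) behaves
correctly and that the federated-vs-centralized contrasts behave as expected
under controlled distributional regimes — not that any particular AUC value
transfers to real cohorts.

## Feature encodings

SNVs: 25 one-hot values (position-major, alphabet order A, C, G, T, N) for
the 5-nucleotide window centred on the mutated position, then phyloP100 and
phyloP470 over positions 1–5, then phyloP3, phyloP4, phyloP7, phyloP17,
phyloP20 — 60 features.

CNVs: 38 features = 22 gene-based + 16 region-based. Gene-based quantitative
scores are aggregated by the maximum across overlapping genes, except minimum
expression and the shortest paths to haploinsufficient/triplosensitive genes,
which take the minimum; categorical gene attributes (ohnolog, transcription
factor, protein-complex membership) encode presence of ≥1 gene with the
attribute. The flat order is frozen in `CNV_FEATURE_NAMES`; the published
group list does not fully determine a 38-column split, so this package fixes
one: haploinsufficiency and triplosensitivity predictions are separate
columns, mean and minimum expression are separate columns, the six
protein-network features are degree, PageRank, betweenness, clustering
coefficient and the two shortest paths, and an overlapping-gene-count column
completes the gene block. When no gene overlaps the CNV, max-aggregated
scores and flags are 0 and the shortest-path minima take the sentinel 10.0
(a large network distance). Features are z-scored with moments fitted on the
training split only (shared with clients; this leaks only per-feature first
and second moments).

## Models

**MLP.** "Three-layer" counts input, hidden, output: one rectified hidden
layer whose width (3–9) is the tuned architecture hyperparameter, sigmoid
output, binary cross-entropy loss. Optional batch normalization on the hidden
pre-activation (eps 1e-5, running-stat momentum 0.1); inference always uses
running statistics, so scoring is deterministic.

**Shallow neural decision forest.** Trees are full binary trees of depth
3/6/9 in heap order; a fully connected layer (per tree, over a fixed random
feature subset drawn once at initialization with probability `feature_rate`
per feature) produces one activation per split node; routing probability is
the sigmoid of the activation; leaf reach probabilities are telescoping
products along root-to-leaf paths (they sum to one by construction); leaf
class distributions π are softmax-parameterized logits; the forest averages
tree mixtures, and the loss is the negative log-likelihood of the forest
probability. π is trained **jointly by gradient** with the split weights
rather than by alternating convex updates: joint training keeps every
trainable quantity inside one flat parameter vector, which federated
parameter exchange requires (an alternating update has no federated
counterpart). Masks travel in the parameter vector as a non-trainable
segment so all clients route identically; masked weights and their gradients
are zeroed.

Both models are implemented directly on NumPy with analytic gradients; the
test suite validates every backward pass against central finite differences
(relative error < 1e-4, with an absolute floor for coordinates whose true
gradient vanishes, e.g. the hidden bias under batch normalization).

## Local training

SGD with momentum 0.9 or Adam (β₁ = 0.9, β₂ = 0.999), learning rate from
{0.1, 0.01, 0.001, 0.0001}, batch size from {4, 8, 16, 32}, 10 local epochs,
L2 weight decay 1e-4 applied through the gradient (coupled, as in framework
SGD/Adam defaults). FedProx adds μ(w − w_anchor) to the gradient (i.e. the
(μ/2)‖w − w_anchor‖² penalty), anchored at the round's broadcast model.
Batch shuffling, weight initialization and client sampling all derive from a
single root seed via seed sequences keyed by (seed, round, client), so runs
are bit-reproducible and a single-client federated run is *identical* to the
centralized trajectory under the same seed.

## Federation

- Client sampling: ⌈rate·n⌉ with round-half-up and a floor of one client,
  uniform without replacement.
- FedAvg/FedProx aggregation: size-weighted mean over the **selected**
  clients, weights renormalized over the round's participants.
- Adaptive family: pseudo-gradient Δ = weighted mean − global; v initialized
  to τ²; update rules as in the README table; server step η·m/(√v + τ).
- Batch-norm policy: `aggregate` exchanges BN affine parameters and running
  statistics like any weight; `keep_local` excludes them from exchange and
  persists them per client.
- Early stopping is evaluated once per **round** on the collaborative
  validation set with patience 20 ("20 consecutive epochs" maps to rounds,
  the server's unit of progress); the best-round parameters are returned.
  Centralized training is organized into blocks of 10 epochs with the same
  controller so the two regimes share the stopping rule.
- The server interface accepts only `(parameters, sample count)` updates;
  raw feature matrices never reach it.

## Evaluation designs

- **LOCO**: 23 folds, one per chromosome symbol; a variant is scored only by
  the classifier whose training set excludes its chromosome. Degenerate folds
  (empty held-out or empty training side) are retained and flagged.
- **Collaborative cross-validation**: each silo splits its own records into k
  near-equal folds (sizes differ by ≤1); global fold f is the union of silo
  folds f; centralized and federated comparisons consume the identical plan.
- **AUC-ROC**: normalized Mann–Whitney U with average ranks (ties count ½).
- **Dropout study**: all-clients plus one-excluded conditions (K+1 per mode);
  the all-clients condition reuses the standalone code path and seeds
  exactly.
- **IID-repartition null**: random reassignments of training rows to silos of
  unchanged sizes; per partition, the median test AUC over 3 weight seeds;
  the original partition's median is z-scored against the null (z undefined
  with a warning when the null variance is zero) and compared with the
  Q1 − 1.5·IQR whisker. p-values are two-sided normal, an approximation that
  assumes near-normal null medians.
- Model-family comparisons use the two-sided Wilcoxon rank-sum test on
  per-seed AUCs, without multiplicity correction.
- The hyperparameter grid reproduces the benchmarked 1344 settings: per
  model family, FedProx 4×2×2×6 = 96 plus three adaptive algorithms at
  4×2×2×4×3 = 192 each; the MLP batch-norm toggle is a model-config flag,
  not a grid axis.

## Desk-scale study conditions

The packaged experiments run at sizes chosen once for a single CPU
(`fedvar.presets`):

- *separable_two_silo*: 2×1000 training variants, separation 1.0 s.d. on all
  35 coordinates, 500-variant test pools, MLP hidden 8, FedAvg 30 rounds —
  the federated/centralized agreement scenario.
- *iid_null_cohort*: 2×150 variants, separation 0.8 s.d. on 5 coordinates
  (model AUC ≈ 0.8, far from saturation so the null has usable variance),
  300-variant test pools, MLP hidden 4, FedAvg 8 rounds, 20 null partitions
  × 3 seeds. Null calibration is assessed by redrawing the 20-partition null
  10 times against the same cohort and requiring |z| ≤ 2 in ≥9 of the 10
  redraws — with only 20 null draws the z statistic is t-like, so a fresh
  cohort per repeat would conflate calibration with binomial noise.
- *clustered_noniid_cohort*: 6 silos × 50 variants with silo-specific
  pathogenic clusters (±3 s.d. random sign patterns, directions fixed by a
  dedicated seed): the original partition's median AUC falls far below the
  IID null (z around −5 to −17 depending on the seed), reproducing the
  signature expected for non-IID silos.

The full-scale defaults (200 rounds, 30 evaluation seeds, 100 null
partitions, 10-fold CCV) remain the library defaults and are overridable
everywhere.

## Known limitations

- Batch-norm aggregation averages running variances linearly, one of several
  defensible conventions; with `keep_local`, clients that are never sampled
  retain the server's initial statistics.
- The sNDF forgoes the alternating π update of the original formulation
  (see above); on hard tasks this can converge slower than the alternating
  scheme.
- The IID-null z assumes approximately normal null medians; with 20
  partitions the tails are heavier than normal, which is why calibration is
  judged over repeated null redraws.
- Everything runs in-process; no transport, stragglers, secure aggregation,
  or privacy mechanisms (encryption, differential privacy) are simulated.
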