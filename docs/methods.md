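# Methods

## The problem and the model

Cell-free DNA (cfDNA) fragments in plasma carry nuclease-cleavage
signatures at their 5' termini. The k-nucleotide sequence at a fragment's
5' end — its *end-motif* — has a frequency distribution over the 4^k
possible motifs that shifts in cancer, which makes end-motif profiles a
liquid-biopsy marker. This package models a sample's end-motif profile not
as a raw frequency vector but as a **ranking**: the motifs sorted by
frequency in descending order, wrapped as a token sequence
`[CLS, m0, m1, ..., mt', SEP]` (ties broken lexicographically;
t motif slots, PAD after SEP when fewer motifs are observed). Rankings
discard depth and scale information, which makes them insensitive to many
technical artifacts while retaining the ordering structure that
distinguishes groups.

A BERT-style transformer encoder is pretrained on such rankings with a
masked-language-model objective:

- **Embedding.** Token embeddings X and learned position embeddings P are
  summed element-wise; the encoder input is X + P.
- **Encoder layer.** Multi-head scaled dot-product self-attention
  (`A = softmax(QK^T / sqrt(d_k))`, output `A V`, heads concatenated),
  residual connection, layer normalization; then the position-wise
  feed-forward network `FFN(x) = max(0, xW1 + b1) W2 + b2`, residual,
  layer normalization (post-LN ordering).
- **Projection head.** A two-layer map with a layer normalization between
  the layers (linear d→d, ReLU, LayerNorm, linear d→vocabulary), producing
  a distribution over the vocabulary at each position.
- **Corruption scheme.** 15% of motif positions per sequence are selected
  (CLS/SEP/PAD never); a selected position becomes the MASK token with
  probability 0.8, a uniformly random motif with 0.1, and stays unchanged
  with 0.1. The loss is cross-entropy at selected positions only. Model
  fit is tracked as the exponentiated cross-entropy (ECE), `exp(mean CE)`:
  1 for a perfect predictor, the vocabulary size for an uninformed one.

After pretraining the encoder is frozen. The final-layer hidden state at
the CLS position is the sample representation (mean pooling over non-PAD
positions is available behind a flag); an L2-regularized logistic
regression probes it for cancer/control status under stratified five-fold
cross-validation, and all metrics are computed from the pooled out-of-fold
probabilities.

## Implementation

The forward and backward passes and the AdamW-style optimizer are written
directly in NumPy (float64). Gradients are exact and are verified in the
test suite against central finite differences on a two-layer model.
Decoupled weight decay applies to 2-D weight matrices only (not biases or
layer-norm parameters), the usual transformer convention.

## Parameters and defaults

| Parameter | Default | Notes |
|---|---|---|
| k (motif length) | 4 | 256 motifs, vocabulary 260 with CLS/SEP/MASK/PAD |
| t (ranked motifs per sequence) | 128 | supported 1..255; probing lengths 64–256 all fit the positional table |
| hidden size d | 64 (desk) | published-scale sizes are 384/768/1536 |
| heads h | 2 (desk) | d must divide by h |
| layers L | 1 | single-layer parameter counts at d = 384/768/1536 (~2M/8M/32M) match the published model-size ladder under a parameters-in-millions reading; configurable |
| FFN width | 4d | standard convention |
| dropout | 0.1 | disabled in evaluation mode |
| max positions | 258 | t = 256 plus CLS and SEP |
| batch size | 256 | desk-scale runs use 64 |
| weight decay | 0.01 | decoupled |
| peak learning rate | 1e-4 | desk-scale runs use 1e-3 (few optimizer steps) |
| schedule | 1-epoch linear warmup, cosine decay to 0 | warmup shortened when the whole run is one epoch |
| epochs | 40 | desk-scale runs use 5–20 |
| holdout | 5,000 sequences | desk-scale 200 |
| masking | 15% selected; 80/10/10 MASK/random/keep | forced single selection when Bernoulli picks none, so every sequence has a defined loss |

A "random motif" replacement is drawn uniformly from the 4^k motifs and
may coincide with the original; observed random/keep shares therefore
shift by ~1/4^k, which the tests' tolerances absorb.

## Evaluation statistics

- **AUROC / DeLong.** The AUROC is the Mann-Whitney statistic with ties
  counted 1/2. Variance, confidence intervals and the paired two-model
  test use DeLong's structural components (placement values). The
  implementation is cross-checked against exhaustive pair counting and
  against R's pROC.
- **Clopper-Pearson.** Accuracy/sensitivity/specificity intervals are the
  exact two-sided binomial intervals via beta quantiles. Note that for
  x = n the exact lower bound is (alpha/2)^(1/n) — e.g. 0.832 for 20/20 —
  and the interval upper bound is 1.
- **Attention interpretation.** alpha_{CLS,j}, the attention CLS places on
  motif j, scores that motif's influence on the sequence representation.
  Scores are keyed by motif identity, since positions are not comparable
  across samples; a motif absent from a sample's ranking is missing data,
  not zero. Group comparison is a two-sided Wilcoxon rank-sum test by
  default (Welch t-test optional), with Benjamini-Hochberg adjustment
  across motifs within each head; a motif enters a head's comparison only
  if observed in both groups. Motif-motif networks accumulate alpha_{i,j}
  over a group's sequences (special tokens excluded, no self-loops) and
  keep the top retention fraction (default 0.1%) of observed ordered pairs
  by cumulative weight, ties broken deterministically by weight then motif
  pair; edges are directed because attention is asymmetric.
- **Motif diversity score.** Normalized Shannon entropy
  `sum_i -P_i ln(P_i) / ln(4^k)`, in [0, 1]; the log base cancels.
- **kBET.** For each sample, the batch composition of its K = 5 nearest
  neighbors (Euclidean, self excluded) is tested against the global batch
  frequencies with a chi-square statistic on m - 1 degrees of freedom; the
  acceptance rate is the percentage of samples with p >= alpha = 0.05.
  The test is representation-agnostic: it can run on frequency vectors,
  rankings' representations, or any embedding.

## Synthetic data: what it emulates and what it does not

The generator models per-sample motif usage as Dirichlet-multinomial:
sample i draws p_i from a Dirichlet with per-motif concentration alpha
(default 50, giving ~1/sqrt(50) ≈ 14% between-sample coefficient of
variation per motif), then draws `reads_per_sample` (default 50,000)
multinomial end-motif counts. The cancer group multiplies the
concentration of the signal motifs — default CCCA, CCAG, CCTG, motifs
reported as over-represented in hepatocellular-carcinoma plasma — by
(1 + effect_size); effect_size = 0 gives an exact null with one shared
generating distribution. Cohort defaults are 100 cancer + 100 control. An
optional batch effect tilts a disjoint motif set the same way, with
batches alternating across samples within each group so batch and group
are never confounded by construction. Profiles expand to FASTQ (first k
bases = assigned motif, random tail, constant qualities) so the
read-level extractor is exercised end to end.

What this does *not* emulate: genome-positional fragmentation, fragment
size distributions, sequence-composition biases, GC effects, mixtures of
tumor fractions, or assay-specific chemistry (bisulfite conversion,
5hmC pulldown). Passing tests therefore demonstrate that the pipeline
recovers planted ranking structure of realistic magnitude — not clinical
performance on real cfDNA cohorts, which depends on signals and
confounders the generator does not model.

## Desk-scale protocol used by the test suite

Full-scale pretraining (hundreds of thousands of sequences, d >= 384) is
out of scope for a library test run; the suite instead checks the same
qualitative behaviors at reduced size:

- **Fit trend.** Corpus of 2,000 sequences (t = 32, 40 generating
  samples), d = 64 vs d = 128, one layer, batch 64, peak LR 1e-3,
  5 epochs, 5 seeds: holdout ECE decreases across epochs in every run and
  the wider model attains the lower mean final ECE.
- **Signal recovery.** A d = 64 model pretrained 20 epochs on the same
  kind of corpus (final holdout ECE ≈ 178, down from ≈ 260 at
  initialization) is frozen and probed on fresh cohorts of 100 + 100
  samples at 50,000 reads each: effect_size = 5 yields probe
  AUROC ≥ 0.99; effect_size = 0 stays at chance.
- The desk-scale learning rate 1e-3 compensates for the small number of
  optimizer steps (~150 at batch 64); the published 1e-4 is the default
  at full scale.

## Numerical and design choices

- Ranking ties are broken lexicographically — deterministic serialization
  was preferred over random tie-breaks.
- Augmented corpora partition a sample's shuffled reads into disjoint
  blocks (sampling without replacement), one sequence per block; the
  incomplete trailing block is dropped. Probing uses one sequence per
  sample built from all of its reads; augmentation is for pretraining
  only, since labels are per-sample.
- Reads shorter than k or starting with non-ACGT bases are skipped and
  counted, never mapped to an UNK bucket: the dictionary has exactly 4^k
  motifs. In alignment-oriented mode, reverse-strand alignments are
  reverse-complemented before taking the prefix so the motif reflects the
  fragment's true 5' terminus; raw-read mode (prefix as sequenced) is the
  default. Only the first mate of paired-end input is used unless both
  are requested.
- PAD positions are excluded from attention via a key mask; logits at
  real positions are provably invariant to PAD-tail length (tested).
- Layer-norm epsilon 1e-5; masked attention bias -1e9; ECE guards
  log(0) with a 1e-300 floor.
- Checkpoints are single .npz archives with an embedded config and schema
  id; reloading reproduces forward outputs bit for bit.
- All randomness in a training run (holdout split, shuffling, corruption,
  dropout, initialization) derives from one seed.

## Known limitations

- Single-threaded NumPy training: practical up to ~10^4 sequences and
  d ≈ 128; the published scale requires a GPU framework.
- The linear probe fixes the L2 strength (C = 1) rather than tuning it,
  keeping the probe a plain linear projection; reported AUROCs are
  therefore conservative.
- DeLong intervals are normal-approximation and truncated to [0, 1];
  they degenerate when the AUROC is exactly 1.
- kBET neighbor ties (exactly equal distances) are resolved by the
  underlying k-d tree's deterministic ordering, which matters only on
  artificial integer-valued embeddings.
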