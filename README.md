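# emit

Self-supervised modelling of cell-free DNA (cfDNA) 5'-end motif rankings
for liquid-biopsy analysis.

cfDNA fragments are cut by nucleases whose preferences leave a signature in
the first k bases of each fragment — its **end-motif**. The distribution of
the 256 possible 4-mers shifts in cancer patients. This package represents
a sample not by its raw motif frequencies but by their **ranking**: the
motifs sorted by descending frequency and encoded as a token sequence
`[CLS, m0, ..., mt, SEP]`. A BERT-style transformer encoder is pretrained
on such rankings with a masked-language-model objective (15% of motif
tokens corrupted, 80/10/10 MASK/random/keep), and the frozen CLS
representation is then probed with a linear classifier for cancer/control
status. The stack also provides:

- end-motif extraction from FASTQ/FASTA/SAM/BAM (raw-read or
  alignment-oriented 5'-end handling),
- CLS-attention interpretation of motif importance with group tests
  (Wilcoxon / Welch, Benjamini–Hochberg) and motif–motif attention
  networks,
- evaluation statistics: DeLong AUROC confidence intervals and paired
  tests, exact Clopper–Pearson intervals, the motif diversity score
  (normalized Shannon entropy), and the kBET batch-mixing test,
- a Dirichlet-multinomial synthetic-cohort generator (with FASTQ export)
  so the entire pipeline runs without any external data.

The transformer forward/backward passes and the AdamW optimizer are
implemented in NumPy; gradients are verified against finite differences in
the test suite.

## Worked example

```python
import numpy as np
from emit import (CohortSpec, EMITConfig, simulate_cohort,
                  simulate_pretraining_corpus, pretrain, rank_and_tokenize,
                  linear_probe_cv)
from emit.probing import extract_representations

# 1. pretrain on ranked end-motif sequences from a synthetic cohort
corpus, vocab = simulate_pretraining_corpus(
    2000, t=32, spec=CohortSpec(n_cancer=20, n_control=20, seed=0))
config = EMITConfig(hidden_size=64, num_heads=2, num_layers=1,
                    vocab_size=vocab.vocab_size)
model, metrics = pretrain(corpus, config, vocab, batch_size=64, epochs=20,
                          holdout_n=200, seed=0, peak_lr=1e-3)
print(f"holdout ECE {metrics.holdout_ece[0]:.1f} -> {metrics.final_ece:.1f}")

# 2. freeze, represent, and linearly probe a labelled cohort
cohort = simulate_cohort(CohortSpec(n_cancer=100, n_control=100,
                                    reads_per_sample=50_000,
                                    effect_size=5.0, seed=11))
seqs = [rank_and_tokenize(p, 32, vocab) for p in cohort.profiles]
reps = extract_representations(model, seqs, vocab)
probe = linear_probe_cv(reps, cohort.labels, folds=5, seed=0)
print(f"AUROC {probe.auroc:.3f} "
      f"({probe.auroc_ci[0]:.3f}-{probe.auroc_ci[1]:.3f})")
```

Output:

```
holdout ECE 262.0 -> 177.8
AUROC 0.999 (0.997-1.000)
```

The ECE (exponentiated cross-entropy) starts near the vocabulary size 260
— an uninformed predictor — and falls as the model learns the structure of
the rankings. The probe then recovers the planted cancer enrichment of the
CCCA/CCAG/CCTG end-motifs from the frozen representations almost
perfectly; with `effect_size=0` the same pipeline stays at AUROC ≈ 0.5.

## Command line

```bash
emit simulate --out-dir cohort/ --seed 4            # FASTQ + labels + truth
emit extract --reads cohort/fastq/cancer_0000.fastq --out c0.tsv
emit build-corpus --profiles c0.tsv --out corpus.txt --t 128
emit pretrain --corpus corpus.txt --out model.npz --epochs 5
emit probe --checkpoint model.npz --profiles cohort/ \
     --labels cohort/labels.tsv --length 128 --folds 5 --out probe.json
emit attention --checkpoint model.npz --profiles cohort/ \
     --labels cohort/labels.tsv --out-dir attn/
emit mds --profile c0.tsv
emit kbet --matrix embedding.tsv --batches batches.tsv --k 5
```

Each stage writes a manifest (resolved parameters, seed, config hash) so
deterministic stages can be re-run bit-identically.

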