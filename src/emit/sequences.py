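"""Ranked end-motif token sequences and augmented pretraining corpora.

A sample's motif counts are sorted by frequency in descending order and the
top-t motifs are wrapped as ``[CLS, m0, ..., mt', SEP, PAD...]`` — the token
sequence the transformer consumes. For pretraining, a sample's reads are
shuffled and split into disjoint blocks, each block yielding one sequence,
which multiplies the number of training instances without reusing any read.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import (
    CLS,
    PAD,
    SEP,
    EmptyProfileError,
    InvalidParameterError,
    MotifCountProfile,
    MotifDictionary,
    count_end_motifs,
)


@dataclass
class EndMotifSequence:
    """A fixed-length token sequence ``[CLS, m0..mt', SEP, PAD...]``.

    ``attention_mask`` flags non-PAD positions; ``t`` is the configured
    number of motif slots (sequence length is t + 2).
    """

    tokens: list[str]
    t: int
    sample_id: str = ""
    label: str | None = None
    attention_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.attention_mask is None:
            self.attention_mask = np.array([tok != PAD for tok in self.tokens], dtype=bool)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def motif_tokens(self) -> list[str]:
        return [tok for tok in self.tokens if tok not in (CLS, SEP, PAD)]

    def token_ids(self, dictionary: MotifDictionary) -> np.ndarray:
        return np.array([dictionary.token_to_id[tok] for tok in self.tokens], dtype=np.int64)


def rank_and_tokenize(
    profile: MotifCountProfile, t: int, dictionary: MotifDictionary
) -> EndMotifSequence:
    """Rank motifs by descending count (lexicographic tie-break) and wrap
    the top t as ``[CLS, ..., SEP]`` padded to length t + 2.

    If fewer than t motifs have nonzero count, all nonzero motifs are used
    and the tail after SEP is PAD.
    """
    if not 0 < t < 4**dictionary.k:
        raise InvalidParameterError(
            f"t must satisfy 0 < t < 4^k = {4**dictionary.k}, got {t}"
        )
    nonzero = [(motif, c) for motif, c in profile.counts.items() if c > 0]
    if not nonzero:
        raise EmptyProfileError(f"profile {profile.sample_id!r} has no nonzero motif counts")
    # sort by (-count, motif): descending frequency, ties lexicographic
    nonzero.sort(key=lambda mc: (-mc[1], mc[0]))
    top = [motif for motif, _ in nonzero[:t]]
    tokens = [CLS, *top, SEP]
    tokens += [PAD] * (t + 2 - len(tokens))
    return EndMotifSequence(tokens=tokens, t=t, sample_id=profile.sample_id)


def build_augmented_corpus(
    sequences_of_reads,
    dictionary: MotifDictionary,
    reads_per_block: int,
    t: int,
    seed: int,
    sample_id: str = "sample",
    label: str | None = None,
) -> list[EndMotifSequence]:
    """Shuffle reads (seeded), partition into disjoint blocks of
    ``reads_per_block``, and tokenize each block into one ranked sequence.

    The incomplete trailing block is dropped. Sampling is without
    replacement: every read contributes to at most one sequence.
    """
    if reads_per_block < t:
        raise InvalidParameterError(
            f"reads_per_block ({reads_per_block}) should be >= t ({t}) "
            "so a full-length ranking is typically possible"
        )
    reads = list(sequences_of_reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    n_blocks = len(reads) // reads_per_block
    if n_blocks == 0:
        warnings.warn(
            f"only {len(reads)} reads for block size {reads_per_block}; empty corpus",
            stacklevel=2,
        )
        return []
    corpus = []
    for b in range(n_blocks):
        idx = order[b * reads_per_block : (b + 1) * reads_per_block]
        profile = count_end_motifs(
            (reads[i] for i in idx), dictionary, sample_id=f"{sample_id}:block{b}"
        )
        seq = rank_and_tokenize(profile, t, dictionary)
        seq.label = label
        corpus.append(seq)
    return corpus


def write_corpus(corpus: list[EndMotifSequence], path, labels_path=None) -> None:
    """One sequence per line, whitespace-separated tokens (PAD tail omitted);
    optional sidecar label table [sample_id, label]."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for seq in corpus:
            real = [tok for tok in seq.tokens if tok != PAD]
            fh.write(" ".join(real) + "\n")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("sample_id\tlabel\n")
            for seq in corpus:
                fh.write(f"{seq.sample_id}\t{seq.label if seq.label is not None else ''}\n")


def read_corpus(path, t: int, labels_path=None) -> list[EndMotifSequence]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    meta: list[tuple[str, str | None]] = []
    if labels_path is not None:
        with open(labels_path) as fh:
            fh.readline()
            for line in fh:
                sid, _, lab = line.rstrip("\n").partition("\t")
                meta.append((sid, lab or None))
    corpus = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            tokens = line.split()
            tokens += [PAD] * (t + 2 - len(tokens))
            sid, lab = meta[i] if i < len(meta) else (f"seq{i}", None)
            corpus.append(EndMotifSequence(tokens=tokens, t=t, sample_id=sid, label=lab))
    return corpus
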