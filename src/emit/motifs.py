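"""End-motif vocabulary and k-mer counting from sequencing reads.

The 5'-terminal k nucleotides of a cfDNA fragment (its *end-motif*) carry a
nuclease-cleavage signature that shifts in cancer. This module builds the
ordered dictionary of all 4^k motifs plus the four special tokens used by the
transformer (CLS, SEP, MASK, PAD), and counts end-motifs from FASTQ/FASTA
reads or SAM/BAM alignments.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

NUCLEOTIDES = "ACGT"
CLS, SEP, MASK, PAD = "CLS", "SEP", "MASK", "PAD"
SPECIAL_TOKENS = (CLS, SEP, MASK, PAD)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class EmitError(Exception):
    """Base error for this package."""


class InvalidParameterError(EmitError, ValueError):
    pass


class EmptyProfileError(EmitError, ValueError):
    pass


class RecordParseError(EmitError, ValueError):
    """A read record could not be parsed; carries the read identifier."""

    def __init__(self, read_id: str, message: str):
        self.read_id = read_id
        super().__init__(f"record {read_id!r}: {message}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDictionary:
    """Ordered vocabulary of all 4^k end-motifs plus special tokens.

    Motifs are enumerated lexicographically over A<C<G<T; the four special
    tokens are appended after the motifs, so ids are contiguous from 0 and
    the vocabulary size is ``4**k + 4``.
    """

    k: int
    motifs: tuple[str, ...]
    special_tokens: tuple[str, ...] = SPECIAL_TOKENS
    token_to_id: Mapping[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.token_to_id is None:
            mapping = {tok: i for i, tok in enumerate(self.motifs + self.special_tokens)}
            object.__setattr__(self, "token_to_id", mapping)

    @property
    def vocab_size(self) -> int:
        return len(self.motifs) + len(self.special_tokens)

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    def id_of(self, token: str) -> int:
        return self.token_to_id[token]

    def motif_ids(self) -> np.ndarray:
        """Ids of the plain motifs (excluding special tokens)."""
        return np.arange(self.n_motifs)

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    def id_to_token(self, idx: int) -> str:
        tokens = self.motifs + self.special_tokens
        return tokens[idx]


def build_dictionary(k: int) -> MotifDictionary:
    """Build the end-motif dictionary for motif length ``k`` (1 <= k <= 8).

    Returns all 4^k motifs in lexicographic order followed by CLS, SEP,
    MASK, PAD. With the conventional k = 4 this yields 256 motifs and a
    vocabulary of 260 tokens.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool) or not 1 <= k <= 8:
        raise InvalidParameterError(f"motif length k must be an integer in [1, 8], got {k!r}")
    motifs = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k))
    return MotifDictionary(k=int(k), motifs=motifs)


@dataclass
class MotifCountProfile:
    """Per-sample end-motif counts.

    ``counts`` maps motif -> non-negative count; ``total_reads_used`` equals
    the sum of counts; reads that were too short or began with a non-ACGT
    base are tallied in ``skipped_reads`` and excluded.
    """

    sample_id: str
    counts: dict[str, int]
    total_reads_used: int = None  # type: ignore[assignment]
    skipped_reads: int = 0

    def __post_init__(self):
        if self.total_reads_used is None:
            self.total_reads_used = int(sum(self.counts.values()))

    def frequencies(self, dictionary: MotifDictionary) -> np.ndarray:
        return profile_to_frequencies(self, dictionary)


def profile_to_frequencies(profile: MotifCountProfile, dictionary: MotifDictionary) -> np.ndarray:
    """Counts -> frequency vector of length 4^k in dictionary motif order."""
    if profile.total_reads_used <= 0:
        raise EmptyProfileError(f"profile {profile.sample_id!r} has no usable reads")
    vec = np.zeros(dictionary.n_motifs)
    for motif, count in profile.counts.items():
        vec[dictionary.token_to_id[motif]] = count
    return vec / profile.total_reads_used


def _open_text(path) -> Iterator[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    return opener(path, "rt")


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzipped FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise RecordParseError(header, "malformed FASTQ record")
            yield header[1:].split()[0], seq


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq)
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            yield rec.id, str(rec.seq)


def iter_reads(path) -> Iterator[tuple[str, str]]:
    """Dispatch on extension: FASTQ (.fastq/.fq[.gz]) or FASTA (.fasta/.fa[.gz])."""
    name = Path(path).name.lower()
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith((".fastq", ".fq")):
        return iter_fastq(path)
    if stem.endswith((".fasta", ".fa", ".fna")):
        return iter_fasta(path)
    raise InvalidParameterError(f"unrecognized read file format: {path}")


def iter_alignments(path, *, first_mate_only: bool = True) -> Iterator[tuple[str, str, bool]]:
    """Yield (read_id, sequence_as_stored, is_reverse) from SAM/BAM.

    Unmapped, secondary and supplementary records are skipped. For paired-end
    data only the first mate is yielded by default, since it carries the
    fragment's sequenced 5' end.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if first_mate_only and aln.is_paired and not aln.is_read1:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            yield aln.query_name, seq, aln.is_reverse


def count_end_motifs(
    sequences: Iterable[str],
    dictionary: MotifDictionary,
    sample_id: str = "sample",
) -> MotifCountProfile:
    """Count the 5'-end k-mer of each sequence string.

    Sequences shorter than k, or whose first k bases contain a non-ACGT
    character, are skipped (the dictionary has exactly 4^k motifs; there is
    no UNK bucket).
    """
    k = dictionary.k
    counts: dict[str, int] = {}
    used = skipped = 0
    valid = dictionary.token_to_id
    for seq in sequences:
        motif = seq[:k].upper()
        if len(motif) < k or motif not in valid or motif in SPECIAL_TOKENS:
            skipped += 1
            continue
        counts[motif] = counts.get(motif, 0) + 1
        used += 1
    return MotifCountProfile(sample_id=sample_id, counts=counts,
                             total_reads_used=used, skipped_reads=skipped)


def extract_end_motifs(
    path,
    dictionary: MotifDictionary,
    mode: str = "raw-read",
    sample_id: str | None = None,
    first_mate_only: bool = True,
) -> MotifCountProfile:
    """Count end-motifs from a reads file.

    mode="raw-read": the first k bases of each read, as sequenced
    (FASTQ/FASTA, plain or gzipped).
    mode="alignment-oriented": SAM/BAM input; reads mapped to the reverse
    strand are reverse-complemented first so the motif reflects the
    fragment's 5' terminus.
    """
    if sample_id is None:
        name = Path(path).name
        for suffix in (".gz", ".fastq", ".fq", ".fasta", ".fa", ".fna", ".sam", ".bam"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        sample_id = name
    if mode == "raw-read":
        seqs = (seq for _, seq in iter_reads(path))
    elif mode == "alignment-oriented":
        seqs = (
            reverse_complement(seq) if is_rev else seq
            for _, seq, is_rev in iter_alignments(path, first_mate_only=first_mate_only)
        )
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return count_end_motifs(seqs, dictionary, sample_id=sample_id)


def write_count_table(profile: MotifCountProfile, dictionary: MotifDictionary, path) -> None:
    """Write a per-sample motif count table: TSV, columns [motif, count],
    one header line, motifs in dictionary (lexicographic) order."""
    with open(path, "w") as fh:
        fh.write("motif\tcount\n")
        for motif in dictionary.motifs:
            fh.write(f"{motif}\t{profile.counts.get(motif, 0)}\n")


def read_count_table(path, sample_id: str | None = None) -> MotifCountProfile:
    counts: dict[str, int] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("motif"):
            raise RecordParseError(str(path), "missing 'motif\\tcount' header")
        for line in fh:
            motif, count = line.rstrip("\n").split("\t")
            if int(count) > 0:
                counts[motif] = int(count)
    if sample_id is None:
        sample_id = Path(path).stem
    return MotifCountProfile(sample_id=sample_id, counts=counts)
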