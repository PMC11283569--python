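"""Synthetic cfDNA end-motif cohorts with controllable cancer signal.

Per-sample motif usage is modelled as Dirichlet-multinomial: each sample
draws a motif probability vector from a Dirichlet prior (capturing
between-subject variability in nuclease activity) and its read end-motifs
are multinomial draws from that vector. The cancer group's prior tilts a
small set of signal motifs — by default CCCA, CCAG and CCTG, motifs known
to be over-represented in hepatocellular-carcinoma plasma — by a
multiplicative factor (1 + effect_size). With effect_size = 0 both groups
share one generating distribution, giving an exact null. An optional batch
effect applies the same kind of tilt to a disjoint motif set, enabling
batch-mixing (kBET) experiments. Profiles can be expanded to FASTQ so the
whole pipeline, from raw reads onward, is exercisable without any external
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import InvalidParameterError, MotifCountProfile, MotifDictionary, build_dictionary
from .sequences import EndMotifSequence, rank_and_tokenize

DEFAULT_SIGNAL_MOTIFS = ("CCCA", "CCAG", "CCTG")


@dataclass
class CohortSpec:
    """Generating conditions for one synthetic cohort.

    effect_size multiplies the Dirichlet concentration of the signal motifs
    in the cancer group by (1 + effect_size); 0 means no group difference.
    batch_effect_size does the same for batch 1 on ``batch_motifs``
    (disjoint from the signal motifs) when ``n_batches > 1``.
    """

    n_cancer: int = 100
    n_control: int = 100
    reads_per_sample: int = 50_000
    k: int = 4
    signal_motifs: tuple[str, ...] = DEFAULT_SIGNAL_MOTIFS
    effect_size: float = 5.0
    dirichlet_concentration: float = 50.0
    n_batches: int = 1
    batch_motifs: tuple[str, ...] = ("AAAA", "AAAC", "AAAG")
    batch_effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cancer, self.n_control, self.reads_per_sample) <= 0:
            raise InvalidParameterError("cohort sizes and read counts must be positive")
        if self.effect_size < 0 or self.batch_effect_size < 0:
            raise InvalidParameterError("effect sizes must be non-negative")
        if self.dirichlet_concentration <= 0:
            raise InvalidParameterError("dirichlet_concentration must be positive")
        for m in (*self.signal_motifs, *self.batch_motifs):
            if len(m) != self.k or set(m) - set("ACGT"):
                raise InvalidParameterError(f"motif {m!r} is not a valid {self.k}-mer")


@dataclass
class SimulatedCohort:
    """Profiles, labels, optional batches, and the generating truth."""

    profiles: list[MotifCountProfile]
    labels: np.ndarray  # 1 = cancer, 0 = control
    batches: np.ndarray
    dictionary: MotifDictionary
    true_probabilities: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _concentration(spec: CohortSpec, dictionary: MotifDictionary,
                   cancer: bool, batch: int) -> np.ndarray:
    # per-motif concentration: between-sample CV of a motif's frequency is
    # roughly 1/sqrt(alpha_i), so the default 50 gives ~14% biological
    # variability around the group mean
    base = np.full(dictionary.n_motifs, float(spec.dirichlet_concentration))
    if cancer and spec.effect_size > 0:
        for m in spec.signal_motifs:
            base[dictionary.token_to_id[m]] *= 1.0 + spec.effect_size
    if batch == 1 and spec.batch_effect_size > 0:
        for m in spec.batch_motifs:
            base[dictionary.token_to_id[m]] *= 1.0 + spec.batch_effect_size
    return base


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw a seeded cohort of per-sample end-motif count profiles.

    Sample i draws p_i ~ Dirichlet(alpha_group) and counts ~
    Multinomial(reads_per_sample, p_i). Batches, when requested, alternate
    across samples within each group so group and batch are not confounded
    by construction.
    """
    rng = np.random.default_rng(spec.seed)
    dictionary = build_dictionary(spec.k)
    labels = np.array([1] * spec.n_cancer + [0] * spec.n_control)
    batches = np.arange(len(labels)) % max(1, spec.n_batches)
    profiles: list[MotifCountProfile] = []
    true_p = np.empty((len(labels), dictionary.n_motifs))
    for i, (lab, bat) in enumerate(zip(labels, batches)):
        alpha = _concentration(spec, dictionary, cancer=bool(lab), batch=int(bat))
        p = rng.dirichlet(alpha)
        counts_vec = rng.multinomial(spec.reads_per_sample, p)
        true_p[i] = p
        counts = {
            dictionary.motifs[j]: int(c) for j, c in enumerate(counts_vec) if c > 0
        }
        group = "cancer" if lab else "control"
        profiles.append(
            MotifCountProfile(sample_id=f"{group}_{i:04d}", counts=counts)
        )
    return SimulatedCohort(
        profiles=profiles, labels=labels, batches=batches,
        dictionary=dictionary, true_probabilities=true_p,
    )


def write_fastq(
    profiles: list[MotifCountProfile],
    out_dir,
    read_length: int = 50,
    k: int = 4,
    seed: int = 0,
) -> list[Path]:
    """Expand count profiles to per-sample FASTQ files.

    Each read's first k bases are its assigned end-motif; the remaining
    bases are uniform random ACGT; quality strings are constant. Re-counting
    end-motifs on the output reproduces the input counts exactly.
    """
    if read_length < k:
        raise InvalidParameterError(f"read_length {read_length} < motif length {k}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qual = "I" * read_length
    paths = []
    bases = np.array(list("ACGT"))
    for profile in profiles:
        path = out_dir / f"{profile.sample_id}.fastq"
        with open(path, "w") as fh:
            r = 0
            for motif in sorted(profile.counts):
                for _ in range(profile.counts[motif]):
                    tail = "".join(bases[rng.integers(0, 4, size=read_length - k)])
                    fh.write(f"@{profile.sample_id}:{r}\n{motif}{tail}\n+\n{qual}\n")
                    r += 1
        paths.append(path)
    return paths


def simulate_pretraining_corpus(
    n_sequences: int,
    t: int,
    spec: CohortSpec,
    reads_per_block: int = 2000,
) -> tuple[list[EndMotifSequence], MotifDictionary]:
    """Labeled desk-scale corpus of ranked end-motif sequences.

    Cycles over the cohort's samples; each sequence is one multinomial
    block of ``reads_per_block`` read end-motifs drawn from that sample's
    generating probability vector, then ranked and tokenized — the same
    construction as partitioning a sample's reads into disjoint blocks.
    """
    dictionary = build_dictionary(spec.k)
    if not 0 < t < dictionary.n_motifs:
        raise InvalidParameterError(f"need 0 < t < {dictionary.n_motifs}")
    rng = np.random.default_rng(spec.seed)
    cohort = simulate_cohort(spec)
    corpus: list[EndMotifSequence] = []
    n_samples = len(cohort.profiles)
    for s in range(n_sequences):
        i = s % n_samples
        counts_vec = rng.multinomial(reads_per_block, cohort.true_probabilities[i])
        counts = {
            dictionary.motifs[j]: int(c) for j, c in enumerate(counts_vec) if c > 0
        }
        profile = MotifCountProfile(
            sample_id=f"{cohort.profiles[i].sample_id}:block{s // n_samples}",
            counts=counts,
        )
        seq = rank_and_tokenize(profile, t, dictionary)
        seq.label = "cancer" if cohort.labels[i] else "control"
        corpus.append(seq)
    return corpus, dictionary
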