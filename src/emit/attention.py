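"""Attention-based interpretation of the trained encoder.

The CLS token aggregates the whole ranked motif sequence, so the attention
weight alpha_{CLS,j} that CLS places on motif j measures that motif's
influence on the sequence representation. Scores are compared between
groups (Wilcoxon rank-sum by default, Welch t-test optionally) with
Benjamini-Hochberg adjustment across motifs within each head. Motif-motif
attention networks accumulate alpha_{i,j} over all sequences of a group and
retain the top fraction of interactions by weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ModelState, forward
from .motifs import CLS, PAD, SEP, EmitError, InvalidParameterError, MotifDictionary
from .sequences import EndMotifSequence


class EmptyGroupError(EmitError, ValueError):
    pass


def cls_attention_scores(
    state: ModelState,
    sequences: list[EndMotifSequence],
    dictionary: MotifDictionary,
    layer: int = -1,
) -> list[list[dict[str, float]]]:
    """Per-sequence, per-head map motif -> alpha_{CLS,motif}.

    For each sequence the CLS row of the attention matrix A (chosen layer,
    each head) is read off and keyed by motif identity — positions are not
    comparable across sequences because each sample ranks motifs
    differently. Motifs absent from a sequence are simply missing from its
    map (not recorded as zero).
    """
    out = []
    for seq in sequences:
        ids = seq.token_ids(dictionary)
        _, _, attentions = forward(ids, state, attention_mask=seq.attention_mask, train=False)
        A = attentions[layer]  # (h, T, T)
        per_head = []
        for head in range(A.shape[0]):
            cls_row = A[head, 0, :]
            scores = {
                tok: float(cls_row[pos])
                for pos, tok in enumerate(seq.tokens)
                if tok not in (CLS, SEP, PAD)
            }
            per_head.append(scores)
        out.append(per_head)
    return out


def sample_mean_scores(score_maps: list[list[dict[str, float]]]) -> list[dict[str, float]]:
    """Average per-head maps across multiple sequences of one sample."""
    if not score_maps:
        raise EmptyGroupError("no sequences")
    n_heads = len(score_maps[0])
    out = []
    for head in range(n_heads):
        acc: dict[str, list[float]] = {}
        for per_seq in score_maps:
            for motif, a in per_seq[head].items():
                acc.setdefault(motif, []).append(a)
        out.append({m: float(np.mean(v)) for m, v in acc.items()})
    return out


@dataclass
class AttentionComparison:
    motif: str
    head: int
    layer: int
    mean_group1: float
    mean_group0: float
    statistic: float
    p_value: float
    p_adjusted: float = np.nan


def compare_attention_groups(
    scores_by_sample: list[list[dict[str, float]]],
    labels,
    test: str = "wilcoxon",
    layer: int = -1,
) -> list[AttentionComparison]:
    """Two-sided per-motif, per-head group comparison of CLS attention.

    ``scores_by_sample[i]`` is sample i's per-head motif->score map (one
    map per head, e.g. from :func:`sample_mean_scores`). A motif enters a
    head's comparison only if it appears in at least one sample of each
    group; BH adjustment is applied across motifs within each head.
    """
    labels = np.asarray(labels).astype(int)
    if len(labels) != len(scores_by_sample):
        raise InvalidParameterError("labels and score maps must align")
    if test not in ("wilcoxon", "t-test"):
        raise InvalidParameterError(f"unknown test {test!r}")
    n_heads = len(scores_by_sample[0])
    results: list[AttentionComparison] = []
    for head in range(n_heads):
        motifs = sorted({m for s in scores_by_sample for m in s[head]})
        head_rows = []
        for motif in motifs:
            g1 = [s[head][motif] for s, y in zip(scores_by_sample, labels) if y == 1 and motif in s[head]]
            g0 = [s[head][motif] for s, y in zip(scores_by_sample, labels) if y == 0 and motif in s[head]]
            if not g1 or not g0:
                continue  # motif absent from one group: excluded, not zero-filled
            if np.ptp(g1 + g0) == 0:
                stat, p = 0.0, 1.0
            elif test == "wilcoxon":
                stat, p = stats.ranksums(g1, g0)
            else:
                stat, p = stats.ttest_ind(g1, g0, equal_var=False)
            head_rows.append(
                AttentionComparison(
                    motif=motif, head=head, layer=layer,
                    mean_group1=float(np.mean(g1)), mean_group0=float(np.mean(g0)),
                    statistic=float(stat), p_value=float(p),
                )
            )
        if head_rows:
            _, p_adj, _, _ = multipletests([r.p_value for r in head_rows], method="fdr_bh")
            for r, q in zip(head_rows, p_adj):
                r.p_adjusted = float(q)
        results.extend(head_rows)
    return results


@dataclass
class MotifNetwork:
    """Directed motif-motif attention network.

    Edge weights are cumulative alpha_{i,j} over all sequences of a group;
    only edges at or above the (1 - retention) weight quantile are kept.
    """

    edges: list[tuple[str, str, float]]
    retention: float

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for src, dst, w in self.edges:
            g.add_edge(src, dst, weight=w)
        return g

    def write_edge_list(self, path):
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for src, dst, w in self.edges:
                fh.write(f"{src}\t{dst}\t{w:.10g}\n")

    def write_graphml(self, path):
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def accumulate_attention(
    state: ModelState,
    sequences: list[EndMotifSequence],
    dictionary: MotifDictionary,
    layer: int = -1,
) -> dict[tuple[str, str], float]:
    """Cumulative alpha_{i,j} summed over sequences and heads, keyed by
    (source motif, target motif); special tokens and self-loops excluded."""
    if not sequences:
        raise EmptyGroupError("empty sequence group")
    weights: dict[tuple[str, str], float] = {}
    for seq in sequences:
        ids = seq.token_ids(dictionary)
        _, _, attentions = forward(ids, state, attention_mask=seq.attention_mask, train=False)
        A = attentions[layer].sum(axis=0)  # sum heads -> (T, T)
        toks = seq.tokens
        motif_pos = [i for i, tok in enumerate(toks) if tok not in (CLS, SEP, PAD)]
        for i in motif_pos:
            for j in motif_pos:
                if i == j:
                    continue
                key = (toks[i], toks[j])
                weights[key] = weights.get(key, 0.0) + float(A[i, j])
    return weights


def build_attention_network(
    state: ModelState,
    sequences: list[EndMotifSequence],
    dictionary: MotifDictionary,
    retention: float = 0.001,
    layer: int = -1,
) -> MotifNetwork:
    """Accumulate attention over a group and keep the top ``retention``
    fraction of motif-motif interactions by cumulative weight."""
    if not 0 < retention <= 1:
        raise InvalidParameterError("retention must be in (0, 1]")
    weights = accumulate_attention(state, sequences, dictionary, layer=layer)
    return threshold_network(weights, retention)


def threshold_network(weights: dict[tuple[str, str], float], retention: float) -> MotifNetwork:
    if not 0 < retention <= 1:
        raise InvalidParameterError("retention must be in (0, 1]")
    items = [(src, dst, w) for (src, dst), w in weights.items() if w > 0]
    if not items:
        return MotifNetwork(edges=[], retention=retention)
    items.sort(key=lambda e: (-e[2], e[0], e[1]))
    # top retention fraction by cumulative weight; deterministic tie-break
    n_keep = int(np.ceil(retention * len(items)))
    return MotifNetwork(edges=items[:n_keep], retention=retention)
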