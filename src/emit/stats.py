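"""Motif diversity score, raw-count baseline probe, and the kBET test.

The motif diversity score (MDS) is the Shannon entropy of a sample's
end-motif frequency distribution normalized by the entropy of the uniform
distribution over all 4^k motifs, so it lies in [0, 1]: 1 for uniform motif
usage, 0 for a point mass. The baseline classifier probes the motif
frequency matrix directly, bypassing the transformer. kBET quantifies batch
mixing: for each sample, the batch composition of its K nearest neighbors
is compared with the global batch frequencies by a chi-square test, and the
acceptance rate is the percentage of samples whose local composition is
consistent with the global one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .motifs import EmitError, InvalidParameterError
from .probing import ProbeResult, linear_probe_cv


class InvalidDistributionError(EmitError, ValueError):
    pass


class DegenerateBatchesError(EmitError, ValueError):
    pass


def mds(frequencies, tol: float = 1e-6) -> float:
    """Motif diversity score: normalized Shannon entropy.

    ``MDS = sum_i -P_i log(P_i) / log(n_motifs)`` with 0 log 0 = 0. The
    logarithm base cancels between numerator and denominator; natural log
    is used. Input must be a valid probability vector over the motif
    vocabulary (any order; the score is permutation-invariant).
    """
    P = np.asarray(frequencies, float)
    if P.ndim != 1 or P.size < 2:
        raise InvalidDistributionError("need a 1-D frequency vector over >= 2 motifs")
    if (P < -tol).any():
        raise InvalidDistributionError("negative frequency")
    if abs(P.sum() - 1.0) > max(tol, 1e-6):
        raise InvalidDistributionError(f"frequencies sum to {P.sum():.6g}, not 1")
    P = np.clip(P, 0.0, None)
    nz = P[P > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(P.size))


def count_baseline_probe(
    count_matrix,
    labels,
    folds: int = 5,
    seed: int = 0,
    normalize: bool = True,
    threshold: float = 0.5,
) -> ProbeResult:
    """Linear probe of the raw end-motif count matrix (samples x 4^k).

    By default rows are normalized to frequencies to remove sequencing-depth
    effects; ``normalize=False`` probes raw counts. Uses the same seeded
    stratified fold construction as the representation probe, so with the
    same seed the fold partitions are identical and the two probes can be
    compared with a paired DeLong test.
    """
    X = np.asarray(count_matrix, float)
    if X.ndim != 2:
        raise InvalidParameterError("count matrix must be 2-D (samples x motifs)")
    if normalize:
        totals = X.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise InvalidParameterError("every sample needs positive total count")
        X = X / totals
    return linear_probe_cv(X, labels, folds=folds, seed=seed, threshold=threshold)


@dataclass
class KBETResult:
    """Per-sample chi-square outcomes and the global acceptance rate (%)."""

    acceptance_rate: float
    statistics: np.ndarray
    p_values: np.ndarray
    batch_frequencies: np.ndarray
    K: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "acceptance_rate": self.acceptance_rate,
            "K": self.K,
            "alpha": self.alpha,
            "batch_frequencies": self.batch_frequencies.tolist(),
            "n_samples": int(len(self.p_values)),
        }


def kbet_acceptance(points, batch_labels, K: int = 5, alpha: float = 0.05) -> KBETResult:
    """k-nearest-neighbour batch-effect test.

    For sample i, its K nearest neighbors (Euclidean, self excluded, ties
    broken by sample index) give observed batch counts n_ji; the statistic
    ``k_i = sum_j (n_ji - f_j K)^2 / (f_j K)`` is chi-square with m - 1
    degrees of freedom under the null of well-mixed batches, where f_j are
    the global batch frequencies. The acceptance rate is
    ``100 * #{p_i >= alpha} / n``: near 100 for mixed batches, near 0 for
    confounded ones.
    """
    X = np.asarray(points, float)
    if X.ndim != 2:
        raise InvalidParameterError("points must be a 2-D matrix")
    batches = np.asarray(batch_labels)
    if len(batches) != len(X):
        raise InvalidParameterError("batch labels must align with points")
    uniq, batch_idx = np.unique(batches, return_inverse=True)
    m = len(uniq)
    n = len(X)
    if m < 2:
        raise DegenerateBatchesError("need at least 2 batches")
    if not 0 < K < n:
        raise InvalidParameterError(f"need 0 < K < n, got K={K}, n={n}")
    f = np.bincount(batch_idx, minlength=m) / n
    expected = f * K
    nn = NearestNeighbors(n_neighbors=K + 1).fit(X)
    _, idx = nn.kneighbors(X)
    stats_i = np.empty(n)
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:K]
        counts = np.bincount(batch_idx[neigh], minlength=m)
        stats_i[i] = ((counts - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(stats_i, df=m - 1)
    rate = 100.0 * float((p >= alpha).mean())
    return KBETResult(
        acceptance_rate=rate, statistics=stats_i, p_values=p,
        batch_frequencies=f, K=K, alpha=alpha,
    )
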