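"""Linear probing of frozen representations and evaluation statistics.

A linear probe tests whether cancer/control status is linearly encoded in
the frozen CLS representation: an L2-regularized logistic regression is fit
under stratified k-fold cross-validation and all metrics are computed from
the pooled out-of-fold predicted probabilities. AUROC confidence intervals
and paired model comparisons use DeLong's structural-components method;
accuracy, sensitivity and specificity carry exact two-sided Clopper-Pearson
binomial intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .model import ModelState, forward
from .motifs import EmitError, InvalidParameterError
from .sequences import EndMotifSequence


class DegenerateLabelsError(EmitError, ValueError):
    pass


# ----------------------------------------------------------- representations


def extract_representation(
    state: ModelState,
    sequence: EndMotifSequence,
    dictionary,
    pooling: str = "cls",
) -> np.ndarray:
    """Final-layer hidden state at the CLS position (evaluation mode).

    ``pooling="mean"`` instead averages the hidden states over non-PAD
    positions.
    """
    ids = sequence.token_ids(dictionary)
    Z, _, _ = forward(ids, state, attention_mask=sequence.attention_mask, train=False)
    if pooling == "cls":
        return Z[0]
    if pooling == "mean":
        return Z[sequence.attention_mask].mean(axis=0)
    raise InvalidParameterError(f"unknown pooling {pooling!r}")


def extract_representations(state, sequences, dictionary, pooling="cls") -> np.ndarray:
    return np.stack([extract_representation(state, s, dictionary, pooling) for s in sequences])


# ------------------------------------------------------------------- metrics


def _check_two_classes(labels: np.ndarray):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise DegenerateLabelsError("both classes (0 and 1) must be present")
    return labels


def delong_variance(scores: np.ndarray, labels: np.ndarray):
    """AUROC and its DeLong variance via structural components.

    The AUROC is the Mann-Whitney U statistic with ties counted 1/2; the
    variance combines the empirical variances of the case and control
    placement values V10 and V01.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, float)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    # placement values: V10_i = P(case_i > control) with ties 1/2
    diff = cases[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = psi.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return float(auc), float(var), v10, v01


def auroc_with_ci(scores, labels, level: float = 0.95):
    """AUROC with a DeLong normal-approximation confidence interval,
    truncated to [0, 1]."""
    auc, var, _, _ = delong_variance(scores, labels)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong z-test for the difference of two AUROCs computed on
    the same samples. Returns (z, two-sided p)."""
    scores_a, scores_b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape:
        raise InvalidParameterError("paired score vectors must have equal length")
    auc_a, _, v10_a, v01_a = delong_variance(scores_a, labels)
    auc_b, _, v10_b, v01_b = delong_variance(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def clopper_pearson(successes: int, trials: int, level: float = 0.95):
    """Exact two-sided binomial confidence interval (beta quantiles)."""
    if trials <= 0:
        raise InvalidParameterError("trials must be positive")
    alpha = 1 - level
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    hi = 1.0 if successes == trials else stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    return float(lo), float(hi)


def binary_metrics_cp(predicted, truth, level: float = 0.95) -> dict:
    """Accuracy, sensitivity and specificity from the confusion matrix,
    each with its exact Clopper-Pearson interval."""
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.size == 0 or predicted.shape != truth.shape:
        raise InvalidParameterError("need non-empty vectors of equal length")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    pos = int((truth == 1).sum())
    neg = int((truth == 0).sum())
    out = {}
    out["accuracy"] = ((tp + tn) / len(truth), clopper_pearson(tp + tn, len(truth), level))
    if pos:
        out["sensitivity"] = (tp / pos, clopper_pearson(tp, pos, level))
    if neg:
        out["specificity"] = (tn / neg, clopper_pearson(tn, neg, level))
    return out


# --------------------------------------------------------------- linear probe


@dataclass
class ProbeResult:
    """Pooled out-of-fold predictions and the metrics derived from them."""

    probabilities: np.ndarray
    labels: np.ndarray
    fold_assignment: np.ndarray
    threshold: float
    auroc: float = field(init=False)
    auroc_ci: tuple[float, float] = field(init=False)
    metrics: dict = field(init=False)

    def __post_init__(self):
        self.auroc, self.auroc_ci = auroc_with_ci(self.probabilities, self.labels)
        self.metrics = binary_metrics_cp(
            (self.probabilities >= self.threshold).astype(int), self.labels
        )

    def to_dict(self) -> dict:
        d = {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "threshold": self.threshold,
            "probabilities": self.probabilities.tolist(),
            "labels": self.labels.astype(int).tolist(),
            "folds": self.fold_assignment.astype(int).tolist(),
        }
        for name, (est, (lo, hi)) in self.metrics.items():
            d[name] = est
            d[f"{name}_ci"] = [lo, hi]
        return d


def linear_probe_cv(
    representations: np.ndarray,
    labels,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    C: float = 1.0,
) -> ProbeResult:
    """Stratified k-fold linear probing of frozen representations.

    Features are standardized with train-fold statistics; the classifier is
    an L2-regularized logistic regression with fixed strength (no tuning, to
    keep the probe a plain linear projection). Out-of-fold probabilities are
    pooled across folds before any metric is computed.
    """
    X = np.asarray(representations, float)
    y = _check_two_classes(labels)
    if len(X) != len(y):
        raise InvalidParameterError("representations and labels must align")
    if len(X) < folds:
        raise InvalidParameterError("need at least one sample per fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    probs = np.zeros(len(y))
    fold_of = np.full(len(y), -1)
    for f, (tr, va) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(scaler.transform(X[tr]), y[tr])
        probs[va] = clf.predict_proba(scaler.transform(X[va]))[:, 1]
        fold_of[va] = f
    return ProbeResult(probabilities=probs, labels=y, fold_assignment=fold_of,
                       threshold=threshold)
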