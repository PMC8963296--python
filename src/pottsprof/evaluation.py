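"""Evaluation of pair metrics against external association labels.

Labels are STRING-like: an association score in [0, 1] per OG pair. A
pair is *positive* when its score is strictly larger than a threshold
``th`` (0.7 and 0.9 are STRING's high / highest confidence cut-offs) and
negative otherwise. Metrics are evaluated by ROC AUC, by the positive
predictive value of the top-M ranked pairs, and by the area under the
precision-recall curve.

Conventions (fixed, because AUPR values differ between conventions):
AUC follows the Mann-Whitney statistic with ties counted 1/2; AUPR uses
the step-wise (conservative) interpolation sum (R_k - R_{k-1}) * P_k.
Pairs without a label are excluded from AUC/AUPR; for PPV the top M is
taken over labeled pairs only unless ``unlabeled_as_negative`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .metrics_integration import PairRanking, Pair, _canonical
from .mi import MetricMatrix

__all__ = [
    "AssociationLabels",
    "EvalResult",
    "read_labels_tsv",
    "label_pairs",
    "auc_roc",
    "aupr",
    "ppv_at_top_m",
    "evaluate_ranking",
    "recombine_channel_scores",
    "metric_pair_scores",
]

DEFAULT_M_GRID = (100, 500, 1000, 5000, 10000)


@dataclass
class AssociationLabels:
    """Map from unordered OG pair to an association score in [0, 1]."""

    scores: dict[Pair, float]

    def __post_init__(self) -> None:
        canon = {}
        for (a, b), s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score for ({a}, {b}) outside [0, 1]: {s}")
            key = _canonical(a, b)
            if key in canon:
                raise ValueError(f"duplicate pair {key}")
            canon[key] = float(s)
        self.scores = canon

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class EvalResult:
    th: float
    auc: float
    aupr: float
    ppv: dict[int, float]
    n_positive: int
    n_negative: int


def read_labels_tsv(path) -> AssociationLabels:
    scores: dict[Pair, float] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.lower().startswith("og_a"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            oa, ob, s = line.rstrip("\n").split("\t")
            scores[(oa, ob)] = float(s)
    return AssociationLabels(scores=scores)


def label_pairs(
    labels: AssociationLabels, th: float
) -> tuple[set[Pair], set[Pair]]:
    """Split labeled pairs into positives (score > th, strict) and negatives."""
    if not 0.0 <= th <= 1.0:
        raise ValueError("th must be in [0, 1]")
    pos = {p for p, s in labels.scores.items() if s > th}
    neg = set(labels.scores) - pos
    return pos, neg


def _aligned_arrays(
    pair_scores: dict[Pair, float], labels: AssociationLabels, th: float
) -> tuple[np.ndarray, np.ndarray]:
    pos, neg = label_pairs(labels, th)
    common = [p for p in pair_scores if p in labels.scores]
    y = np.array([1 if p in pos else 0 for p in common])
    s = np.array([pair_scores[p] for p in common])
    return y, s


def auc_roc(pair_scores: dict[Pair, float], labels: AssociationLabels,
            th: float) -> float:
    """ROC AUC of metric scores over the labeled pairs (ties count 1/2)."""
    y, s = _aligned_arrays(pair_scores, labels, th)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative pair")
    return float(roc_auc_score(y, s))


def aupr(pair_scores: dict[Pair, float], labels: AssociationLabels,
         th: float) -> float:
    """Area under the precision-recall curve, step-wise interpolation."""
    y, s = _aligned_arrays(pair_scores, labels, th)
    if y.sum() == 0:
        raise ValueError("need at least one positive pair")
    return float(average_precision_score(y, s))


def ppv_at_top_m(
    ranking: PairRanking,
    labels: AssociationLabels,
    th: float,
    M: int,
    unlabeled_as_negative: bool = False,
) -> float:
    """Fraction of the top-M ranked pairs that are positive at threshold th."""
    pos, _ = label_pairs(labels, th)
    if unlabeled_as_negative:
        candidates = ranking.pairs
    else:
        candidates = [p for p in ranking.pairs if p in labels.scores]
    if M > len(candidates):
        raise ValueError(f"M={M} exceeds the {len(candidates)} available pairs")
    top = candidates[:M]
    return sum(1 for p in top if p in pos) / M


def metric_pair_scores(metric: MetricMatrix) -> dict[Pair, float]:
    """Metric matrix as a canonical pair -> score dict."""
    return {_canonical(oa, ob): s for oa, ob, s in metric.pair_scores()}


def evaluate_ranking(
    pair_scores: dict[Pair, float],
    ranking: PairRanking,
    labels: AssociationLabels,
    th: float,
    m_grid=DEFAULT_M_GRID,
) -> EvalResult:
    """AUC, AUPR and PPV@M in one report (M values exceeding the labeled
    pair count are skipped)."""
    pos, neg = label_pairs(labels, th)
    ppv = {}
    n_labeled = sum(1 for p in ranking.pairs if p in labels.scores)
    for m in m_grid:
        if m <= n_labeled:
            ppv[m] = ppv_at_top_m(ranking, labels, th, m)
    return EvalResult(
        th=th,
        auc=auc_roc(pair_scores, labels, th),
        aupr=aupr(pair_scores, labels, th),
        ppv=ppv,
        n_positive=len(pos),
        n_negative=len(neg),
    )


def recombine_channel_scores(
    channel_scores: dict[str, dict[Pair, float]],
    exclude: str | tuple[str, ...] = (),
    prior: float = 0.0,
) -> AssociationLabels:
    """Combine per-channel scores, leaving out the excluded channel(s).

    Plain noisy-OR: combined = 1 - prod_c (1 - s_c) over the retained
    channels. With a nonzero ``prior`` p each channel is first corrected
    to (s - p)/(1 - p) (clipped at 0) and the prior is re-added to the
    combination — a hook for STRING-style prior handling; exact
    reproduction of STRING's pipeline is not attempted. Used to rebuild
    evaluation labels that ignore the occurrence-pattern channel.
    """
    if isinstance(exclude, str):
        exclude = (exclude,)
    keep = [c for c in channel_scores if c not in exclude]
    pairs: set[Pair] = set()
    for c in keep:
        pairs.update(_canonical(*p) for p in channel_scores[c])
    combined: dict[Pair, float] = {}
    for p in pairs:
        prod = 1.0
        for c in keep:
            s = channel_scores[c].get(p, 0.0)
            if prior > 0.0:
                s = max(0.0, (s - prior) / (1.0 - prior))
            prod *= 1.0 - s
        score = 1.0 - prod
        if prior > 0.0:
            score = score * (1.0 - prior) + prior
        combined[p] = score
    return AssociationLabels(scores=combined)
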