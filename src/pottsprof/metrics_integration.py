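"""Ranking OG pairs per metric and integrating rankings across metrics.

Pairs are ranked 1..P in descending score order (ties broken by
lexicographic pair id, so every ranking is a total, reproducible order).
Integrated rankings combine per-metric ranks by their maximum, average or
minimum; the combined value is the pair's *prediction score* (smaller is
better) and pairs are re-sorted ascending by it.

A skewness diagnostic summarizes how concentrated a metric's score
distribution is: scores are normalized so the maximum is 1 and the
adjusted Fisher-Pearson sample skewness is reported (the normalization
leaves skewness unchanged; it only standardizes the plotted axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mi import MetricMatrix

__all__ = [
    "PairRanking",
    "rank_pairs",
    "integrate_ranks",
    "normalized_skewness",
    "write_ranking_tsv",
    "read_ranking_tsv",
]

Pair = tuple[str, str]


@dataclass
class PairRanking:
    """A total order over unordered OG pairs.

    ``pairs`` is best-first; ``ranks[p]`` in 1..P; ``scores[p]`` is the
    metric score (single metric) or the combined rank value (integrated —
    the pair's prediction score, smaller is better).
    """

    pairs: list[Pair]
    ranks: dict[Pair, int]
    scores: dict[Pair, float]
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        p = len(self.pairs)
        if sorted(self.ranks.values()) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..P")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _canonical(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def rank_pairs(metric: MetricMatrix) -> PairRanking:
    """Rank all unordered pairs of a metric matrix, best (highest) first."""
    entries = [( _canonical(oa, ob), s) for oa, ob, s in metric.pair_scores()]
    entries.sort(key=lambda e: (-e[1], e[0]))
    pairs = [p for p, _ in entries]
    ranks = {p: r for r, (p, _) in enumerate(entries, start=1)}
    scores = {p: s for p, s in entries}
    return PairRanking(pairs=pairs, ranks=ranks, scores=scores,
                       sources=(metric.metric_name,))


_MODES = {"max": max, "average": lambda xs: sum(xs) / len(xs), "min": min}


def integrate_ranks(rankings: list[PairRanking], mode: str) -> PairRanking:
    """Combine 2+ rankings over the same pair set by max/average/min rank."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}")
    if len(rankings) < 2:
        raise ValueError("need at least two rankings to integrate")
    pair_set = set(rankings[0].pairs)
    for r in rankings[1:]:
        if set(r.pairs) != pair_set:
            raise ValueError("rankings cover different pair sets")
    agg = _MODES[mode]
    combined = {p: float(agg([r.ranks[p] for r in rankings])) for p in pair_set}
    ordered = sorted(pair_set, key=lambda p: (combined[p], p))
    ranks = {p: r for r, p in enumerate(ordered, start=1)}
    sources = tuple(s for r in rankings for s in r.sources)
    return PairRanking(
        pairs=ordered,
        ranks=ranks,
        scores=combined,
        sources=sources + (f"integrated:{mode}",),
    )


def normalized_skewness(metric: MetricMatrix) -> float:
    """Adjusted Fisher-Pearson skewness of the max-normalized score
    distribution. Returns NaN for degenerate (zero-variance) inputs."""
    vals = np.array([s for _, _, s in metric.pair_scores()])
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise ValueError("need at least 3 pairs")
    vmax = vals.max()
    if vmax != 0:
        vals = vals / vmax
    if np.ptp(vals) == 0:
        return math.nan
    return float(stats.skew(vals, bias=False))


def write_ranking_tsv(ranking: PairRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("og_a\tog_b\tprediction_score\trank\n")
        for p in ranking.pairs:
            fh.write(f"{p[0]}\t{p[1]}\t{float(ranking.scores[p])!r}\t{ranking.ranks[p]}\n")


def read_ranking_tsv(path) -> PairRanking:
    pairs, ranks, scores = [], {}, {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            oa, ob, s, r = line.rstrip("\n").split("\t")
            p = _canonical(oa, ob)
            pairs.append(p)
            scores[p] = float(s)
            ranks[p] = int(r)
    pairs.sort(key=lambda p: ranks[p])
    return PairRanking(pairs=pairs, ranks=ranks, scores=scores, sources=("file",))
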