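"""Mutual information between OG pairs (SMI / EMI).

MI is the *local* association metric: for OGs a, b it is

    MI_ab = sum_{i,j} f_ab(i,j) * ln[ f_ab(i,j) / (f_a(i) f_b(j)) ]

in nats, computed from the empirical pair frequencies alone. It detects
both co-occurring and anti-correlated profiles, but — being local — it is
exposed to spurious (transitive) correlation through shared partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import FrequencyTables, ProfileTable, compute_frequencies

__all__ = ["MetricMatrix", "mutual_information", "mutual_information_from_table"]


@dataclass
class MetricMatrix:
    """Symmetric L x L pair-score matrix for one named association metric.

    The diagonal is undefined and stored as NaN. ``metric_name`` is one of
    SMI, EMI, SDI, EDI or ``integrated:<spec>``.
    """

    og_ids: list[str]
    scores: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        l = len(self.og_ids)
        if self.scores.shape != (l, l):
            raise ValueError("scores shape does not match og_ids")
        off = ~np.eye(l, dtype=bool)
        if not np.allclose(
            self.scores[off], self.scores.T[off], equal_nan=True
        ):
            raise ValueError("score matrix is not symmetric")

    @property
    def L(self) -> int:
        return len(self.og_ids)

    def pair_scores(self):
        """Yield (og_a, og_b, score) for a < b in column order."""
        for a in range(self.L):
            for b in range(a + 1, self.L):
                yield self.og_ids[a], self.og_ids[b], float(self.scores[a, b])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("og_a\tog_b\tscore\n")
            for oa, ob, s in self.pair_scores():
                fh.write(f"{oa}\t{ob}\t{float(s)!r}\n")

    @classmethod
    def read_tsv(cls, path, metric_name: str | None = None) -> "MetricMatrix":
        pairs: list[tuple[str, str, float]] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("og_a"):
                raise ValueError("expected header 'og_a\\tog_b\\tscore'")
            for line in fh:
                oa, ob, s = line.rstrip("\n").split("\t")
                pairs.append((oa, ob, float(s)))
        ids: list[str] = []
        seen = set()
        for oa, ob, _ in pairs:
            for og in (oa, ob):
                if og not in seen:
                    seen.add(og)
                    ids.append(og)
        idx = {og: k for k, og in enumerate(ids)}
        scores = np.full((len(ids), len(ids)), np.nan)
        for oa, ob, s in pairs:
            scores[idx[oa], idx[ob]] = s
            scores[idx[ob], idx[oa]] = s
        return cls(og_ids=ids, scores=scores,
                   metric_name=metric_name or "unknown")


def mutual_information(
    freqs: FrequencyTables, og_ids: list[str] | None = None
) -> MetricMatrix:
    """MI (nats) for every unordered OG pair from frequency tables.

    Terms with ``f_ab(i,j) == 0`` contribute zero. The metric is named SMI
    for binary (Q=1) tables and EMI for gain/loss (Q=2) tables.
    """
    fa, fab = freqs.fa, freqs.fab
    outer = fa[:, None, :, None] * fa[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(fab > 0, fab * (np.log(fab) - np.log(outer)), 0.0)
    scores = terms.sum(axis=(2, 3))
    scores = 0.5 * (scores + scores.T)  # symmetrize away float noise
    np.fill_diagonal(scores, np.nan)
    name = "SMI" if freqs.Q == 1 else "EMI"
    if og_ids is None:
        og_ids = [f"og{k}" for k in range(freqs.L)]
    return MetricMatrix(og_ids=list(og_ids), scores=scores, metric_name=name)


def mutual_information_from_table(table: ProfileTable) -> MetricMatrix:
    """Convenience wrapper: frequencies + MI, keeping the table's OG ids."""
    return mutual_information(compute_frequencies(table), og_ids=table.og_ids)
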