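"""Ortholog-group (OG) profile tables and empirical frequency tables.

A profile table is an N x L integer matrix ``D``. In the *standard* setting
rows are species and ``D[i, j]`` in {0, 1} records whether species *i*
carries OG *j*. In the *evolutionary* setting rows are phylogenetic-tree
branches and ``D[i, j]`` in {0, 1, 2} records whether OG *j* had no event,
a gain, or a loss on branch *i*. Every downstream metric consumes the
one-site and two-site relative frequencies computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SETTING_Q = {"standard": 1, "evolutionary": 2}

__all__ = [
    "ProfileTable",
    "FrequencyTables",
    "FilterReport",
    "ProfileParseError",
    "read_profile_table",
    "write_profile_table",
    "filter_ogs",
    "compute_frequencies",
]


class ProfileParseError(ValueError):
    """Raised when a profile TSV is malformed; names the offending cell."""


@dataclass
class ProfileTable:
    """Species-x-OG (standard) or branch-x-OG (evolutionary) state matrix.

    Parameters
    ----------
    row_ids : list of str
        Species or branch identifiers, unique, length N.
    og_ids : list of str
        Ortholog-group identifiers, unique, length L.
    D : ndarray of shape (N, L)
        Integer states in ``[0, Q]``.
    setting : {"standard", "evolutionary"}
        Determines ``Q`` (1 or 2).
    """

    row_ids: list[str]
    og_ids: list[str]
    D: np.ndarray
    setting: str

    def __post_init__(self) -> None:
        if self.setting not in SETTING_Q:
            raise ValueError(f"unknown setting {self.setting!r}")
        self.D = np.asarray(self.D)
        if not np.issubdtype(self.D.dtype, np.integer):
            raise ValueError("D must be an integer matrix")
        self.D = self.D.astype(np.int8, copy=False)
        if self.D.ndim != 2:
            raise ValueError("D must be 2-dimensional")
        n, l = self.D.shape
        if len(self.row_ids) != n or len(self.og_ids) != l:
            raise ValueError("id lengths do not match D shape")
        if len(set(self.row_ids)) != n:
            raise ValueError("duplicate row ids")
        if len(set(self.og_ids)) != l:
            raise ValueError("duplicate OG ids")
        bad = (self.D < 0) | (self.D > self.Q)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"state out of range [0, {self.Q}] at row {self.row_ids[i]!r}, "
                f"OG {self.og_ids[j]!r}: {self.D[i, j]}"
            )

    @property
    def Q(self) -> int:
        return SETTING_Q[self.setting]

    @property
    def n_rows(self) -> int:
        return self.D.shape[0]

    @property
    def n_ogs(self) -> int:
        return self.D.shape[1]

    def presence_fraction(self) -> np.ndarray:
        """Per-OG fraction of rows with a non-zero state."""
        return (self.D != 0).mean(axis=0)


@dataclass
class FrequencyTables:
    """One-site and two-site relative frequencies of a profile table.

    ``fa[a, i]`` is the relative frequency of OG *a* in state *i*;
    ``fab[a, b, i, j]`` the joint relative frequency of the pair.
    The tensor is stored for all ordered (a, b) with the symmetry
    ``fab[a, b] == fab[b, a].T``; the diagonal block ``fab[a, a]`` holds
    ``diag(fa[a])``.
    """

    fa: np.ndarray  # (L, Q+1)
    fab: np.ndarray  # (L, L, Q+1, Q+1)
    n_rows: int | None = None

    @property
    def L(self) -> int:
        return self.fa.shape[0]

    @property
    def Q(self) -> int:
        return self.fa.shape[1] - 1

    def pair_joint(self, a: int, b: int) -> np.ndarray:
        """Joint (Q+1)x(Q+1) distribution of OGs a and b."""
        return self.fab[a, b]

    def validate(self, atol: float = 1e-12) -> None:
        if not np.allclose(self.fa.sum(axis=1), 1.0, atol=atol):
            raise ValueError("one-site frequencies do not sum to 1")
        if not np.allclose(self.fab.sum(axis=(2, 3)), 1.0, atol=atol):
            raise ValueError("two-site frequencies do not sum to 1")
        # marginalizing fab over either index must recover fa
        if not np.allclose(self.fab.sum(axis=3), self.fa[:, None, :], atol=atol):
            raise ValueError("row-marginal of fab does not match fa")
        if not np.allclose(self.fab.sum(axis=2), self.fa[None, :, :], atol=atol):
            raise ValueError("column-marginal of fab does not match fa")


@dataclass
class FilterReport:
    kept_og_ids: list[str]
    removed_og_ids: list[str]
    presence_fraction: dict[str, float] = field(default_factory=dict)


def read_profile_table(path, setting: str) -> ProfileTable:
    """Read a TSV profile table (header = OG ids, first column = row ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(r) for r in df.index]
    og_ids = [str(c) for c in df.columns]
    D = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = values[i, j]
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise ProfileParseError(
                    f"non-integer cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {og_ids[j]!r}"
                ) from None
            D[i, j] = v
    q = SETTING_Q[setting]
    bad = (D < 0) | (D > q)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ProfileParseError(
            f"state out of range [0, {q}] at row {row_ids[i]!r}, "
            f"column {og_ids[j]!r}: {D[i, j]}"
        )
    if len(set(row_ids)) != len(row_ids):
        raise ProfileParseError("duplicate row ids in table")
    if len(set(og_ids)) != len(og_ids):
        raise ProfileParseError("duplicate OG ids in header")
    return ProfileTable(row_ids=row_ids, og_ids=og_ids, D=D, setting=setting)


def write_profile_table(table: ProfileTable, path) -> None:
    df = pd.DataFrame(table.D, index=table.row_ids, columns=table.og_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def filter_ogs(
    table: ProfileTable,
    min_frac: float = 0.10,
    max_frac: float = 0.90,
) -> tuple[ProfileTable, FilterReport]:
    """Drop OGs with presence fraction below ``min_frac`` or above ``max_frac``.

    The boundaries are inclusive: an OG present in exactly ``min_frac`` or
    exactly ``max_frac`` of the rows is kept. Presence counts any non-zero
    state (copy number is not modelled). Column order is preserved.
    """
    frac = table.presence_fraction()
    keep = (frac >= min_frac) & (frac <= max_frac)
    kept = [og for og, k in zip(table.og_ids, keep) if k]
    removed = [og for og, k in zip(table.og_ids, keep) if not k]
    if not kept:
        warnings.warn("filter_ogs removed every OG", stacklevel=2)
    out = ProfileTable(
        row_ids=list(table.row_ids),
        og_ids=kept,
        D=table.D[:, keep],
        setting=table.setting,
    )
    report = FilterReport(
        kept_og_ids=kept,
        removed_og_ids=removed,
        presence_fraction={og: float(f) for og, f in zip(table.og_ids, frac)},
    )
    return out, report


def compute_frequencies(table: ProfileTable) -> FrequencyTables:
    """Empirical one- and two-site relative frequencies (plain counts / N).

    No pseudocounts are added; zero cells are legal and downstream code uses
    the 0*ln(0) = 0 convention.
    """
    if table.n_rows < 1:
        raise ValueError("need at least one row")
    q1 = table.Q + 1
    onehot = np.eye(q1, dtype=np.float64)[table.D]  # (N, L, Q+1)
    fa = onehot.mean(axis=0)
    fab = np.einsum("nai,nbj->abij", onehot, onehot) / table.n_rows
    return FrequencyTables(fa=fa, fab=fab, n_rows=table.n_rows)
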