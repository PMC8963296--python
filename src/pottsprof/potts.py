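"""The Potts model in the lattice-gas gauge and the direct-information metric.

The joint distribution over L categorical OG variables with states 0..Q is

    P(x_1..x_L) = (1/Z) exp{ sum_a h_a(x_a) + sum_{a<b} J_ab(x_a, x_b) }

— the maximum-entropy model matching one- and two-site frequencies (for
Q=1 this is the Ising / lattice-gas model). The gauge fixes
h_a(0) = J_ab(0, i) = J_ab(i, 0) = 0, leaving L*Q + L(L-1)/2 * Q^2 free
parameters.

Direct information (DI) is the *global* association metric: for each pair
the two-site "direct" distribution

    P^dir_ab(i,j) = (1/Z_ab) exp{ h_a(i) + h_b(j) + J_ab(i,j) }

is built from that pair's own fields and coupling, and DI_ab is the mutual
information of P^dir against its own marginals. Because J_ab captures only
the conditional (direct) dependence, DI discounts correlation transmitted
through other OGs. This DI variant keeps the model's fitted h in P^dir
rather than re-solving fields against the empirical one-site frequencies
as the original protein-DCA formulation does.

Exact enumeration utilities (partition function, marginals) are provided
for small L; they serve as oracles and as the backend of the exact sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .mi import MetricMatrix
from .profiles import FrequencyTables

__all__ = [
    "PottsModel",
    "EnumerationCapExceeded",
    "enumerate_states",
    "log_unnormalized",
    "log_unnormalized_batch",
    "log_partition_function",
    "partition_function_exact",
    "exact_marginals",
    "conditional_distribution",
    "direct_information",
    "gauge_transform",
    "project_lattice_gas",
    "write_model",
    "read_model",
]

DEFAULT_ENUM_CAP = 2**24


class EnumerationCapExceeded(ValueError):
    """(Q+1)^L exceeds the configured enumeration cap."""


@dataclass
class PottsModel:
    """Fields ``h`` of shape (L, Q+1) and couplings ``J`` of shape
    (L, L, Q+1, Q+1) with the symmetry ``J[a,b,i,j] == J[b,a,j,i]`` and a
    zero diagonal block. In the (default) lattice-gas gauge all entries
    touching state 0 are pinned to zero."""

    h: np.ndarray
    J: np.ndarray
    gauge: str = "lattice_gas"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        l, q1 = self.h.shape
        if self.J.shape != (l, l, q1, q1):
            raise ValueError("J shape does not match h")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("parameters must be finite")
        if not np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2))):
            raise ValueError("J must satisfy J[a,b,i,j] == J[b,a,j,i]")
        if np.abs(self.J[np.arange(l), np.arange(l)]).max(initial=0.0) != 0.0:
            raise ValueError("diagonal blocks J[a,a] must be zero")
        if self.gauge == "lattice_gas":
            if (
                np.abs(self.h[:, 0]).max(initial=0.0) != 0.0
                or np.abs(self.J[:, :, 0, :]).max(initial=0.0) != 0.0
                or np.abs(self.J[:, :, :, 0]).max(initial=0.0) != 0.0
            ):
                raise ValueError("lattice-gas gauge entries must be exactly 0")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def Q(self) -> int:
        return self.h.shape[1] - 1

    def coupling(self, a: int, b: int) -> np.ndarray:
        """J_ab as a (Q+1)x(Q+1) matrix; J_ba(j,i) is the same quantity."""
        return self.J[a, b]

    @classmethod
    def zeros(cls, L: int, Q: int) -> "PottsModel":
        q1 = Q + 1
        return cls(h=np.zeros((L, q1)), J=np.zeros((L, L, q1, q1)))

    def n_free_parameters(self) -> int:
        l, q = self.L, self.Q
        return l * q + l * (l - 1) // 2 * q * q


def enumerate_states(L: int, Q: int, cap: int = DEFAULT_ENUM_CAP) -> np.ndarray:
    """All (Q+1)^L state vectors as an (S, L) int matrix (mixed-radix order)."""
    n_states = (Q + 1) ** L
    if n_states > cap:
        raise EnumerationCapExceeded(
            f"(Q+1)^L = {n_states} exceeds enumeration cap {cap}"
        )
    idx = np.arange(n_states)
    radix = (Q + 1) ** np.arange(L - 1, -1, -1)
    return (idx[:, None] // radix[None, :]) % (Q + 1)


def log_unnormalized(model: PottsModel, x) -> float:
    """Energy-like score sum_a h_a(x_a) + sum_{a<b} J_ab(x_a, x_b)."""
    x = np.asarray(x, dtype=np.int64)
    if x.shape != (model.L,):
        raise ValueError("state vector length must equal L")
    if ((x < 0) | (x > model.Q)).any():
        raise ValueError("state out of range")
    return float(log_unnormalized_batch(model, x[None, :])[0])

def log_unnormalized_batch(model: PottsModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.int64)
    n, l = X.shape
    rows = np.arange(l)
    e = model.h[rows, X].sum(axis=1)
    for a in range(l):
        for b in range(a + 1, l):
            e = e + model.J[a, b][X[:, a], X[:, b]]
    return e


def log_partition_function(model: PottsModel, cap: int = DEFAULT_ENUM_CAP) -> float:
    states = enumerate_states(model.L, model.Q, cap)
    return float(logsumexp(log_unnormalized_batch(model, states)))


def partition_function_exact(model: PottsModel, cap: int = DEFAULT_ENUM_CAP) -> float:
    """Z by full enumeration (log-space internally). Small L only."""
    return float(np.exp(log_partition_function(model, cap)))


def exact_probabilities(
    model: PottsModel, cap: int = DEFAULT_ENUM_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """(states, probabilities) over the full state space."""
    states = enumerate_states(model.L, model.Q, cap)
    loge = log_unnormalized_batch(model, states)
    loge -= loge.max()
    p = np.exp(loge)
    p /= p.sum()
    return states, p


def exact_marginals(model: PottsModel, cap: int = DEFAULT_ENUM_CAP) -> FrequencyTables:
    """Exact one- and two-site marginals p_a(i), p_ab(i,j) by enumeration."""
    states, p = exact_probabilities(model, cap)
    l, q1 = model.L, model.Q + 1
    fa = np.zeros((l, q1))
    for a in range(l):
        np.add.at(fa[a], states[:, a], p)
    fab = np.zeros((l, l, q1, q1))
    for a in range(l):
        for b in range(l):
            np.add.at(fab[a, b], (states[:, a], states[:, b]), p)
    return FrequencyTables(fa=fa, fab=fab, n_rows=None)


def conditional_distribution(model: PottsModel, x, j: int) -> np.ndarray:
    """P(x_j = s | x_{-j}) over the Q+1 states, the Gibbs-sampler kernel."""
    x = np.asarray(x, dtype=np.int64)
    if ((x < 0) | (x > model.Q)).any():
        raise ValueError("state out of range")
    l = model.L
    # J[a, j][x_a, :] summed over a != j; the diagonal block is zero
    e = model.h[j] + model.J[np.arange(l), j, x, :].sum(axis=0)
    e -= e.max()
    p = np.exp(e)
    return p / p.sum()


def _mi_of_joint(p: np.ndarray) -> float:
    """MI of a normalized two-site joint against its own marginals."""
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    outer = np.outer(pi, pj)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(outer)), 0.0)
    return float(terms.sum())


def direct_pair_distribution(model: PottsModel, a: int, b: int) -> np.ndarray:
    """P^dir_ab(i,j) = exp{h_a(i) + h_b(j) + J_ab(i,j)} / Z_ab."""
    e = model.h[a][:, None] + model.h[b][None, :] + model.J[a, b]
    e -= e.max()
    p = np.exp(e)
    return p / p.sum()


def direct_information(
    model: PottsModel, og_ids: list[str] | None = None
) -> MetricMatrix:
    """DI for every unordered pair: the MI of the pair's direct distribution.

    Named SDI for Q=1 models and EDI for Q=2 models.
    """
    l = model.L
    scores = np.full((l, l), np.nan)
    for a in range(l):
        for b in range(a + 1, l):
            di = _mi_of_joint(direct_pair_distribution(model, a, b))
            scores[a, b] = scores[b, a] = di
    name = "SDI" if model.Q == 1 else "EDI"
    if og_ids is None:
        og_ids = [f"og{k}" for k in range(l)]
    return MetricMatrix(og_ids=list(og_ids), scores=scores, metric_name=name)


def gauge_transform(model: PottsModel, site_shifts: np.ndarray) -> PottsModel:
    """Redistribute per-site, per-state offsets between h and J.

    ``site_shifts[a, i]`` is subtracted from ``h_a(i)`` and spread evenly
    over the couplings incident to site *a*, so the total score of every
    configuration — and hence the joint distribution — is unchanged while
    the (h, J) split differs. The result generally leaves the lattice-gas
    gauge; use :func:`project_lattice_gas` to return to it.
    """
    s = np.asarray(site_shifts, dtype=np.float64)
    if s.shape != model.h.shape:
        raise ValueError("site_shifts shape must match h")
    if not np.isfinite(s).all():
        raise ValueError("site_shifts must be finite")
    l = model.L
    if l < 2:
        raise ValueError("gauge_transform needs L >= 2")
    h = model.h - s
    J = model.J.copy()
    share = s / (l - 1)
    # J'_ab(i,j) = J_ab(i,j) + s_a(i)/(L-1) + s_b(j)/(L-1) for a != b
    J += share[:, None, :, None] + share[None, :, None, :]
    idx = np.arange(l)
    J[idx, idx] = 0.0
    return PottsModel(h=h, J=J, gauge="free")


def project_lattice_gas(model: PottsModel) -> PottsModel:
    """Re-express an arbitrary-gauge model in the lattice-gas gauge.

    The joint distribution is preserved exactly (the dropped terms are a
    configuration-independent constant absorbed by Z).
    """
    h, J = model.h, model.J
    l = model.L
    Jp = J - J[:, :, :1, :] - J[:, :, :, :1] + J[:, :, :1, :1]
    idx = np.arange(l)
    Jp[idx, idx] = 0.0
    cross = (J[:, :, :, 0] - J[:, :, 0, 0][:, :, None]).copy()  # (a,b,i)
    cross[idx, idx] = 0.0
    hp = h - h[:, :1] + cross.sum(axis=1)
    hp[:, 0] = 0.0  # exact zero (identical terms cancel analytically)
    Jp[:, :, 0, :] = 0.0
    Jp[:, :, :, 0] = 0.0
    return PottsModel(h=hp, J=Jp, gauge="lattice_gas")


def write_model(model: PottsModel, path) -> None:
    """Flat TSV of the free parameters plus an L/Q/gauge header."""
    with open(path, "w") as fh:
        fh.write(f"#potts\tL={model.L}\tQ={model.Q}\tgauge={model.gauge}\n")
        for a in range(model.L):
            for i in range(1, model.Q + 1):
                fh.write(f"h\t{a}\t{i}\t{float(model.h[a, i])!r}\n")
        for a in range(model.L):
            for b in range(a + 1, model.L):
                for i in range(1, model.Q + 1):
                    for j in range(1, model.Q + 1):
                        fh.write(f"J\t{a}\t{b}\t{i}\t{j}\t{float(model.J[a, b, i, j])!r}\n")


def read_model(path) -> PottsModel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#potts"):
            raise ValueError("not a Potts model file")
        meta = dict(kv.split("=") for kv in header.split("\t")[1:])
        l, q = int(meta["L"]), int(meta["Q"])
        model = PottsModel.zeros(l, q)
        model.gauge = meta.get("gauge", "lattice_gas")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "h":
                a, i, v = int(parts[1]), int(parts[2]), float(parts[3])
                model.h[a, i] = v
            elif parts[0] == "J":
                a, b, i, j = map(int, parts[1:5])
                v = float(parts[5])
                model.J[a, b, i, j] = v
                model.J[b, a, j, i] = v
            else:
                raise ValueError(f"unknown record type {parts[0]!r}")
    return model
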