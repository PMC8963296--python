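"""Synthetic data with known ground truth.

Three generators back the test battery and the worked examples:

* exact and Gibbs samplers for an arbitrary Potts model, used to make
  profile tables whose true couplings are known;
* planted-coupling ("chain") models for the confounding scenario — a hub
  OG directly coupled to two partners makes the partner pair spuriously
  correlated even though their direct coupling is zero;
* gene-content evolution along a rooted Newick tree: per branch, an
  absent gene is gained with probability 1 - exp(-gain_rate * length) and
  a present gene lost with 1 - exp(-loss_rate * length) (at most one
  effective event per OG per branch, matching the 0/1/2 event encoding).
  The branch-event table uses the evolutionary-setting codes and the leaf
  states form the companion standard-setting table.

A Fitch small-parsimony reconstruction maps leaf presence back to branch
gains/losses, standing in at desk scale for probabilistic gene-content
reconstruction tools. Ties at the root resolve toward absence; elsewhere
the parent state is kept when allowed, so reconstruction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .potts import (
    PottsModel,
    exact_probabilities,
)
from .pcd import _sweep
from .profiles import ProfileTable

__all__ = [
    "SimTreeSpec",
    "PlantedCouplingSpec",
    "sample_potts_exact",
    "sample_potts_gibbs",
    "build_chain_model",
    "ring_model",
    "confounded_chain_model",
    "random_tree",
    "simulate_gene_content",
    "simulate_coevolving_blocks",
    "fitch_gain_loss",
]


# ---------------------------------------------------------------------------
# Potts samplers


def sample_potts_exact(
    model: PottsModel, n: int, seed: int, og_ids: list[str] | None = None
) -> ProfileTable:
    """n i.i.d. rows from the exact joint (inverse-CDF over all states)."""
    states, p = exact_probabilities(model)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(p), size=n, p=p)
    D = states[idx].astype(np.int8)
    setting = "standard" if model.Q == 1 else "evolutionary"
    if og_ids is None:
        og_ids = [f"og{k}" for k in range(model.L)]
    row_ids = [f"s{i}" for i in range(n)]
    return ProfileTable(row_ids=row_ids, og_ids=og_ids, D=D, setting=setting)


def sample_potts_gibbs(
    model: PottsModel,
    n: int,
    burnin: int = 200,
    thin: int = 5,
    seed: int = 0,
    n_chains: int = 64,
    og_ids: list[str] | None = None,
) -> ProfileTable:
    """Gibbs-chain samples for models too large to enumerate.

    Runs ``n_chains`` parallel chains from uniform-random starts, discards
    ``burnin`` full sweeps, then collects every chain's state every
    ``thin`` sweeps until n rows are gathered.
    """
    if burnin < 1 or thin < 1:
        raise ValueError("burnin and thin must be >= 1")
    rng = np.random.default_rng(seed)
    c = min(n_chains, n)
    chain = rng.integers(0, model.Q + 1, size=(c, model.L))
    for _ in range(burnin):
        _sweep(model.h, model.J, chain, rng)
    rows = []
    collected = 0
    while collected < n:
        for _ in range(thin):
            _sweep(model.h, model.J, chain, rng)
        take = min(c, n - collected)
        rows.append(chain[:take].copy())
        collected += take
    D = np.concatenate(rows).astype(np.int8)
    setting = "standard" if model.Q == 1 else "evolutionary"
    if og_ids is None:
        og_ids = [f"og{k}" for k in range(model.L)]
    return ProfileTable(
        row_ids=[f"s{i}" for i in range(n)], og_ids=og_ids, D=D, setting=setting
    )


# ---------------------------------------------------------------------------
# Planted-coupling models


@dataclass
class PlantedCouplingSpec:
    """Ground-truth Potts model description: nonzero couplings only on the
    planted pairs. A scalar strength c sets J_ab(i,j) = c for i == j >= 1
    (same-state attraction); a (Q, Q) matrix gives the free block directly."""

    L: int
    Q: int
    couplings: list[tuple[int, int, float | np.ndarray]]
    fields: dict[int, float | np.ndarray] = field(default_factory=dict)
    n: int = 800
    seed: int = 0


def build_chain_model(spec: PlantedCouplingSpec) -> PottsModel:
    """Potts model with J nonzero exactly on the planted pairs."""
    model = PottsModel.zeros(spec.L, spec.Q)
    for a, b, c in spec.couplings:
        if not (0 <= a < spec.L and 0 <= b < spec.L and a != b):
            raise ValueError(f"invalid planted pair ({a}, {b})")
        block = np.zeros((spec.Q + 1, spec.Q + 1))
        if np.isscalar(c):
            for i in range(1, spec.Q + 1):
                block[i, i] = c
        else:
            block[1:, 1:] = np.asarray(c)
        model.J[a, b] += block
        model.J[b, a] += block.T
    for a, v in spec.fields.items():
        if np.isscalar(v):
            model.h[a, 1:] = v
        else:
            model.h[a, 1:] = np.asarray(v)
    return model


def ring_model(
    L: int = 6,
    Q: int = 1,
    strength: float = 0.8,
    field_scale: float = 0.5,
    seed: int = 123,
) -> PottsModel:
    """Ring-coupled benchmark model: neighbors on a cycle carry couplings
    of alternating sign +/-strength (same-state blocks) and fields are
    drawn uniformly from [-field_scale, field_scale]. Small enough to
    enumerate exactly, structured enough to be a nontrivial fitting
    target."""
    rng = np.random.default_rng(seed)
    couplings = [
        (a, (a + 1) % L, strength if a % 2 == 0 else -strength)
        for a in range(L)
    ]
    fields = {a: rng.uniform(-field_scale, field_scale, size=Q) for a in range(L)}
    return build_chain_model(
        PlantedCouplingSpec(L=L, Q=Q, couplings=couplings, fields=fields)
    )


def confounded_chain_model(
    j_strong: float = 4.5, j_weak: float = 0.7
) -> PottsModel:
    """The three-OG confounding scenario A - B - C (binary states).

    B is the hub: strong direct coupling to A, moderate direct coupling
    to C, and no direct A-C coupling — yet A and C co-occur through B.
    The defaults put the indirect A-C dependence in the same range as the
    weaker direct pair (exact MI 0.010 vs 0.015 nats), the regime where a
    local metric is genuinely at risk of ranking the spurious pair above
    a real one while the direct coupling structure stays identifiable.
    Fields are set to -(sum of incident couplings)/2, which makes the
    distribution symmetric under the global 0<->1 flip, so every marginal
    is exactly 1/2.
    """
    spec = PlantedCouplingSpec(
        L=3,
        Q=1,
        couplings=[(0, 1, j_strong), (1, 2, j_weak)],
        fields={
            0: -j_strong / 2,
            1: -(j_strong + j_weak) / 2,
            2: -j_weak / 2,
        },
    )
    return build_chain_model(spec)


# ---------------------------------------------------------------------------
# Trees and gene-content evolution


@dataclass
class SimTreeSpec:
    """Gene-content simulation conditions: a rooted Newick tree with branch
    lengths, per-branch gain/loss rates (events per unit length), number of
    OGs, root presence probability and a seed."""

    newick: str
    L: int
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    root_presence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.root_presence <= 1.0:
            raise ValueError("root presence must be a probability")


def random_tree(
    n_leaves: int, seed: int, min_len: float = 0.2, max_len: float = 1.0
) -> str:
    """Random rooted binary tree (uniform random joins, uniform branch
    lengths) as a Newick string with leaf labels t1..tn."""
    rng = np.random.default_rng(seed)
    nodes = [f"t{i + 1}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        bl = rng.uniform(min_len, max_len)
        br = rng.uniform(min_len, max_len)
        nodes.append(f"({left}:{bl:.6f},{right}:{br:.6f})")
    return nodes[0] + ";"


def _load_tree(newick: str) -> tuple[dendropy.Tree, list]:
    """Parse Newick; label unnamed internal nodes; return (tree, branches).

    A branch is identified by its child node, so the branch list is every
    non-root node in preorder.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            counter += 1
            node.label = f"node{counter}"
    branches = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    return tree, branches


def _node_name(node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def simulate_gene_content(spec: SimTreeSpec) -> tuple[ProfileTable, ProfileTable]:
    """Evolve presence/absence of L independent OGs down the tree.

    Returns ``(extant, events)``: the leaf presence table (standard
    setting) and the true branch-event table (evolutionary setting,
    0 none / 1 gain / 2 loss). Replaying the events from the root state
    reproduces the leaf states exactly.
    """
    tree, branches = _load_tree(spec.newick)
    rng = np.random.default_rng(spec.seed)
    state: dict = {}
    root = tree.seed_node
    state[root] = (rng.random(spec.L) < spec.root_presence).astype(np.int8)
    events = np.zeros((len(branches), spec.L), dtype=np.int8)
    for bi, node in enumerate(branches):
        length = node.edge.length or 0.0
        p_gain = 1.0 - np.exp(-spec.gain_rate * length)
        p_loss = 1.0 - np.exp(-spec.loss_rate * length)
        parent = state[node.parent_node]
        u = rng.random(spec.L)
        gained = (parent == 0) & (u < p_gain)
        lost = (parent == 1) & (u < p_loss)
        child = parent.copy()
        child[gained] = 1
        child[lost] = 0
        events[bi, gained] = 1
        events[bi, lost] = 2
        state[node] = child
    og_ids = [f"og{k}" for k in range(spec.L)]
    leaves = [n for n in tree.leaf_node_iter()]
    extant = ProfileTable(
        row_ids=[_node_name(n) for n in leaves],
        og_ids=og_ids,
        D=np.stack([state[n] for n in leaves]),
        setting="standard",
    )
    event_table = ProfileTable(
        row_ids=[_node_name(n) for n in branches],
        og_ids=og_ids,
        D=events,
        setting="evolutionary",
    )
    return extant, event_table


def simulate_coevolving_blocks(
    newick: str,
    block_sizes: tuple[int, ...] = (3, 3),
    n_background: int = 6,
    follow_prob: float = 0.9,
    block_gain_rate: float = 0.5,
    block_loss_rate: float = 0.5,
    background_gain_rate: float = 0.08,
    background_loss_rate: float = 0.08,
    noise_gain_rate: float = 0.08,
    noise_loss_rate: float = 0.08,
    root_presence: float = 0.5,
    seed: int = 0,
) -> tuple[ProfileTable, ProfileTable, list[tuple[str, str]]]:
    """Gene-content evolution with planted co-evolving OG blocks.

    Each block follows a latent "pathway" presence trajectory: on a branch
    where the latent pathway gains (or loses), every member OG that can
    follow does so with probability ``follow_prob``; members additionally
    pick up independent low-rate noise events. Background OGs evolve
    independently. Returns ``(extant, events, positive_pairs)`` where the
    positive pairs are all within-block OG pairs — the ground-truth labels
    for benchmarking association metrics.
    """
    tree, branches = _load_tree(newick)
    rng = np.random.default_rng(seed)
    n_block = sum(block_sizes)
    L = n_block + n_background
    og_ids = [f"og{k}" for k in range(L)]

    # latent pathway trajectories, one per block
    n_blocks = len(block_sizes)
    latent_state = {tree.seed_node: (rng.random(n_blocks) < root_presence).astype(np.int8)}
    latent_event: dict = {}
    for node in branches:
        length = node.edge.length or 0.0
        pg = 1.0 - np.exp(-block_gain_rate * length)
        pl = 1.0 - np.exp(-block_loss_rate * length)
        parent = latent_state[node.parent_node]
        u = rng.random(n_blocks)
        ev = np.zeros(n_blocks, dtype=np.int8)
        ev[(parent == 0) & (u < pg)] = 1
        ev[(parent == 1) & (u < pl)] = 2
        child = parent.copy()
        child[ev == 1] = 1
        child[ev == 2] = 0
        latent_event[node] = ev
        latent_state[node] = child

    block_of = np.full(L, -1)
    k = 0
    for b, size in enumerate(block_sizes):
        block_of[k : k + size] = b
        k += size

    state = {}
    root_state = np.empty(L, dtype=np.int8)
    root_state[:n_block] = latent_state[tree.seed_node][block_of[:n_block]]
    root_state[n_block:] = (rng.random(n_background) < root_presence).astype(np.int8)
    state[tree.seed_node] = root_state

    events = np.zeros((len(branches), L), dtype=np.int8)
    for bi, node in enumerate(branches):
        length = node.edge.length or 0.0
        parent = state[node.parent_node]
        child = parent.copy()
        ev = np.zeros(L, dtype=np.int8)
        # block members: follow the latent event, else background noise
        lat_ev = latent_event[node][block_of[:n_block]]
        u = rng.random(n_block)
        follow = u < follow_prob
        member_gain = (lat_ev == 1) & (parent[:n_block] == 0) & follow
        member_loss = (lat_ev == 2) & (parent[:n_block] == 1) & follow
        png = 1.0 - np.exp(-noise_gain_rate * length)
        pnl = 1.0 - np.exp(-noise_loss_rate * length)
        un = rng.random(n_block)
        noise_gain = (lat_ev == 0) & (parent[:n_block] == 0) & (un < png)
        noise_loss = (lat_ev == 0) & (parent[:n_block] == 1) & (un < pnl)
        ev[:n_block][member_gain | noise_gain] = 1
        ev[:n_block][member_loss | noise_loss] = 2
        # background OGs: independent evolution
        pbg = 1.0 - np.exp(-background_gain_rate * length)
        pbl = 1.0 - np.exp(-background_loss_rate * length)
        ub = rng.random(n_background)
        bg = parent[n_block:]
        bg_gain = (bg == 0) & (ub < pbg)
        bg_loss = (bg == 1) & (ub < pbl)
        ev[n_block:][bg_gain] = 1
        ev[n_block:][bg_loss] = 2
        child[ev == 1] = 1
        child[ev == 2] = 0
        events[bi] = ev
        state[node] = child

    leaves = list(tree.leaf_node_iter())
    extant = ProfileTable(
        row_ids=[_node_name(n) for n in leaves],
        og_ids=og_ids,
        D=np.stack([state[n] for n in leaves]),
        setting="standard",
    )
    event_table = ProfileTable(
        row_ids=[_node_name(n) for n in branches],
        og_ids=og_ids,
        D=events,
        setting="evolutionary",
    )
    positives = []
    for b in range(n_blocks):
        members = [og_ids[i] for i in range(n_block) if block_of[i] == b]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                positives.append((members[i], members[j]))
    return extant, event_table, positives


# ---------------------------------------------------------------------------
# Parsimony reconstruction


def fitch_gain_loss(newick: str, extant: ProfileTable) -> ProfileTable:
    """Fitch small-parsimony gain/loss mapping of leaf presence states.

    Bottom-up: each node's candidate set is the intersection of its
    children's sets when nonempty, else the union. Top-down: the root
    takes absence when ambiguous; a child keeps its parent's state when
    its set allows, else switches (recording a gain for 0 -> 1, a loss
    for 1 -> 0). Branch rows follow the same child-node naming as the
    simulator, so reconstructed tables are directly comparable to truth.
    """
    if extant.setting != "standard":
        raise ValueError("fitch_gain_loss expects a standard-setting table")
    tree, branches = _load_tree(newick)
    leaf_index = {r: i for i, r in enumerate(extant.row_ids)}
    L = extant.n_ogs
    candidate: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = _node_name(node)
            if name not in leaf_index:
                raise ValueError(f"leaf {name!r} missing from profile table")
            states = extant.D[leaf_index[name]]
            sets = np.zeros((L, 2), dtype=bool)
            sets[np.arange(L), states] = True
            candidate[node] = sets
        else:
            children = [candidate[c] for c in node.child_nodes()]
            inter = np.logical_and.reduce(children)
            union = np.logical_or.reduce(children)
            nonempty = inter.any(axis=1)
            sets = np.where(nonempty[:, None], inter, union)
            candidate[node] = sets
    if set(leaf_index) != {_node_name(n) for n in tree.leaf_node_iter()}:
        raise ValueError("leaf ids do not match the tree")

    assigned: dict = {}
    root = tree.seed_node
    rs = candidate[root]
    assigned[root] = np.where(rs[:, 0], 0, 1).astype(np.int8)  # absence preferred
    events = np.zeros((len(branches), L), dtype=np.int8)
    for bi, node in enumerate(branches):
        parent = assigned[node.parent_node]
        sets = candidate[node]
        keep = sets[np.arange(L), parent]
        # when the parent state is disallowed the set is a singleton
        other = np.where(sets[:, 0], 0, 1).astype(np.int8)
        child = np.where(keep, parent, other).astype(np.int8)
        events[bi][(parent == 0) & (child == 1)] = 1
        events[bi][(parent == 1) & (child == 0)] = 2
        assigned[node] = child
    return ProfileTable(
        row_ids=[_node_name(n) for n in branches],
        og_ids=list(extant.og_ids),
        D=events,
        setting="evolutionary",
    )
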