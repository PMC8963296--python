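# pottsprof

Phylogenetic profiling with inverse-Potts (direct-coupling) association
metrics.

Phylogenetic profiling predicts functional links between ortholog groups
(OGs): genes that act together are gained and lost together, so similar
presence/absence profiles across species suggest shared function. Local
similarity metrics compare two profiles at a time and suffer from
*spurious correlation* — if A is coupled to B and to C, the pair (B, C)
co-occurs through the confounder A. `pottsprof` fits the maximum-entropy
(Potts) model of all profiles jointly,

    P(x_1..x_L) = (1/Z) exp{ Σ_a h_a(x_a) + Σ_{a<b} J_ab(x_a, x_b) },

and scores each pair by **direct information**, the mutual information of
the pair's *direct* two-site distribution
P^dir_ab(i,j) ∝ exp{h_a(i) + h_b(j) + J_ab(i,j)}, which keeps only the
conditional (direct) dependence. Four metrics are provided, crossing the
local/global axis with the data representation:

|                | species presence (Q=1) | branch gain/loss events (Q=2) |
|----------------|------------------------|-------------------------------|
| mutual information (local) | SMI | EMI |
| direct information (global) | SDI | EDI |

The evolutionary setting consumes per-branch event tables (0 none,
1 gain, 2 loss) produced by gene-content reconstruction, removing the
evolutionary bias of treating related species as independent samples.
The package also includes: persistent-contrastive-divergence (PCD)
fitting with L2 regularization and the standard hyperparameter grid,
exact small-system oracles (partition function, marginals, samplers),
rank integration of several metrics (max / average / min of ranks),
AUC / PPV@M / AUPR evaluation against STRING-like association labels,
a gene-content simulator on Newick trees with planted co-evolving
blocks, and a Fitch-parsimony gain/loss mapper as a desk-scale stand-in
for probabilistic reconstruction tools.

## Worked example

The packaged confounding scenario: a chain A–B–C with direct couplings
only on A–B (strong) and B–C (moderate); A–C has **no** direct link but
co-occurs through the hub B.

```python
from pottsprof import (confounded_chain_model, sample_potts_exact,
                       mutual_information_from_table, fit_potts_pcd, PcdConfig,
                       direct_information, rank_pairs, integrate_ranks)

model = confounded_chain_model()          # A - B - C, no direct A-C coupling
table = sample_potts_exact(model, 800, seed=42)

smi = mutual_information_from_table(table)
fit, trace = fit_potts_pcd(table, PcdConfig(K=200, epsilon=0.01, lam=0.0,
                                            n_iterations=3000, seed=1))
sdi = direct_information(fit, og_ids=table.og_ids)

for name, m in [("SMI", smi), ("SDI", sdi)]:
    print(f"{name}:  A-B {m.scores[0,1]:.4f}   B-C {m.scores[1,2]:.4f}   "
          f"A-C {m.scores[0,2]:.4f}")
print("fitted J_AC(1,1) =", round(fit.J[0,2,1,1], 4),
      "   true J_AC(1,1) = 0.0")

combined = integrate_ranks([rank_pairs(smi), rank_pairs(sdi)], "average")
for p in combined.pairs:
    print(p, "prediction score", combined.scores[p])
```

prints

```
SMI:  A-B 0.3920   B-C 0.0178   A-C 0.0102
SDI:  A-B 0.1483   B-C 0.0023   A-C 0.0002
fitted J_AC(1,1) = 0.1003    true J_AC(1,1) = 0.0
('og0', 'og1') prediction score 1.0
('og1', 'og2') prediction score 2.0
('og0', 'og2') prediction score 3.0
```

Read: under the local metric the spurious pair A–C (0.0102 nats) sits
uncomfortably close to the genuine pair B–C (0.0178). The fitted model
recovers a near-zero direct coupling for A–C, so direct information
pushes the spurious pair an order of magnitude below the real one
(0.0002 vs 0.0023). The integrated ranking (average of ranks — the
pair's *prediction score*, smaller is better) orders the pairs
correctly.

The same workflow is available from the shell:

```sh
pottsprof simulate tree --leaves 32 --ogs 20 --seed 7 sim
pottsprof filter sim.extant.tsv filtered.tsv
pottsprof reconstruct sim.nwk filtered.tsv events.tsv
pottsprof mi --setting evolutionary events.tsv emi.tsv
pottsprof fit --setting evolutionary --lambda 0.01 --seed 7 events.tsv model.tsv
pottsprof di model.tsv edi.tsv
pottsprof integrate --metrics emi.tsv --metrics edi.tsv --mode average out.tsv
pottsprof evaluate --labels labels.tsv --th 0.7 --M 100 edi.tsv report.tsv
```

`pottsprof fit --grid` fits all 14 (λ, ε) hyperparameter combinations;
`pottsprof pipeline run.toml` chains the stages from a config file and
writes a replay manifest.

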