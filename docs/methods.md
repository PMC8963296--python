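# Methods

## The problem

Phylogenetic profiling infers functional links between ortholog groups
(OGs) from the similarity of their occurrence patterns: genes that work
together tend to be gained and lost together. Local similarity metrics —
here mutual information (MI) — compare two profiles at a time and are
therefore exposed to *spurious correlation*: if A is functionally coupled
to both B and C, the pair (B, C) co-occurs through A even with no direct
link. `pottsprof` addresses this with a *global* metric, direct
information (DI), derived from a Potts model fitted to all profiles
jointly, in both a species-presence ("standard") and a branch-event
("evolutionary") representation of the data.

## Data model

A profile table is an N x L integer matrix `D`. In the standard setting
rows are species and entries are presence/absence (states 0/1, Q = 1).
In the evolutionary setting rows are phylogenetic-tree branches and
entries encode gene-content events on that branch: 0 none, 1 gain,
2 loss (Q = 2). Event tables are normally produced by an external
gene-content reconstruction tool; the package ships a Fitch-parsimony
mapper as a desk-scale stand-in (below). Copy number is ignored
throughout.

OG filtering keeps columns whose presence fraction (share of rows with a
non-zero state) lies in the inclusive band [min_frac, max_frac], default
[0.10, 0.90]: near-universal and near-absent OGs carry almost no
information and dominate run time, since fitting cost grows with L².
Filtering is applied to the presence table; the event table inherits the
OG selection through whatever reconstruction produces it.

One- and two-site relative frequencies f_a(i), f_ab(i,j) are plain
counts over N with no pseudocounts and no row weighting (each species or
branch counts once — unlike protein covariation analysis, there is no
redundant-sequence reweighting step here). Zero cells are legal; MI uses
the 0·ln 0 = 0 convention.

## Metrics

**Mutual information** (SMI standard / EMI evolutionary), in nats:

    MI_ab = sum_{i,j=0..Q} f_ab(i,j) ln [ f_ab(i,j) / (f_a(i) f_b(j)) ]

MI detects co-occurring and anti-correlated pairs alike.

**Potts model.** The maximum-entropy joint distribution matching all
one- and two-site frequencies is

    P(x_1..x_L) = (1/Z) exp{ sum_a h_a(x_a) + sum_{a<b} J_ab(x_a,x_b) }

(the Ising / lattice-gas model when Q = 1). The parameterization is
redundant; we pin the *lattice-gas gauge* h_a(0) = J_ab(0,i) =
J_ab(i,0) = 0, leaving LQ + L(L-1)/2 · Q² free parameters. A
`gauge_transform` utility produces equivalent models with a different
(h, J) split and a projector returns any model to the lattice-gas gauge;
these exist so gauge sensitivity of downstream scores can be *measured*
rather than assumed (DI built from P^dir with the model's own fields is
not claimed to be exactly gauge-invariant here).

**Direct information** (SDI / EDI). For each pair the two-site direct
distribution

    P^dir_ab(i,j) = (1/Z_ab) exp{ h_a(i) + h_b(j) + J_ab(i,j) }

is built from that pair's own parameters, and DI_ab is the MI of P^dir
against its own marginals P^dir_{a|b}(i) = sum_j P^dir_ab(i,j). Because
J_ab encodes only conditional dependence, correlation routed through
third OGs is discounted. This DI variant deliberately keeps the fitted
fields in P^dir instead of re-solving them against the empirical
one-site frequencies as the original protein-DCA definition does.
Frobenius-norm and APC scores are not implemented: they are
gauge-dependent and are only meaningful in the zero-sum gauge, which
this package does not fit.

## Parameter estimation: persistent contrastive divergence

Exact likelihood needs Z, which is a sum over (Q+1)^L states; PCD
replaces the model expectation with a persistent set of K Gibbs chains.

Protocol (all defaults as listed):

* K = 200 chains, seeded by sampling K rows with replacement from D;
  all parameters start at 0.
* Per iteration: one full Gibbs sweep — sites in ascending column
  order, each site of each chain row resampled from its conditional
  given updated sites to the left and old sites to the right (L·K
  single-site updates). The implementation updates all K independent
  rows of a site at once; this differs from a row-by-row loop only in
  the order random numbers are consumed, which is fixed and documented
  so runs replay exactly.
* Update with learning rate ε (0.01 or 0.001) and L2 shrinkage λ:

      h_a(i)    += ε (f_a(i)    − f̂_a(i))    − 2λ h_a(i)
      J_ab(i,j) += ε (f_ab(i,j) − f̂_ab(i,j)) − 2λ J_ab(i,j)

  applied to free (non-gauge) parameters only; f̂ are the chain
  frequencies. Data frequencies f come from the full table (a switch
  selects the K-row chain seed instead, for users who prefer that
  reading of the protocol).
* 3000 iterations, constant ε, no early stopping. At the λ = 0 fixed
  point the model moments equal the data moments — the
  maximum-likelihood condition.

The hyperparameter grid is λ ∈ {0, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0} ×
ε ∈ {0.01, 0.001} (14 combinations; `fit --grid` writes one model per
combination so the best-scoring one can be selected downstream).

**Stability caveat.** The shrinkage term above is applied exactly as
written, *not* scaled by ε, so each iteration multiplies a parameter by
(1 − 2λ) before adding the gradient. For λ ≥ 1 this factor has magnitude
≥ 1 and the iteration diverges geometrically; `fit_potts_pcd` detects
the overflow and raises a clear error rather than returning garbage.
λ = 5.0 remains listed in the grid for completeness, but any practical
run should use λ < 1 (or rescale the shrinkage into the learning rate,
which this package does not do, to keep the printed rule intact).
Note also that because the shrinkage is not scaled by ε, its strength
relative to the gradient is 2λ/ε: at ε = 0.01 even λ = 0.01 is a heavy
penalty (stationary parameters ≈ ε/(2λ) times the moment gap), pulling
the fit toward a correlation-like score rather than a fully matched
maximum-likelihood model. That regime can still rank pairs well — the
training-trace `moment_gap` shows how far from moment matching a given
(λ, ε) ends up — but quantitative moment matching requires λ = 0 or
λ ≪ ε.

## Ranking, integration, skewness

Pairs are ranked 1..P per metric in descending score order; ties break
by lexicographic pair id so every ranking is total and reproducible.
Rankings from 2–3 metrics (the useful combinations are EMI/SDI/EDI and
their pairs) are integrated by taking the max, average or min of each
pair's ranks; the combined value is the pair's *prediction score*
(smaller = better) and pairs re-sort ascending, ties again
lexicographic. The skewness diagnostic divides scores by their maximum
and reports the adjusted Fisher–Pearson sample skewness; the
normalization does not change skewness (it is scale-invariant) — it
only standardizes the axis when distributions are plotted. Strong right
skew indicates a metric that concentrates high scores on few pairs.

## Evaluation

Labels are STRING-like association scores in [0, 1] per pair; a pair is
positive when its score is *strictly* greater than the threshold th
(grid 0.5–0.9; 0.7 and 0.9 are STRING's high/highest-confidence
cut-offs). Metrics are scored by

* **AUC** — Mann–Whitney convention, ties counted 1/2 (delegated to
  scikit-learn's `roc_auc_score`; an O(P²) brute-force oracle guards it
  in the tests);
* **PPV@M** — fraction of positives among the top M ranked pairs, M ∈
  {100, 500, 1000, 5000, 10000}; by default the top-M is taken over
  labeled pairs only (a switch counts unlabeled pairs as negatives);
* **AUPR** — step-wise (conservative) interpolation, i.e. scikit-learn's
  average precision. The convention is fixed and stated because AUPR
  differs between interpolation conventions.

A channel-recombination utility rebuilds combined association scores
while excluding a channel (e.g. occurrence-pattern similarity, which
must not leak into phylogenetic-profiling evaluation) via plain
noisy-OR, 1 − Π(1 − s_c), with an optional prior-correction hook.
Bit-exact reproduction of STRING's own prior handling is out of scope.

## Synthetic data

* `sample_potts_exact` enumerates all (Q+1)^L states (cap 2^24,
  configurable) and draws i.i.d. rows; `sample_potts_gibbs` runs
  parallel Gibbs chains (default 64) with burn-in and thinning for
  larger L. Both are seed-deterministic.
* `build_chain_model` plants couplings on chosen pairs only.
  `confounded_chain_model` is the packaged confounding scenario: a hub
  B with strong coupling to A (J = 4.5) and moderate coupling to C
  (J = 0.7), J_AC = 0, and fields −(incident J)/2 so the distribution
  is symmetric under the global 0↔1 flip and every marginal is exactly
  1/2. The strengths put the *indirect* A–C dependence (exact MI
  ≈ 0.010 nats) in the same range as the weaker *direct* pair
  (≈ 0.015), so a local metric genuinely risks misranking the spurious
  pair while the coupling structure remains identifiable — the regime
  the global metric exists for. Much stronger hubs (J ≳ 5) leave this
  regime: 3000 PCD iterations at ε = 0.01 can no longer reach the hub
  coupling and DI degrades too.
* `simulate_gene_content` evolves presence/absence down a rooted Newick
  tree: per branch, P(gain) = 1 − exp(−gain_rate·length) for absent
  genes, P(loss) likewise for present ones — at most one effective
  event per OG per branch, matching the 0/1/2 encoding. Branches are
  named by their child node. The branch-event and leaf tables are
  consistent by construction (replaying events reproduces the leaves).
  `random_tree` supplies random binary trees with uniform branch
  lengths in [0.2, 1.0].
* `simulate_coevolving_blocks` adds planted structure: each block
  follows a latent pathway trajectory (gain/loss rates 0.5) and members
  copy each latent event with probability 0.9, plus independent noise
  events at rate 0.08; background OGs evolve independently at the same
  background rate. Within-block pairs are the ground-truth positives.
  Defaults (32 leaves, two blocks of 3, 6 background OGs) are sized so
  a full PCD fit on the resulting 62-branch table runs in seconds.
* `fitch_gain_loss` is the parsimony stand-in for probabilistic
  gene-content reconstruction: bottom-up Fitch sets (intersection if
  non-empty, else union), top-down assignment preferring absence at an
  ambiguous root and the parent's state elsewhere, branch events read
  off the state changes. On low-rate simulations it recovers ≥ 90% of
  branch events; it is *not* a substitute for likelihood-based
  reconstruction on real data, where rate heterogeneity and multiple
  events per branch matter.

What the generators do **not** emulate: copy-number variation,
missing/ambiguous states, rate variation across OGs, horizontal
transfer hotspots, and the size and label noise of real STRING-derived
datasets. Passing tests therefore demonstrate correctness of the
machinery and the qualitative MI-vs-DI behavior under controlled
conditions, not empirical performance on any real clade.

## Numerical choices

* All enumeration works in log space with max-subtraction before
  exponentiation; the enumeration cap (default 2^24 states) makes exact
  routines refuse rather than thrash.
* MI/DI terms with zero probability contribute exactly 0.
* One `numpy` Generator per run drives subsampling and every Gibbs draw
  in a fixed order: identical seed + config + table gives bit-identical
  models, samples and output files.
* Metric score files store full `repr` precision so write/read round
  trips are exact.
* Problem sizes in the test battery and the acceptance script (L ≤ 6
  exact oracles; 5–30 fit replicates; one 62-branch evolutionary fit)
  are chosen so the full battery completes in a few minutes on one CPU
  while keeping every statistical margin at ≥ 3–4 standard errors.

## Known limitations

* PCD with constant ε leaves O(ε·K^-1/2) stochastic wobble in the
  fitted parameters; the ~0.02 max-norm moment error observed at the
  default settings is inherent to the estimator, not a convergence bug.
* DI's gauge sensitivity is exposed, not resolved: `gauge_transform`
  lets a user quantify it for their model.
* The evaluation utilities assume labels fit in memory as a pair dict;
  they target desk-scale benchmarking, not genome-scale STRING dumps.
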