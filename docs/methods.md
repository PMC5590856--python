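# Methods

## Problem and model

`evogeo` predicts unobserved protein–protein interactions (PPIs) from the
topology of a partially known interaction network. The working hypothesis
is twofold: (i) PPI networks have low-dimensional geometric structure, so
interacting proteins sit close together in a latent metric space; and
(ii) because the networks arose by gene duplication and post-duplication
divergence, evolutionary reasoning on a sparse training sub-network can
recover interactions that plain graph distance misses.

The pipeline, for an undirected simple graph `G = (V, E)` with adjacency
`a_ij ∈ {0, 1}`:

1. **Component.** Only the maximum connected component is used; embedding
   disconnected components superimposes them arbitrarily. Ties in
   component size are broken toward the component containing the
   lexicographically smallest identifier.
2. **Split.** A spanning tree of the component is the training
   sub-network `TrnE` (Prim's algorithm; all edges have weight 1, so the
   tree is non-unique and a seeded random tie-break selects among valid
   trees). The held-out edges `TstE = E − TrnE` are the test set; every
   unordered non-tree pair (`CdtE = C(n,2) − (n−1)` of them) is a
   prediction candidate.
3. **Evolutionary distance.** With `SP(i,j)` the tree shortest path,
   `deg(i)` the tree degree and `Δ` the maximum tree degree, each
   non-adjacent pair is collapsed to distance 1 by one Bernoulli draw with
   probability

   * DANEOsf (duplication + scale-free neofunctionalization):
     `α` for `SP ∈ {2, 3}`, `(deg(i)·deg(j)/Δ²)^SP` for `SP > 3`;
   * LPA (linear preferential attachment): `½·deg(i)·deg(j)/Δ²`;
   * RM (random mutation): `β`;

   and adjacent pairs stay at 1 with certainty. All probabilities are
   evaluated against the *static* tree — degrees, `Δ` and `SP` are frozen
   before sampling — and each unordered pair gets exactly one draw,
   mirrored symmetrically. Since `deg ≤ Δ`, every probability is in
   [0, 1]. Defaults `α = 0.3`, `β = 0.15` are the operating points the
   method was developed at; no grid search is performed here.
4. **Distance realization.** Default mode `evolved_graph` adds the
   sampled edges to the tree and recomputes all-pairs shortest paths, so
   an added edge also shortens third-party paths; this implements
   "distances in the evolved network". The alternative `literal` mode
   uses the branch values verbatim (sampled pair → 1, otherwise the tree
   `SP`). Both are exposed because the definition can be read either way;
   `evolved_graph` is the default since the evolved *network*, not the
   matrix, is what gets embedded conceptually.
5. **Embedding.** Classical MDS: `A = −½·J·D²·J`, `J = I − n⁻¹11′`, top-m
   eigenpairs by algebraic value, `X = E_m Λ_m^{1/2}`. Graph distances are
   usually non-Euclidean, so negative retained eigenvalues are clamped to
   zero (their column becomes zero) — standard Torgerson practice that
   keeps `X` real. A non-centered SVD backend (`X = U_m Σ_m^{1/2}` of `D`
   itself) is provided as the minimum-curvilinearity-style variant.
   Column signs are fixed (largest-magnitude entry positive) so the
   embedding is deterministic. Default `m = 5`, the dimension at which
   cross-validated accuracy plateaus before declining.
6. **Scoring.** Two k-component 1-D Gaussian mixtures are fitted by EM:
   `p(dist|edge)` on the Euclidean distances of training-tree edges and
   `p(dist|nonedge)` on a seeded uniform sample (default 100,000, or all
   if fewer) of pairs outside the evolved training network. Training
   edges only — never test edges — feed the edge density, preserving
   cross-validation hygiene. The confidence score is the normalized
   posterior `S = p(d|e)p(e) / (p(d|e)p(e) + p(d|ne)p(ne))`; the shared
   `p(dist)` evidence cancels and is never computed. `p(edge)` defaults
   to the training-graph density `2(n−1)/(n(n−1))`. Default `k = 3`
   (distance histograms show at most three modes). A hard distance
   threshold ε predictor is provided for completeness, but ranking by `S`
   is the supported path.
7. **Evaluation.** Candidates ranked by `S`; ROC area computed with
   rank-averaged ties (equals the Mann–Whitney statistic), PR area with
   step-wise interpolation (linear PR interpolation is biased under the
   extreme skew of candidate sets, where positives are ≲ 0.1 %).
   Cross-validation mode scores non-tree pairs against `TstE`;
   whole-network-recovery mode scores all pairs against all of `E`.
   Repeated experiments redraw the tree (seed + repeat index) and every
   model within a repeat reuses the same tree, verified by logged tree
   hashes, so paired t-tests on the AUC vectors are genuinely paired.

## Numerical choices

* **EM**: means initialized at evenly spread sample quantiles with pooled
  ML variance (a tiny seeded jitter separates coincident quantiles);
  1/N-weighted variances with a floor of 1e-6 against collapse; stop at
  log-likelihood improvement < 1e-8 or 500 iterations. The M step runs on
  sufficient statistics, so 500 iterations at N = 1e5 cost ~2 s.
* **Confidence underflow**: if both class densities underflow to zero in
  double precision the score is the uninformative 0.5 (the posterior is
  0/0 there).
* **Degenerate t-tests**: identically zero differences give p = 1;
  zero-variance nonzero differences give p = 0.
* **MST tie-breaks**: a seeded random priority per frontier edge inside
  Prim's heap; any spanning tree is a valid minimum under unit weights.
* **Dense eigh/SVD** throughout: component sizes targeted here (≤ a few
  thousand nodes) are comfortably dense-solver territory.

## Synthetic study conditions

Real curated PPI releases sit behind registration-gated downloads, so the
package ships generators for the two structures the method assumes:

* **Geometric random graphs** — n points uniform in the unit hypercube,
  edge iff within radius r. Defaults n = 500, 3 latent dimensions,
  r = 0.1665; the radius is fixed so the *realized* mean degree is ≈ 8
  (the interior-point formula `n·V_ball(r)` ignores boundary effects and
  under-shoots by ~15 %). Mean degree 8 keeps the graph connected with
  realistic sparsity at this size.
* **Duplication–divergence growth** — from a triangle seed, duplicate a
  uniform node, retain each parent edge w.p. 0.4, add the parent link
  w.p. 0.3, and w.p. 0.1 add one degree-proportional
  neofunctionalization edge; isolated duplicates are discarded. The
  retention/linking rates are in the range of published
  duplication–divergence fits; the generator is a forward analogue of the
  mechanism the evolutionary distance reasons about backwards.
* **Toy fixture** — a 6-node network (5-node component + isolated node)
  whose path-tree exhibits every model band (SP = 2 duplication band,
  SP = 4 neofunctionalization band) with hand-computed shortest paths and
  collapse probabilities. It is an analogue of a worked example, not a
  replica of any published figure.

What the generators do *not* emulate: experimental false
positives/negatives, study bias toward well-characterised proteins,
hub-spoke artifacts of bait-prey assays, and the sheer size of curated
interactomes (10⁷–10⁸ candidate pairs). Passing the synthetic suite
therefore demonstrates correctness of the machinery and the *direction*
of the model ordering (DANEOsf > shortest-path baseline > LPA > RM on
geometric networks, with RM near chance), not absolute accuracy on any
real interactome.

The repeated-run study condition is 10 repeats with paired trees at
n = 500; AUC standard deviations across tree draws are ~0.02, so 10
paired repeats resolve the DANEOsf-vs-baseline gap (~0.03) at p < 0.05.

## Known limitations

* Identifier namespaces are taken verbatim; no cross-database mapping.
* The evolved network is sampled once per fit; averaging multiple
  evolutionary draws per tree is not implemented.
* `α`, `β` are fixed inputs; the package does not fit them.
* Whole-network-recovery AUC rewards memorising training edges and is
  reported only for comparison with cross-validation numbers.
* Non-edge density estimation uses uniform pair sampling; for small
  components it silently switches to full enumeration of non-edges.
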