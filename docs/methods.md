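# Methods

This note documents the models, numerical choices and limitations behind
`ccinet`, in the order the pipeline runs them.

## Data model

A multilayer CCI network is a stack of binary bipartite incidence matrices
(chaperones × clients), one per environment, over *shared, identically
ordered* node sets. Node order is fixed lexicographically at load time so
spectral statistics and EM initialisation are reproducible across
platforms; layer order comes from the manifest, never from file-system
order. On disk each layer is a TSV edge list (sparse, diffable); matrices
are an in-memory representation only.

## Coexpression network construction

Edges are called per layer from Spearman rank correlation between every
chaperone and every client. Choices:

* **Correction family.** Bonferroni over all chaperone × client tests in
  one layer (m = 15 × 1142 = 17,130 at study scale). Networks are built
  per environment, so the layer is the natural family.
* **Sign rule.** Two-sided p-values with a positivity filter: an edge
  requires rho > 0 *and* corrected p < α. This is conservative and matches
  the "significant and positive" consensus rule.
* **Ties.** Midranks (standard Spearman); FPKM-like data tie at zero.
* **p-values.** The t-distribution approximation
  t = ρ·√((n−2)/(1−ρ²)), vectorised over the whole pair grid; this is the
  same large-sample form `scipy.stats.spearmanr` uses (cross-checked in the
  tests against scipy, including tied data). Constant-expression genes have
  undefined ρ and are never significant.
* **Bootstrap consensus.** Subsample `n_subsample` samples *without*
  replacement (default 288 — the smallest cohort, so statistical power is
  matched across layers by construction), repeat `n_boot = 1000` times,
  keep pairs called in ≥ 95% of attempts; exactly 95% qualifies. Per-layer
  RNG substreams spawn from one master seed, so layers can be rebuilt
  independently.

## Niche statistics

P_c is the size of the union of a chaperone's client sets across layers;
S_c, S_c^α, R_c^α follow from the definitions in the README. Conventions:

* Jaccard similarity of two *empty* sets is undefined (excluded from
  medians), not 0 or 1 — either constant would bias sparse chaperones'
  fidelity medians.
* Medians use the midpoint convention for even counts.
* The S denominator is the network's client-set size, never a hard-coded
  constant.
* Chaperones with P_c = 0 are flagged and their ratio fields are NaN.

## Weighted nestedness

ρ(B) is the largest singular value of the non-negative matrix B, equal to
the largest eigenvalue of the symmetric embedding [[0, B], [Bᵀ, 0]]. This
definition is invariant to row/column permutation and monotone in every
entry (Perron–Frobenius), both verified numerically in the tests.

The null model shuffles the *underlying CCI layers* (curveball per layer),
then rebuilds the statistic matrix — for the realized-niche matrix this
recomputes P_c per replicate. The p-value uses strict inequality; ties
count toward non-significance. A `recompute` of P_c is the default because
the shuffle is defined at the network level; holding P_c fixed would mix
observed and null quantities.

**Degenerate nulls.** Curveball conserves row sums, so any statistic
matrix that depends only on per-layer row sums — the S_c^α matrix in
particular — is *invariant* under this null: every null sample ties the
observed value and the literal p-value is 0 without carrying evidence. The
pipeline flags this (`degenerate_null` column) rather than reporting such
a p as significant. Only the realized-niche statistic, which varies
through P_c, is informative under this null.

## Curveball randomisation

Each trade picks two distinct rows, pools the columns unique to each, and
redeals the pool at random with row counts preserved; margins are
conserved exactly after every trade. Default trade count is 5 × n_rows —
a mixing heuristic that is cheap at 15 rows; the tests verify empirical
uniformity over the exhaustively enumerated fixed-margin class of a 3×3
matrix. z-scores use the sample (n−1) SD. Layers are shuffled
independently (no cross-layer coupling).

## Multilayer mixed-membership SBM

The adjacency is treated as Poisson counts with mean
M_ij^(α) = Σ_kl u_ik v_jl w_kl^(α); directing links from chaperones to
clients realises the bipartite constraint (within-set rates are
structurally zero). The log-likelihood (constants dropped) is
Σ [A log M − M] over observed cells.

* **Updates.** Multiplicative EM block updates of u, v, w (the KL/Poisson
  NMF fixed-point form), each block recomputing M first, so the likelihood
  never decreases — asserted per iteration in the tests to 1e−10.
* **Masking.** An optional boolean cell mask restricts the likelihood to
  visible cells; the numerators and denominators of each update sum over
  visible cells only. Held-out cells therefore cannot influence the fit
  (a leakage test flips them and checks the fitted parameters are
  bit-identical), and their fitted M is the prediction score.
* **Initialisation.** u, v, w ~ Uniform(0.1, 1); 10 restarts by default,
  best likelihood kept. Convergence when the log-likelihood improves by
  less than 1e−6 (absolute) between checks every 10 iterations, capped at
  500 iterations; hitting the cap returns the model with a warning rather
  than failing, since the remaining drift is far below the scale that
  moves BIC or assignments.
* **Model selection.** BIC = −2 logL + p log n with
  p = K(n_chap + n_cli) + K²L free parameters and n the number of observed
  adjacency cells. The mixed-membership normalisation could be argued to
  remove one parameter per node; with n in the tens of thousands this
  shifts every K's score by a near-identical constant and never changes
  the argmin, so the simpler count is used.
* **Hard assignment.** Argmax of the membership vector; ties break to the
  lowest group index; all-zero rows are labelled unassigned (−1).
* **Recovery metric.** Pairwise co-assignment agreement, which is
  invariant to label permutation.

## Link prediction

The hold-out unit is the adjacency *cell*, not only the present edges: the
likelihood ranges over all cells, and AUC needs negatives. "5-fold with an
80% hold-out" is inverted cross-validation — fit on one fold, score on the
other four — the only reading consistent with both phrases. K is fixed at
2 (the BIC-selected group count). Cross-layer prediction fits exactly two
layers: the focal layer's visible cells plus the complete auxiliary.
Per-fold fits use looser EM settings (2 restarts, 150 iterations,
tolerance 1e−3) than model selection: prediction depends on score
*rankings*, which stabilise long before the likelihood converges. AUC uses
midranks (ties count half).

Note a structural fact verified during development: with balanced planted
blocks and only 20% of a single layer visible, client memberships are
essentially unidentifiable and within-layer AUC sits at chance — the
information that lifts real-data within-layer AUC above 0.5 (degree
heterogeneity, identifiable block structure) must be present in the layer.
The cross-layer gain, by contrast, is robust whenever layers share
structure, and that ordering (cross > within) is what the tests assert.

## Robustness

Removal orders use *static* initial degrees (ties by identifier) — simple
and reproducible; scenario 4 is a uniform permutation, averaged over 100
seeded replicates with SD reported. "Module 1/2" are the SBM hard groups
ordered by descending size (ties by lowest member identifier). The
survival denominator is the layer's initially-connected client count, so T
measures the collapse of what was there to lose. T integrates the curve
trapezoidally on the k/N grid including both endpoints; the complete
bipartite closed form is (2N−1)/(2N). No rewiring after removal is
simulated, and clients are unweighted — both known limitations of this
style of in-silico analysis.

## Synthetic generators

* **Networks.** Memberships from a symmetric Dirichlet (concentration
  0.05 → near-hard groups, with occasional genuinely mixed nodes, as
  mixed-membership models intend); affinities put the within-group rate
  `affinity_contrast` (default 10) times the between-group rate, scaled so
  the mean edge probability is `mean_density` (default 0.2, the scale of
  per-layer CCI density implied by realistic specialization values).
  Edges are Bernoulli(min(1, M)) — incidence is binary, and clipping is
  counted and logged. Sharing w across layers plants high cross-layer
  fidelity; per-layer lognormal perturbation (or resampling) lowers it.
* **Expression.** Each chaperone gets a latent standard-normal per-sample
  signal z; its observed value is exp(z) (monotone, so rank correlations
  are preserved; exp gives FPKM-like positive skew). Linked clients are
  a·z̄ + σ·ε with a calibrated via the bivariate-normal identity
  ρ_s = (6/π)·asin(r/2) so singly-linked pairs hit the target Spearman
  correlation; clients linked to several chaperones use the (normalised)
  summed signal, a documented behaviour. There is no attempt to mimic real
  FPKM marginals, tumor purity or batch effects — recovery results on this
  generator demonstrate the statistical machinery, not robustness to those
  artefacts.
* **Nested patterns.** `generate_nested_matrix` builds a perfectly nested
  weight staircase. `generate_nested_multilayer` plants that gradient in
  the realized-niche matrix by giving each chaperone a fixed client pool
  and realising layer-specific random subsets of it. The realised subsets
  are drawn independently per layer on purpose: a layer whose rows are
  nested prefixes is the *unique* member of its fixed-margin class and
  curveball cannot move it, which would make the significance test
  vacuous.

## Pipeline and reproducibility

Every stochastic stage derives its seed from the master seed and the stage
name (CRC-mixed through a `SeedSequence`), so adding or skipping a stage
never perturbs the others, and one master seed determines the entire
bundle byte for byte (asserted in the tests). Problem sizes used by the
test-suite and the acceptance script — e.g. 15×1000×12 for model
selection, 15×400×8 for the nestedness test, hundreds of clients for
prediction — are chosen as the smallest scales at which each property is
clearly identifiable; all are configurable upward.

## Known limitations

* The coexpression stage assumes rank-correlation is evidence of
  interaction; confounders that coexpress unlinked genes will create
  false edges (no partial correlations or covariate adjustment).
* The SBM has no degree correction; strongly heterogeneous degrees within
  one group are absorbed into mixed memberships instead.
* The curveball null is highly conservative (degree sequences fixed), and
  for statistics that are functions of the fixed margins it is degenerate
  (see above).
* Robustness ignores rewiring and client importance weights.
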