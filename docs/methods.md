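# Methods

## Model

A cohort is a binary incidence matrix *A* ∈ {0,1}^{m×n}: patients in rows,
genes in columns, A_{ij} = 1 when gene *j* carries a somatic mutation in
patient *i*.  For a gene set *M* with |M| = k, Γ(j) = {i : A_{ij} = 1} and
Γ(M) = ∪_{j∈M} Γ(j).  The covariate-weighted maximum-weight-submatrix
objective is

    W(M) = 2·|Γ(M)| − Σ_{j∈M} v_j·|Γ(j)|,

equivalently |Γ(M)| minus the weighted overlap penalty
ω(M) = Σ_j v_j|Γ(j)| − |Γ(M)|.  With all v_j = 1 it is the classic
coverage-minus-overlap score; a set of perfectly exclusive genes attains
W = |Γ(M)|.  W(M) also equals the optimum of the unary integer program
max 2Σ_i x_i − Σ_j y_j v_j|Γ(j)| over x ∈ {0,1}^m subject to
Σ_j y_j A_{ij} ≥ x_i, with y the indicator of M — covered patients take
x_i = 1 because their objective coefficient is +2.  The test suite checks
this equivalence exhaustively on small matrices.

The driving assumption is that genes of one driver pathway are mutated in
largely non-overlapping patient subsets while jointly covering most of the
cohort.  The weights v_j discount genes whose high mutation count merely
reflects a high background rate (regional mutational heterogeneity) rather
than selection.

## Covariate fusion

Three per-gene covariates track background mutation rate: expression
level, replication time, and chromosome (chromatin) status.  They are
strongly mutually correlated, so a single factor captures most of their
variance.  Each column is z-scored (population 1/n variance; constant
columns map to zeros), the 3×3 covariance — correlation — matrix is
formed, and the leading unit eigenvector a = [a1, a2, a3] gives the raw
fused score υ = a1x′ + a2y′ + a3z′.

Two numerical conventions make the output backend-independent: the
eigenvector sign is fixed so its component sum is positive (first nonzero
component positive when the sum vanishes), and a degenerate leading
eigenspace returns the normalized projection of the first standard basis
vector with nonzero projection (so the identity matrix yields (1,0,0)).

Raw first-component scores are centred around zero, but W(M) needs
strictly positive weights — a negative v_j would turn the exclusivity
penalty into a bonus.  The scores are therefore affinely rescaled to
[0.5, 1.5] (configurable bounds): midpoint 1 is the neutral weight, so the
weighted objective stays on the same scale as the unweighted one, and the
most/least mutable genes are discounted/boosted by at most 50%.  A
degenerate table whose raw scores are constant yields all-ones weights.
Matrix genes missing from the covariate table also get weight 1.0 (with a
warning); synthetic cohorts use neutral weights throughout, since their
genes carry no covariate meaning.

## MBF search

The search space is {y ∈ {0,1}^n : Σ y_j = k}.  Each of nFish = 50
cichlids holds a continuous position in [0,1]^n decoded to a gene set by
taking the k largest coordinates (ties to the lowest index), so every
candidate satisfies the cardinality constraint by construction.  Per
iteration:

1. **attraction** — every fish except the current population best moves
   toward the incumbent best position by SP·u∘(best − self), u uniform per
   coordinate; SP starts at 0.6 and is damped by SPdamp = 0.95 per
   iteration;
2. **dispersal** — with probability Pdis = 0.2 a fish has ⌈Dis⌉ = 2
   random coordinates perturbed by uniform noise of half-width
   Dis/n_span; positions are clamped to [0,1].

The five named parameters (SP, nFish, Dis, Pdis, SPdamp) use the
behaviourally derived values above.  The scale divisor n_span converts the
dispersal distance into coordinate units; its default 2.0 gives half-width
0.9, chosen so that a single dispersal event can move any coordinate past
the top-k threshold anywhere in the unit interval — with substantially
smaller noise the search cannot escape local optima once the population
has contracted onto the incumbent.

The continuous encoding has a blind spot: an improving *single-gene swap*
(one gene out, one in) requires two coordinates to cross the top-k
threshold jointly, which per-coordinate dispersal almost never proposes.
Each run's incumbent is therefore finished with a deterministic
steepest-ascent swap hill climb (all k·(n−k) swaps evaluated per pass,
best improving swap taken, ties to the lowest index pair) until locally
optimal.  The incumbent never worsens; every step and the polish are
deterministic given the seed.

A run stops at max_iter = 200 iterations or after 50 iterations without
incumbent improvement; three independent restarts (seeded as
(seed, restart)) are pooled.  Final populations of all restarts are
deduplicated and ranked by fitness (ties lexicographic by gene indices) —
the candidate list the significance fallback walks; the reported optimum
is the head of that ranking, making the two views consistent by
construction.  `exhaustive_search` enumerates all C(n,k) subsets (guarded
at 10^6) as the validation oracle, and `multi_k_scan` runs independent
optimizations per k with seed offset k, reporting per-k pathways and their
union as the aggregate driver-gene set.

Measured behaviour (recomputed by `scripts/acceptance.py` and the test
suite): the search attains the exhaustive optimum on 50/50 random
instances (m=50, n=15, Bernoulli 0.1, k=3) and exactly recovers a planted
k=4 pathway (m=200, n=100, coverage 0.8, co-mutation 0.05, background
0.02) in 20/20 replicates under default parameters.

## Permutation test

Null model: each gene column is permuted independently across patients
(`numpy` Generator.permuted along axis 0).  This preserves every gene's
marginal mutation frequency — exactly the quantity the covariates model —
while destroying between-gene coverage/exclusivity structure, which is the
property under test.  The null statistic is the *re-optimized* maximum
weight on each permuted matrix, so the observed statistic (itself a
maximum over sets) is compared against its proper selection-aware null; a
`fixed-set` variant that merely re-scores the observed genes is available
but anti-conservative.  Null re-optimizations use a single restart at
budget_factor × max_iter iterations (default 0.5): with the swap polish
the reduced budget still reaches the null optimum in practice, and the
observed-side search keeps its full budget, which only makes the test
conservative, never liberal.

p = (1 + #{null ≥ observed}) / (B + 1) with B = 100 permutations by
default — never exactly zero, minimum 1/(B+1) ≈ 0.0099, resolving
α = 0.05.  When the top-ranked candidate is not significant, candidates
are tested in decreasing fitness order and the first with p ≤ α is
reported (none, with all p-values logged, if the list is exhausted).

**Calibration note.**  The test is exactly valid: conditional on column
sums, the observed matrix and column-permuted matrices are exchangeable,
so P(p ≤ α) ≤ α.  It is however markedly conservative on null Bernoulli
matrices with neutral weights: the objective is then integer-valued and
the conditional distribution of the maximum concentrates on a handful of
integers, so ties between observed and null optima are common and the
plus-one, tie-inclusive estimator rarely reaches small p-values.  Measured
type-I error at α = 0.05 on null cohorts (m=100, n=50, rate 0.05, k=3, 50
permutations) is ≈ 0.008 (3/400 datasets) — well below nominal.  Users
should read a non-significant result on weak signals accordingly; on
planted-signal cohorts the observed weight exceeds every null optimum and
p attains its minimum.

## Synthetic data

`random_matrix` draws i.i.d. Bernoulli entries (default rate 0.05, a
typical per-gene mutation frequency for exome cohorts).  `planted_matrix`
embeds a k-gene pathway: each patient is covered with probability
`coverage` (default 0.8); a covered patient receives exactly one planted
mutation (uniform over the set) with probability 1 − `co_mutation_rate`
(default 0.05) and two distinct ones otherwise; passenger columns are
Bernoulli(`background_rate`, default 0.02).  Planted columns are filled
solely by the planting process, so the planted set's coverage is exactly
Binomial(m, coverage)/m and at most two planted mutations occur per
patient — the minimal departure from perfect exclusivity parameterized by
one number.  `correlated_covariates` draws three columns from a shared
standard-normal latent factor (col = √ρ·latent + √(1−ρ)·noise), giving
pairwise correlation ρ and, at high ρ, fusion loadings ≈ (1,1,1)/√3.

Default sizes are desk-scale (m = 200, n = 100) so full pipelines run in
seconds; the generators accept cohort sizes up to the tens of thousands of
genes.  What the generators do **not** emulate: mutation-spectrum
structure (e.g. C→A vs C→T), patient-level rate heterogeneity, copy-number
segments, and correlation between covariates and the *realized* per-gene
rates (covariates and matrix are generated independently, so synthetic
runs exercise the fusion arithmetic, not its biological rationale).
Passing tests on synthetic data therefore demonstrate algorithmic
correctness — scoring, optimization, calibration — not biological validity
on real cohorts.

## Numerical and degenerate-input conventions

* All tie-breaks (top-k decode, exhaustive argmax, swap polish, candidate
  ranking) are lexicographic by gene index, for bit-reproducibility.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived streams use seed sequences
  (seed, restart) and (seed, permutation index).
* Empty gene selections score 0 coverage/weight/mutex; a gene with empty
  support never changes any score.
* Symmetry of the covariance matrix is enforced within 1e-9; loadings are
  unit-norm within 1e-9.
* The exhaustive oracle refuses instances beyond 10^6 subsets rather than
  running unbounded.

## Known limitations

* Weighted objectives are reported on the raw W(M) scale; no normalized
  per-cohort scale is attempted.
* The significance fallback tests candidates sequentially without
  multiple-testing correction across the k-range — each pathway is
  assessed at α individually.
* The permutation test's conservativeness on weak/null signals (above)
  means its power near the significance boundary is limited at B = 100.
* Single-threaded; cohorts with n in the tens of thousands are supported
  but multi-k scans there take minutes per k.
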