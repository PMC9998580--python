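# Methods

This note documents the models and procedures implemented in `gsopt`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer should know.

## Setting and notation

A *candidate set* of n genotyped individuals is available; a *training set*
(TRS) of fixed size is chosen from it, phenotyped, and used to fit a genomic
prediction model whose accuracy is evaluated on a *test set* disjoint from
the candidates. The *remaining set* is candidate − training. In *targeted*
optimization the test-set genotypes are available while choosing the TRS;
in *untargeted* optimization they are not, and a placeholder target
population (TP) must stand in. A is the genomic relationship matrix, X the
centered marker matrix, h² the trait heritability.

## Genomic relationship matrix

VanRaden method 1: `A = W W' / (2 Σ_j p_j (1 − p_j))` with
`W = dosages − 2p` (column-wise allele-frequency centering). Under
Hardy–Weinberg equilibrium the expected diagonal is 1; population structure
inflates it. Missing dosages are imputed to column means before anything
else, and monomorphic (zero-variance) columns are dropped on input. A ridge
of 1e-6 (configurable) is added to any relationship matrix's diagonal
before inversion; singularities beyond that raise rather than being
regularized silently.

## Selection criteria

**CDmean.** For each target individual i, the coefficient of determination
of its genetic value given phenotypes on the TRS in the GBLUP model,

    CD_i = [A − λ (Z'MZ + λ A⁻¹)⁻¹]_ii / A_ii,

averaged over the TP. Z is the incidence of the training rows, M is the
projector orthogonal to the intercept on the training set (intercept-only
fixed effects, matching the prediction models), and λ = σe²/σg² is the
shrinkage, default 1. A is restricted to training ∪ target for each
evaluation. CD_i ∈ [0, 1) and CDmean is non-decreasing under training-set
supersets at fixed target.

**CDMEAN2.** The same quantity in a rank-k spectral basis: with the ridged
A = Q Q' + (discarded components), Q = V_k Λ_k^{1/2},

    CD_i = (q_i'q_i − λ q_i'(Q_t'M Q_t + λ I_k)⁻¹ q_i) / q_i'q_i.

This is an algebraic identity at k = n (equal to CDmean to machine
precision) and reduces the per-evaluation cost from O(n³) to O(t k²),
which makes the preselection of large candidate sets practical. Inside a
search the basis is computed once over candidate ∪ test and reused; note
that rank-truncated values from *different* bases (different training ∪
target unions) are not mutually comparable — the search evaluator always
uses one fixed basis.

**Rscore.** The expected Pearson correlation between ridge-regression GEBVs
of the TP and the TP phenotypes under the working prior β ~ N(0, I),
e ~ N(0, λI). With G the Gram matrix of the centered markers and
H = G_vt (G_tt + λI)⁻¹ the training-to-target predictor,

    Rscore = tr(P G_vt H') / sqrt( tr(P H (G_tt + λI) H') · tr(P (G_vv + λI)) ),

with P the centering projector on the TP. It depends on the markers only
through G, so substituting the full set of n principal components changes
nothing (the standard acceleration). The unit prior variance and λ = 1
mirror the CDmean shrinkage choice; both are configurable. A Monte-Carlo
oracle (simulating traits from the same prior and averaging realized
correlations) confirms the ranking behaviour in the test suite.

**gAvg_GRM family.** `a · mean(A_TRS,TP) − b · mean(A_TRS,TRS)`; the
within-TRS mean includes the diagonal (the plain mean of the submatrix —
the alternative convention would only shift the criterion by a size-dependent
constant at fixed subset size). Variants: Avg_GRM (1, 0), Avg_GRM_self
(0, 1), Avg_GRM_MinMax (1, 1). Avg_GRM_self ignores the TP entirely, so it
has no targeted form.

**Target-population rules.** Targeted: TP = test set for every criterion.
Untargeted placeholders: remaining set for CDmean/CDMEAN2 and
Avg_GRM_MinMax (using the candidate set would let the TRS reward relation
to itself and dilute the within-TRS penalty), candidate set for Rscore and
Avg_GRM, none for Avg_GRM_self.

## Clustering-based selectors

Stratified sampling: Ward's minimum-variance hierarchical clustering
(ward.D2 on Euclidean dosage distances) cut at a user-chosen k, then
uniform sampling without replacement inside clusters with per-cluster
quotas by largest-remainder apportionment (quotas deviate from exact
proportionality by < 1; remainder ties are broken by the seeded generator).
The number of clusters is deliberately user-supplied — choosing k from
dendrogram inspection and prior knowledge cannot be automated faithfully —
and defaults to the generator's true K in the synthetic fixtures.

PAM: k-medoids on Euclidean dosage distances with k = training-set size,
greedy BUILD followed by steepest-descent single swaps until no
medoid/non-medoid exchange lowers the total dissimilarity. The medoids are
the training set. On instances small enough to enumerate, the swap-optimal
solution matches the exact optimum in the test suite.

## Subset search

A genetic algorithm over fixed-size subsets — tournament selection (size
3), a size-preserving uniform exchange crossover (children keep the
parents' intersection and fill the quota from the symmetric difference),
one-swap mutation at rate 0.2, 10% elitism — interleaved with a simulated
annealing chain on the incumbent: after each generation, 10 Metropolis swap
moves with geometric cooling, the chain state re-injected into the
population. Defaults: 200 generations × population 100, 2000 SA steps
total. The initial temperature is the standard deviation of the criterion
over 50 random subsets — scale-free across criteria whose magnitudes differ
by orders — cooling to 1% of it by the final step. All evaluations are
memoized; the best subset ever evaluated is returned, so the best-so-far
trace is monotone. Runs are bit-reproducible from (inputs, config, seed).

Clustered orchestrations: *within* mode apportions the size over clusters
and runs an independent search inside each (targeted variants assign each
test individual to its nearest cluster centroid in dosage space to define
per-cluster targets — a documented choice, configurable by supplying
per-cluster evaluators); *overall* mode runs one global search whose moves
only exchange individuals within a cluster, holding the apportioned
per-cluster counts fixed.

## Prediction models

**GBLUP**: y = 1μ + g + e with g ~ N(0, σg²A). Variance components by
restricted maximum likelihood, profiled over δ = σe²/σg² via the spectral
decomposition of the (ridged) training kinship — exact for a single random
effect; δ is located on a 40-point log grid refined by bounded scalar
minimization on [1e-6, 1e6]. GEBVs by BLUP:
ĝ = A_pt (A_tt + δI)⁻¹ (y − 1μ̂). GEBVs are invariant to phenotype shifts
(the intercept absorbs them).

**RKHS**: K_ij = exp(−d_ij²/h) on column-standardized dosages, h = median
off-diagonal squared distance by default, then exactly the GBLUP machinery
with K for A (one code path; K = A reproduces GBLUP bitwise).

**BayesB**: marker effects are zero with probability 1 − π (default
π = 0.05) and otherwise normal with per-locus scaled-inverse-χ² variances
(df = 5), i.e. a scaled-t slab; Gibbs sampling over inclusion indicators,
effects, per-locus variances, the intercept and σe² (default 6000
iterations, 1000 burn-in). The slab scale is matched so the prior genetic
variance is half the phenotypic variance. GEBVs are posterior-mean effects
times centered dosages. In the joint limit π → 1, df → ∞ the model is
RR-BLUP and its GEBVs track GBLUP (asserted in tests); at finite df the
per-locus variances leave differential shrinkage, so that correlation is
not expected to be 1.

Accuracy is the Pearson correlation between test-set GEBVs and the
genotypic values; in synthetic runs the targets are the *true* simulated
genetic values (the real-data analogue — BLUP genotypic values — has no
synthetic counterpart).

## Cross-validation benchmark

Per replicate: an 85/15 candidate/test split (test size = round-half-up of
0.15 n; reproducible from (seed, replicate index) alone, so replicates are
order-independent and parallelizable), optional CDMEAN2 preselection to
1000 genotypes when the candidate set exceeds that cap, then every method ×
size × model cell. Sizes default to {10, 20, 40, 60, 80, 100}% of the
candidate set; the 100% size takes the whole candidate set and involves no
optimization, so all methods coincide there. Default 40 replicates, with a
fresh simulated trait per replicate where traits are simulated. Cell
failures are recorded and skipped, never fatal.

AUC is the trapezoid sum over the sizes below 100% (nTRS = 5 at the
defaults; constant accuracy c gives 70c in %-size units). The gain of a
method is 100 · (mean AUC − mean random AUC) / mean random AUC on
replicate-mean AUCs; the SEM is the standard error of the per-replicate AUC
difference and a difference is flagged when |mean| > 2 SEM — an informal
screening rule, not a formal test. Trade-off coordinates per method: mean
training–test relationship and negated mean within-training relationship,
z-scored across methods and min-max rescaled to [0, 1].

## Training-set size optimization

The evaluation metric of the training sets selected at each size is fitted
against size s (%) with `metric(s) = ln(s − d) / (m (s − d)^p) + n`,
by nonlinear least squares from a deterministic multi-start grid
(d ∈ {0, 0.5 s_min, 0.9 s_min} × p ∈ {0.3, 0.7, 1.5}, with 1/m and n solved
by ordinary least squares at each start since the model is linear in them),
refined with bounded trust-region least squares (d < s_min); the best
residual wins. Fits use replicate-mean metric values by default. The fitted
p classifies the regime: slowing growth (p < 0.5), plateau (0.5 < p < 1),
or an interior maximum (p > 1); boundary values map to the lower regime
with a warning. Only the maximum regime admits an argmax,
s* = d + e^(1/p) (the exact stationary point; clipped at 100). Otherwise
the smallest size whose fitted metric reaches a target fraction (0.95 or
0.99 recommended; > 0.95 advised for Avg_GRM_self, whose size estimates
have high variance) of the fitted value at s = 100 is selected on a
0.01-resolution grid — a grid scan rather than bisection because the fitted
family need not be monotone. Selected sizes are validated by
piecewise-linear interpolation of the cross-validation accuracies,
expressed as a percentage of the accuracy at the 100% size.

Recommended defaults encode the benchmark's conclusions: targeted →
Avg_GRM_MinMax with argmax; untargeted → Avg_GRM_self with a target
fraction above 0.95.

**Identifiability caveat.** With six observed sizes and four parameters,
(d, m, p, n) are weakly identified: small noise (σ ≈ 0.001) can move the
global least-squares fit to a different parameter basin — even flipping the
regime — while the fitted *curve values* stay within the noise scale. Tests
therefore pin down exact parameter recovery only on noiseless data, and
assess noisy fits by curve values. Users should treat the regime label on
noisy curves with caution and prefer the target-fraction rule when the
metric curve is flat.

## Synthetic data generator

Populations follow the Balding–Nichols model: ancestral allele frequencies
uniform on [0.05, 0.5], per-subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), dosages Binomial(2, p_sub), genotypes split
evenly over K subpopulations. F ∈ {0.05, 0.15, 0.45} spans the
weak/intermediate/strong structure range observed in real diversity panels
(leading-2-PC variance from < 5% to ≈ 50%). Defaults n = 300, m = 2000,
K = 3, F = 0.15. Monomorphic draws are discarded so the panel holds exactly
m polymorphic markers.

Traits: effects β ~ N(0, 1) on the effect loci (default: all markers),
g = X_c β, residual variance scaled from the *realized* var(g) as
σe² = var(g)(1 − h²)/h², so the mean realized heritability var(g)/var(y)
matches the target in expectation (recovered to ±0.02 over 200 traits in
the acceptance run); h² = 1 returns y = g exactly.

What the generator does **not** emulate: linkage disequilibrium along a
genome (markers are exchangeable given the frequency hierarchy), pedigree
or family structure within subpopulations, dominance/epistasis,
genotype-by-environment interaction, and real genotyping artifacts
(call-rate patterns, allele-frequency spectra). Consequently, passing tests
demonstrate the correctness and the qualitative behaviour of the machinery
(targeted beats untargeted; Avg_GRM's poor diversity; accuracy growth with
training size), not quantitative transferability of any specific gain
figure to a real breeding panel.

## Problem sizes and numerical defaults

The shipped test and acceptance runs use desk-scale problem sizes chosen as
the smallest at which each property is stable: the directional benchmark
runs n = 300, K = 3, h² = 0.3 with 40 replicates at the 20% size under a
reduced search budget (60 generations × population 40 × 5 SA steps, ~1600
evaluations per cell); preselection is exercised at 1200 → 1000 with a
capped budget; search-vs-enumeration equivalence is checked at C(10, 4).
All tolerances (GRM ridge 1e-6, symmetry 1e-10, full-rank identities 1e-6
to 1e-8) are stated at the assertion sites. Ties are broken
deterministically throughout: lexicographic id order in enumeration, seeded
permutations in apportionment and sampling.
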