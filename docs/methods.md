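# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic cohorts do and do not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Profile preparation

Samples with fewer than 500 reads are removed first; taxa present in fewer
than 25% of the remaining samples are removed second. The order matters only
at the margin, but it is fixed and documented (samples, then prevalence).

Relative profiling (RMP) rarefies each sample to a fixed target (default
10,000 reads) by multivariate-hypergeometric subsampling — drawing reads
without replacement from the observed pool — and excludes samples below the
target rather than padding them. Quantitative profiling (QMP) divides counts
by 16S rRNA copy number, defines a sample's sampling depth as corrected depth
over flow-cytometry microbial load (cells/g), rarefies every sample to the
cohort-minimum sampling depth (targets floored to integers; corrected counts
floored before subsampling), excludes samples whose rarefied total falls
below 150, and rescales retained counts to cells per gram. Multiplying all
loads by a constant therefore rescales the output by that constant without
changing which reads survive.

Alpha diversity is the Shannon index on relative abundances (natural log)
with a two-sided Mann–Whitney test between outcome groups. Neither choice is
forced by the data; both are standard, overridable, and echoed in the output
so results are self-describing. Family-level descriptive statistics use read
fractions per cohort × timepoint with a >10% dominance flag; paired
timepoint comparisons use a paired t-test per family with Bonferroni over
the families actually tested (restricted to dominant families when so
configured).

## Population network: ZINB-copula graphical model

Each taxon's marginal is a zero-inflated negative binomial fitted by maximum
likelihood (L-BFGS-B on β, log θ, logit π) with a log link and a per-sample
size-factor offset; taxa whose ZINB fit fails fall back to a plain NB with a
warning. Covariates (age, gender, disease duration, disease location —
continuous ones scaled to their ranges, location dummy-coded) enter the
marginal regression, so the latent scores are covariate-adjusted at the
source rather than residualised post hoc.

Size factors are GMPR (geometric mean of pairwise ratios of shared non-zero
taxa). Raw library size is a poor offset here: with tens of taxa the
realized library total is dominated by a few abundant taxa, and conditioning
every marginal on that shared noisy statistic induces spurious cross-taxon
correlation in the scores (~0.2 at 30 taxa in our simulations — enough to
contaminate edge selection). GMPR's pairwise-median construction suppresses
that leakage.

Observed counts are mapped to latent normal scores through the fitted
discrete CDF. The default is the deterministic mid-probability transform
v = (F(x−1) + F(x))/2, z = Φ⁻¹(v); a randomized transform
v ~ U[F(x−1), F(x)] averaged over five seeded draws is available
(`score_method="randomized"`). Both are accepted treatments of discreteness;
the deterministic variant keeps the default pipeline free of an extra seed.

The graphical lasso runs on corr(Z) along a decreasing geometric penalty
grid whose top is 1.3× the largest off-diagonal |corr| (capped at 1), so the
most-penalised model is empty even on subsamples and the instability curve
is anchored at zero; 15 grid points down to rho_max/15. StARS draws 20
subsamples of size ⌊min(0.8, 10√n/n)·n⌋, measures per-edge selection
instability 2θ(1−θ) averaged over all pairs, monotonises the curve from the
penalised end, and selects the smallest ρ with instability ≤ 0.05 (the cited
StARS defaults). Lasso tolerances are 1e-3 — ample for support and partial
correlations, and avoiding dual-gap oscillation near the sparsity phase
transition. Edge weights are the partial correlations −Ω_ij/√(Ω_iiΩ_jj) on
the selected support; the binary network is their support.

Samples sharing fewer than ten non-zero taxa with the rest of the cohort
("common" = non-zero in the sample and in at least one other) are excluded
before fitting.

Family-family connectivity sums edge weights between two families' taxa and
divides by the number of possible pairs (|A||B| across families,
|A|(|A|−1)/2 within; loops admitted, signs preserved). Network summaries
(average node strength, average eigenvector centrality) are computed on |W|.

## Individual-specific networks

The leave-one-out extrapolation e^q = N(e^α − e^(α−q)) + e^(α−q) is
estimator-agnostic; `lioness_from_contributions` accepts any callable from a
samples × features matrix to a symmetric weight matrix, and the linear
identity (a mean-of-contributions estimator returns each sample's
contribution exactly) is enforced by test.

For the copula pipeline both e^α and every e^(α−q) are computed with the
support held fixed at the population StARS selection and the weights given
by the support-constrained Gaussian MLE of the (leave-one-out) correlation
matrix — the classical covariance-selection fit by node-wise regressions,
with a closed-form fast path (inverse correlation) when the support is
saturated. Re-running the lasso per fold is available
(`copula_estimator(net, mode="glasso")`) but is *not* the default: the lasso
is discontinuous in the data, an edge flipping out of a leave-one-out
support shifts that sample's extrapolated weight by N× the edge weight, and
the per-sample networks then no longer aggregate back to the population
network. With the constrained-MLE refit the aggregation gap
|mean_q e^q − e^α| is ~0.002 at N = 100 and decreases with N.

The ISN edge universe defaults to the population support; `edge_universe=
"all"` computes all-pairs ISNs with the saturated estimator (needed when the
effect of interest is absent from the pooled support, e.g. group-specific
edges that cancel across groups).

## Differential edges

Edges with |mean(group a) − mean(group b)| at or below the difference
threshold (default 0.5, the guideline default for ISN differential analysis;
the cohort scripts state explicitly when they relax the FDR cutoff) are
discarded before testing and excluded from the multiple-testing family.
Surviving edges get a moderated two-sample t: the per-edge pooled variance
s² (df = n₁+n₂−2) is shrunk toward a prior (d₀, s₀²) estimated by matching
the mean and variance of log s² to a scaled-F law (digamma/trigamma moment
equations; the trigamma inverse by Newton iteration); s̃² = (d₀s₀² + d·s²)/
(d₀+d), t = diff / (s̃·√(1/n₁+1/n₂)) on d₀+d df. When the observed spread of
log s² is no larger than expected under a common variance, d₀ = ∞ and every
edge uses the common prior variance. BH runs across tested edges; selection
requires both p and q below their cutoffs (defaults 0.05/0.05). The group
labelled "remission" is always group a, so the sign of `diff` is stable.

Over-representation uses the hypergeometric upper tail P(X ≥ k) with BH
across annotation sets when batched.

## Response prediction

The random forest is built from scratch on sklearn decision trees because
per-tree class-balanced bootstraps (each tree draws minority-class-count
samples per class, with replacement) are part of the protocol and are
asserted by test. Feature importance is out-of-bag permutation importance,
computed with one batched predict per tree. Rankings from every fold ×
repeat of a stratified CV (defaults 5 × 10) are aggregated by mean rank
(Borda, deterministic, ties broken by feature id); a seeded stochastic
footrule refinement is available. The SVM protocol is leave-one-out: on each
training set of N−1 samples, features are ranked by absolute point-biserial
correlation with the outcome, the top n_screen (default 20) are kept,
standardised, and fed to an RBF SVM (C = 1, gamma = 'scale'); the held-out
sample's decision value is mapped through a sigmoid so scores live in [0,1]
(AUC is rank-based and unaffected). Screening strictly inside the loop
prevents leakage; AUC is the Mann–Whitney statistic with averaged ties.

## Topology metrics

All ten metrics (degree, average shortest path length, eccentricity,
closeness = 1/asp, betweenness normalised by (n−1)(n−2)/2, stress =
unnormalised shortest-path counts, clustering coefficient, neighbourhood
connectivity, radiality, topological coefficient) are computed from one
all-pairs BFS/path-count core on the unweighted, undirected support graph,
because the NetworkAnalyzer definitions of closeness, stress, radiality and
the topological coefficient differ from networkx's. Distances are taken
within a node's component; cross-component pairs are excluded, not infinite.
Undefined values (clustering for degree < 2, topological coefficient for
nodes sharing no neighbour with anyone, betweenness for n < 3, radiality in
singleton components) are recorded as missing; ISNs with fewer than four
nodes are skipped. A brute-force oracle (explicit enumeration of all
shortest paths) must agree exactly on every connected atlas graph up to six
nodes, canonical fixtures, and random 8-node graphs.

Feature matrices are sample × (node, metric) under two protocols: zero-fill
(missing cells, including nodes absent from a sample's ISN, become 0) and
drop-node (a node missing any metric anywhere is removed from the feature
space). Dense all-pairs ISNs can be binarised at a magnitude threshold
before graph construction (`weight_threshold`), since every entry of a
saturated partial-correlation matrix is technically non-zero. The screen
runs stratified k-fold CV (default 10) per metric/protocol instance with a
random forest (top-20 importance features re-selected inside each training
fold) and an RBF SVM; instances with CV AUC ≥ 0.75 are flagged.

## Multiplex dynamics

Per trajectory group, the two layers are |mean ISN| at each timepoint over a
shared node set. Each node is represented per layer by the visit-frequency
profile of seeded random walks with restart (restart 0.5, 20 walks of length
10 per node; isolated nodes stay put); the 2n profiles are jointly reduced
by PCA (default dim 5) and a node's dynamic is the cosine distance between
its two embedded points. Embedding repeats R = 50 times with fresh walk
seeds; nodes are ranked within each repeat and rank sums taken per node
(the alternative reading — ranking over repeats — is `rank_over="nodes"`).

Because walk profiles are row-normalised, cosine dynamics detect *partner*
changes, not pure magnitude changes: a degree-one node whose single edge
halves its weight has an identical profile in both layers. Demonstrations
therefore plant re-partnering, and pipelines that need shared supports
(avoiding support churn between independently estimated layers) should fit
one network per group with both timepoints pooled.

The permutation null shuffles the upper-triangle edge weights within each
layer independently and recomputes the repeated distances;
p = (1 + #{null rank sum ≥ observed})/(1 + n_perm), BH across nodes,
significance at q < 0.05 by default. The rank-sum statistic is scale-free,
so the null is calibrated under identical layers while concentrated
between-layer change exceeds it. A layer-swap scheme (exchange each pair's
weights between layers with probability 1/2) is provided for comparison but
it preserves every edge's between-layer difference magnitude and therefore
tests the direction of assignment, not the amount of change. The group
contrast ranks nodes by |mean distance difference| between two results,
descending, ties broken by node id.

## Synthetic cohorts

The generator inverts exactly the model the estimator assumes: latent
z ~ N(0, Ω_g⁻¹) per group, u = Φ(z), counts by ZINB quantile inversion
(ties at zero: u ≤ π + (1−π)F_NB(0) maps to zero) with depth entering as a
multiplicative factor on μ and covariates acting linearly on log μ
(age ~ U[18,75], gender ~ Bernoulli(0.5), duration ~ U[0,20], location
categorical; effects applied to range-scaled covariates). Planted edges
shift the precision entry by −δ in non-reference groups, i.e. a +δ
partial-correlation shift at unit diagonal. Paired designs draw one sample
per timepoint per individual, independently across timepoints — no
within-individual carry-over, which real longitudinal microbiomes do have.
Default marginals: μ lognormal (median 40, one log-unit spread), θ = 1.5,
π ~ U[0.05, 0.3]; depth lognormal with sdlog 0.5. The generator does not
emulate compositional closure beyond the depth factor, read-level artifacts,
phylogenetic correlation, or strain structure — passing tests say the
estimators recover the generative law they assume, not that they are robust
to everything real 16S data does.

Benchmark problem sizes (30 taxa; 40–400 samples per group; 20-node
multiplex toys with connected ring-plus-random backgrounds; synthetic ISN
tables with per-edge noise sd 0.85, the median per-edge sd the pipeline's
own ISNs show at N = 80) were chosen as realistic single-centre scales that
keep the full suite and the benchmark script within minutes on one core.

## Known limitations

* The ZINB fit uses numerical gradients; a taxon observed only at zero is
  degenerate and rides on the NB fallback.
* StARS supports are unstable below ~50 samples; independently estimated
  layers then differ by selection churn as much as by biology (visible in
  the paired-cohort demonstration).
* Jackknife ISN pseudo-values are noisy (per-edge sd near 1 at N ≈ 100 for
  saturated estimators), which bounds differential-edge power at small
  cohort sizes.
* The embedding is a linear reduction of random-walk profiles; it reproduces
  the repeated-embedding/cosine-distance contract, and is pluggable, but it
  is not a trained neural encoder.
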