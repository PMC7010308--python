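# Methods

This note records the models, conventions and numerical choices behind
`woodwebs`, and what the synthetic-data tests do and do not establish.

## Data model

A rearing experiment produces long-format records
`(treatment, host, beetle, count[, interval])`. Records aggregate by
summation into one host × beetle count matrix per treatment. Conventions
fixed throughout: rows are hosts, columns are beetles; labels sort
lexicographically; matrices are trimmed so no all-zero row or column
survives (a species "occurs" in a treatment iff it has ≥ 1 emergence
there). Trimming never changes the grand total m. Species present in one
treatment and absent in another are simply absent from the latter's
matrix; alignment across treatments happens only inside the β-diversity
operations. Counts are individuals, so fractional inputs are rejected.
Emergences from the four collection intervals are pooled per treatment by
default; `interval` is kept as an optional grouping key
(`build_matrix(..., by_interval=True)`) because pooling is an analysis
choice, not a property of the data.

## Diversity

Hill numbers ^qD express diversity as an effective number of equally
abundant species: ^0D = richness, ^1D = exp(Shannon), ^2D = inverse
Simpson; the general form (Σ p^q)^{1/(1−q)} is accepted for any q ≥ 0.
The default assemblage per treatment is the beetle column totals (the
comparison of interest is insect diversity); host vectors are available.
Confidence intervals are multinomial-bootstrap percentile intervals
(default 100 replicates, 2.5/97.5 percentiles), with no correction for
unseen species: sample coverage in the regime this package targets is
near-complete (the coverage estimator Ĉ = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁+2f₂)
is reported alongside), so rarefaction/extrapolation machinery is out of
scope. Two caveats follow and are deliberate: the percentile CI of a
boundary statistic (e.g. an equal-abundance vector, whose ^qD is the
attainable maximum) can undershoot the point estimate by Monte-Carlo
error; and estimates are *observed*, not coverage-standardized.
Treatments are compared by CI overlap: treatments whose 95% CIs do not
overlap differ. Letters are the connected components of the CI-overlap
graph, assigned alphabetically by descending estimate — a deliberately
simple rule that can merge chains of pairwise-overlapping treatments into
one letter.

## β diversity

Species-pool dissimilarity uses the pairwise Sørensen partition: with a
shared species and b, c unique to each side,
β_sor = (b+c)/(2a+b+c), β_sim = min(b,c)/(a+min(b,c)),
β_sne = β_sor − β_sim. The partition is pairwise (one value per treatment
pair, summarized as mean ± sample SD), not multi-site.

Interaction dissimilarity treats links qualitatively (a link exists iff
its count is positive). β_WN is the Sørensen dissimilarity of the two
full link sets; β_OS restricts both link sets to the shared subweb
(links whose host *and* beetle occur in both networks) before applying
the same measure; β_ST = β_WN − β_OS is the turnover contribution. When
two networks share no species at some level the shared subweb is empty
and β_OS is defined as 0 (logged): all dissimilarity is then attributed
to turnover. Weighted link dissimilarities are not implemented.

## Network-level statistics

**WNODF.** Rows and columns are sorted by decreasing marginal total
(ties: decreasing fill, then label). For an ordered pair with strictly
larger upper total, the pair score is the percentage of the lower line's
nonzero cells whose count is positive yet strictly smaller than the
upper line's count in the same position; equal-total pairs score 0.
WNODF is the mean over all row and column pairs, 0–100.

**Modularity.** Barber's weighted bipartite modularity
Q = (1/m) Σ_ij (a_ij − r_i c_j/m) δ(g_i, g_j) is maximized by label
propagation: rows start with unique labels (plus random
constrained-module-count starts), columns then rows repeatedly adopt the
label with the largest modularity contribution (ties to the smallest
label), followed by an agglomerative phase that greedily merges module
pairs while Q increases; the best partition over `n_trials` (default 20)
seeded restarts is reported. Convergence tolerance 1e−10. Against an
exhaustive best-partition search the procedure attains the optimum on
every trimmed matrix up to 3×3 with m ≤ 6 (2,212 matrices).

**H₂′.** Observed Shannon entropy of the interaction proportions,
standardized between the extremes achievable under the fixed marginals:
H₂′ = (H₂max − H₂)/(H₂max − H₂min), clamped to [0, 1]. The bounds are
computed on *integer* tables. At small scale they are exact: H₂max by
successive-shortest-path min-cost flow (entropy is separable-concave, so
unit-by-unit cheapest augmenting paths are optimal; used for m ≤ 80),
and H₂min by a memoized depth-first search over saturating allocations
(a concave function is minimized at a vertex of the transportation
polytope, and every vertex arises from some saturation order; used for
m ≤ 40 and ≤ 12 species). Beyond those sizes, greedy heuristics take
over: for H₂max the floor of the expected table plus largest-residual
assignment, refined by entropy-increasing elementary 4-cycle unit swaps;
for H₂min the classical largest-row-with-largest-column concentration.
A single-cell matrix has no degrees of freedom; H₂′ is reported as 0
with a warning.

**Niche overlap.** Horn's index
R = [Σ(p+q)ln(p+q) − Σp ln p − Σq ln q]/(2 ln 2) on the two species'
normalized usage vectors, averaged (unweighted) over all unordered
species pairs of one trophic level.

**Species-level indices.** degree = realized partners;
effective partners = exp(Shannon entropy of the species' usage);
species strength = Σ over partners of the partner's proportional
dependence (strengths at one level therefore sum exactly to the number
of partner-level species); d′ = d/d_max with
d = Σ_j p′_j ln(p′_j/q_j), availability q_j = partner totals / m, and
d_min = 0. For d_max, note that d is convex in p′, so its maximum over
all (integer or not) allocations is the point mass on the
lowest-availability partner: d_max = −ln min_j q_j. The spec-style
exhaustive search over integer allocations is therefore unnecessary —
the point mass is itself an integer allocation.

## Null models

The null distribution is the multiple hypergeometric: random
contingency tables with exactly the observed row and column totals,
drawn by Patefield's algorithm (`scipy.stats.random_table`). p-values
use the add-one convention p = (1 + #{null ≥ obs})/(1 + n_rand) (upper
tail; mirrored for the lower; `tail="auto"` picks the direction from
the sign of obs − null mean, and the chosen tail is reported — the
convention matters only for metrics that can fall on either side).
z = (obs − mean)/SD with sample SD; a degenerate (constant) null
reports z = 0 with a warning. Defaults follow the study design: 1,000
randomizations, significance p < 0.01 for WNODF/H₂′/overlap, z ≥ 2 for
modularity. Null modularity values are re-optimized per draw; because
that dominates runtime, nulls default to `n_trials_null = 5` restarts
(the observed network keeps 20). Abundance-probability and binary swap
nulls are out of scope.

## Traits

wood density = oven-dry weight / dry volume (g/cm³), averaged over a
species' branches; PDD = 100 × ((initial − final)/initial) / exposure
days (percent mass *lost* per day — the complementary
percent-mass-remaining reading of the same operands is available as
`pdd(..., literal_remaining=True)` since the defining formula can be
typeset ambiguously); BSI = body length × width (mm²) per individual,
averaged per species. Branches that gain weight (moisture) give
negative PDD; they are flagged, not clamped.

## Ordination and treatment comparisons

PCA is computed on the correlation matrix of the species × variables
table (variables standardized; zero-variance variables rejected; rows
with missing values dropped and logged). Loadings are reported as
variable–component correlations (eigenvector × √λ) and flagged at
|r| ≥ 0.6 — the absolute value, since a strong negative loading is a
relationship, with its sign retained. Component signs are made
deterministic by orienting the largest-magnitude loading positive.
Default variable sets: beetles — degree, d′, effective partners, BSI;
hosts — degree, d′, species strength, wood density, PDD. Species-level
indices are compared across treatments with Kruskal–Wallis (tie-
corrected, χ² approximation, k−1 df); all-identical data return H = 0,
p = 1.

## Synthetic generator

The generator emulates the study design, not wood-decay mechanics. Per
treatment: beetle abundances are lognormal (μ = 0, σ = 1, normalized);
each beetle's host-preference vector is Dirichlet with concentration
parameters κ·n_hosts·w̃, where the base weights w̃ combine a nestedness
gradient exp(−γ·rank/n_hosts) (γ = 1: early-pool hosts attract
everyone) and a same-module boost (1 + module_boost·𝟙[same module],
boost = 4, K = 4 latent modules); counts are Poisson around
total × abundance × preference (a negative-binomial switch exists,
default off). Treatments retain a fraction ρ of their species pools
from a shared global core (with persistent module labels), the rest
drawn from the remainder of a global pool — so both rewiring (β_OS)
and turnover (β_ST) arise. All randomness descends from one seed with
a sub-stream per treatment.

Preset defaults are the reference study conditions: per-treatment pools
of 22/28/47/42 hosts and 21/22/40/34 beetles, global pools of 65 hosts
and 57 beetles, ~1,323 emergences allocated proportionally to network
size, ρ = 0.75, κ = 0.1. Chosen once, these place the generated
networks in the study's regime — H₂′ ≈ 0.64–0.68, Q ≈ 0.55–0.6,
WNODF ≈ 6–12, host overlap ≈ 0.1–0.2 — with one known gap: beetle
niche overlap lands near 0.10 rather than the study's 0.05, because
independent Dirichlet preferences leave more incidental sharing than
real emergence phenology does. What the generator does **not** emulate:
overdispersion beyond Poisson (by default), within-treatment spatial
structure, interval-resolved phenology, and trait-driven interaction
probabilities (traits correlate with degree only through the PDD
coupling). Passing recovery tests therefore show that the estimators
respond correctly to specialization, modularity and retention knobs —
not that field data meet these assumptions.

Recovery tests run at reduced scale (single treatments of 10–12 hosts ×
8–9 beetles, 250–800 emergences, 30 replicates, 50 null draws), sizes
at which every property examined is already decisive (e.g. modularity
z ≥ 2 in 30/30 replicates with K = 3).

## Numerical conventions

Sample SD (ddof = 1) everywhere a dispersion is summarized. Label-
propagation ties break to the smallest label; all stochastic stages
are seeded and sub-streamed (`numpy` `SeedSequence.spawn`), making
every report byte-stable under a fixed seed. Clamping to the unit
interval is applied to H₂′ and d′ only after standardization.
Degenerate inputs are errors when the quantity is undefined (all-zero
abundance vectors, 1×n matrices for WNODF, empty species pools) and
warnings when a convention exists (single-cell H₂′ = 0, β_OS = 0
without shared species, constant nulls).

## Known limitations

- H₂′ entropy bounds beyond the exact-size cutoffs are heuristic;
  their error is negligible at large m but unquantified in general.
- The CI-overlap lettering is a simplification of compact-letter
  displays and can be conservative with chained overlaps.
- β_ST is obtained by subtraction, so it inherits the binary-link
  convention of β_WN and β_OS; weighted variants are not provided.
- The label-propagation modularity is a best-found maximizer; its
  optimality is verified exhaustively only at small scale.
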