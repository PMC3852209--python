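# Methods

## Network construction

Input is a matched pair of genes × samples matrices (log-scale
intensities) from two tissue compartments of the same specimens. Because
the two compartments are typically normalized separately upstream, a
single global linear map (`median_match_normalize`, default a pure shift)
aligns the stroma matrix's overall median to the tumor's; this changes no
ranks and no correlations, only the shared scale. Genes with small
variation are then removed, since near-constant profiles make Pearson
correlation estimates unstable. The "small variation" criterion is
ambiguous in common usage, so both readings are implemented:
coefficient of variation sd/|mean| < threshold (default, threshold 0.2)
and a bottom-fraction-by-variance quantile cut. Zero-variance genes are
removed under either mode because their correlation is undefined.

Edges connect tumor gene *i* to stroma gene *j* with weight ρ_ij (sample
Pearson correlation across the matched samples) whenever
ρ_ij ≥ `min_weight` (default 0.6). The density arithmetic and the bound
below presuppose nonnegative weights, so the default keeps only positive
correlations; `absolute=True` folds anticorrelation in as |ρ| for
exploratory use. Sub-threshold pairs count as weight 0 in every density
sum. The correlation matrix is computed blockwise purely to bound memory;
the result is identical to the naive all-pairs computation.

## BCM mining

Edges are sorted by descending weight (ties lexicographic by endpoint
ids). Each unselected edge with weight ≥ β·w_max seeds a BiNet; edges of
earlier BiNets enter a *Selected* set (including the seed itself, making
Selected a complete cover record) and are skipped as seeds, but vertices
may be shared across BiNets. Growth repeatedly takes the
maximum-contribution candidate on each side (ties to the smallest vertex
id, for determinism); the X candidate wins only on a strictly larger
contribution, otherwise the Y branch runs. The winner is admitted iff its
contribution is ≥ α·d(B) with α from the λ-schedule; when the winning
side fails, growth stops even if the other side's candidate might have
passed — that asymmetry is part of the algorithm as specified, though a
`--both-sides` style relaxation would be easy to add. A side with no
remaining candidates contributes −∞.

The α-schedule is α = 1 − 1/(λ(size+τ+1)) with λ = max{1, C/(size+τ+1)²}.
In the λ > 1 regime this simplifies to 1 − (size+τ+1)/C, which *decreases*
as the side grows (admission becomes easier up to size ≈ √C−τ−1), then in
the λ = 1 regime it is 1 − 1/(size+τ+1), tightening toward 1. The product
of the per-step density-ratio bounds telescopes into the guarantee

    F(C, τ) = ((2C−τ−2)/(2C))^(2k) · ((√C−τ−1)/(√C−τ))²,
    k = #{ i ≥ 1 : (i+τ+1)² < C },

valid for integer C > (τ+2)². Non-perfect-square C is handled through the
real √C and the counting definition of k. F(100,1) ≈ 0.639, F(10000,0) ≈
0.9611, F(36,2) ≈ 0.4475. `verify_density_guarantee` recomputes every
BiNet's density from the graph and checks ratio ≥ F − 1e−9; the property
suite additionally sweeps random graphs and replays each growth trace.

Defaults C = 36, τ = 2, β = 0.7, and a 10-distinct-gene floor for the
post-mining filter (a symbol appearing on both sides counts once).

## Merging

BiNets are summarized by best-first agglomerative merging: start with one
cluster per BiNet and repeatedly merge the pair with the largest merged
density (density of the union vertex sets, recomputed exactly against the
graph; ties to the smallest id pair). The macro-network partition is
frozen the first time the best available merge falls below the threshold
(default 0.3); merging then continues threshold-free only to complete the
dendrogram. Consequently every macro network with ≥ 2 members has
recomputed density ≥ the threshold by construction. Candidate densities
are recomputed exactly after every merge — at hundreds of BiNets the
O(k²)-per-round cost is immaterial. The dendrogram is exported as Newick
with branch length equal to the child's merge density. The merge ordering
is this package's own documented choice; best-first order also makes the
root-ward merge densities non-increasing on all fixtures exercised here,
which the tests assert on the synthetic runs.

## Survival evaluation

Each BiNet's union gene set indexes the cohort's feature columns (missing
genes dropped with a logged count; zero overlap skips the BiNet with an
explicit status). Patients are split by K-means with K = 2 under
city-block distance — centroids updated as the component-wise median, the
L1-optimal centroid — taking the best of 100 random restarts by total
within-cluster L1 cost (ties to the first found). Features are used on
their own scale by default; a `standardize` option exists because
real-data practice varies. Group orientation (good/poor) is assigned by
comparing event rates and affects labels only.

The two-group log-rank test is implemented directly so the result can
expose per-group observed and expected event counts: at each distinct
event time the observed events in one group are compared with their
hypergeometric expectation given the risk sets, and
(ΣO₁−ΣE₁)²/ΣV is referred to χ²(1). Censored samples leave the risk set
at their censoring time; zero events (or zero variance) give statistic 0,
p = 1. An independent implementation (lifelines) serves as the oracle in
the test suite. Raw p-values are reported, matching common practice for
this screen; Benjamini–Hochberg correction is available behind a flag.

## Synthetic data

The generator emulates the paired-tissue design: K matched samples
(default 47, matching the motivating cohort's matched-pair count), two
gene panels (default 60 + 60), and planted cross-tissue modules. Each
module m has a standard-normal latent factor z_m per sample; every member
gene is loading·z_m + σ·ε with σ the background noise sd (default 1).
Since both tissues share the loading, the expected member-pair
cross-correlation is ρ\* = loading²/(loading²+σ²), inverted to set the
loading from a requested ρ\* — the closed form the tests check by Monte
Carlo. Non-member genes are pure noise. The default planted module is
15×15 at ρ\* = 0.8.

Survival times are exponential with baseline hazard 1; samples above the
median of the prognostic module's latent factor form the poor-outcome
group and have their hazard multiplied by `hazard_ratio`. Censoring is
independent uniform on [0, T_max] with T_max solved by bisection on the
closed-form expected censored fraction (1−e^{−hT})/(hT) averaged over
groups, accurate to a few percent at realistic n. A latent-factor model
was chosen over a copula because it gives closed-form control of the
cross-correlation, hence sharp tests.

What the generator does *not* emulate: probe-level structure, batch
effects, heavy-tailed intensity marginals, correlated background blocks,
or dependent censoring. Passing tests therefore demonstrate algorithmic
correctness and calibration under a clean factor model, not performance
on real microarray cohorts.

## Problem sizes and numerics

The test and verification workloads use desk-scale instances chosen to
make the statistical assertions sharp: 20×20 random graphs over 200 seeds
for the guarantee sweep, 60×60 genes × 200 samples for module recovery
(10 seeds), 1000 null replicates at n = 100 for log-rank calibration, and
50 replicates for power at hazard ratio 3. Density recomputations are
compared at 1e−9, closed-form identities at 1e−12. All randomness flows
through seeded `numpy.random.default_rng`; mining and merging are
deterministic given their tie rules (smallest id), so reruns are
byte-identical.

## Known limitations

- The growth loop's single-winner termination can stop a BiNet that the
  losing side could still legally extend; this is faithful to the
  algorithm but means mined BiNets are not maximal dense subgraphs.
- The merge ordering is one reasonable density-guaranteeing scheme among
  several; other linkage choices would produce different dendrograms with
  the same per-macro density guarantee.
- With highly overlapping modules the partition of BiNets does not imply
  disjoint gene sets; genes may appear in several macro networks.
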