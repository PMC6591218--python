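# Methods

## Pipeline overview

`cooccurnet` infers correlation-based co-occurrence networks from a size-
fractionated OTU survey and characterizes their topology against random
null models. The observational unit for correlation is the water mass
(month × station × depth): each size fraction of a water mass is one
sequencing sample, and a variable is an OTU *within* a fraction
(`OTU_0001|FL`), an environmental parameter, or a phytoplankton genus.
Monthly networks correlate variables over that month's station × depth
grid; a pooled mode correlates over the whole grid.

### Filtering

Per fraction, an OTU enters the analysis iff its maximum per-sample
relative abundance exceeds 0.1 % **and** it is observed in more than 70 %
of the fraction's samples in scope. Both comparisons are strict (`>`),
and boundary tests lock this in. Relative abundance is computed within
the fraction's sample columns. Phytoplankton genera face only the
prevalence screen and are log10(x+1)-transformed (the pseudocount makes
zero counts representable; as a per-variable monotone map it does not
alter Spearman correlations). Family-level summaries are arcsine-
square-root transformed, the standard variance stabilization for
proportions.

### Correlation and thresholding

Spearman ρ uses average ranks for ties; two-sided P-values come from the
t statistic t = ρ√((n−2)/(1−ρ²)) with n−2 df (exact permutation is used
only as a test oracle at tiny n; the t approximation is adequate at the
survey's sample sizes). |ρ| = 1 maps to P = 0; constant variables yield
NaN and never form edges. Q-values are Benjamini–Hochberg step-up values
Q(i) = min_{j≥i} m·P(j)/j, capped at 1. An edge requires Q < q_max
(default 0.01; October override 0.05, matching the sparser post-typhoon
signal) and |ρ| ≥ 0.7. The magnitude threshold admits negative
correlations with the sign stored on the edge — environment–OTU
associations are naturally signed — and `positive_only=True` restricts to
ρ ≥ 0.7 for users who want the literal one-sided rule. Variables without
any retained edge are excluded from the node set, so reported node counts
mean *connected* variables.

### Topology and the Erdős–Rényi null

The null is G(n, m): a uniform simple graph with exactly the observed
node and edge counts, honouring the "same nodes and edges" comparison
(not G(n, p)). Defaults: 100 replicates, seeded; per replicate the local
clustering coefficient (nodes of degree < 2 contribute 0), average
shortest path length, and Louvain modularity. Because monthly networks
are typically multi-component, APL and diameter are computed on the
largest connected component, for observed and null networks alike; this
is a convention, and the null APL under it need not match values produced
by other disconnected-pair treatments. σ = (CC/CC_r)/(APL/APL_r) is
computed from unrounded internal values. Degree-distribution power-law
R² is the OLS fit of log10 raw degree frequencies on log10 degree
(k ≥ 1, no binning, no CCDF); with fewer than three distinct degrees it
is reported as NaN with a warning. Degree concentration takes the top
⌈0.1·N⌉ nodes by degree, ties broken by node id.

### Modules, roles, depth profiles, recurrence

Louvain modularity maximization runs with seeded tie-breaking; the
reported partition is the best of 10 seeded restarts. Within-module
degree Z_i standardizes a node's internal link count against its module's
mean and population SD (σ_s = 0, including singleton modules, gives
Z = 0). The participation coefficient is C_i = 1 − Σ_t (κ_it/k_i)²
(degree-0 nodes: C = 0). Roles partition the (Z, C) plane at Z = 1.5 and
C = 0.62 with the ≤ side inclusive, so (1.5, 0.62) is peripheral.

Module depth profiles average member-OTU relative abundance per depth
layer (each OTU within its own fraction's samples) and normalize the
three layer means to sum 1. Labels: S if f_surface ≥ 0.5, MB if
f_middle + f_bottom ≥ 0.75, else W. These thresholds are package
choices mimicking drawn (not parameterized) ternary-plot regions; both
are configurable. Modules without OTU members get "n/a".

The recurrence network retains variable pairs present in ≥ 3 monthly
networks ("more than 3 times" is read inclusively because 3-occurrence
edges are explicitly part of the published display; a `strict_greater`
switch gives the exclusive reading). Occurrence counting ignores the
correlation sign; a per-edge sign-consistency flag lets users filter.
Node attribute `mean_degree` averages the node's degree over the monthly
networks containing it. Z/C roles are computed on the monthly networks
(not on the recurrence network), and hub summaries are reported both
per month and deduplicated by variable (maximum-Z occurrence).

### Diversity

Shannon H = −Σ p_i ln p_i (nats), Chao1 = S_obs + n1(n1−1)/(2(n2+1))
(bias-corrected form), Simpson evenness E = (1/D)/S_obs with
D = Σ n_i(n_i−1)/(N(N−1)). E can exceed 1 on very small samples — a
property of the estimator that is documented, not clamped — and D = 0
(all singletons) is defined as E = 1.

## The synthetic generator

The generator emulates the study design: a factorial grid of 5 months ×
6 stations × 3 depths, each water mass split into up to three size
fractions (270 samples at the full design; the single-fraction
strong-signal variant has 90). Environmental parameters are clipped
normals with depth-dependent means and SDs chosen to match reported
coastal ranges (e.g. surface temperature 21.8 ± 4.5 °C within
[14.1, 29.7]; bottom NOx clipped to [0.17, 12.04] µM); the three
fractions of a water mass share one environmental state.

Community structure is a latent-factor model. Module *m* has a per-site
factor f_m = α_m·depth_code + β·z(driver) + γ_m(month) + η with
depth_code 0/0.5/1, η ~ N(0,1), and γ_m(month) ~ N(0, 0.3); the factor
is standardized to unit variance so the loadings alone set correlation
strengths. Member OTUs have log-abundance base_i + loading_i·f_m + ε_i.
Defaults: member loadings ~0.35 (uniform ±5 %), ε SD 0.25, giving
member–factor correlation ≈ 0.81; the planted hub (max-loading member)
has its loading raised 1.2× and its idiosyncratic noise zeroed,
giving hub–factor correlation ≈ 0.99. At the |ρ| ≥ 0.7 edge threshold
this makes modules star-like around their hubs — hub–member correlations
(≈ 0.8) pass while most member–member correlations (≈ 0.65) do not — so
planted hubs are recoverable from within-module degree. All OTUs have
similar log-abundance SD (~0.43), which keeps any single OTU from
dominating the composition: that matters because counts are drawn
multinomially per sample (columns sum exactly to the 100,000-read
library), and both the compositional closure and multinomial resampling
erode rank correlations of OTUs with wide abundance swings. Background
OTUs are independent log-normals. Effect sizes are package choices —
no published effect-size estimates exist for OTU–environment coupling —
selected so the generator exhibits the structure the pipeline is meant
to detect, at realistic sample sizes.

Depth preferences: S/MB/W modules get α = ∓0.5/0 inside the standardized
factor. At the default α this tilts abundance by depth only mildly, so
default-generator module profiles classify as W; strong, classifiable
depth preferences require α ≈ 3 (see `depth_effect`), at the cost of
correlating same-preference modules through the shared depth covariate —
an inherent tension, since depth preference *is* shared structure. Tests
exercise the S/MB classifier on toy profiles and on a raised-α
configuration.

What the generator does **not** emulate: sequence-level noise (no reads,
chimeras, or OTU-clustering artifacts), phylogenetic signal, taxon-
specific library-size variation, overdispersion beyond multinomial,
rare-taxon dynamics, or true ecological interactions (associations are
driven by shared latent responses, as correlation networks themselves
assume). Passing recovery tests therefore shows the inference machinery
is correct and calibrated under the model's own assumptions, not that
correlation networks capture real interactions.

Reproducibility: each operation owns one RNG stream seeded as
`default_rng([op_code, seed])` (0 = environment, 1 = counts,
2 = taxonomy), so environment and counts are independently reproducible.

## Problem sizes and numerical choices

The validation suite uses: G(355, 1096) × 200 replicates for the
clustering-coefficient null (its mean has a small finite-size deficit
versus the analytic 2m/(n(n−1)) because degree < 2 nodes count as 0;
within 3 SE at this ensemble size); 50 replicates for null Louvain
modularity; 10 generator seeds for module/hub recovery (median adjusted
Rand index and hub Z > 1.5); exhaustive tie patterns at n ≤ 5 plus
random tie-heavy draws at n = 6–8 for the Spearman rank oracle
(enumeration of all weak orderings grows as the Fubini numbers and is
exhaustive only where tractable); 1,000 random vectors for the
BH step-up versus its O(m²) definition. Louvain ties are broken by
seeded node order; `small_world_sigma` returns NaN rather than raising
on zero denominators; empty networks are valid results everywhere except
module detection, which requires at least one node.

## Known limitations

- Plain Spearman on relative abundances is the implemented (and
  reproduced) estimator; compositionality-aware methods (SparCC,
  SPIEC-EASI) are out of scope by design, and the generator's
  compositional closure demonstrates exactly the artifact they address.
- The published APL_r convention for disconnected null pairs is not
  recoverable; our largest-component convention is reported as such.
- Q-values are BH; Storey's q-value estimator is not implemented.
- No rarefaction, beta-diversity ordinations, or functional prediction.
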