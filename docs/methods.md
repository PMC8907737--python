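# Methods

## Problem and model

National food-safety monitoring produces, per region × food-category
combination, a set of contaminant concentration measurements (mg/kg), a
survey estimate of mean daily consumption FC (kg/day), a regulatory limit S
(mg/kg), and toxicological reference values — for lead an oral reference
dose RfD = 3.5 μg/(kg·day), a benchmark-dose lower bound BMDL01 =
0.6 μg/(kg·day) and a reference body weight W = 60 kg. The package turns
these into an ordinal risk grading in three stages.

**Indexes.** Each combination is summarised by its mean, median (P50), 95th
percentile (P95) and maximum concentration, and three indexes are derived:

- Nemerow integrated pollution index
  `Pc = sqrt((Pmax² + Pave²)/2)`, `P = X/S`. `Pave` is computed as
  mean concentration over S, which is algebraically identical to the mean of
  per-sample pollution indexes, so published group means are valid inputs.
  `Pc` always lies in `[Pmax/√2, Pmax]`.
- Hazard index `HI = EDI95/RfD` with `EDI = FC·X/W`; concentrations in
  mg/kg are converted to μg (×1000) so intakes share the μg/(kg·day) scale
  of RfD and BMDL01.
- Margin of exposure `MOE = BMDL01/EDI50`. MOE is undefined at zero median
  exposure; in whole-table assembly it is capped at 10⁶ with a warning
  rather than failing the run (a zero median can only arise in synthetic
  edge cases, since any positive LOD substitutes to a positive value).

**Censoring.** Non-detects are replaced following GEMS/FOOD low-level
practice: if the non-detect proportion is below 60%, each becomes LOD/2;
at 60% or above, the full LOD. The proportion is evaluated globally by
default (one blanket rule per dataset), with a per-combination scope
available. The boundary at exactly 60% uses the full-LOD branch. The rule
is idempotent and monotone in the LOD. No likelihood-based or Kaplan–Meier
censoring treatment is attempted — substitution is the method being
reproduced.

**Clustering.** The n × 3 feature matrix (Pc, HI, MOE) is standardized
column-wise (population variance; constant columns pass through centered
with a warning, since their scale carries no information). Affinities are
Gaussian: `A[u,v] = exp(−γ‖z_u − z_v‖²)`. The symmetric normalized
Laplacian `L = I − D^{−1/2} A D^{−1/2}` is formed with self-affinities
excluded (Ng–Jordan–Weiss convention: the affinity diagonal does not enter
the degrees), the k eigenvectors of the smallest eigenvalues are taken and
row-normalized to the unit sphere, and k-means runs in that embedding.
An alternative `embedding="affinity"` mode (top eigenvectors of A itself)
is exposed for sensitivity checks; the Laplacian mode is the default and
the standard reading of "sort the spectrum and take the first k".

k-means uses greedy distance-weighted (k-means++-style) seeding, Lloyd
iterations to a stable assignment or 300 iterations, and 10 restarts keeping
the best inertia. Inertia is asserted non-increasing at every Lloyd step. An
empty cluster is reseeded at the point farthest from its current centroid.
Restarts that end with fewer than k non-empty clusters (possible only with
duplicate points) are discarded.

**Model selection.** The Calinski–Harabasz index
`CH = [B/(k−1)]/[W/(n−k)]` is evaluated for every (γ, k) cell of the grid
(γ ∈ {1..10}, k ∈ {3..7} by default). CH is computed in the *standardized
feature space*, not the spectral embedding, so scores are comparable across
k (the embedding's dimension changes with k). The argmax is selected; exact
ties break toward smaller k, then smaller γ (parsimony). Cells that fail
(e.g. k > n) score NaN, are logged and excluded. The γ grid is interpreted
as the RBF width acting on standardized features — integer widths 1–10 are
a natural scale there because squared distances between standardized rows
are O(1).

**Grading.** Clusters are ordered by the mean over members of the composite
standardized risk `z(Pc) + z(HI) − z(MOE)` (MOE is protective, hence
negated) and assigned levels 1..k ascending. Ties break by cluster size
descending, then cluster id. Level proportions use largest-remainder
rounding so the per-level percentages sum to exactly 100.00. The high-risk
report lists combinations at level ≥ 3, sorted by level then composite
score descending, with the exceedance factor `Xmax/S` attached when the
limit and summary tables are available. The ordering rule is a declared
convention validated on synthetic tiers; with one cluster per true tier it
reduces to ordering by contamination.

## Synthetic reference scenario

`ScenarioConfig.default()` emulates the structure of a national monitoring
campaign: 20 regions × 9 categories (180 combinations), 30 samples per
combination, five planted risk tiers cycled across combinations (36 each).
Concentrations are lognormal per tier — monitoring residues are positive
and right-skewed — with log-sd 0.08 and tier log-means spaced exactly
3 log-sd apart starting from a median of 0.01 mg/kg, giving tier medians
0.010–0.026 mg/kg and single-factor pollution indexes within the range
real campaigns report. The LOD (0.0095 mg/kg) sits just below the lowest
tier's median, so left-censoring concentrates in tier 1 (≈25% there, ≈6%
overall). Consumption is gamma-distributed (shape 400) around a flat
0.1 kg/day; the regulatory limit is uniform at 0.1 mg/kg.

Three of these choices deserve justification, because they were forced by
the geometry of the method rather than free:

- **LOD below the lowest tier's median.** Substitution maps every censored
  value to the same constant; if the LOD sits above two tiers' medians,
  their P50s both become LOD/2 and the tiers are *unrecoverable* in the MOE
  dimension. Heavy blanket censoring therefore genuinely destroys low-end
  risk resolution — a property of the substitution method itself, not of
  this implementation.
- **Uniform limit.** Category-specific limits (0.3/0.2/0.1 mg/kg) modulate
  Pc across categories by up to 3×, which exceeds a 3-log-sd tier spacing
  and turns Pc into a category feature rather than a tier feature. The
  preset national scheme remains the generator's default mode for
  paper-shaped fixtures and is tested; the reference recovery scenario uses
  a uniform limit so the planted tiers are the only structure.
- **Small within-tier dispersion.** Tier ladders are multiplicative, but
  clustering and CH scoring operate on linearly standardized features, where
  the top tier's absolute spread competes with the bottom tiers' absolute
  gaps. With loose within-tier variation (log-sd ≳ 0.3, or consumption
  CV ≳ 0.2) CH prefers splitting the elongated extreme tiers over separating
  the compressed middle ones and selects k above the true tier count. The
  reference scenario keeps within-tier CV small so that the planted
  partition is the CH optimum.

Consequently, passing the recovery tests shows the pipeline is internally
consistent and recovers well-separated, compact planted structure; it does
*not* show that five levels would be recovered from real monitoring data,
whose tiers — if any — are neither compact nor equally populated. The
generator also omits seasonal/spatial correlation, per-laboratory LODs and
any attempt to match the real 2019 concentration distribution.

## Numerical choices

- Quantiles: linear interpolation at rank p·(n−1) (the common default of
  mainstream numeric stacks), configurable via `quantile_method`.
- A group mean may exceed the group maximum by float rounding when all
  values are identical; `nemerow_index` clamps `p_ave` to `p_max` within a
  1e-9 relative tolerance and rejects larger violations as inconsistent.
- Eigendecomposition is dense (`scipy.linalg.eigh`); n is at most a few
  hundred combinations, so sparse solvers are deliberately out of scope.
- All randomness descends from one root seed: the sampling and consumption
  generators and every (γ, k) grid cell draw from independent
  `SeedSequence([seed, ...])` streams, making every artifact reproducible
  byte-for-byte from the run report alone.
- Rows of all-zero norm in the embedding are left unnormalized (guard
  against division by zero); they cannot occur for connected graphs.

## Limitations

- Risk levels are relative: they rank combinations against each other
  within one dataset and carry no absolute-risk meaning.
- The substitution rule biases summaries when censoring is heavy; the P50
  of a mostly-censored group is an artifact of the rule, and MOE built on
  it inherits that artifact.
- CH-based selection in linear standardized space favors splitting
  high-variance clusters; on strongly skewed index distributions the
  selected k should be read as a data description, not an estimate of a
  true number of risk classes.
- The carcinogenic target-risk extension (for contaminants like Cd or Cr)
  is not implemented; the schema reserves no special handling for it.
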