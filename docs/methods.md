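# Methods

## Model and assumptions

The package couples three components on a single-outlet dendritic river
network: a production model, a transport/decay model, and an observation
model.

**Network substrate.** Reaches (segments between confluences, split to a
maximum length, 1 km by default) are the habitat unit; every quantity lives
on reaches, not junction nodes. The downstream relation must form a rooted
tree: exactly one outlet, no cycles, every reach connected. Drainage area
accumulates local contributing areas over upstream sets; Strahler order
follows the usual merge rule. Units are fixed throughout: lengths m,
drainage areas km², source areas m², discharge m³/s, time s internally
(decay times are accepted in hours at every interface and converted).

**Production.** Each genus sheds eDNA at rate p_i = p₀·exp(βᵀX(i)) per m²
of open water, a Poisson-GLM-style log-linear response to standardized
covariates. Covariates are standardized once, over the full reach set,
before inference; maps produced from fitted parameters reuse the same
scaling. Constant covariate columns are rejected (they would alias p₀).

**Transport and decay.** Expected concentration at reach j is
C_j = (1/Q_j) Σ_{i∈γ(j)} p_i A_{S,i} exp(−t_ij/τ), with t_ij the water
travel time from i to j (so the harmonic-mean velocity of the transit is
implied, as the per-reach times are summed). The model assumes steady
uniform flow per season, first-order decay, no resuspension or hyporheic
exchange, and no within-reach gradients.

*Endpoint convention.* The within-reach positions of the eDNA origin and of
the sampling point determine how much of the two endpoint reaches counts
toward t_ij. Three conventions are provided (`path_endpoints`):

- `half` (default): origin and sampling mid-reach — half of i, half of j,
  all of the reaches between. Unbiased on average and reduces to t = 0 for
  i = j.
- `full`: origin at the upstream end of i, sampling at the upstream end of
  j — all of i, none of j. The simplest convention for hand-checked
  arithmetic.
- `exclusive`: only the reaches strictly between i and j.

All conventions give t = 0 for i = j; the choice shifts decay by at most
one reach's residence time and is configurable end to end.

**Hydraulics.** Width, depth and discharge follow power laws on drainage
area fitted by OLS on log-log pairs (the hydrological standard; exactly
reproducible, unlike iterative nonlinear fits). Width is fitted once,
pooled over seasons (channel geometry); discharge and depth per season.
Velocity comes from continuity under rectangular cross-sections,
v = Q/(w·d), so Q = v·w·d holds to machine precision by construction. A
degenerate fit in which all gauges share one drainage area returns a
constant law through the geometric mean, so a law supported by a single
gauge reproduces that gauge.

**Observation model.** Reads are geometric on {0, 1, 2, …} with mean
μ = C_j; the proportionality constant between concentration and expected
reads is fixed at 1 and absorbed into p₀, which therefore carries
read-equivalent units (its U(0,1) prior spans the plausible range once
absorbed). The support includes 0 so that μ = 0 and n = 0 are consistent
(point mass at zero). Detection probability at a reach is the chance of a
nonzero count if the reach were disconnected from the network:
μ_local = p_i·A_{S,i}/Q_i and P(N>0) = μ_local/(1+μ_local). Presence is
declared at detection ≥ 0.5 (boundary inclusive).

## Inference

Parameters θ = (β…, p₀, τ) are fitted independently per genus and season.
Priors: β ~ N(0, 3) per component; p₀ ~ U(0, 1); τ log-normal constructed
from a stated median and mode via meanlog = ln(median),
sdlog = √ln(median/mode) — the default (5 h, 4 h) encodes laboratory decay
scales and requires mode < median.

The sampler is differential-evolution MCMC with a sampled-history archive
(DE-MC-Z, the scheme underlying the DREAM-ZS family), re-implemented with
the published defaults of that family: jump scale γ = 2.38/√(2d) with 10%
of proposals at γ = 1 (mode jumps), uniform jitter 1e-6, snooker updates
with probability 0.1 (with the (‖x′−z‖/‖x−z‖)^(d−1) Metropolis
correction), archive appended every 10 iterations, archive seeded with 10·d
prior draws, chains initialized from the priors with up to 100 retries for
a finite posterior. Three chains of 2·10⁴ iterations with 5·10³ burn-in are
the package's working scale for synthetic studies; production-scale chain
lengths are configuration. Convergence is monitored with the
between/within-chain potential scale reduction factor R̂ (clamped below at
1; fits with R̂ > 1.1 are flagged in the outputs). The MAP estimate is the
retained sample with the highest log posterior (global argmax across
chains, which also handles multimodal fits conservatively).

Everything stochastic consumes a seed derived from the run seed by hashing
the stage labels (SHA-256 of `"seed:stage:genus:season"`, first 4 bytes,
mod 2³¹), so a full rerun is bit-identical and a single genus can be re-fit
without disturbing other streams.

## Diversity analyses

**Contamination filter.** Within each sample (site × season), an amount
equal to 0.1% of the sample's total reads is removed from every genus with
nonzero reads. "Removed" admits two readings, both implemented: subtract
the amount and clamp at zero (default; counts are floored to integers), or
zero out genera below the amount (`mode="threshold"`).

**α-diversity.** Richness is the number of genera present per reach
(predicted) or with nonzero reads per site (raw). Predicted richness values
are spatially autocorrelated through the shared covariates, so trends on
drainage area are tested by a decile-stratified bootstrap: 10 drainage-area
decile bins, 50 reaches resampled with replacement per bin, OLS on natural
(untransformed) area per replicate, 100 replicates; a trend is significant
when ≥ 95 replicates agree on the slope sign, and the 2.5th–97.5th
percentile envelope of the 100 fitted lines forms the confidence band. Raw
(site-level) trends use ordinary two-sided slope p-values, treating sites
as independent.

**Spatial β-diversity.** Reaches split at the median drainage area into
upstream (strictly below) and downstream (at or above; ties downstream)
groups. Within each group, a random maximal matching of flow-unconnected
pairs is drawn — each reach used at most once, pairing stops when no unused
pair remains unconnected — which removes the bias that downstream reaches
are more often connected by flow (hence similar) and keeps pair distances
independent. Mean total Jaccard distance per group is recorded over 100
pair-selection replicates; the group effect is significant when the two
equal-tailed 95% intervals do not overlap. Jaccard dissimilarity is
partitioned additively into turnover 2·min(b,c)/(a+2·min(b,c)) and
nestedness (the remainder), the Jaccard-family decomposition — chosen
because every distance reported is a Jaccard distance (the Sørensen-family
analogue is out of scope). Pairs of two empty communities are undefined and
excluded.

**Temporal β-diversity.** Per reach, the Jaccard decomposition between the
spring (benchmark) community and each other season; reaches empty in both
seasons are undefined and excluded from the area regressions (Jaccard is
undefined on two empty sets) rather than assigned 0. Trends on area use the
same bootstrap as α-diversity.

**Predicted vs raw.** Welch (unequal-variance) two-sample t-tests compare
the means of predicted (reach-level) and raw (site-level) distributions;
two identical constant samples return (t = 0, p = 1) by convention.

**Cross-season summaries.** Pearson correlations between per-reach richness
vectors across seasons, and per genus an occupancy-overlap statistic:
reaches occupied in all seasons divided by reaches occupied in any season
(denominator configurable to the maximum single-season occupancy; the union
is the default as the more conservative reading).

## Synthetic scenarios

The generator emulates a seasonal eDNA survey with known truth, so every
stage is testable without external data:

- **Network**: random binary-confluence tree (real confluences are
  overwhelmingly binary) built by iteratively merging branches; segment
  lengths uniform 450–1350 m, partitioned at 1 km — mean reach length
  ≈ 600 m, comparable to real catchment partitions; local areas uniform
  0.25–2 km² (0.25 km² being a typical channel-initiation threshold). The
  default 18 headwaters give ≈ 50 reaches after partitioning.
- **Covariates**: 5 by default — 3 continuous AR(1) cascades down the tree
  (ρ = 0.7; a reach's value is ρ times the mean of its upstream neighbours
  plus √(1−ρ²) noise), emulating smooth land-cover/geology gradients, plus
  2 standardized tributary-subtree indicators.
- **Hydraulics**: known power laws with exponents near classical downstream
  hydraulic geometry (Q ~ A¹, w ~ A^0.5, d ~ A^0.4) and seasonal flow
  multipliers (wet spring 1.3, dry summer 0.6); four synthetic gauges at
  the largest reaches read exactly off the laws, so law recovery is exact.
- **Genus parameters**: per genus, 60% of effects at |β| = 1.5 with random
  signs (strong, identifiable signal), the rest zero; τ = 4 h; p₀
  log-uniform on (1e-4, 1e-2). The p₀ scale is chosen so that
  p₀·exp(βᵀX) straddles the local detection boundary Q/A_S across reaches:
  occupancy then spans rare to widespread genera (≈ 0.5–0.98 per genus,
  ≈ 0.85 overall), read medians land in the tens-to-hundreds, and
  presence/absence actually varies — a generator whose taxa are present
  everywhere would make every diversity analysis degenerate.
- **Survey**: 20 sites at random reaches over three seasons, with 5% of
  sites unsampled in summer (temporarily dry reaches); one geometric read
  count per site × genus × season drawn from the forward model.

What the generator does **not** emulate: overdispersion beyond geometric
(no replicate-level variance components), spatially correlated observation
error, taxonomy misassignment, PCR/sequencing depth effects beyond the
proportionality absorbed into p₀, non-binary confluences, braided or
intermittent channels, and seasonal changes in the covariate effects
themselves (β and τ are held constant across seasons; only hydrology and
p₀-mediated read scales vary). Passing recovery tests therefore show the
inference machinery is correct and well calibrated under the model's own
assumptions — not that the model is adequate for any particular real
catchment.

## Numerical choices and edge cases

- Travel times on a tree are computed as differences of cumulative
  reach-to-outlet residence times (O(n) precompute), avoiding per-pair path
  walks; the transport sum is evaluated as one masked matrix product per
  likelihood call.
- Geometric log-pmf uses log1p throughout; μ = 0 is the point mass at 0.
- −∞ encodes prior-support violations in the posterior; the likelihood is
  never evaluated outside support.
- R̂ below 1 (possible for near-identical chains in the raw
  between/within formula) is clamped to 1.
- Decile bins use right-closed quantile edges; an empty bin (degenerate
  area distribution) raises a binning error with guidance instead of
  silently merging bins.
- Median-area ties go to the downstream group, matching the strict
  "lower than the median" definition of upstream.
- partition_reaches splits a segment of length L > max into ceil(L/max)
  equal parts (areas divided equally); a segment exactly at the maximum is
  left alone.
- Pair selection discards an id only when it is flow-connected to every
  remaining unused id, which makes the matching maximal by construction.
- All diversity outputs are invariant to reach and genus ordering; outputs
  are written with %.12g float formatting so reruns are byte-comparable.

## Known limitations

- The MAP is a single posterior draw; parameter uncertainty is available in
  the posterior summaries but not propagated into the presence maps.
- The geometric observation model has no free dispersion parameter; heavily
  replicated designs may warrant a negative-binomial extension.
- The bootstrap trend test controls sign stability, not a nominal type-I
  error rate; its null behaviour is verified empirically in the tests.
- Production-scale chain lengths (10⁶+) are supported but slow in pure
  Python; the working scale here (3 × 2·10⁴) is sized for ~50-reach,
  ~20-site studies where it passes convergence and recovery checks.
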