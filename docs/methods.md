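# Methods

`raretaxa` implements a complete abundant/rare-taxa analysis of microbial
community survey data: rarity classification, diversity and niche breadth,
distance-decay and Mantel biogeography, null-model community-assembly
inference (NTI, NST), and co-occurrence network analysis with
module-environment regressions. This note records the statistical
definitions, the defaults and why they are what they are, and what the
bundled synthetic scenarios do and do not demonstrate.

## Input model and preprocessing

The pipeline starts from a rarefied-or-rarefiable OTU count table
(samples × OTUs), per-sample metadata (site coordinates plus pH, OM, TN,
AP, AK, NH4-N, NO3-N in soil units, and MAT/MAP climate values), and
optionally a rooted, branch-length-bearing phylogeny whose tips cover the
OTU set.

- **Rarefaction** subsamples each sample's counts without replacement to a
  common depth (one multivariate-hypergeometric draw per sample, the
  `rrarefy` semantics). Samples whose totals fall below the depth are
  dropped with a warning. A single rarefied table feeds all downstream
  stages; we do not average over repeated rarefactions.
- **Prevalence filtering** (used only before network construction) keeps an
  OTU iff it is detected in at least `ceil(f·n)` samples, default f = 1/5 —
  8 of 36 samples at the reference design.

## Rarity classification

Each OTU's minimum m and maximum M relative abundance across samples place
it in exactly one of six regions, with abundant_cut = 1% (closed bound, ≥)
and rare_cut = 0.01% (open bound, <):

| m ≥ 0.01% | condition on M | category |
|---|---|---|
| yes | m ≥ 1% | AAT (always abundant) |
| yes | M ≥ 1% | CAT (conditionally abundant) |
| yes | M < 1% | MT (moderate) |
| no | M ≥ 1% | CRAT (conditionally rare and abundant) |
| no | 0.01% ≤ M < 1% | CRT (conditionally rare) |
| no | M < 0.01% | ART (always rare) |

AT = AAT∪CAT and RT = ART∪CRT are the comparison aggregates. The CAT
definition requires m ≥ rare_cut in *all* samples (the only reading that
yields a clean partition of the min/max plane; looser "most samples"
phrasings found in the applied literature do not partition). Summary
percentages are 100·count/total rounded half-up to two decimals.

## Diversity and niche breadth

Richness is the positive-count OTU number; Shannon H = −Σ p ln p in nats
(the R vegan convention). Beta diversity uses Bray-Curtis on counts and
Jaccard on presence/absence; "box-plot" beta diversity is the full set of
within-group pairwise dissimilarities. Levins niche breadth per OTU is
B = 1/Σᵢ qᵢ², qᵢ the OTU's across-sample abundance distribution; B runs
from 1 (single-sample specialist) to n (even generalist) and is invariant
to rescaling the OTU's counts. Group contrasts use two-sided Mann-Whitney
U tests (exact when both groups ≤ 8 without ties, else the tie-corrected
normal approximation), Benjamini-Hochberg adjustment across pairs, and an
insert-and-absorb compact letter display at α = 0.05. Per-OTU (not
community-weighted) niche breadth is the default reporting unit.

## Biogeography

Geographic distances are haversine great-circle distances (Earth radius
6371 km). Environmental variables except pH are log(x+1)-transformed, then
all are z-standardized; environmental distance is Euclidean over the
retained variables. Collinearity screening iteratively drops the variable
with the largest VIF (1/(1−R²) against the others) until all VIF ≤ 10,
breaking ties toward the largest column index.

The distance-decay relationship (DDR) is the OLS fit of community
*similarity* (1 − Bray-Curtis) on distance over all n(n−1)/2 unordered
pairs; dispersal limitation and environmental filtering both appear as
negative slopes. The parametric p-value is reported with a logged caveat
that pairs are non-independent; the Mantel test is the permutational
complement.

The Mantel statistic is the Spearman correlation of the two condensed
distance vectors; significance is one-sided ("greater", the vegan
convention) under simultaneous row/column permutation of the second
matrix, p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm). The partial Mantel
statistic is the first-order partial correlation computed from the three
pairwise Spearman correlations, permuting the second matrix. When the
tested matrix coincides with the control the partial correlation is
defined as 0. The per-variable Mantel table tests community dissimilarity
against single-variable Euclidean distances, one variable at a time.

db-RDA embeds the community distance matrix by PCoA (negative eigenvalues
discarded with their magnitude logged; Lingoes correction is not applied by
default) and regresses the coordinates on environmental predictors. Forward
selection adds, at each step, the candidate with the best Ezekiel-adjusted
R² gain, admitted when a permutation test at α = 0.05 passes. The null
distribution is the *maximum* pseudo-F over the remaining candidates —
a max-statistic test that corrects the selection bias of testing only the
best-of-k candidate, keeping the per-step false-selection rate near α under
pure noise (an uncorrected marginal test selects spurious variables at
roughly k·α).

Variation partitioning reports adjusted-R² fractions from db-RDA on the
selected environmental variables, on the geographic representation
(latitude and longitude as two predictor columns; dbMEM eigenvectors are
deliberately not the default since a 12-site design yields few usable
spatial eigenvectors), and on their union: env-only = R²(both) − R²(geo),
geo-only analogous, shared = R²(env) + R²(geo) − R²(both), residual =
1 − R²(both). The shared fraction can be negative (suppressor predictors);
the four fractions always sum to 1.

## Community assembly

**MNTD/NTI.** The mean nearest taxon distance of a sample averages, over
its ≥ 2 present OTUs, each OTU's patristic distance to the closest other
present OTU (optionally abundance-weighted; unweighted by default, the
picante `ses.mntd` default). The null model shuffles tip labels among the
analyzed table's OTUs — equivalently permutes the patristic matrix —
recomputing every sample's MNTD per shuffle (999 by default).
NTI = −(MNTD_obs − mean_null)/sd_null, so phylogenetic clustering gives
NTI > 0 and |NTI| > 2 marks a significant departure. Samples with a
zero-spread null (e.g. star phylogenies) are flagged NaN rather than given
an arbitrary value.

**NST.** The normalized stochasticity ratio compares each sample pair's
observed dissimilarity D (Bray-Curtis or Jaccard) with its expectation E
under a null that preserves per-sample richness, draws taxa with
probability proportional to regional occupancy frequency, and assigns
abundances proportional to regional relative abundance (the
proportional-occupancy, fixed-richness "PF" algorithm; 1000 null draws by
default). Per pair, selection strength SS = (E−D)/E when D < E (selection
toward similarity) and (D−E)/(1−E) otherwise, and NST = 1 − SS clamped to
[0,1]: agreement with the null scores 1 (stochastic), either deterministic
extreme scores 0, and 0.5 is the conventional boundary. Group values are
reported per pair (the box-plot distribution) with the group mean
alongside.

A structural caveat found while validating on synthetic data: a community
of exchangeable multinomial draws from one fixed pool reads *more
deterministic* than the PF null when sampling is very deep relative to the
pool, because the null occasionally excludes a dominant taxon while deep
observed samples never do. NST's "stochasticity" is identity turnover; to
emulate it, sampling intensity matters as much as process strength (see
the generator notes below).

## Co-occurrence networks

Edges are Spearman correlations (average ranks for ties; t-approximation
p-values, appropriate at n = 36 where exact enumeration is infeasible)
computed for all OTU pairs of the prevalence-filtered table, BH-adjusted
over the full upper triangle, and retained iff |ρ| > 0.6 **and** q < 0.01.
Constant OTU vectors are excluded with a warning. Node metrics are
unnormalized betweenness, within-component closeness, and per-component
power-iteration eigenvector centrality (tol 1e-10, max 10⁴ iterations;
non-convergence raises, naming the component). Global metrics are the mean
local clustering coefficient (zero for degree < 2 nodes), the mean
shortest path over the largest component, and Newman modularity of the
Louvain partition (resolution 1.0, seeded); the random reference is an
Erdős–Rényi G(n, m) ensemble. The scale-free diagnostic is the R² of
log10 frequency vs log10 degree over the integer degree distribution with
zero-frequency bins dropped, defined for ≥ 3 distinct positive degrees.

Louvain in networkx iterates over node sets internally, so its result can
depend on the interpreter's per-process hash seed even with a fixed RNG
seed; `raretaxa` runs it on a sorted-integer relabeling of the graph,
making partitions reproducible across processes. Eigenvector centrality is
likewise computed on an insertion-ordered copy of each component because
subgraph views iterate node sets.

Modules are ranked by mean abundance — the mean over samples of the summed
relative abundance of member OTUs — and the top four are the major
modules. For module-environment regressions, counts are TMM-normalized
(reference sample = upper quartile closest to the mean upper quartile;
M-values doubly trimmed 30%/5% with A-values; inverse-asymptotic-variance
weights; factors rescaled to geometric mean 1 — verified against edgeR to
six decimals during development) and expressed as counts per million. The
response per (module, aggregate) is the per-sample accumulated CPM of
member OTUs in AT or RT, regressed by OLS on pH and MAT with p < 0.05
separating solid from dashed reporting.

## Synthetic-data generator

The generator emulates a 12-site × 3-replicate regional survey with a
lognormal(μ = 0, σ = 2) regional pool. The default pool size and depth are
2737 OTUs at 43,991 reads per sample — the scale of a rarefied fungal ITS
survey — which gives ≈ 10-16 reads per pool OTU and a long tail with
≥ 60% of OTUs below 0.01% mean relative abundance, so RT dominates the
classification as in real surveys. The bundled scenario presets use a
300-OTU pool at depth 3000, preserving that per-OTU sampling intensity:
oversampling a small pool suppresses the neutral sampling variance that
the stochastic scenarios rely on.

Three latent processes with strengths in [0,1]:

- **Environmental filtering**: Gaussian niche response on z-standardized
  MAT and pH with optima simulated by Brownian motion on the generated
  birth-death tree (birth 1.0, death 0.5), giving phylogenetically
  autocorrelated niches; weight = exp(−2s·mismatch²). Strong filtering
  therefore produces both env-driven composition and phylogenetic
  clustering — making NTI > 2 achievable by construction.
- **Dispersal limitation**: each OTU originates at one site and its
  expected abundance decays as exp(−s·d/150 km) with distance from it.
  Sites sit on a ~1000 km box, so distances span the range where decay is
  visible.
- **Planted modules**: blocks of mid-to-high-rank OTUs share a random
  lognormal site-preference profile, producing correlated abundances that
  the network stage should recover as modules.

Samples are single multinomial draws at the configured depth from the
per-site expected composition (pool × filter × dispersal × module
preference, renormalized), so every sample total equals the depth exactly
and replicate variation is purely multinomial. All latent quantities are
returned in a ground-truth record that serializes to JSON; regeneration
from the same config is bit-identical.

What the presets do *not* emulate: compositional sequencing artifacts,
overdispersion beyond multinomial, taxon interactions (modules are
site-preference-driven, not mechanistic), temporal dynamics, or realistic
phylogenetic signal in abundance. Passing the recovery suites shows the
statistics respond correctly to their target signals at survey scale, not
that they are calibrated for any particular real dataset.

## Determinism and problem sizes

Every stochastic step takes a seed; the pipeline derives per-stage streams
from one master seed by hashing stage names, and records them in the run
manifest. Two runs with the same config produce byte-identical tables.

Library defaults are 999 permutations (Mantel, db-RDA), 999 NTI nulls and
1000 NST nulls. The pipeline config and the bundled scenario analyses use
reduced counts (199/99 permutations, 199 NTI nulls, 100 NST nulls) —
enough for the effect sizes the scenarios are built to produce, where the
recovered signals sit far from their decision boundaries (e.g. mean NTI
≈ 4, NST ≈ 0.33 vs 0.74 on either side of 0.5).

## Known limitations

- DDR p-values are parametric and anti-conservative under pair
  non-independence; use the Mantel test for inference.
- The NST implementation fixes the null algorithm to PF; the other
  richness/abundance constraint combinations of the original framework are
  not exposed.
- Closeness centrality is within-component; comparing values across
  components of very different sizes is not meaningful.
- The classification operates on one rarefied table; rarefaction noise
  near the 0.01% boundary can move borderline OTUs between ART/CRT/MT.
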