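# Methods

This note documents the models and procedures implemented in
`methanocoexist`, the tunable parameters and their defaults, what the
synthetic generator does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## 1. Ensemble co-occurrence inference

Each site's OTU × sample table is closed to per-sample relative
abundance. Pairwise association is scored by four measures: Pearson and
Spearman correlation of the two OTUs' relative-abundance profiles;
Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) of the profiles; and
symmetrized Kullback–Leibler divergence ½[KL(p‖q) + KL(q‖p)] of the
profiles normalized to distributions, with zeros replaced by a
pseudocount (half the table's smallest nonzero relative abundance by
default, `kl_pseudocount` to override).

**Candidate windows.** Per measure, the `n_pos_edges` strongest
positive-direction and `n_neg_edges` strongest negative-direction pairs
are candidates (defaults 1000/1000). Correlations carry their own sign;
dissimilarities do not, so the smallest values are the strongest
positive (co-presence) candidates and the largest the strongest negative
ones. On small instances the two dissimilarity windows can overlap; a
pair inside both is assigned the side where its rank is stronger and
dropped on an exact tie. Ties at a window's cutoff rank are all kept.

**ReBoot significance.** The null distribution permutes each OTU of the
pair across samples independently and re-closes every sample to sum 1
before re-scoring ("renormalized permutation", `n_perm` = 1000). Because
the closure denominators are preserved in the null, correlation induced
purely by compositionality is reproduced there and does not register as
signal. The one-sided p-value is (1 + #{null at least as extreme in the
candidate direction}) / (n_perm + 1). A bootstrap distribution (`n_boot`
= 1000 sample resamples) vetoes the edge (p forced to 1) unless at least
95% of bootstrap scores lie on the observed side of the null mean
(`bootstrap_veto`); this encodes the two published roles of the scheme —
the permutation null carries significance, the bootstrap carries
direction stability. `n_perm < 100` is rejected as too coarse.

**Brown's merge.** The four measure-specific p-values are dependent
(they score the same pair). T = Σ −2 ln pᵢ is referred to a scaled
chi-square with E[T] = 2k and Var[T] = 4k + 2 Σᵢ<ⱼ cov(−2 ln Pᵢ,
−2 ln Pⱼ); the covariances are estimated from null p-value columns
computed under the *same* permutation draws for all four measures, which
is what makes the dependence estimable. Degenerate variance estimates
fall back to Fisher's method (logged). Benjamini–Hochberg step-up over
one network's candidates retains edges with q < `alpha` (0.05), and an
edge finally survives only with candidate support from all four measures
in one consistent direction (candidate-set support, pre-merge; the
post-BH alternative can be built from the per-measure p-values the edge
records carry).

**Topology.** Eight attributes per network: node and edge number,
modularity (deterministic greedy agglomeration on the unsigned graph —
no random restarts, so runs are reproducible), positive/negative edge
counts, average clustering (degree < 2 contributes 0), and diameter and
characteristic path length on the largest connected component (both are
infinite on disconnected graphs, and surveys report finite values). The
cross-site **network index** is the first principal component of the
z-scored attribute matrix (constant columns dropped), sign-fixed to
correlate positively with edge number; the explained-variance fraction
is reported alongside.

**Per-site preprocessing.** OTUs with ≤ `min_total_reads` (2) total
reads are dropped globally — the read-count filter applied to the
underlying survey data is ambiguous between < 2 and ≤ 2, so the cutoff
is a config knob with ≤ 2 as default. Within a site, OTUs present in
fewer than `site_min_prevalence` samples are not scored (default 3;
the scaled profile uses 5 of 8 — correlations over sparser profiles at
n = 8 are dominated by coincident zeros).

## 2. Coexistence groups and keystones

Edge identity is the lexicographically ordered OTU pair, ignoring sign:
the frequency classification counts connections between pairs, not
signed connections, and a pair positive at one site and negative at
another still represents one coexistence link (direction conflicts are
visible in the per-site edge lists). Frequencies over the local networks
are binned at thresholds (1, 3, 10, 20): frequency 1 → always endemic,
(1,3] → conditionally endemic, (3,10] → moderate, (10,20] →
conditionally common, > 20 → always common; there is no special "in all
networks" bin. Group proportions are percentages to two decimals; each
group's related OTUs are the union of its edges' endpoints, and the
keystone set is the de-duplicated union over the two common groups.
For 6-network scaled runs the analogous binning (1, 2, 3, 4) is used.

## 3. Phylogenetic null models

MNTD is the mean distance from each present taxon to its closest other
present taxon on the cophenetic matrix (optionally abundance-weighted —
the convention in the source analyses is unstated, so weighting is off
by default for MNTD); ses.MNTD is its z-score under taxa-label
shuffling (NTI = −ses.MNTD). βMNTD is the between-community analogue,
abundance-weighted by default, with shared taxa contributing distance 0;
βNTI is its z-score under `n_null_phylo` (999) label shuffles with
abundances fixed. The literal asymmetric rule is applied: z > 2 or
z ≤ −2 is deterministic, so a value exactly at −2 is deterministic and
exactly at +2 is stochastic; `symmetric_cutoff` switches to |z| ≥ 2.

Degenerate nulls (e.g. a community saturating the pool, or two
identical communities whose shared taxa pin βMNTD at 0 under every
relabeling) return NaN and are counted as skipped, with a tolerance of
1e−12 relative spread so that accumulated rounding is not mistaken for
variance.

**Pool choice for per-group assembly.** `group_assembly` subsets the
table to a group's related OTUs and, by default, shuffles labels within
that group's own tip pool — the pruned-tree convention, equivalent to
handing the subset table to the standard phylogenetic tooling. This
conditions on group composition and measures how the group's taxa
assemble across samples. Shuffling across the whole table's tips
(`assembly_pool = "table"`) is also available, but it conflates
incidental phylogenetic clustering of the group's membership with its
assembly signal: a randomly chosen but incidentally clustered OTU set
then reads as "deterministic" even under fully neutral abundances. The
sample-pair universe is all within-dataset pairs; `max_pairs` evaluates
a random subset when the quadratic cost is not worth paying.

## 4. Biogeography

Richness counts present OTUs; Shannon uses natural log (as does every
logarithm in the package). Bray–Curtis β-diversity is computed on
per-sample relative abundances (raw-count option available); it is
bounded in [0,1], symmetric, zero on the diagonal — the triangle
inequality is *not* asserted, Bray–Curtis not being a metric.
Geographic distance is great-circle with Earth radius 6371 km. The
distance-decay slope is OLS of ln(1 − BC) on ln(km) over unordered
pairs inside half-open windows [min, max) km — local (0.001–0.1),
meso (0.1–50), regional (100–3500); a pair at exactly 0.1 km falls in
the meso window. Pairs with zero similarity or zero distance cannot
enter a log-log fit and are dropped with their count reported; fewer
than 3 qualifying pairs flags the scale unavailable. The CH₄
production-potential utility converts an incubation OLS slope from
per-hour to per-day (×24).

## 5. Function and contribution

GeoChip preprocessing: spots with SNR < 2 are zeroed; per sample,
signals are divided by total detected intensity, multiplied by a
constant (10⁶) and ln(1+·)-transformed; within each site's replicate
set, probes detected in ≤ `detection_min` (2) samples are treated as
undetected there ("detected in only two out of eight samples" is
ambiguous between <2, =2 and ≤2; ≤2 is the default and the knob is
exposed), and probes undetected everywhere are dropped. The
normalization is skipped on re-application, making the function
idempotent.

Random-forest contribution: predictors are z-scored; importance is
permutation importance (mean MSE increase over 10 shuffles per
predictor, computed with one stacked predict call); significance comes
from `n_perm_sig` response-permutation refits, p = rank of the observed
importance in the null importances; model fit is out-of-bag variance
explained. Contributions normalize non-negative importances to 100%
over a predictor subset (negatives clipped, logged). Group-level
features are each group's summed relative abundance per sample — the
simplest faithful encoding, swappable for e.g. per-group edge counts.

The functional network stacks keystone abundances (pass them relative
to the *whole* community; re-closing a small keystone subset to sum 1
would replace abundances with within-subset shares and decouple them
from the gene signals) with gene probe signals and runs the same
ensemble inference. Edge weight is |mean of the Pearson and Spearman
scores|, summed within gene–gene, species–gene and species–species
categories; the weight rule is declared here, not claimed to match any
particular published sum.

## 6. The synthetic generator

The generator emulates the statistical structure the analysis assumes
of a continental paddy-soil survey; its defaults mirror the study
design (39 sites × 11 samples; tests and examples run at 6 × 8 with 64
OTUs for speed, with candidate windows scaled to 300 via
`PipelineConfig.scaled()` to keep the same few-percent admission rate).

* **Phylogeny**: a pure-birth (Yule) tree, simulated directly with a
  seeded numpy generator (one rate parameter, ultrametric — the
  nearest-taxon statistics only need a distance structure with
  heritable signal).
* **Sites**: centers uniform in a lat/lon box spanning roughly
  19.5–47 °N, MAT linear in latitude over (1.5, 23.8) °C and constant
  within a site; samples jittered within a 100 m plot.
* **Niche structure**: thermal optima evolve by Brownian motion on the
  tree; the realisation is standardized in shape and given amplitude
  √(trait_signal) · range/4 around the mid-range, clipped to the range.
  Tying the amplitude to `trait_signal` (rather than rescaling every
  realisation to the full range, which would cancel the parameter) is
  what makes the niche-determinism dial monotone; trait_signal → 0
  collapses all optima to the mid-range, the neutral limit. Expected
  log-abundance of OTU i in sample j is
  baselineᵢ − (MATⱼ − oᵢ)² / 2σᵢ², plus i.i.d. lognormal noise
  (`noise_sd`, 0.5); per-OTU baselines (sd 1.5) create the stable
  background dominants real communities have. σ is global
  (`niche_breadth`, 6 °C) with per-OTU overrides.
* **Planted coexistence**: designated pairs share a per-sample latent
  factor (loading `pair_weight` = 1.5) at all sites (common) or one
  site (endemic), injected *before* multinomial sampling so the signal
  must survive compositional closure — exactly the bias the
  renormalized permutation null addresses. Consortium modules
  (4 modules × 5 OTUs, loading 1.2) share a global factor and supply
  the bulk of genuine edges per network that real co-occurrence
  networks have; without them the multiple-testing step would operate
  against an unrealistically sparse truth and collapse. Planted taxa
  are selected *conditional on* the evolved optima (optima-adjacent
  tips near the relevant temperature; common pairs near mid-range,
  endemic pairs near their site's MAT, `common_span="guilds"` selects
  clade-coherent thermal guilds spread along the gradient), never by
  overriding optima — overriding would sever the phylogeny–trait
  association the assembly statistics detect. Planted taxa are pinned
  to modest baselines so their factor swings cannot shake the
  compositional denominator and induce spurious correlation among
  unrelated rare taxa. Tie-breaks in taxon selection are randomized
  because tip labels follow tree traversal order.
* **Counts**: multinomial per sample at fixed depth (default 5000;
  scaled runs use 800–2000), so every column sums exactly to depth.
* **CH₄ response**: site-level
  ch4 = β₀ + β_net·x_net + β_div·x_div + β_MAT·MAT + ε, with defaults
  (10, 3, 1.5, 0.2, sd 1) chosen so the network term dominates the
  realized variance (the index is unit-scale while raw MAT spans
  ~22 °C), matching the predictor structure the contribution analysis
  is meant to recover.
* **Gene signals**: nonnegative linear combinations of keystone
  relative abundances plus Gaussian noise, clamped at zero.

What the generator does *not* emulate: sequencing error, chimeras and
primer bias; taxonomic structure beyond the tree; soil-chemistry
dynamics (soil covariates are independent site-level draws); temporal
dynamics; and negative associations (planted structure is positive —
negative edges arise only through closure). Passing tests therefore
show that the pipeline recovers the *kind* of structure it assumes, at
the stated effect sizes, through compositional closure and multiple
testing — not that any particular field dataset has that structure, nor
that effect sizes in real paddies are as strong.

## 7. Scaled test conditions

Tests and the acceptance script run at 6 sites × 8 samples. Two cutoff
translations from the 39-network scale are applied: the common-link
recovery criterion "frequency > 10 of 39" becomes "≥ 3 of 6"
(proportional; > 10 is unattainable with 6 networks), while the endemic
criterion "frequency ≤ 3" applies as stated. The qualitative assembly
contrast uses two dedicated scenarios: *filtered* (guild-structured
common taxa with σ = 2, unfiltered endemic taxa with σ = 40, depth 800)
and *neutral* (no trait signal, no planted weights, per-sample noise
only — drift-like turnover; fixed per-OTU dominance would otherwise
bias βNTI whole-seed-wise because the same incidentally-clustered
dominants recur in every sample). Problem sizes throughout (200
replicates for null calibrations, 400 sample pairs and 499
randomizations for assembly fractions, 150-tree forests with 19
response permutations) are chosen to give stable statistics on one CPU.

## 8. Determinism

Every random draw flows from one master seed through named substreams
(`config.rng("network:S07")` etc.), so a stage re-run alone reproduces
the draws it saw inside a full run, and two full CLI runs with the same
seed produce byte-identical outputs (numeric text is written with 6
significant digits). Seeds derived for substreams stay below 2³¹.

## 9. Known limitations

* The renormalized permutation null mitigates but cannot fully remove
  closure-induced dependence; heavily dominated communities can still
  leak weak spurious edges (visible as the endemic pairs occasionally
  recovered in one extra network).
* βNTI on highly overlapping communities is numerically fragile — the
  shared-taxon mass is invariant under relabeling, so the null variance
  shrinks; such pairs are skipped (counted) rather than imputed.
* The per-group determinism fractions depend on the null pool
  convention (Section 3); both conventions are implemented and the
  choice is explicit in the config.
* `rf_importance` refits the forest once per response permutation;
  significance at the default 100 permutations has resolution ~0.01
  and is the slowest step of the contribution stage.
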