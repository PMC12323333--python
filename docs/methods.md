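# Methods

`rhizonet` re-implements, as a tested library, a drought-gradient analysis
of a rhizosphere fungal community: per-treatment co-occurrence networks
from genus-level amplicon counts, network topology and core-taxon
profiling, alpha diversity and differential-abundance screening, Mantel
and correlation analyses against leaf physiology and root metabolites, and
an LDA-effect-size screen for differential metabolites.  Because raw reads
are not required for any of these stages, the package ships a synthetic
study generator with recorded ground truth; every stage is validated by
recovering planted structure rather than by inspection.

## Study design emulated

Six watering treatments — a watered control plus five drought stages of
increasing severity (`control, drought1 .. drought5`) — with six
biological replicates each (36 samples).  Per sample: genus-level fungal
counts, a six-indicator leaf physiology panel (AsA, GSSG, MDA, Pro, SOD,
SS, in assay-kit units), and untargeted root-metabolite intensities.

## Co-occurrence networks (the core computation)

For each treatment separately (scope configurable to global):

1. **Prevalence filter.** A genus is retained iff it is detected in
   *strictly more than* 80% of the in-scope samples.
2. **Spearman correlation** on relative abundances, average ranks for
   ties.  p-values use the t-distribution approximation by default; an
   exact permutation mode (all n! sample permutations, vectorized with a
   null-distribution cache keyed by rank multisets) is available for
   n ≤ 9.  Constant genera have undefined correlation and are reported as
   missing, never as 0.
3. **Edge rule.** Edge iff |ρ| > 0.6 (strict) AND p < 0.05 (strict).  No
   multiple-testing correction by default (a BH option exists).  Isolated
   genera are dropped from the node set, so node counts vary by treatment.

With n = 6 samples per treatment, p < 0.05 already forces |ρ| ≳ 0.83, so
the significance rule is the binding constraint at study size; the 0.6
threshold binds only for larger n.  Note that at any n the rule admits
roughly α·(pairs) spurious edges — plain pairwise Spearman has no
network-wide error control, and compositional closure (proportions sum to
1) adds a deterministic negative correlation between dominant taxa.  Both
effects are properties of the method being reproduced, not defects of the
implementation; compositionality-aware estimators are out of scope.

**Topology.** Node/edge counts; average degree 2E/N (this identity alone
reproduces the printed average degree of all six published network sizes
to 3 decimals, validating the undirected simple-graph convention);
modularity of the best partition over 8 seeded Louvain restarts at
resolution 1.0 (Louvain is a stochastic heuristic; best-of-restarts is the
standard stabilization — on ≤ 8-node graphs the returned partition attains
the exhaustive-partition optimum in ≥ 90% of random instances and never
exceeds it); mean local clustering with 0 for degree < 2 nodes; average
shortest-path length over connected ordered pairs and the diameter over
the same pair set (undefined quantities are NaN).  Unweighted by default,
with a weighted flag.

**Core taxa.** Core = nodes at or above the q-quantile (default q = 0.9,
numpy linear quantile, boundary ties included) of *both* degree and
closeness centrality.  Three closeness variants are computed: classic
per-component closeness, the Wasserman–Faust component-size-scaled
closeness, and harmonic closeness.  The core rule uses Wasserman–Faust by
default: these networks are typically disconnected, and classic
per-component closeness assigns 1.0 to every member of an isolated dyad,
letting trivial satellite components capture the upper quantile and
excluding the genuinely central taxa of the main component.  Classic
closeness remains in every report and can be selected for the rule.

## Synthetic data generator

Counts come from a **Gaussian copula with negative-binomial margins**: per
treatment, a latent multivariate normal with a planted correlation matrix
is sampled per replicate, pushed through Φ to uniforms, and inverted
through NB quantile functions whose means follow per-taxon trend
archetypes (`flat, increasing, decreasing, hump, crash, spike`; default
amplitude 4-fold).  Spearman is rank-based, so the latent correlation
survives the marginal transform up to a small attenuation (~0.02–0.04 at
these count levels).  Library size is drawn log-uniformly in
[10 000, 50 000] per sample and imposed exactly by largest-remainder
rescaling — column sums equal the drawn depths, and all downstream
inference is forced through relative abundances.  NB size (dispersion)
defaults to 10 (CV ≈ 0.32 for abundant taxa).

**Abundance and occupancy.** Baseline relative abundances are heavy-tailed
log-normal (σ = 2.0), giving one dominant genus (~15–30%) and a long rare
tail.  Unstructured taxa additionally get a structural-zero occupancy
drawn from U(0.2, 0.6) except the top abundance decile, which is always
present: occupancy must rise with abundance, because abundance-independent
dropout of a dominant taxon swings sample totals and induces spurious
compositional correlations across the whole community.  Together these
make the 80% prevalence filter selective (typically 60–80 of 150 genera
survive), matching the scale of real genus-level networks.

**Planted correlation structure.** Three layers, all recorded in the truth
record together with the realized (repaired) latent matrices:

- *Pairs*: ten vertex-disjoint taxon pairs at latent ρ = 0.9.  A chain or
  star of 0.9-edges was rejected: the minimal positive-definite completion
  of a 0.9-chain is AR(1), which plants a dense transitive block that
  dominates the centrality rankings, and a 0.9-star is far from positive
  definite.  The pairs are drawn inside the hub partner pool — two guild
  members with loadings λᵢ, λⱼ can be lifted to 0.9 while staying positive
  definite (residual correlation (0.9 − λᵢλⱼ)/√((1−λᵢ²)(1−λⱼ²)) < 1), and
  pair members then live inside the main network component instead of
  forming isolated dyads.
- *Hubs*: two designated hub taxa per treatment anchor a shared latent
  "guild" factor — hubs load at 0.99, 32 partner taxa at loadings spread
  over [0.70, 0.80].  A hub strongly correlated with many *mutually
  uncorrelated* partners is mathematically impossible (Σᵢ ρ(hub,i)² ≤ 1
  for jointly Gaussian variables), so hub-planting necessarily makes
  partners correlate at the loading products; the chosen band keeps
  hub–partner correlations mostly above the edge rule while
  partner–partner products mostly fall below it, making the hubs the
  strict degree and closeness maxima.
- *Repair*: any residual indefiniteness is fixed by eigenvalue clipping
  with unit-diagonal restoration; the generator aborts (naming the
  offending edges) if repair distorts a planted entry by more than 0.05,
  and the maximal distortion is recorded in the truth.

**Physiology.** Treatment-level means follow per-indicator archetypes with
Gaussian replicate noise (CV 0.08): AsA unimodal peaking at stage 3 with a
+21.53% amplitude, GSSG decreasing, MDA and Pro increasing, SOD unimodal
(peak stage 3), soluble sugar unimodal (peak stage 4).

**Metabolites.** Log-normal intensities (cross-feature baseline
log₁₀ ~ N(5, 0.25), within-class log-noise σ = 0.1, i.e. CV ≈ 10% — the
scale of QC-filtered LC-MS features).  Fourteen planted differential
features follow strong treatment trends (fold 10).  Directions are
balanced — features alternate increasing/decreasing/hump/crash down the
baseline-intensity ranking — so the per-sample total stays stable;
unbalanced planting would shift every feature under total-sum
normalization and smear the signal onto null features.  Six further
features are noisy monotone functions of named taxa's relative abundances
(Gaussian-copula-style, target Spearman 0.9), planting recoverable
taxon × metabolite correlations.

**What the generator does not emulate.** Real amplicon artifacts
(chimeras, copy-number variation, taxonomic mis-annotation), batch
effects, non-monotone taxon–metabolite relations, and any coupling between
the fungal community and the physiology panel beyond their shared
treatment ordering.  Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it targets at the stated sample sizes —
not that any particular biological conclusion transfers to field data.

## Statistical screens

- **Diversity**: Shannon index −Σ pᵢ ln pᵢ (natural log; base
  configurable) and observed richness; per-treatment summaries with
  pairwise Mann–Whitney tests, BH-adjusted across pairs.
- **Composition**: top-N (default 20) groups at phylum or genus rank by
  overall mean abundance plus an "Other" bucket; ties break
  lexicographically.
- **Differential abundance**: per-genus Kruskal–Wallis across treatments
  (tie-corrected H, chi-square p; all-identical values give H = 0, p = 1).
  BH q-values are always computed; the significance flag follows raw
  p < 0.05 by default (the common practice this mirrors), with the
  q-decision reported alongside.  A seeded permutation p for H is
  available as a cross-check.
- **Mantel test**: Spearman (default) or Pearson correlation of the upper
  triangles of two sample distance matrices; permutation p with mandatory
  seed, two-sided by default, p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm)
  with 999 permutations by default; exhaustive enumeration of all n!
  relabelings for n ≤ 8.  Distances are Euclidean on group-abundance
  vectors by default; any scipy metric (e.g. Bray–Curtis) is accepted.
  Each permutation costs one gather plus one dot product, because
  relabeling only permutes the condensed-distance multiset.
- **Heatmaps**: cellwise Spearman between features (taxa or group
  abundances) and traits; stars follow raw p (* < 0.05, ** < 0.01,
  *** < 0.001) to match figure-legend convention; BH q over all defined
  cells is written alongside; constant columns yield missing cells.

## LDA effect size screen

One-factor, two stages, on intensities rescaled to a common per-sample
total of 10⁶ (relative-intensity convention).  Stage 1: per-feature
Kruskal–Wallis across treatments, keep p < α (default 0.05).  Stage 2: over
30 class-stratified bootstrap subsamples (fraction 2/3, without
replacement, ≥ 2 per class), compute the between-extreme-class difference
of feature means; with a single feature and a unit-norm discriminant
direction the projected class-mean difference equals the raw one, so the
per-bootstrap score is log₁₀ of that difference and the reported score is
the bootstrap mean.  A feature passes at score ≥ 3.5 (the emulated
screen's threshold; 2.0 is the tool default elsewhere).  The subclass
(pairwise Wilcoxon) stage is omitted — the emulated design is one-factor.
Raising the threshold can only remove features; results are deterministic
given the seed.

## Pipeline, configuration and determinism

`rhizonet run --config config.yaml` executes synth (or reads user tables)
→ community → network → LEfSe → association.  Every threshold the
pipeline applies (prevalence 0.8, |ρ| 0.6, p 0.05, core quantile 0.9,
LDA 3.5, α levels, permutation counts) lives once in the config with the
defaults above; a missing seed is a validation error before any stage
runs.  The manifest records package version, config hash, input hashes,
per-stage row counts and a SHA-256 per output file; two runs with the same
config and seed produce byte-identical outputs (the manifest's stage
timers are the only fields that differ between reruns, which is why
determinism is checked on the recorded output hashes and the files
themselves).

## Numerical choices and edge cases

- Spearman: ranks via average-rank midranks; |ρ| clipped to 1; exact-mode
  permutation p includes the identity permutation (never returns 0).
- Empty prevalence-filtered sets warn and yield empty networks; empty or
  edgeless graphs report NaN for modularity and path metrics.
- Quantiles in the core rule use numpy's default linear interpolation;
  ties at the cutoff are included by the ≥ comparisons.
- PD repair floor 1e-6 on eigenvalues; planted-value distortion tolerance
  0.05.
- Seeds: every stochastic component takes an explicit seed;
  `generate_study` spawns independent child streams for counts,
  physiology and metabolites.

## Problem sizes used in the validation suite

Oracle-equivalence checks run on 1 000 random tied vectors (Spearman),
500 random ≤ 12-node graphs (path metrics vs Floyd–Warshall) and ~40
random ≤ 8-node graphs (Louvain vs exhaustive partition enumeration).
Type-I calibration uses 200 null studies per screen (40-taxa communities,
flat physiology).  Planted-structure recovery uses 50 default studies
(edge recovery on all 36 samples pooled; hub recovery at 12 replicates per
treatment; metabolite screen at study size).  `scripts/acceptance.py`
recomputes the same quantities at moderately smaller Monte-Carlo sizes
(25–100 repetitions), chosen to keep a full from-scratch rerun fast.

## Known limitations

- Pairwise Spearman networks inherit compositional bias; the dominant-taxon
  closure correlation is visible in the generator's own null (it is the
  method's property, and the reason prevalence filtering is essential).
- The t-approximation for Spearman p at n = 6 is coarse; the exact mode
  exists but the study-size behavior (p < 0.05 ⇔ |ρ| ≳ 0.83) makes the
  difference immaterial to the edge rule.
- The LDA score reduces to a bootstrap-averaged log₁₀ mean difference in
  the one-feature case; multivariate discriminant weighting (as in joint
  LDA over all features) is intentionally not implemented.
- Core-taxon calls at q = 0.9 are a ranking statistic: on very small
  networks (< 20 nodes) the quantile cutoffs are dominated by ties and
  should be interpreted loosely.
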