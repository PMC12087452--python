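# Methods

`ruminate` implements a longitudinal analysis of gut-microbiome succession
around calving in dairy cattle: community-state typing, Markov-chain
succession staging, phylogenetic-bin null-model assembly partitioning,
compartment coupling, and microbe → pathway → phenotype mediation. This
note records the models, their assumptions, the numerical choices, and what
the synthetic-data validation does and does not demonstrate.

## Data model

All analyses consume a `FeatureTable` (integer counts, samples × taxa), a
`CohortDesign` (subject, day relative to calving with negative = prepartum,
habitat, covariates, serum phenotypes), and optionally a rooted `Phylogeny`
with branch lengths. The day grid is data-driven; nothing assumes the
−21/1/3/7/14/21 schedule beyond the defaults of the simulator. Rarefaction
is multivariate-hypergeometric subsampling without replacement (zero counts
stay zero; samples under the target depth are dropped, not padded), with
`depth="min"` rarefying to the shallowest library.

## Community-state typing (Dirichlet-multinomial mixture)

Samples are clustered by a finite mixture whose components are
Dirichlet-multinomial (DM) distributions — the standard "community state
type" model for overdispersed count compositions. Fitting is EM:

* E-step: exact responsibilities from the component DM log-likelihoods
  (multinomial coefficients are constant in the parameters and across K and
  are omitted everywhere).
* M-step: mixture weights in closed form; each component's concentration
  vector by a small number of weighted Minka fixed-point iterations. The
  fixed point is a minorize–maximize step, so the observed-data
  log-likelihood is non-decreasing across EM iterations (asserted to 1e-8
  relative tolerance in the tests).
* Initialisation: seeded k-means on relative abundances, responsibilities
  softened to 0.95/0.05; concentrations start at 20 × the component mean
  composition. `select_k` restarts each K (`n_init`, default 3) and keeps
  the best likelihood.

K is chosen by the lowest Laplace-approximation score (negative log model
evidence). The evidence is evaluated in log-concentration space with a weak
log-normal prior, η = log α ~ N(0, 3²), and a flat Dirichlet prior on the
mixture weights; `d = K·n_taxa + (K−1)` parameters. The per-component
Hessian is rank-one plus diagonal and is evaluated exactly with the matrix
determinant lemma; the mixture block uses the multinomial observed
information. The prior matters: with a flat prior on α the evidence of
near-empty components is inflated (their concentration parameters are
weakly identified, so the curvature term contributes almost no penalty) and
K selection drifts upward. The N(0, 3²) prior is weak — it spans roughly
e±9 in concentration — but bounds the determinant away from zero.

Cluster "driver" taxa are ranked by a descriptive score: the
Kruskal–Wallis H of a taxon's relative abundance across clusters, signed
and scaled by the cluster's mean-abundance excess over the grand mean.
This is a defined stand-in for LDA-effect-size style ranking, not a claim
of equivalence to it.

## Markov succession and staging

Per consecutive grid-day pair, a subject contributes one transition if it
has labelled samples at both endpoints; subjects missing either endpoint
are skipped and counted (no two-step imputation). Interval count matrices
are retained (the per-interval view) and summed into a pooled,
time-homogeneous chain whose row-normalised matrix is the maximum
likelihood transition estimate.

Stages follow a threshold rule applied in order: self-transition rate
below 0.20 → *rapid transition*; self-rate at or above 0.50 and a mutual
exchange rate of at least 0.30 (both directions) with some other
stable-eligible state → *stable*; otherwise *transition*. A stable-eligible
state with no reachable eligible partner (zero exchange both ways) is
absorbing and therefore stable. The three thresholds are descriptive
conventions, exposed as parameters.

The stage classifier is a random forest on relative abundances of taxa
with mean relative abundance above 0.1%. Evaluation is five repeats of a
stratified 70/30 hold-out with macro one-vs-rest AUC on the held-out 30%;
an optional `top_n` refits each repeat on its most important features.
(The cross-validation description this follows is internally inconsistent
in its source — "five 10-fold cross-validations … 70% / 30%" — so the
repeated hold-out is the primary scheme and the fold machinery is not
duplicated inside it.)

## Assembly partitioning (phylogenetic-bin null models)

Taxa are grouped into bins of at least `ds = 24` members by scanning the
average-linkage hierarchy of cophenetic distances for the lowest cut that
maximises the number of size-≥ds clusters, then merging undersized
clusters into the phylogenetically nearest large bin. This is
deterministic and invariant to taxon input order.

Per sample pair and bin:

* **βMNTD / βNTI** — abundance-weighted mean nearest-taxon distance
  between the two communities, restricted to the bin; the null shuffles
  taxon labels across the bin's tips (one permutation of the bin's distance
  submatrix per draw, shared by all pairs); βNTI is the z-score against
  `n_null` draws (default 1,000; 200 in the validation harness). If the
  null spread is zero the observation cannot deviate and βNTI is 0.
* **RC (modified Raup–Crick)** — the observed within-bin Bray–Curtis
  against nulls that redistribute each sample's bin total over the bin's
  taxa at the pooled taxon frequencies (per-sample totals preserved
  exactly); `RC = 2(frac_below + 0.5·frac_ties) − 1 ∈ [−1, 1]`.

Process calls use the conventional thresholds, in order: βNTI < −1.96
homogeneous selection, > +1.96 heterogeneous selection; otherwise
RC < −0.95 homogenizing dispersal, RC > +0.95 dispersal limitation, else
drift. Aggregation weights each bin by the mean of the pair's two relative
bin abundances, normalised within the pair, so per-pair, per-bin and
overall fractions each sum to one exactly. `compare_groups` tests process
contributions across sample groupings (stages or timepoints) with
Kruskal–Wallis and BH-adjusted Dunn post hoc over within-group pairs.

### What the validation scenarios emulate

The scenario generator builds communities assembled under a single pure
process on a shared tree model: two deep clades, each containing tight
clusters (pure-birth subtrees, branch lengths ×0.02) on mutually
equidistant stems. That shape mirrors the rate heterogeneity of real
phylogenies and makes the clade-respecting binning deterministic (two
60-taxon bins at the 120-taxon default).

* *Selection*: a fixed clade-level fitness trait admits only the top 30%
  of clusters; each admitted clade establishes at least one member per
  sample and each member establishes with probability 0.45, with mild
  log-normal abundance noise at depth 2,000. Turnover between samples is
  therefore phylogenetically shallow — a missing taxon is replaced by a
  close relative — and βNTI is strongly negative.
* *Drift*: neutral multinomial resampling of one near-even metacommunity
  (Dirichlet concentration 20) at depth 40. The shallow depth keeps
  occupancy sparse so each pair's z-score varies independently; this is
  the regime in which the null calibration (mean ≈ 0, sd ≈ 1) is
  evaluated. Because pairs sharing a sample are correlated, the
  calibration is assessed pooled over replicate cohorts (ten cohorts,
  ~8,700 z values), not within one cohort.
* *Dispersal limitation*: each sample assembles from the cophenetic
  neighbourhood of its own random seed taxon, producing turnover far above
  the compositional null.

These scenarios demonstrate that the estimator discriminates pure
processes at desk scale (30 samples, 120 taxa, 200 nulls). They do not
emulate mixed processes, varying depths within a cohort, or the
thousands-of-taxa bins of real amplicon data, where the within-bin null
has substantially more power; passing them says nothing about effect
sizes in real communities.

## Diversity, ordination, PERMANOVA, variability

Chao1 is the bias-corrected estimator (`S_obs + F1(F1−1)/(2(F2+1))`);
Shannon uses natural logs (the vegan convention), base configurable; both
delegate to scikit-bio. Bray–Curtis is computed on counts by default
(intended for rarefied tables), with a relative-abundance switch. PCoA is
classical scaling via scikit-bio; negative eigenvalues are dropped and
counted, proportions renormalised over the positive spectrum.

PERMANOVA is implemented in-package because an exhaustive mode is needed:
the pseudo-F from the squared-distance decomposition, with either seeded
Monte Carlo label permutations (`p = (1 + #{F≥F_obs})/(1 + n_perm)`) or
full enumeration of distinct labelings (`p = #{F≥F_obs}/#labelings`,
identity included) — the exact test, verified against an independent
brute-force oracle. Type-I error is calibrated (0.044 at α = 0.05 over
1,000 null draws). A free permutation scheme is the default; repeated
measures in the cohort are not exchangeability-corrected, which inflates
apparent time effects in real longitudinal data and is the caller's
responsibility to restrict.

Individual variability: per subject, *intra* is the median Bray–Curtis
over its within-subject pairs and *inter* the median over its samples
against all other subjects' samples. (A source convention of "20
dissimilarity values per 6 samples" is arithmetically inconsistent with
the 15 within-subject pairs; all pairs are used.)

## Compartment coupling and host links

Procrustes uses the symmetric superposition (both configurations centred
and scaled to unit trace, then rotated/scaled), so M² ∈ [0, 1] and is
invariant to joint rigid motion; significance comes from row permutations
of one configuration. Residual vectors are compared across compartments
with the paired Wilcoxon signed-rank test.

Source tracking is a collapsed Gibbs sampler in the SourceTracker family:
each sink read is assigned to a declared source (posterior-predictive
taxon probabilities from the fixed source counts, prior α₁ = 0.001) or to
an adaptive "unknown" source (own counts, prior α₂ = 0.001), with a
count prior β = 10 per environment on the mixing proportions; defaults
are 100 burn-in sweeps, 25 draws, 10 restarts. Reads are initialised from
the known-source likelihoods: seeding the unknown with a uniform share of
reads hands it the sink's empirical profile and traps the chain in a
local mode that overstates the unknown fraction. `track_fecal_sources`
applies the peripartum design: for each subject and day, the fecal sample
is the sink and its candidate sources are the previous-day fecal sample
and the same-day rumen sample.

EnvFit: continuous covariates score the r² of their least-squares
projection onto the leading ordination axes; categorical covariates the
centroid-separation r² (1 − SS_within/SS_total); p-values by permuting
covariate rows. Constant covariates are reported with r² = 0 and a flag.

RBHB (revised insulin-sensitivity check index with β-hydroxybutyrate) is
`1/(log₁₀ GLU[mg/dl] + log₁₀ INS[μU/ml] + log₁₀ NEFA[mmol/l] +
log₁₀ BHB[mmol/l])`; any non-positive analyte makes it undefined (NaN,
logged). Succession-type phenotype tests pair each subject's stage
transition over an interval with the within-subject phenotype change over
the same interval; types with enough subjects are compared by
Kruskal–Wallis with BH-adjusted Dunn post hoc.

## Mediation

The mediator model `m = a·s + e₁` and outcome model `y = c′·s + b·m + e₂`
give ACME = a·b, ADE = c′ and total = c′ + a·b; the identity
ACME + ADE = total is exact for the OLS point estimates (the total equals
the simple-regression slope of y on s). Species exposures are z-scores of
log₁₀ relative abundance with half-minimum zero replacement, so effects
are comparable across taxa. Inference is a nonparametric bootstrap
(default 1,000 resamples): percentile confidence intervals, and two-sided
p-values from the normal approximation (estimate over bootstrap SE).
Percentile p-values were rejected deliberately: their 2/n_boot resolution
floor makes them useless under BH adjustment across a large screen.
Near-collinear mediators (|r| > 0.999) are flagged; the decomposition is
not interpretable there.

The screen filters species (prevalence > 50%, mean relative abundance
> 0.1%) and pathways (> 50%, > 0.01%), optionally retains only
group-differential features, tests every surviving triple, BH-adjusts the
ACME p-values across the screen, and labels a triple *mediating* (adjusted
ACME p < 0.05) or *full* (ACME, ADE and total all significant), ranked by
|proportion mediated|. Because taxa that co-vary with a true mediator
genuinely carry indirect associations through the same pathway, the
screen's full set can contain correlated proxy species alongside the
planted/true triples; interpretation should treat hits as association
clusters, not isolated causal claims (the usual sequential-ignorability
caveats apply on top).

## Synthetic cohort

`simulate_cohort` draws, per habitat and subject, a latent state path from
the initial distribution and transition matrix, then emits counts from the
state's Dirichlet-multinomial at a log-normal depth (median ≈ 20,000,
σ_log = 0.3, floor 5,000 — a realistic shotgun/amplicon depth range).
Defaults mirror the study design: 91 subjects, days −21/1/3/7/14/21, two
habitats, three states with self-rates 0.15/0.42/0.90 flowing forward
(rapid → transition → stable), 70% of subjects starting in the rapid
state. State concentrations are a shared sparse baseline (0.3) plus a
disjoint per-state block enrichment (+4.0 over ~n/4 taxa), so states share
the bulk community but differ in drivers. Habitat preference is a
Brownian trait on a pure-birth tree, exponentiated into per-taxon
multiplicative factors — phylogenetically conserved, as selection-based
assembly assumes. Phenotypes are drawn around realistic bovine serum
baselines; planted mediation triples write the two-equation model
(defaults a = 0.5, b = 0.4, c′ = 0.2, noise sd 0.5) into a pathway column
and a phenotype, with the truth object recording the slopes on the stored
scale. One global seed expands into independent child streams per
component (tree, paths, counts, depths, traits, phenotypes).

What passing on this cohort shows: the estimators recover planted
structure at study-like sample sizes. What it does not show: robustness
to compositional artefacts absent from the generator (contamination,
batch effects, taxonomic misassignment), to unbalanced designs, or to the
weaker cluster separation of real communities.

## Problem sizes and runtime

The validation suite uses 20 seeded replicates of a 120-subject,
60-taxon, 3-state cohort for K selection (≥18/20 must select K = 3 with
ARI ≥ 0.90); 500 subjects for transition recovery (max-abs error ≤ 0.05 —
note the rapid state's row carries only ~470 observations at these
settings, so this bound sits ~2 se from zero); ten 30-sample, 120-taxon
scenario replicates at 200 nulls for assembly discrimination; 1,000 null
draws for PERMANOVA type-I error; depth-5,000 sinks for source tracking;
and 100 replicates at n = 300 for mediation CI coverage. The full pytest
suite runs in under three minutes and `scripts/acceptance.py` in about 80
seconds on one CPU.

## Known limitations

* The pooled Markov chain assumes time-homogeneity; per-interval matrices
  are exported but the staging rule reads only the pooled chain.
* PERMANOVA and EnvFit permute freely; repeated-measures exchangeability
  restrictions are not imposed.
* The within-bin taxon-shuffle null has limited power in small bins
  (few dozen taxa); negative βNTI saturates near z ≈ −2 unless turnover
  is concentrated in unshared, clade-clustered taxa.
* The DM mixture assumes per-state exchangeability of samples; it ignores
  the subject structure the Markov layer then models.
* Mediation assumes linearity and sequential ignorability; screen hits
  include correlated proxies of true mediators by construction.
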