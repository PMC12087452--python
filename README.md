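# ruminate

Longitudinal gut-microbiome succession analysis for peripartum ruminants.

The three weeks before and after calving are the most metabolically
precarious window in a dairy cow's life: negative energy balance drives
serum NEFA and BHB up, and both the rumen and the hindgut community are
remodelled. `ruminate` is a toolkit for analysing that remodelling from
16S/metagenomic count tables sampled repeatedly per animal in one or two
gut habitats. It is written for microbial ecologists and animal scientists
who want the full chain — from raw count tables to host-phenotype links —
as tested, scriptable Python rather than a collection of R one-offs.

## What it computes

* **Community-state typing** — a Dirichlet-multinomial mixture over taxon
  counts, `x_i | z_i = k ~ DM(α_k)`, fitted by EM with the component count
  K chosen by the lowest Laplace-approximation score (negative log model
  evidence), plus a Kruskal–Wallis-based ranking of each state's driver
  taxa.
* **Markov succession** — per-interval and pooled transition matrices
  `P_ij = C_ij / Σ_j C_ij` over consecutive sampling days, a
  threshold rule mapping states to succession stages (*rapid transition* /
  *transition* / *stable* from self- and mutual-transition rates), and a
  random-forest stage classifier with repeated stratified hold-out AUC.
* **Assembly partitioning** — phylogenetic bins of ≥ 24 taxa; per pair and
  bin the abundance-weighted βNTI (z-score of βMNTD against a
  taxon-shuffling null) and modified Raup–Crick index; each comparison
  assigned to homogeneous/heterogeneous selection, homogenizing dispersal,
  dispersal limitation or drift by the ±1.96 / ±0.95 conventions, with
  abundance-weighted process fractions overall, per bin and per stage.
* **Diversity & variability** — bias-corrected Chao1, Shannon,
  Bray–Curtis, PCoA, PERMANOVA (seeded Monte Carlo or exact exhaustive
  permutation), and Olsson-style intra- vs inter-individual medians.
* **Compartment coupling** — symmetric Procrustes (M² ∈ [0,1]) with
  permutation test and residual comparison; SourceTracker-style collapsed
  Gibbs source tracking of each fecal sample against the previous fecal
  and same-day rumen samples.
* **Host links** — EnvFit covariate r² on ordinations, the RBHB
  insulin-sensitivity index `1/(log₁₀GLU + log₁₀INS + log₁₀NEFA +
  log₁₀BHB)`, Kruskal–Wallis/Dunn tests of phenotype changes across
  succession-transition types, and species → pathway → phenotype mediation
  (ACME = a·b, ADE = c′, bootstrap inference, screen with BH control).
* **Synthetic cohorts** — a generator producing cohorts with the exact
  statistical structure the analyses assume (latent Markov state paths,
  DM count emission, clade-conserved habitat preference, planted mediation
  paths) plus pure-process assembly scenarios, so every estimator is
  validated against known truth.

## Worked example

Simulate a 91-cow, single-habitat cohort, type its communities, and stage
the succession:

```python
from ruminate.simulate import SyntheticCohortConfig, simulate_cohort
from ruminate.cohort import rarefy
from ruminate.dmm import select_k
from ruminate.succession import estimate_transitions, classify_stages
from ruminate.diversity import bray_curtis, permanova

cfg = SyntheticCohortConfig(n_subjects=91, habitats=("rumen",), seed=11)
table, design, tree, pathways, truth = simulate_cohort(cfg)
rare = rarefy(table, "min", seed=11)

best_k, scores, fits = select_k(rare, range(1, 6), seed=11, n_init=1)
model, assign = fits[best_k]
chain = estimate_transitions(assign, design)
staging = classify_stages(chain)

dm = bray_curtis(rare)
day = design.subset(list(dm.ids)).frame["day"].to_numpy()
res = permanova(dm, day, n_perm=999, seed=11)

print("selected K =", best_k)
print("pooled P =\n", chain.pooled_probabilities.round(2))
print("stages:", staging.stage_by_state)
print(f"day effect: F={res.f_statistic:.2f} R2={res.r_squared:.3f} p={res.p_value:.3f}")
```

Output:

```
selected K = 3
pooled P =
 [[0.43 0.52 0.05]
 [0.06 0.9  0.04]
 [0.67 0.25 0.08]]
stages: {0: 'transition', 1: 'stable', 2: 'rapid_transition'}
day effect: F=18.27 R2=0.145 p=0.001
```

The mixture recovers the three planted community states (the labels are an
arbitrary permutation of the generator's), the pooled chain reproduces the
planted self-transition structure (0.15 / 0.42 / 0.90), the staging rule
reads off rapid-transition → transition → stable, and sampling day explains
a significant share of the Bray–Curtis variation. A file-based interface
covers the same pipeline: `ruminate simulate`, `ruminate diversity`,
`ruminate dmm`, `ruminate succession`, `ruminate icamp` (see `--help`).

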