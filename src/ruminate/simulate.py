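"""Synthetic longitudinal cohorts with known ground truth.

The generator mirrors the structure of a peripartum dairy-cow study: a
cohort of subjects sampled on a fixed day grid around calving in one or two
gut habitats (rumen, feces).  Each subject carries a latent community-state
path evolving by a first-order Markov chain; counts are emitted per sample
from a state-specific Dirichlet-multinomial at a log-normally distributed
sequencing depth.  A birth-process phylogeny links taxa, with Brownian
traits down the tree providing phylogenetically conserved habitat
preference.  Host phenotypes are generated with planted
species -> pathway -> phenotype mediation paths so mediation recovery can be
scored against truth.

A separate harness, :func:`simulate_assembly_scenario`, produces communities
assembled under pure selection, dispersal limitation, or neutral drift, for
validating the null-model assembly partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from skbio import TreeNode

from .cohort import CohortDesign, CohortError, FeatureTable, Phylogeny

__all__ = [
    "SyntheticCohortConfig",
    "MediationPlan",
    "SyntheticTruth",
    "default_transition_matrix",
    "default_state_alphas",
    "yule_tree",
    "brownian_trait",
    "simulate_cohort",
    "simulate_mediation_triple",
    "simulate_assembly_scenario",
]

#: serum panel baselines: analyte -> (mean, sd). Units follow the
#: conventional bovine serum panel (GLU mg/dl, INS uU/ml, NEFA and BHB
#: mmol/l, TG mmol/l, IGF1 ng/ml, AST/ALT U/l, TAOC mM, HP mg/ml).
PHENOTYPE_BASELINES: dict[str, tuple[float, float]] = {
    "GLU": (60.0, 8.0),
    "INS": (12.0, 4.0),
    "NEFA": (0.45, 0.15),
    "BHB": (0.80, 0.25),
    "TG": (0.15, 0.05),
    "IGF1": (80.0, 25.0),
    "AST": (80.0, 20.0),
    "ALT": (25.0, 8.0),
    "TAOC": (1.2, 0.3),
    "HP": (0.30, 0.10),
}


def default_transition_matrix(k: int = 3) -> np.ndarray:
    """A succession-flavoured chain: early states flow toward a stable sink.

    For k=3 the self-transition rates are 0.15 / 0.42 / 0.90, mimicking the
    rapid-transition -> transition -> stable progression seen in peripartum
    gut communities.
    """
    if k == 1:
        return np.ones((1, 1))
    T = np.zeros((k, k))
    # convex spacing keeps intermediate states clearly below the 0.5
    # stable-eligibility convention (k=3 -> 0.15, 0.42, 0.90)
    selfs = 0.15 + 0.75 * (np.arange(k) / (k - 1)) ** 1.5
    for i in range(k):
        T[i, i] = selfs[i]
        forward = np.arange(i + 1, k)
        backward = np.arange(0, i)
        rest = 1.0 - selfs[i]
        if forward.size:
            # most of the leaving mass moves forward, biased to near states
            w = 1.0 / (forward - i)
            fw = 0.9 * rest if backward.size else rest
            T[i, forward] = fw * w / w.sum()
            if backward.size:
                wb = 1.0 / (i - backward)
                T[i, backward] = 0.1 * rest * wb / wb.sum()
        else:
            wb = 1.0 / (i - backward)
            T[i, backward] = rest * wb / wb.sum()
    return T / T.sum(axis=1, keepdims=True)


def default_state_alphas(
    n_taxa: int,
    k: int,
    baseline: float = 0.3,
    boost: float = 4.0,
    block_size: int | None = None,
) -> np.ndarray:
    """Dirichlet concentrations: shared sparse baseline + per-state block.

    Each state enriches a disjoint contiguous block of taxa on top of a
    baseline shared by all states, so states differ in their driver taxa but
    still share the bulk community — the structure community-state typing
    assumes.  With the defaults a state's block holds roughly three quarters
    of its expected relative abundance.
    """
    if block_size is None:
        block_size = max(2, n_taxa // (k + 1))
    if block_size * k > n_taxa:
        raise CohortError("state blocks exceed the number of taxa")
    alphas = np.full((k, n_taxa), baseline)
    for s in range(k):
        alphas[s, s * block_size : (s + 1) * block_size] += boost
    return alphas


@dataclass
class MediationPlan:
    """Planted species -> pathway -> phenotype effects.

    ``a`` is the species-to-pathway slope, ``b`` the pathway-to-phenotype
    slope and ``c_prime`` the direct species-to-phenotype slope, all on the
    standardized model scale; ``noise_sd`` is the residual sd of both
    equations.
    """

    a: float = 0.5
    b: float = 0.4
    c_prime: float = 0.2
    noise_sd: float = 0.5
    n_pathways: int = 20
    n_planted: int = 3
    phenotypes: tuple[str, ...] = ("NEFA", "INS", "TG")


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 91
    timepoints: tuple[int, ...] = (-21, 1, 3, 7, 14, 21)
    n_taxa: int = 60
    k_states: int = 3
    initial_state_probs: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    state_dirichlet_alphas: np.ndarray | None = None
    habitats: tuple[str, ...] = ("rumen", "feces")
    depth_mean_log: float = float(np.log(20000.0))
    depth_sigma_log: float = 0.3
    min_depth: int = 5000
    habitat_preference_strength: float = 1.0
    mediation: MediationPlan = field(default_factory=MediationPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.k_states
        if self.initial_state_probs is None:
            # cohorts start mostly in the earliest (rapid-transition) state
            p = np.full(k, 0.3 / max(k - 1, 1))
            p[0] = 0.7 if k > 1 else 1.0
            self.initial_state_probs = p
        self.initial_state_probs = np.asarray(self.initial_state_probs, float)
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(k)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        if self.state_dirichlet_alphas is None:
            self.state_dirichlet_alphas = default_state_alphas(self.n_taxa, k)
        self.state_dirichlet_alphas = np.asarray(self.state_dirichlet_alphas, float)

        if self.initial_state_probs.shape != (k,):
            raise CohortError("initial_state_probs length must equal k_states")
        if abs(self.initial_state_probs.sum() - 1.0) > 1e-12:
            raise CohortError("initial_state_probs must sum to 1")
        if self.transition_matrix.shape != (k, k):
            raise CohortError("transition_matrix must be k_states x k_states")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12):
            raise CohortError("transition_matrix rows must sum to 1 (1e-12)")
        if np.any(self.transition_matrix < 0):
            raise CohortError("transition_matrix entries must be non-negative")
        if self.state_dirichlet_alphas.shape != (k, self.n_taxa):
            raise CohortError(
                "state_dirichlet_alphas must be k_states x n_taxa "
                f"(got {self.state_dirichlet_alphas.shape})"
            )
        if np.any(self.state_dirichlet_alphas <= 0):
            raise CohortError("Dirichlet concentrations must be positive")
        if len(self.timepoints) < 2:
            raise CohortError("need at least two timepoints")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    state_by_sample: dict[str, int]
    paths: dict[tuple[str, str], list[int]]  # (habitat, subject) -> path
    transition_matrix: np.ndarray
    state_alphas: np.ndarray
    mediation_triples: list[dict]
    habitat_traits: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# phylogeny


def yule_tree(
    n_tips: int, seed: int = 0, rate: float = 1.0, prefix: str = "t"
) -> Phylogeny:
    """Pure-birth tree with exponential waiting times; tips contemporaneous."""
    if n_tips < 2:
        raise CohortError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active: list[TreeNode] = [root]
    birth = {id(root): 0.0}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth.pop(id(node))
        for _ in range(2):
            child = TreeNode(parent=node)
            node.children.append(child)
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (rate * len(active)))
    for node in active:
        node.length = t - birth[id(node)]
    names = [f"{prefix}{i:04d}" for i in range(n_tips)]
    for name, tip in zip(names, root.tips()):
        tip.name = name
    root.length = None
    return Phylogeny(root)


def brownian_trait(
    phylo: Phylogeny, seed: int = 0, sigma: float = 1.0
) -> dict[str, float]:
    """Trait evolved along branches (increments ~ N(0, sigma^2 * length))."""
    rng = np.random.default_rng(seed)
    value = {id(phylo.tree): 0.0}
    out: dict[str, float] = {}
    for node in phylo.tree.preorder(include_self=False):
        length = node.length or 0.0
        v = value[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(length))
        value[id(node)] = v
        if node.is_tip():
            out[node.name] = v
    return out


# ---------------------------------------------------------------------------
# cohort simulation


def _sample_id(subject: str, day: int, habitat: str) -> str:
    return f"{subject}.d{day:+d}.{habitat}"


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[FeatureTable, CohortDesign, Phylogeny, pd.DataFrame, SyntheticTruth]:
    """Simulate a longitudinal two-habitat cohort with known truth.

    Returns the count table (all habitats stacked), the design, the
    phylogeny, a pathway abundance table (samples x pathways, planted
    mediator pathways included) and the :class:`SyntheticTruth`.

    One global seed is expanded into independent child streams for the
    tree, state paths, counts, depths, traits and phenotypes so that each
    component is reproducible in isolation.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (s_tree, s_path, s_counts, s_depth, s_trait, s_pheno, s_path2) = [
        np.random.default_rng(c) for c in ss.spawn(7)
    ]

    k = cfg.k_states
    taxa = [f"t{i:04d}" for i in range(cfg.n_taxa)]
    phylo = yule_tree(cfg.n_taxa, seed=int(s_tree.integers(2**31)))
    subjects = [f"cow{i:03d}" for i in range(cfg.n_subjects)]
    n_tp = len(cfg.timepoints)

    # clade-conserved habitat preference: one Brownian trait per habitat
    habitat_traits: dict[str, np.ndarray] = {}
    for h in cfg.habitats:
        tr = brownian_trait(phylo, seed=int(s_trait.integers(2**31)))
        z = np.array([tr[t] for t in taxa])
        z = (z - z.mean()) / (z.std() + 1e-12)
        habitat_traits[h] = z

    paths: dict[tuple[str, str], list[int]] = {}
    state_by_sample: dict[str, int] = {}
    rows = []
    counts_rows = []
    sample_ids: list[str] = []

    for h_idx, habitat in enumerate(cfg.habitats):
        pref = np.exp(cfg.habitat_preference_strength * habitat_traits[habitat])
        alphas_h = cfg.state_dirichlet_alphas * pref[None, :]
        for subj in subjects:
            path = [int(s_path.choice(k, p=cfg.initial_state_probs))]
            for _ in range(n_tp - 1):
                path.append(int(s_path.choice(k, p=cfg.transition_matrix[path[-1]])))
            paths[(habitat, subj)] = path
            for day, state in zip(cfg.timepoints, path):
                sid = _sample_id(subj, day, habitat)
                depth = int(
                    max(
                        cfg.min_depth,
                        np.exp(s_depth.normal(cfg.depth_mean_log, cfg.depth_sigma_log)),
                    )
                )
                p = s_counts.dirichlet(alphas_h[state])
                counts_rows.append(s_counts.multinomial(depth, p))
                sample_ids.append(sid)
                state_by_sample[sid] = state
                rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subj,
                        "day": day,
                        "habitat": habitat,
                    }
                )

    table = FeatureTable(sample_ids, taxa, np.asarray(counts_rows))
    frame = pd.DataFrame(rows)

    # mild per-subject covariates (parity, pH) for covariate-fitting demos
    parity = {s: int(s_pheno.integers(1, 5)) for s in subjects}
    frame["parity"] = frame["subject_id"].map(parity)
    frame["ruminal_pH"] = s_pheno.normal(6.3, 0.25, len(frame)).round(3)

    pathways, truth_triples, pheno_frame = _plant_mediation(
        cfg, table, frame, s_pheno, s_path2
    )
    frame = frame.merge(pheno_frame, on="sample_id", how="left")
    design = CohortDesign(frame, phenotype_cols=list(PHENOTYPE_BASELINES))

    truth = SyntheticTruth(
        state_by_sample=state_by_sample,
        paths=paths,
        transition_matrix=cfg.transition_matrix.copy(),
        state_alphas=cfg.state_dirichlet_alphas.copy(),
        mediation_triples=truth_triples,
        habitat_traits=habitat_traits,
    )
    return table, design, phylo, pathways, truth


def _species_z(rel: np.ndarray) -> np.ndarray:
    """z-score of log10 relative abundance with half-minimum zero replacement."""
    x = rel.copy()
    positive = x[x > 0]
    floor = 0.5 * positive.min() if positive.size else 1e-6
    x[x == 0] = floor
    lx = np.log10(x)
    sd = lx.std()
    return (lx - lx.mean()) / (sd if sd > 0 else 1.0)


def _plant_mediation(cfg, table, frame, rng, rng2):
    """Build the pathway table and phenotype panel with planted triples.

    Mediator pathways follow ``m = a * species_z + e``; phenotypes follow
    ``y = c' * species_z + b * m + e`` on the standardized scale, then are
    mapped to the analyte's baseline units (shift by mean, scale by sd).
    The truth records the slopes on the stored scale.
    """
    plan = cfg.mediation
    med_habitat = cfg.habitats[0]
    mask = (frame["habitat"] == med_habitat).to_numpy()
    sample_order = list(table.sample_ids)
    rel = table.relative_abundance()

    pw_names = [f"PWY{j:04d}" for j in range(plan.n_pathways)]
    n_samples = table.n_samples
    pw = rng2.normal(5.0, 1.0, (n_samples, plan.n_pathways))

    # choose planted species from distinct state blocks so they vary strongly
    block = max(2, cfg.n_taxa // (cfg.k_states + 1))
    candidates = [min(s * block, cfg.n_taxa - 1) for s in range(cfg.k_states)]
    n_plant = min(plan.n_planted, len(candidates), plan.n_pathways, len(plan.phenotypes))

    pheno = {}
    for name, (mu, sd) in PHENOTYPE_BASELINES.items():
        base = rng.normal(mu, sd, n_samples)
        pheno[name] = np.maximum(base, 0.05 * mu)  # serum analytes stay positive

    triples = []
    for i in range(n_plant):
        sp_idx = candidates[i]
        pw_idx = i
        ph_name = plan.phenotypes[i]
        mu, sd = PHENOTYPE_BASELINES[ph_name]
        z = np.zeros(n_samples)
        z[mask] = _species_z(rel[mask, sp_idx])
        m_std = plan.a * z + rng2.normal(0, plan.noise_sd, n_samples)
        y_std = plan.c_prime * z + plan.b * m_std + rng2.normal(0, plan.noise_sd, n_samples)
        pw[:, pw_idx] = m_std + 5.0  # shift only: slopes preserved
        vals = np.maximum(mu + sd * y_std, 0.05 * mu)
        pheno[ph_name] = np.where(mask, vals, pheno[ph_name])
        triples.append(
            {
                "species": table.taxon_ids[sp_idx],
                "pathway": pw_names[pw_idx],
                "phenotype": ph_name,
                "habitat": med_habitat,
                "a": plan.a,
                "b": sd * plan.b,
                "c_prime": sd * plan.c_prime,
                "acme": sd * plan.a * plan.b,
            }
        )

    pathways = pd.DataFrame(pw, index=sample_order, columns=pw_names)
    pathways.index.name = "sample_id"
    pheno_frame = pd.DataFrame({"sample_id": sample_order, **pheno})
    return pathways, triples, pheno_frame


def simulate_mediation_triple(
    a: float = 0.5,
    b: float = 0.4,
    c_prime: float = 0.2,
    noise_sd: float = 0.5,
    n: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one (species_z, pathway, phenotype) triple from the linear model."""
    rng = np.random.default_rng(seed)
    s = rng.normal(0, 1, n)
    m = a * s + rng.normal(0, noise_sd, n)
    y = c_prime * s + b * m + rng.normal(0, noise_sd, n)
    return s, m, y


# ---------------------------------------------------------------------------
# assembly scenarios


def clustered_tree(
    n_taxa: int,
    cluster_size: int = 6,
    n_clades: int = 2,
    seed: int = 0,
    within_scale: float = 0.02,
    stem_length: float = 1.0,
    clade_depth: float = 2.0,
    prefix: str = "t",
) -> tuple[Phylogeny, np.ndarray]:
    """Rate-heterogeneous tree: tight tip clusters on a deep clade skeleton.

    The skeleton is ``n_clades`` deep clades hanging off the root
    (``clade_depth`` branches); inside each clade, clusters of
    ``cluster_size`` tips sit on equal ``stem_length`` stems, and each
    cluster is a small pure-birth subtree with branch lengths scaled by
    ``within_scale``.  Close relatives are near-identical phylogenetically
    while clusters within a clade are mutually equidistant — the shape a
    clade-respecting binning recovers as one bin per deep clade.  Returns
    the tree and each tip's cluster index (in tip order).
    """
    if cluster_size < 2:
        raise CohortError("cluster_size must be >= 2")
    n_clusters, rem = divmod(n_taxa, cluster_size)
    if n_clusters < 2 * n_clades:
        raise CohortError("need at least two clusters per clade")
    sizes = [cluster_size] * n_clusters
    for i in range(rem):  # distribute any remainder
        sizes[i % n_clusters] += 1
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(n_clusters)
    root = TreeNode()
    cluster_of: list[int] = []
    tip_counter = 0
    # round-robin clusters over clades so every clade holds ~equal clusters
    clade_nodes = []
    for _ in range(n_clades):
        clade = TreeNode(parent=root)
        clade.length = clade_depth
        root.children.append(clade)
        clade_nodes.append(clade)
    for c in range(n_clusters):
        clade = clade_nodes[c % n_clades]
        sub = yule_tree(
            max(sizes[c], 2),
            seed=int(np.random.default_rng(seeds[c]).integers(2**31)),
        )
        for node in sub.tree.traverse(include_self=False):
            if node.length is not None:
                node.length *= within_scale
        for st in sub.tree.tips():
            st.name = f"{prefix}{tip_counter:04d}"
            tip_counter += 1
            cluster_of.append(c)
        sub.tree.parent = clade
        sub.tree.length = stem_length
        clade.children.append(sub.tree)
    return Phylogeny(root), np.asarray(cluster_of)


def simulate_assembly_scenario(
    mode: str,
    n_taxa: int = 120,
    n_samples: int = 30,
    seed: int = 0,
    depth: int | None = None,
    cluster_size: int = 6,
    favored_fraction: float = 0.3,
    establishment: float = 0.45,
    abundance_sd: float = 0.2,
    drift_evenness: float = 20.0,
    dispersal_tau_frac: float = 0.08,
) -> tuple[FeatureTable, Phylogeny]:
    """Communities assembled under a single ecological process.

    All modes share the clustered tree model of :func:`clustered_tree`.

    ``selection``
        A fixed clade-level fitness trait (iid per cluster, constant within
        it) deterministically filters the pool: only taxa in the favoured
        top ``favored_fraction`` of clades can establish, every favoured
        clade establishes at least one member, and which members do varies
        stochastically per sample (Bernoulli ``establishment`` with
        log-normal abundances).  Between two samples, a taxon missing
        from its partner is almost always replaced by a close relative from
        the same favoured clade, so between-sample phylogenetic turnover
        falls far below the taxon-shuffling null. Default depth 2000.
    ``dispersal_limitation``
        Each sample assembles from the phylogenetic neighbourhood of its
        own random seed taxon (weights decay with cophenetic distance,
        scale ``dispersal_tau_frac`` x mean distance): samples occupy
        different clades, giving turnover far above the compositional
        null. Default depth 1000.
    ``drift``
        Neutral multinomial resampling of one shared, phylogenetically
        unstructured metacommunity (Dirichlet with concentration
        ``drift_evenness``).  The default depth (40) keeps per-sample
        occupancy sparse so pairs vary independently — the regime in which
        the null z-scores are calibrated.
    """
    if mode not in ("selection", "dispersal_limitation", "drift"):
        raise CohortError(f"unknown assembly mode {mode!r}")
    if n_taxa < 48:
        raise CohortError("need n_taxa >= 48 so at least two bins exist")
    ss = np.random.SeedSequence(seed)
    rng_tree, rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    phylo, cluster_of = clustered_tree(
        n_taxa, cluster_size=cluster_size, seed=int(rng_tree.integers(2**31))
    )
    taxa = list(phylo.tip_names)
    n_clusters = cluster_of.max() + 1

    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    if mode == "drift":
        # shallow depth keeps occupancy sparse so pairs vary independently;
        # that is the regime where the null z-scores are calibrated
        depth = depth or 40
        meta = rng.dirichlet(np.full(n_taxa, drift_evenness))
        for i in range(n_samples):
            counts[i] = rng.multinomial(depth, meta)
    elif mode == "selection":
        depth = depth or 2000
        fitness = rng.normal(0, 1, n_clusters)
        n_fav = max(2, int(round(favored_fraction * n_clusters)))
        favored_clusters = np.argsort(fitness)[::-1][:n_fav]
        favored = np.isin(cluster_of, favored_clusters)
        for i in range(n_samples):
            present = favored & (rng.random(n_taxa) < establishment)
            # the filter passes every favoured clade; at least one of its
            # members establishes, which ones varies stochastically
            for c in favored_clusters:
                members = np.flatnonzero(cluster_of == c)
                if not present[members].any():
                    present[rng.choice(members)] = True
            w = np.where(present, np.exp(rng.normal(0, abundance_sd, n_taxa)), 0.0)
            counts[i] = rng.multinomial(depth, w / w.sum())
    else:  # dispersal_limitation
        depth = depth or 1000
        D = phylo.cophenetic_for(taxa)
        tau = dispersal_tau_frac * D[np.triu_indices(n_taxa, 1)].mean()
        for i in range(n_samples):
            seed_taxon = rng.integers(n_taxa)
            w = np.exp(-D[seed_taxon] / tau)
            counts[i] = rng.multinomial(depth, w / w.sum())
    while np.any(counts.sum(axis=1) == 0):  # ensure positive totals
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        for i in empty:
            counts[i, rng.integers(n_taxa)] += 1
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    return FeatureTable(sample_ids, taxa, counts), phylo
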