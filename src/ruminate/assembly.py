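"""Phylogenetic-bin null-model partitioning of community assembly.

Taxa are first grouped into phylogenetic bins of at least ``ds`` members
(default 24) by recursively splitting the cophenetic-distance hierarchy.
Within each bin, for every sample pair, two null-model metrics are
computed:

* the beta nearest-taxon index (bNTI) — the z-score of the observed
  abundance-weighted between-sample mean nearest-taxon distance (bMNTD)
  against a null built by shuffling taxon labels across the bin's tips;
* the modified Raup-Crick index (RC) — the null-standardised Bray-Curtis
  dissimilarity, in [-1, 1], with nulls that redistribute each sample's bin
  total over the bin's taxa at the bin-wide taxon frequencies.

Each (pair, bin) is then assigned exactly one assembly process:
bNTI < -1.96 homogeneous selection (HOS); bNTI > +1.96 heterogeneous
selection (HeS); otherwise RC < -0.95 homogenizing dispersal (HD),
RC > +0.95 dispersal limitation (DL), and the remainder drift.  Process
fractions are aggregated per pair with bins weighted by their mean relative
abundance across the two samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from ._stats import kw_dunn
from .cohort import CohortError, FeatureTable, Phylogeny

__all__ = [
    "PhyloBins",
    "AssemblyResult",
    "PROCESSES",
    "build_bins",
    "beta_nti",
    "raup_crick",
    "classify_processes",
    "partition_assembly",
    "compare_groups",
]

PROCESSES = ("HeS", "HOS", "HD", "DL", "drift")


@dataclass
class PhyloBins:
    bins: dict[int, list[str]]
    ds: int
    diameters: dict[int, float]

    @property
    def taxon_to_bin(self) -> dict[str, int]:
        return {t: b for b, taxa in self.bins.items() for t in taxa}


@dataclass
class AssemblyResult:
    metrics: pd.DataFrame  # long: one row per evaluable (pair, bin)
    fractions: dict[str, float]  # overall abundance-weighted, sums to 1
    per_pair: pd.DataFrame  # per pair x process contribution (rows sum to 1)
    per_bin: pd.DataFrame  # per bin x process fractions (rows sum to 1)


def build_bins(phylo: Phylogeny, taxa: list[str], ds: int = 24) -> PhyloBins:
    """Group taxa into clade-respecting bins of size >= ds.

    Average-linkage clustering of the cophenetic distances is traversed
    top-down: a cluster is split into its two children only while both
    children can hold at least ``ds`` taxa, so an undersized subclade is
    retained with its phylogenetically nearest sibling rather than forming
    its own bin.  Deterministic and invariant to taxon input order (taxa
    are sorted before clustering).
    """
    if ds < 2:
        raise CohortError("ds must be >= 2")
    missing = [t for t in taxa if t not in set(phylo.tip_names)]
    if missing:
        raise CohortError(f"taxa absent from tree: {missing[:5]}")
    taxa = sorted(set(taxa))
    if len(taxa) < ds:
        raise CohortError(f"fewer taxa ({len(taxa)}) than the bin size limit {ds}")
    D = phylo.cophenetic_for(taxa)
    Z = linkage(squareform(D, checks=False), method="average")
    # scan the merge heights: pick the lowest cut that yields the maximum
    # number of clusters of size >= ds
    heights = np.unique(Z[:, 2])
    best_cut: np.ndarray | None = None
    best_n_big = 0
    for h in heights:
        lab = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(lab)
        n_big = int((sizes[1:] >= ds).sum())
        if n_big > best_n_big:
            best_n_big = n_big
            best_cut = lab
    if best_cut is None:  # degenerate: no cut reaches ds -> single bin
        best_cut = np.ones(len(taxa), dtype=int)
    # merge undersized clusters into the phylogenetically nearest big bin
    sizes = np.bincount(best_cut)
    big = [c for c in np.unique(best_cut) if sizes[c] >= ds]
    small = [c for c in np.unique(best_cut) if sizes[c] < ds]
    if not big:
        big, small = [int(np.unique(best_cut)[0])], list(np.unique(best_cut)[1:])
    assign = best_cut.copy()
    for c in small:
        members = np.flatnonzero(best_cut == c)
        dists = [
            D[np.ix_(members, np.flatnonzero(assign == b))].mean() for b in big
        ]
        assign[members] = big[int(np.argmin(dists))]
    bins: dict[int, list[str]] = {}
    diameters: dict[int, float] = {}
    order = sorted(np.unique(assign), key=lambda c: int(np.flatnonzero(assign == c).min()))
    for b, c in enumerate(order):
        idx = np.flatnonzero(assign == c)
        bins[b] = sorted(taxa[i] for i in idx)
        diameters[b] = float(D[np.ix_(idx, idx)].max())
    return PhyloBins(bins, ds, diameters)


def _bmntd_pairs(D: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Abundance-weighted bMNTD for all sample pairs within one bin.

    D: (m, m) tip distances; P: (n, m) within-bin relative abundances
    (rows may be all-zero when the bin is absent from a sample).
    Returns an (n, n) matrix; entries involving empty rows are NaN.
    """
    n, m = P.shape
    present = P > 0
    M = np.full((m, n), np.nan)
    for t in range(n):
        supp = np.flatnonzero(present[t])
        if supp.size:
            M[:, t] = D[:, supp].min(axis=1)
    with np.errstate(invalid="ignore"):
        A = P @ np.nan_to_num(M, nan=0.0)
    empty = ~present.any(axis=1)
    out = 0.5 * (A + A.T)
    out[empty, :] = np.nan
    out[:, empty] = np.nan
    return out


def beta_nti(
    table: FeatureTable,
    phylo: Phylogeny,
    bins: PhyloBins,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-bin bNTI for every sample pair.

    The null shuffles taxon labels across the bin's tips (one permutation
    of the bin distance submatrix per draw, shared by all pairs, as in
    bin-based null models).  A (pair, bin) with fewer than two taxa in the
    union of the pair's supports, or with a sample missing the bin, is
    marked not evaluable.  A null sd of zero (e.g. equidistant tips) yields
    bNTI = 0: the observation cannot deviate from its null.
    """
    if table.n_samples < 2:
        raise CohortError("need at least two samples")
    if n_null < 100:
        raise CohortError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)
    n = table.n_samples
    iu = np.triu_indices(n, 1)
    t_index = {t: j for j, t in enumerate(table.taxon_ids)}
    rows = []
    for b, members in bins.bins.items():
        cols = np.array([t_index[t] for t in members if t in t_index])
        if cols.size < 2:
            continue
        D = phylo.cophenetic_for([table.taxon_ids[j] for j in cols])
        sub = counts[:, cols]
        totals = sub.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(totals[:, None] > 0, sub / totals[:, None], 0.0)
        obs = _bmntd_pairs(D, P)
        m = cols.size
        s1 = np.zeros((n, n))
        s2 = np.zeros((n, n))
        for _ in range(n_null):
            perm = rng.permutation(m)
            null = _bmntd_pairs(D[np.ix_(perm, perm)], P)
            s1 += np.nan_to_num(null)
            s2 += np.nan_to_num(null) ** 2
        mean = s1 / n_null
        var = np.clip(s2 / n_null - mean**2, 0.0, None)
        sd = np.sqrt(var)
        support = P > 0
        for a, bb in zip(*iu):
            union = int((support[a] | support[bb]).sum())
            evaluable = totals[a] > 0 and totals[bb] > 0 and union >= 2
            if evaluable and sd[a, bb] > 0:
                z = (obs[a, bb] - mean[a, bb]) / sd[a, bb]
            elif evaluable:
                z = 0.0
            else:
                z = np.nan
            rows.append(
                {
                    "sample_a": table.sample_ids[a],
                    "sample_b": table.sample_ids[bb],
                    "bin": b,
                    "obs_bmntd": obs[a, bb] if evaluable else np.nan,
                    "null_mean": mean[a, bb] if evaluable else np.nan,
                    "null_sd": sd[a, bb] if evaluable else np.nan,
                    "bnti": z,
                    "evaluable": bool(evaluable),
                }
            )
    return pd.DataFrame(rows)


def raup_crick(
    table: FeatureTable,
    bins: PhyloBins,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-bin modified Raup-Crick index for every sample pair.

    Nulls redistribute each sample's observed bin total across the bin's
    taxa by a multinomial at the bin-wide pooled taxon frequencies, so
    per-sample bin totals are preserved exactly.
    ``RC = 2 (frac_below + 0.5 frac_ties) - 1`` of the observed Bray-Curtis
    against its null distribution.
    """
    if n_null < 100:
        raise CohortError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    iu = np.triu_indices(n, 1)
    t_index = {t: j for j, t in enumerate(table.taxon_ids)}
    rows = []
    for b, members in bins.bins.items():
        cols = np.array([t_index[t] for t in members if t in t_index])
        if cols.size < 2:
            continue
        sub = table.counts[:, cols]
        totals = sub.sum(axis=1)
        pooled = sub.sum(axis=0).astype(float)
        if pooled.sum() == 0:
            continue
        freq = pooled / pooled.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            obs_bc = squareform(pdist(sub.astype(float), metric="braycurtis"))
        below = np.zeros((n, n))
        ties = np.zeros((n, n))
        null_sub = np.empty_like(sub)
        for _ in range(n_null):
            for i in range(n):
                null_sub[i] = rng.multinomial(totals[i], freq)
            null_bc = squareform(pdist(null_sub.astype(float), metric="braycurtis"))
            below += null_bc < obs_bc - 1e-12
            ties += np.abs(null_bc - obs_bc) <= 1e-12
        rc = 2.0 * ((below + 0.5 * ties) / n_null) - 1.0
        for a, bb in zip(*iu):
            evaluable = totals[a] > 0 and totals[bb] > 0
            rows.append(
                {
                    "sample_a": table.sample_ids[a],
                    "sample_b": table.sample_ids[bb],
                    "bin": b,
                    "obs_bc": obs_bc[a, bb] if evaluable else np.nan,
                    "rc": rc[a, bb] if evaluable else np.nan,
                    "evaluable_rc": bool(evaluable),
                }
            )
    return pd.DataFrame(rows)


def classify_processes(
    table: FeatureTable,
    bins: PhyloBins,
    bnti_frame: pd.DataFrame,
    rc_frame: pd.DataFrame,
    bnti_threshold: float = 1.96,
    rc_threshold: float = 0.95,
) -> AssemblyResult:
    """Merge bNTI and RC into one process call per (pair, bin) and aggregate.

    Bin weights are the mean of the pair's two relative bin abundances,
    normalised within each pair over its evaluable bins, so per-pair
    contributions — and hence all aggregated fractions — sum to one.
    """
    merged = bnti_frame.merge(
        rc_frame, on=["sample_a", "sample_b", "bin"], how="inner"
    )
    merged = merged[merged["evaluable"] & merged["evaluable_rc"]].copy()
    if merged.empty:
        raise CohortError("no evaluable (pair, bin) metrics")
    if merged[["bnti", "rc"]].isna().any().any():
        raise CohortError("missing metric for an evaluable pair")

    def call(row) -> str:
        if row.bnti < -bnti_threshold:
            return "HOS"
        if row.bnti > bnti_threshold:
            return "HeS"
        if row.rc < -rc_threshold:
            return "HD"
        if row.rc > rc_threshold:
            return "DL"
        return "drift"

    merged["process"] = [call(r) for r in merged.itertuples(index=False)]

    rel = table.relative_abundance()
    s_index = {s: i for i, s in enumerate(table.sample_ids)}
    t_index = {t: j for j, t in enumerate(table.taxon_ids)}
    bin_rel = {}
    for b, members in bins.bins.items():
        cols = [t_index[t] for t in members if t in t_index]
        bin_rel[b] = rel[:, cols].sum(axis=1)
    weight = np.array(
        [
            0.5
            * (
                bin_rel[r.bin][s_index[r.sample_a]]
                + bin_rel[r.bin][s_index[r.sample_b]]
            )
            for r in merged.itertuples(index=False)
        ]
    )
    merged["weight"] = weight
    # normalise weights within each pair so per-pair contributions sum to 1
    pair_tot = merged.groupby(["sample_a", "sample_b"])["weight"].transform("sum")
    merged["contribution"] = np.where(pair_tot > 0, merged["weight"] / pair_tot, 0.0)

    per_pair = (
        merged.pivot_table(
            index=["sample_a", "sample_b"],
            columns="process",
            values="contribution",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(PROCESSES), fill_value=0.0)
    )
    fractions = per_pair.mean(axis=0)
    fractions = (fractions / fractions.sum()).to_dict()

    def _bin_fracs(g: pd.DataFrame) -> pd.Series:
        w = g["weight"].sum()
        out = g.groupby("process")["weight"].sum() / (w if w > 0 else 1.0)
        return out.reindex(list(PROCESSES), fill_value=0.0)

    per_bin = merged.groupby("bin")[["process", "weight"]].apply(_bin_fracs)
    return AssemblyResult(merged, fractions, per_pair, per_bin)


def partition_assembly(
    table: FeatureTable,
    phylo: Phylogeny,
    ds: int = 24,
    n_null: int = 1000,
    seed: int = 0,
) -> AssemblyResult:
    """Convenience driver: bins -> bNTI -> RC -> process classification."""
    bins = build_bins(phylo, list(table.taxon_ids), ds=ds)
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(2))
    bnti_frame = beta_nti(table, phylo, bins, n_null=n_null, seed=s1)
    rc_frame = raup_crick(table, bins, n_null=n_null, seed=s2)
    return classify_processes(table, bins, bnti_frame, rc_frame)


def compare_groups(
    result: AssemblyResult,
    groups,
    min_pairs: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group process fractions and tests over within-group pairs.

    ``groups`` maps sample_id -> group label (e.g. succession stage).  Only
    pairs whose two samples share a group enter.  For each process, the
    per-pair contributions are compared across groups by Kruskal-Wallis
    with Dunn post hoc (BH-adjusted).  Returns ``(fractions, tests)``.
    """
    pp = result.per_pair.reset_index()
    ga = pp["sample_a"].map(groups)
    gb = pp["sample_b"].map(groups)
    pp = pp[(ga == gb) & ga.notna()].copy()
    pp["group"] = ga[pp.index]
    counts = pp.groupby("group").size()
    keep = counts[counts >= min_pairs].index
    pp = pp[pp["group"].isin(keep)]
    if pp["group"].nunique() < 2:
        raise CohortError("need at least two groups with enough within-group pairs")
    fractions = pp.groupby("group")[list(PROCESSES)].mean()
    fractions = fractions.div(fractions.sum(axis=1), axis=0)
    rows = []
    for proc in PROCESSES:
        h, p, dunn = kw_dunn(pp[proc].to_numpy(), pp["group"].to_numpy())
        rows.append({"process": proc, "kw_h": h, "kw_p": p, "dunn": dunn})
    tests = pd.DataFrame(rows)
    return fractions, tests
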