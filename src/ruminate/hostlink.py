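"""Compartment coupling and microbiome-host phenotype links.

Covers: symmetric Procrustes comparison of two ordinations with a
permutation test and per-sample residuals; Bayesian source tracking of a
sink community against labelled sources (collapsed Gibbs, SourceTracker
style); EnvFit-style covariate fitting onto an ordination; the RBHB
insulin-sensitivity index; and Kruskal-Wallis/Dunn tests of phenotype
changes across succession-transition types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.stats import wilcoxon

from ._stats import bh_adjust, kw_dunn
from .cohort import CohortDesign, CohortError, FeatureTable
from .diversity import OrdinationResult

logger = logging.getLogger(__name__)

__all__ = [
    "ProcrustesResult",
    "SourceProfile",
    "procrustes",
    "compare_residuals",
    "source_track",
    "track_fecal_sources",
    "envfit",
    "rbhb",
    "succession_type_effects",
]


# ---------------------------------------------------------------------------
# Procrustes


@dataclass
class ProcrustesResult:
    m_squared: float
    p_value: float
    residuals: pd.Series  # per-sample distance after superposition
    n_permutations: int


def _superimpose(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Symmetric Procrustes M^2 and per-sample residuals.

    Both configurations are centred and scaled to unit trace, then ``b`` is
    rotated (and uniformly scaled) onto ``a``; M^2 is the sum of squared
    residual distances and lies in [0, 1].
    """
    m1, m2, m2_stat = _scipy_procrustes(a, b)
    res = np.linalg.norm(m1 - m2, axis=1)
    return float(m2_stat), res


def procrustes(
    ord_a: OrdinationResult,
    ord_b: OrdinationResult,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Compare two ordinations over the same samples.

    Axes are truncated to the smaller axis count; samples are matched by ID
    (``ord_b`` is reordered).  ``p = (1 + #{M2_perm <= M2_obs}) / (1 + n_perm)``
    with row permutations of the second configuration.
    """
    shared = [s for s in ord_a.sample_ids if s in set(ord_b.sample_ids)]
    if len(shared) < 3:
        raise CohortError("need at least 3 shared samples")
    ia = [ord_a.sample_ids.index(s) for s in shared]
    ib = [ord_b.sample_ids.index(s) for s in shared]
    k = min(ord_a.coordinates.shape[1], ord_b.coordinates.shape[1])
    A = ord_a.coordinates[ia, :k]
    B = ord_b.coordinates[ib, :k]
    m2_obs, res = _superimpose(A, B)
    rng = np.random.default_rng(seed)
    count_le = 0
    for _ in range(n_perm):
        m2_p, _ = _superimpose(A, B[rng.permutation(len(shared))])
        if m2_p <= m2_obs + 1e-12:
            count_le += 1
    p = (1 + count_le) / (1 + n_perm)
    return ProcrustesResult(m2_obs, p, pd.Series(res, index=shared), n_perm)


def compare_residuals(res_a: pd.Series, res_b: pd.Series) -> dict:
    """Paired Wilcoxon signed-rank test on matched per-sample residuals."""
    shared = res_a.index.intersection(res_b.index)
    if len(shared) != len(res_a) or len(shared) != len(res_b):
        raise CohortError("residual vectors are not matched on the same samples")
    a = res_a.loc[shared].to_numpy()
    b = res_b.loc[shared].to_numpy()
    if len(shared) < 6:
        logger.warning("only %d pairs: the paired test is underpowered", len(shared))
    diff = a - b
    if np.allclose(diff, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(a, b)
    return {
        "n": int(len(shared)),
        "statistic": float(stat),
        "p_value": float(p),
        "median_difference": float(np.median(diff)),
    }


# ---------------------------------------------------------------------------
# source tracking


@dataclass
class SourceProfile:
    proportions: pd.DataFrame  # sinks x (sources + unknown), rows sum to 1
    draws: int
    burn_in: int
    restarts: int


def _gibbs_one_sink(
    sink: np.ndarray,
    source_counts: np.ndarray,  # (V, T)
    alpha1: float,
    alpha2: float,
    beta: float,
    burn_in: int,
    draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Collapsed Gibbs for one sink; returns mean mixing proportions (V+1,)."""
    V, T = source_counts.shape
    taxa = np.repeat(np.arange(T), sink)
    n_reads = taxa.size
    # posterior-predictive taxon probabilities of the known sources
    src_prob = (source_counts + alpha1) / (
        source_counts.sum(axis=1, keepdims=True) + alpha1 * T
    )
    # initialise each read from the known-source likelihoods (unknown gets
    # a uniform-predictive share); seeding the unknown with a third of the
    # reads would hand it the sink profile and trap the sampler there
    init_p = np.vstack([src_prob, np.full(T, 1.0 / T)])  # (V+1, T)
    z = np.empty(n_reads, dtype=np.int64)
    for i in range(n_reads):
        col = init_p[:, taxa[i]]
        z[i] = rng.choice(V + 1, p=col / col.sum())
    env_counts = np.bincount(z, minlength=V + 1).astype(float)
    unk_taxon = np.zeros(T)
    for i in range(n_reads):
        if z[i] == V:
            unk_taxon[taxa[i]] += 1
    theta_acc = np.zeros(V + 1)
    n_acc = 0
    order = np.arange(n_reads)
    for sweep in range(burn_in + draws):
        rng.shuffle(order)
        for i in order:
            t = taxa[i]
            v_old = z[i]
            env_counts[v_old] -= 1
            if v_old == V:
                unk_taxon[t] -= 1
            p = np.empty(V + 1)
            p[:V] = src_prob[:, t] * (env_counts[:V] + beta)
            p[V] = (
                (unk_taxon[t] + alpha2)
                / (env_counts[V] + alpha2 * T)
                * (env_counts[V] + beta)
            )
            v_new = rng.choice(V + 1, p=p / p.sum())
            z[i] = v_new
            env_counts[v_new] += 1
            if v_new == V:
                unk_taxon[t] += 1
        if sweep >= burn_in:
            theta_acc += (env_counts + beta) / (n_reads + beta * (V + 1))
            n_acc += 1
    return theta_acc / n_acc


def source_track(
    sinks: FeatureTable,
    sources: list[tuple[str, np.ndarray]],
    alpha1: float = 0.001,
    alpha2: float = 0.001,
    beta: float = 10.0,
    burn_in: int = 100,
    draws: int = 25,
    restarts: int = 10,
    seed: int = 0,
) -> SourceProfile:
    """Estimate the source composition of each sink community.

    ``sources`` is a list of ``(label, counts)`` with counts aligned to the
    sink table's taxa.  Each sink read is assigned to a declared source or
    to an "unknown" source by collapsed Gibbs sampling; reported
    proportions are posterior means over post-burn-in sweeps, averaged over
    independent restarts.
    """
    if not sources:
        raise CohortError("need at least one source")
    src_labels = [s[0] for s in sources]
    src_counts = np.asarray([np.asarray(c, dtype=float) for _, c in sources])
    if src_counts.shape[1] != sinks.n_taxa:
        raise CohortError("source counts are not aligned with sink taxa")
    ss = np.random.SeedSequence(seed)
    out = np.zeros((sinks.n_samples, len(sources) + 1))
    for i, sink in enumerate(sinks.counts):
        if sink.sum() == 0:
            raise CohortError(f"zero-depth sink {sinks.sample_ids[i]!r}")
        children = ss.spawn(restarts)
        acc = np.zeros(len(sources) + 1)
        for r in range(restarts):
            rng = np.random.default_rng(children[r])
            acc += _gibbs_one_sink(
                sink, src_counts, alpha1, alpha2, beta, burn_in, draws, rng
            )
        out[i] = acc / restarts
    out /= out.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(out, index=sinks.sample_ids, columns=src_labels + ["unknown"])
    return SourceProfile(frame, draws, burn_in, restarts)


def track_fecal_sources(
    table: FeatureTable,
    design: CohortDesign,
    sink_habitat: str = "feces",
    companion_habitat: str = "rumen",
    **kwargs,
) -> pd.DataFrame:
    """Per-subject source tracking across the day grid.

    For each subject and each day after the first, the fecal sample is the
    sink; its candidate sources are the same subject's fecal sample at the
    previous grid day and the companion-habitat (rumen) sample from the
    same day.  Returns a long frame of proportions.
    """
    meta = design.indexed()
    days = design.days
    sample_of = {
        (r["subject_id"], int(r["day"]), r["habitat"]): sid
        for sid, r in meta.iterrows()
    }
    t_idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for subj in meta["subject_id"].unique():
        for prev_day, day in zip(days[:-1], days[1:]):
            sink_id = sample_of.get((subj, day, sink_habitat))
            prev_id = sample_of.get((subj, prev_day, sink_habitat))
            same_id = sample_of.get((subj, day, companion_habitat))
            if sink_id is None or (prev_id is None and same_id is None):
                continue
            if sink_id not in t_idx:
                continue
            sources = []
            if prev_id in t_idx:
                sources.append(("prior_feces", table.counts[t_idx[prev_id]]))
            if same_id in t_idx:
                sources.append(("same_day_rumen", table.counts[t_idx[same_id]]))
            sink_tab = table.select_samples([sink_id])
            prof = source_track(sink_tab, sources, **kwargs)
            rec = {"subject_id": subj, "day": day, "sink": sink_id}
            rec.update(prof.proportions.iloc[0].to_dict())
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EnvFit


def envfit(
    ordination: OrdinationResult,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Fit covariates onto ordination space, vegan-envfit style.

    Continuous covariates: r^2 of the least-squares projection of the
    (centred) covariate onto the first ``n_axes`` ordination axes.
    Categorical covariates: r^2 from between-centroid separation of the
    coordinates (1 - SS_within / SS_total).  P-values come from permuting
    covariate rows.  A constant covariate is reported with r^2 = 0 and a
    flag.
    """
    if n_perm < 1:
        raise CohortError("n_perm must be >= 1")
    ids = [s for s in ordination.sample_ids if s in covariates.index]
    if len(ids) < 3:
        raise CohortError("covariate rows do not match ordination samples")
    rows_idx = [ordination.sample_ids.index(s) for s in ids]
    X = ordination.coordinates[rows_idx, : min(n_axes, ordination.coordinates.shape[1])]
    Xc = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)
    out = []
    for name in covariates.columns:
        col = covariates.loc[ids, name]
        numeric = pd.api.types.is_numeric_dtype(col)
        if numeric:
            v = col.to_numpy(dtype=float)
            if np.ptp(v) == 0:
                out.append({"covariate": name, "kind": "continuous", "r2": 0.0,
                            "p": 1.0, "constant": True})
                continue

            def r2_of(vec: np.ndarray) -> float:
                vc = vec - vec.mean()
                coef, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
                fit = Xc @ coef
                return float(1.0 - ((vc - fit) ** 2).sum() / (vc**2).sum())

            r2 = r2_of(v)
            perm_ge = sum(r2_of(rng.permutation(v)) >= r2 - 1e-12 for _ in range(n_perm))
        else:
            labels = col.to_numpy()
            if len(np.unique(labels)) < 2:
                out.append({"covariate": name, "kind": "categorical", "r2": 0.0,
                            "p": 1.0, "constant": True})
                continue

            def r2_of_cat(lab: np.ndarray) -> float:
                ss_total = float((Xc**2).sum())
                ss_within = 0.0
                for g in np.unique(lab):
                    sub = Xc[lab == g]
                    ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
                return 1.0 - ss_within / ss_total if ss_total > 0 else 0.0

            r2 = r2_of_cat(labels)
            perm_ge = sum(
                r2_of_cat(rng.permutation(labels)) >= r2 - 1e-12 for _ in range(n_perm)
            )
        p = (1 + perm_ge) / (1 + n_perm)
        out.append({"covariate": name, "kind": "continuous" if numeric else "categorical",
                    "r2": r2, "p": p, "constant": False})
    return pd.DataFrame(out).set_index("covariate")


# ---------------------------------------------------------------------------
# RBHB


def rbhb(
    glucose_mg_dl, insulin_uU_ml, nefa_mmol_l, bhb_mmol_l, base: float = 10.0
):
    """Revised insulin-sensitivity check index with BHB.

    ``1 / (log glucose + log INS + log NEFA + log BHB)`` with base-10 logs
    (the original QUICKI convention); any non-positive component makes the
    index undefined (NaN).  Accepts scalars or arrays.
    """
    comps = [
        np.asarray(x, dtype=float)
        for x in (glucose_mg_dl, insulin_uU_ml, nefa_mmol_l, bhb_mmol_l)
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = [np.where(c > 0, np.log(np.clip(c, 1e-300, None)) / math.log(base), np.nan)
                for c in comps]
        denom = sum(logs)
        out = np.where(np.isfinite(denom), 1.0 / denom, np.nan)
    bad = ~np.isfinite(np.asarray(denom))
    if np.any(bad):
        logger.warning("rbhb undefined for %d sample(s) (non-positive component)",
                       int(np.sum(bad)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# succession-type phenotype effects


def succession_type_effects(
    design: CohortDesign,
    stage_labels,
    phenotypes: list[str] | None = None,
    habitat: str | None = None,
    min_group: int = 5,
) -> pd.DataFrame:
    """Test phenotype changes across succession-transition types.

    For every subject and consecutive grid-day pair, the transition type is
    ``stage_t -> stage_t+1`` (from per-sample stage labels) and the
    response is the within-subject phenotype change over the same
    interval.  Types with at least ``min_group`` subjects are compared by
    Kruskal-Wallis with Dunn post hoc; KW p-values are BH-adjusted across
    phenotypes, Dunn p-values across type pairs within a phenotype.
    """
    if hasattr(stage_labels, "labels_by_sample"):
        stage_labels = stage_labels.labels_by_sample()
    phenos = phenotypes or design.phenotype_cols
    if not phenos:
        raise CohortError("no phenotype columns declared")
    meta = design.frame
    if habitat is not None:
        meta = meta[meta["habitat"] == habitat]
    days = sorted(meta["day"].unique())
    sample_of = {
        (r.subject_id, r.day): r.sample_id for r in meta.itertuples(index=False)
    }
    idx = design.indexed()
    records = []
    for subj in meta["subject_id"].unique():
        for d0, d1 in zip(days[:-1], days[1:]):
            sa, sb = sample_of.get((subj, d0)), sample_of.get((subj, d1))
            if sa not in stage_labels or sb not in stage_labels:
                continue
            ttype = f"{stage_labels[sa]}->{stage_labels[sb]}"
            rec = {"subject_id": subj, "interval": (d0, d1), "type": ttype}
            for ph in phenos:
                rec[ph] = idx.loc[sb, ph] - idx.loc[sa, ph]
            records.append(rec)
    deltas = pd.DataFrame(records)
    if deltas.empty:
        raise CohortError("no labelled subject intervals")
    counts = deltas["type"].value_counts()
    keep = counts[counts >= min_group].index
    dropped = counts[counts < min_group]
    if len(dropped):
        logger.warning("excluding %d transition type(s) below min_group=%d",
                       len(dropped), min_group)
    deltas = deltas[deltas["type"].isin(keep)]
    if deltas["type"].nunique() < 2:
        raise CohortError("fewer than two transition types meet min_group")
    rows = []
    for ph in phenos:
        vals = deltas[ph].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        h, p, dunn = kw_dunn(vals[ok], deltas["type"].to_numpy()[ok])
        rows.append({"phenotype": ph, "kw_h": h, "kw_p": p, "dunn": dunn})
    out = pd.DataFrame(rows)
    out["kw_p_adj"] = bh_adjust(out["kw_p"].to_numpy())
    return out
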