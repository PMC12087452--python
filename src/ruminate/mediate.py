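"""Differential filtering and species -> pathway -> phenotype mediation.

Mediation follows the product-of-coefficients formulation: a mediator model
``m = a s + e1`` and an outcome model ``y = c' s + b m + e2`` give the
average causal mediation effect ACME = a*b, the average direct effect
ADE = c', and the total effect c' + a*b (which equals the simple-regression
slope of y on s exactly, an OLS identity).  Uncertainty comes from a
nonparametric bootstrap with percentile intervals.  Species abundances are
standardized as z-scores of log10 relative abundance (half-minimum zero
replacement) before regression so effects are comparable across taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._stats import bh_adjust, kw_dunn
from .cohort import CohortError, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialFilter",
    "MediationResult",
    "species_zscores",
    "differential_filter",
    "mediate",
    "mediation_screen",
]


@dataclass
class DifferentialFilter:
    prevalence_min: float
    abundance_min: float
    surviving: list[str]
    stats: pd.DataFrame  # per surviving feature: kw_h, p, p_adj
    dunn: dict[str, pd.DataFrame]


@dataclass
class MediationResult:
    species: str
    pathway: str
    phenotype: str
    acme: float
    ade: float
    total: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    total_p: float
    proportion_mediated: float
    n: int
    collinear: bool = False


def species_zscores(rel_column: np.ndarray) -> np.ndarray:
    """z of log10 relative abundance with half-minimum zero replacement."""
    x = np.asarray(rel_column, dtype=float).copy()
    pos = x[x > 0]
    if pos.size == 0:
        return np.zeros_like(x)
    x[x == 0] = 0.5 * pos.min()
    lx = np.log10(x)
    sd = lx.std()
    return (lx - lx.mean()) / (sd if sd > 0 else 1.0)


def differential_filter(
    abundances: pd.DataFrame,
    groups,
    prevalence_min: float = 0.5,
    abundance_min: float = 0.001,
    alpha: float = 0.05,
) -> DifferentialFilter:
    """Prevalence/abundance filter + Kruskal-Wallis differential testing.

    ``abundances`` is samples x features (counts or TPM-like); features are
    kept iff present in more than ``prevalence_min`` of samples AND their
    mean relative abundance exceeds ``abundance_min``.  Surviving features
    are tested across groups (KW, BH-adjusted); Dunn post hoc is run for
    features significant at ``alpha`` after adjustment.
    """
    groups = np.asarray(pd.Series(groups).loc[abundances.index])
    if len(np.unique(groups)) < 2:
        raise CohortError("need at least two groups")
    data = abundances.to_numpy(dtype=float)
    totals = data.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise CohortError("samples with zero total abundance")
    rel = data / totals
    prevalence = (data > 0).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    keep = (prevalence > prevalence_min) & (mean_rel > abundance_min)
    surviving = [f for f, k in zip(abundances.columns, keep) if k]
    if not surviving:
        logger.warning("no features survive the %.0f%%/%g filter",
                       prevalence_min * 100, abundance_min)
        empty = pd.DataFrame(columns=["kw_h", "p", "p_adj"])
        return DifferentialFilter(prevalence_min, abundance_min, [], empty, {})
    stats_rows = []
    for f in surviving:
        j = abundances.columns.get_loc(f)
        h, p, _ = kw_dunn(rel[:, j], groups)
        stats_rows.append({"feature": f, "kw_h": h, "p": p})
    stats = pd.DataFrame(stats_rows).set_index("feature")
    stats["p_adj"] = bh_adjust(stats["p"].to_numpy())
    dunn = {}
    for f in stats.index[stats["p_adj"] < alpha]:
        j = abundances.columns.get_loc(f)
        _, _, d = kw_dunn(rel[:, j], groups)
        dunn[f] = d
    return DifferentialFilter(prevalence_min, abundance_min, surviving, stats, dunn)


def _slopes(s: np.ndarray, m: np.ndarray, y: np.ndarray):
    """(a, b, c') by OLS: m ~ s and y ~ s + m, via closed-form moments."""
    sc = s - s.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    vss = sc @ sc
    a = (sc @ mc) / vss
    # two-regressor OLS for y ~ s + m
    vmm = mc @ mc
    vsm = sc @ mc
    det = vss * vmm - vsm**2
    c_prime = (vmm * (sc @ yc) - vsm * (mc @ yc)) / det
    b = (vss * (mc @ yc) - vsm * (sc @ yc)) / det
    return a, b, c_prime


def _boot_p(samples: np.ndarray, estimate: float) -> float:
    """Two-sided bootstrap p-value for the null of zero effect.

    Normal approximation using the bootstrap standard error; unlike a
    percentile p-value it has no 2/n_boot resolution floor, so strong
    effects stay distinguishable after multiple-testing adjustment across
    a large screen.
    """
    se = samples.std(ddof=1)
    if se == 0:
        return 0.0 if estimate != 0 else 1.0
    return float(2.0 * norm.sf(abs(estimate) / se))


def mediate(
    species_z: np.ndarray,
    pathway: np.ndarray,
    phenotype: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    labels: tuple[str, str, str] = ("species", "pathway", "phenotype"),
) -> MediationResult:
    """Product-of-coefficients mediation with bootstrap inference.

    ACME = a*b, ADE = c', total = c' + a*b (exact identity for the point
    estimates).  Percentile CIs and two-sided p-values from ``n_boot``
    nonparametric resamples.  Near-perfect collinearity between species and
    mediator is flagged and the effect split is not interpretable.
    """
    s = np.asarray(species_z, dtype=float)
    m = np.asarray(pathway, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if not (len(s) == len(m) == len(y)):
        raise CohortError("input vectors must share a length")
    if len(s) < 10:
        raise CohortError("need at least 10 observations")
    if np.isnan(s).any() or np.isnan(m).any() or np.isnan(y).any():
        mask = np.isfinite(s) & np.isfinite(m) & np.isfinite(y)
        s, m, y = s[mask], m[mask], y[mask]
        if len(s) < 10:
            raise CohortError("fewer than 10 complete observations")
    for name, v in (("species", s), ("pathway", m), ("phenotype", y)):
        if np.ptp(v) == 0:
            raise CohortError(f"zero variance in {name}")
    r_sm = np.corrcoef(s, m)[0, 1]
    collinear = bool(abs(r_sm) > 0.999)
    if collinear:
        logger.warning("species and mediator are collinear (r=%.4f)", r_sm)

    a, b, c_prime = _slopes(s, m, y)
    acme, ade = a * b, c_prime
    total = acme + ade

    rng = np.random.default_rng(seed)
    n = len(s)
    boots = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ab, bb, cb = _slopes(s[idx], m[idx], y[idx])
        except (ZeroDivisionError, FloatingPointError):
            ab, bb, cb = a, b, c_prime
        boots[i] = (ab * bb, cb, ab * bb + cb)
    lo = (1 - ci_level) / 2 * 100
    hi = 100 - lo
    cis = [tuple(np.percentile(boots[:, j], [lo, hi])) for j in range(3)]
    ps = [_boot_p(boots[:, j], est) for j, est in zip(range(3), (acme, ade, total))]
    prop = acme / total if total != 0 else np.nan
    return MediationResult(
        labels[0], labels[1], labels[2],
        float(acme), float(ade), float(total),
        cis[0], cis[1], cis[2],
        ps[0], ps[1], ps[2],
        float(prop), n, collinear,
    )


def mediation_screen(
    species_table: FeatureTable,
    pathway_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    groups=None,
    prevalence_min: float = 0.5,
    species_abundance_min: float = 0.001,
    pathway_abundance_min: float = 0.0001,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen all (species, pathway, phenotype) triples for mediation.

    Species and pathways are first reduced by the prevalence/abundance
    filters (differential testing is applied when ``groups`` is given, and
    only differential features at ``alpha`` are retained).  Every surviving
    triple is tested with :func:`mediate`; ACME p-values are BH-adjusted
    across the screen.  A triple is "mediating" if its adjusted ACME p is
    below ``alpha``, and "full" if ACME (adjusted), ADE and total are all
    significant.  Results are ranked by |proportion mediated| within the
    full/mediating strata.
    """
    shared = [s for s in species_table.sample_ids
              if s in pathway_table.index and s in phenotypes.index]
    if not shared:
        raise CohortError("no samples shared across species, pathways, phenotypes")
    sp = species_table.select_samples(shared)
    pw = pathway_table.loc[shared]
    ph = phenotypes.loc[shared]

    def _survivors(frame: pd.DataFrame, ab_min: float) -> list[str]:
        data = frame.to_numpy(dtype=float)
        totals = data.sum(axis=1, keepdims=True)
        rel = np.where(totals > 0, data / totals, 0.0)
        keep = ((data > 0).mean(axis=0) > prevalence_min) & (rel.mean(axis=0) > ab_min)
        return [c for c, k in zip(frame.columns, keep) if k]

    sp_frame = sp.to_dataframe()
    species_keep = _survivors(sp_frame, species_abundance_min)
    pathway_keep = _survivors(pw, pathway_abundance_min)
    if groups is not None:
        g = pd.Series(groups).loc[shared]
        df_sp = differential_filter(sp_frame[species_keep] if species_keep else sp_frame,
                                    g, 0.0, 0.0, alpha)
        species_keep = list(df_sp.stats.index[df_sp.stats["p_adj"] < alpha])
        df_pw = differential_filter(pw[pathway_keep] if pathway_keep else pw,
                                    g, 0.0, 0.0, alpha)
        pathway_keep = list(df_pw.stats.index[df_pw.stats["p_adj"] < alpha])
    if not species_keep or not pathway_keep:
        logger.warning("empty surviving species or pathway set; nothing to screen")
        return pd.DataFrame()

    rel = sp.relative_abundance()
    sp_idx = {t: j for j, t in enumerate(sp.taxon_ids)}
    z_cache = {t: species_zscores(rel[:, sp_idx[t]]) for t in species_keep}
    rng = np.random.default_rng(seed)
    rows = []
    for t in species_keep:
        for pwy in pathway_keep:
            for phen in ph.columns:
                try:
                    res = mediate(
                        z_cache[t],
                        pw[pwy].to_numpy(dtype=float),
                        ph[phen].to_numpy(dtype=float),
                        n_boot=n_boot,
                        seed=int(rng.integers(2**31)),
                        labels=(t, pwy, phen),
                    )
                except CohortError:
                    continue
                rows.append(res)
    if not rows:
        return pd.DataFrame()
    out = pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "pathway": [r.pathway for r in rows],
            "phenotype": [r.phenotype for r in rows],
            "acme": [r.acme for r in rows],
            "ade": [r.ade for r in rows],
            "total": [r.total for r in rows],
            "acme_p": [r.acme_p for r in rows],
            "ade_p": [r.ade_p for r in rows],
            "total_p": [r.total_p for r in rows],
            "proportion_mediated": [r.proportion_mediated for r in rows],
            "collinear": [r.collinear for r in rows],
        }
    )
    out["acme_p_adj"] = bh_adjust(out["acme_p"].to_numpy())
    out["mediating"] = out["acme_p_adj"] < alpha
    out["full"] = out["mediating"] & (out["ade_p"] < alpha) & (out["total_p"] < alpha)
    out["rank_key"] = out["proportion_mediated"].abs()
    out = out.sort_values(
        ["full", "mediating", "rank_key"], ascending=[False, False, False]
    ).drop(columns="rank_key").reset_index(drop=True)
    return out
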