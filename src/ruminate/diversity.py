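"""Alpha/beta diversity, ordination, PERMANOVA and individual variability.

Alpha metrics delegate to scikit-bio (bias-corrected Chao1; Shannon with a
natural-log default, matching the vegan convention).  Bray-Curtis and
classical PCoA are computed through scipy/scikit-bio.  PERMANOVA is written
here because the pipeline needs an exhaustive-enumeration mode whose p-value
is exactly reproducible, alongside seeded Monte Carlo permutations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _alpha
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .cohort import CohortDesign, CohortError, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "chao1",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "PermanovaResult",
    "permanova",
    "individual_variability",
]


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise CohortError("chao1 undefined for an all-zero sample")
    return float(_alpha.chao1(counts, bias_corrected=True))


def shannon(counts: np.ndarray, base: float = math.e) -> float:
    """Shannon entropy of the relative abundances (natural log by default)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise CohortError("shannon undefined for zero total")
    return float(_alpha.shannon(counts.astype(np.int64), base=base))


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon indices."""
    rows = [
        {"sample_id": s, "chao1": chao1(c), "shannon": shannon(c)}
        for s, c in zip(table.sample_ids, table.counts)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: FeatureTable, use_relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    With ``use_relative`` the matrix is computed on proportions rather than
    (typically rarefied) counts.
    """
    if table.n_samples < 2:
        raise CohortError("need at least two samples")
    data = table.relative_abundance() if use_relative else table.counts.astype(float)
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Sample coordinates from classical scaling of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int = 0

    def as_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (Gower-centered classical scaling).

    Axes with negative eigenvalues are dropped and counted; retained
    proportions are relative to the sum of positive eigenvalues.
    """
    if dm.shape[0] < 3:
        raise CohortError("pcoa needs at least 3 samples")
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    n_neg = int((eig < -1e-10).sum())
    pos = eig > 1e-12
    coords = res.samples.to_numpy()[:, pos]
    eig_pos = eig[pos]
    total = eig_pos.sum()
    prop = eig_pos / total if total > 0 else np.zeros_like(eig_pos)
    if not pos.any():  # fully degenerate (all distances zero)
        coords = np.zeros((dm.shape[0], 1))
        eig_pos = np.zeros(1)
        prop = np.zeros(1)
    return OrdinationResult(list(dm.ids), coords, eig_pos, prop, n_neg)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    f_statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from the squared-distance decomposition."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        if ng > 1:
            sub = d2[np.ix_(mask, mask)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    a = len(groups)
    denom = ss_within / (n - a) if n > a else np.inf
    f = (ss_among / (a - 1)) / denom if denom > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Monte Carlo mode uses free permutation of labels with
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.  In exhaustive mode all
    distinct label arrangements are enumerated (identity included) and
    ``p = #{F >= F_obs} / #arrangements`` — the exact permutation test.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dm.shape[0]:
        raise CohortError("labels length must match distance matrix")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise CohortError("permanova needs at least two groups")
    if not exhaustive and n_perm < 1:
        raise CohortError("n_perm must be >= 1")
    d2 = dm.data**2
    f_obs, r2 = _pseudo_f(d2, labels, groups)
    if exhaustive:
        n = len(labels)
        seen: set[tuple] = set()
        count_ge = 0
        for perm in itertools.permutations(range(n)):
            lab = tuple(labels[list(perm)])
            if lab in seen:
                continue
            seen.add(lab)
            f_p, _ = _pseudo_f(d2, np.asarray(lab), groups)
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / len(seen)
        return PermanovaResult(f_obs, r2, p, len(seen), True)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        f_p, _ = _pseudo_f(d2, labels[rng.permutation(len(labels))], groups)
        if f_p >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, False)


# ---------------------------------------------------------------------------
# intra- vs inter-individual variability


def individual_variability(
    dm: DistanceMatrix, design: CohortDesign
) -> pd.DataFrame:
    """Olsson-style per-subject variability medians.

    ``intra`` is the median dissimilarity over all within-subject sample
    pairs; ``inter`` the median over pairs of this subject's samples against
    every other subject's samples.  Subjects with fewer than two samples are
    excluded from ``intra`` (logged) but still receive an ``inter`` value.
    """
    meta = design.indexed()
    ids = [s for s in dm.ids if s in meta.index]
    if len(ids) < 2:
        raise CohortError("need at least two designed samples")
    subj = meta.loc[ids, "subject_id"]
    data = dm.filter(ids).data
    rows = []
    for s in subj.unique():
        own = np.flatnonzero((subj == s).to_numpy())
        other = np.flatnonzero((subj != s).to_numpy())
        intra = np.nan
        if len(own) >= 2:
            pairs = data[np.ix_(own, own)]
            intra = float(np.median(pairs[np.triu_indices(len(own), 1)]))
        else:
            logger.warning("subject %s has <2 samples; intra skipped", s)
        inter = (
            float(np.median(data[np.ix_(own, other)])) if len(other) else np.nan
        )
        rows.append({"subject_id": s, "intra": intra, "inter": inter,
                     "n_samples": len(own)})
    return pd.DataFrame(rows).set_index("subject_id")
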