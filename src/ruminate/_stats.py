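"""Shared nonparametric test helpers (Kruskal-Wallis + Dunn, BH adjustment)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "dunn_test", "kw_dunn"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based z-tests for all group pairs, with tie correction.

    Two-sided normal p-values; BH adjustment across the pairs is added as
    ``p_adj``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    uniq = np.unique(groups)
    rows = []
    for a_i in range(len(uniq)):
        for b_i in range(a_i + 1, len(uniq)):
            ga, gb = uniq[a_i], uniq[b_i]
            ra = ranks[groups == ga]
            rb = ranks[groups == gb]
            se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
            z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
            p = 2.0 * norm.sf(abs(z))
            rows.append({"group_a": ga, "group_b": gb, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def kw_dunn(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across groups followed by Dunn pairwise tests.

    Returns ``(H, p, dunn_frame)``; degenerate inputs (a single group, or
    all values identical) give ``H=0, p=1`` and an empty frame.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2 or np.ptp(np.asarray(values, dtype=float)) == 0:
        return 0.0, 1.0, pd.DataFrame(columns=["group_a", "group_b", "z", "p", "p_adj"])
    arrays = [np.asarray(values)[groups == g] for g in uniq]
    h, p = kruskal(*arrays)
    return float(h), float(p), dunn_test(values, groups)
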