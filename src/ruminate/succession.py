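"""Markov-chain succession over community states and the stage classifier.

Community-state labels per sample (from the DMM step, or any labelling) are
turned into per-interval and pooled transition count/probability matrices;
states are then classified into succession stages (rapid transition /
transition / stable) from their self- and mutual-transition rates; finally a
tree-ensemble classifier predicts a sample's stage from taxon abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .cohort import CohortDesign, CohortError, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionModel",
    "SuccessionStaging",
    "StageClassifierReport",
    "estimate_transitions",
    "classify_stages",
    "dominant_transitions",
    "train_stage_classifier",
]

RAPID, TRANSITION, STABLE = "rapid_transition", "transition", "stable"


@dataclass
class TransitionModel:
    states: list[int]
    intervals: list[tuple[int, int]]  # (day_t, day_t+1) pairs of the grid
    interval_counts: dict[tuple[int, int], np.ndarray]
    pooled_counts: np.ndarray
    n_subjects_observed: dict[tuple[int, int], int]
    skipped: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def pooled_probabilities(self) -> np.ndarray:
        """Row-normalised pooled transition matrix (MLE); empty rows are 0."""
        C = self.pooled_counts.astype(float)
        totals = C.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(totals > 0, C / totals, 0.0)
        return P


@dataclass
class SuccessionStaging:
    stage_by_state: dict[int, str]
    thresholds: dict[str, float]


@dataclass
class StageClassifierReport:
    features: list[str]
    per_repeat_auc: list[float]
    mean_auc: float
    importances: pd.DataFrame
    n_candidate_features: int
    scheme: str


def estimate_transitions(
    labels: Mapping[str, int] | "object",
    design: CohortDesign,
) -> TransitionModel:
    """Count state transitions over consecutive grid timepoints.

    ``labels`` maps sample_id -> state (a :class:`~ruminate.dmm.ClusterAssignment`
    is also accepted).  For each consecutive pair of days on the design's
    grid, a subject contributes one transition if it has labelled samples at
    both endpoints; otherwise it is skipped and counted in the completeness
    report.  The pooled matrix sums the interval matrices (time-homogeneous
    view).
    """
    if hasattr(labels, "labels_by_sample"):
        labels = labels.labels_by_sample()
    days = design.days
    if len(days) < 2:
        raise CohortError("need at least two grid timepoints")
    states = sorted({int(v) for v in labels.values()})
    s_index = {s: i for i, s in enumerate(states)}
    k = len(states)
    meta = design.frame
    sample_of = {
        (r.subject_id, r.day): r.sample_id for r in meta.itertuples(index=False)
    }
    intervals = list(zip(days[:-1], days[1:]))
    interval_counts: dict[tuple[int, int], np.ndarray] = {}
    n_obs: dict[tuple[int, int], int] = {}
    skipped: dict[tuple[int, int], int] = {}
    subjects = meta["subject_id"].unique()
    total = 0
    for iv in intervals:
        C = np.zeros((k, k), dtype=np.int64)
        obs = skip = 0
        for subj in subjects:
            sa = sample_of.get((subj, iv[0]))
            sb = sample_of.get((subj, iv[1]))
            if sa in labels and sb in labels:
                C[s_index[int(labels[sa])], s_index[int(labels[sb])]] += 1
                obs += 1
            else:
                skip += 1
        interval_counts[iv] = C
        n_obs[iv] = obs
        skipped[iv] = skip
        total += obs
    if total == 0:
        raise CohortError("no observable consecutive sample pairs")
    pooled = sum(interval_counts.values())
    return TransitionModel(states, intervals, interval_counts, pooled, n_obs, skipped)


def classify_stages(
    model: TransitionModel,
    self_rapid: float = 0.20,
    self_stable: float = 0.50,
    mutual_stable: float = 0.30,
) -> SuccessionStaging:
    """Assign each state a succession stage from the pooled chain.

    Rule, applied in order: (1) self-transition rate < ``self_rapid`` ->
    rapid transition; (2) self-rate >= ``self_stable`` and a reciprocal rate
    >= ``mutual_stable`` with some other stable-eligible state (or no other
    eligible partner exists) -> stable; (3) otherwise -> transition.
    Raising a state's self-rate can never demote it.
    """
    P = model.pooled_probabilities
    row_sums = model.pooled_counts.sum(axis=1)
    if np.any((row_sums > 0) & (np.abs(P.sum(axis=1) - 1.0) > 1e-12)):
        raise CohortError("unnormalised transition probabilities")
    k = len(model.states)
    self_rates = np.diag(P)
    eligible = [i for i in range(k) if self_rates[i] >= self_stable]
    stage: dict[int, str] = {}
    for i, state in enumerate(model.states):
        if self_rates[i] < self_rapid:
            stage[state] = RAPID
        elif i in eligible:
            # partners are eligible states this one actually exchanges with;
            # a state with no reachable partner is absorbing, hence stable
            partners = [
                j for j in eligible if j != i and (P[i, j] > 0 or P[j, i] > 0)
            ]
            # mutual rate = both directions of exchange crossing the bar
            if not partners or any(
                min(P[i, j], P[j, i]) >= mutual_stable for j in partners
            ):
                stage[state] = STABLE
            else:
                stage[state] = TRANSITION
        else:
            stage[state] = TRANSITION
    return SuccessionStaging(
        stage,
        {
            "self_rapid": self_rapid,
            "self_stable": self_stable,
            "mutual_stable": mutual_stable,
        },
    )


def dominant_transitions(
    model: TransitionModel, interval: tuple[int, int]
) -> pd.DataFrame:
    """Transitions of one interval ranked by their share of all transitions."""
    if interval not in model.interval_counts:
        raise CohortError(f"unknown interval {interval!r}")
    C = model.interval_counts[interval]
    total = C.sum()
    if total == 0:
        raise CohortError(f"no observed transitions in interval {interval!r}")
    rows = []
    for i, si in enumerate(model.states):
        for j, sj in enumerate(model.states):
            if C[i, j] > 0:
                rows.append(
                    {
                        "from_state": si,
                        "to_state": sj,
                        "count": int(C[i, j]),
                        "share": C[i, j] / total,
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["share", "from_state", "to_state"], ascending=[False, True, True]
    ).reset_index(drop=True)


def train_stage_classifier(
    table: FeatureTable,
    stage_labels: Mapping[str, str],
    n_repeats: int = 5,
    test_fraction: float = 0.30,
    abundance_min: float = 0.001,
    top_n: int | None = None,
    n_estimators: int = 300,
    seed: int = 0,
) -> StageClassifierReport:
    """Random-forest stage classifier with repeated stratified hold-out.

    Candidate features are taxa with mean relative abundance above
    ``abundance_min`` (default 0.1%).  Each repeat holds out
    ``test_fraction`` of samples stratified by stage, fits on the rest, and
    scores macro one-vs-rest AUC on the hold-out; if ``top_n`` is given, the
    model is refit on the training fold using only the ``top_n``
    most-important features before scoring.  Importances are mean decrease
    in impurity averaged over repeats.
    """
    ids = [s for s in table.sample_ids if s in stage_labels]
    if len(ids) < len(table.sample_ids):
        logger.warning(
            "%d samples lack a stage label and are excluded",
            len(table.sample_ids) - len(ids),
        )
    sub = table.select_samples(ids)
    y = np.array([stage_labels[s] for s in ids])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise CohortError("need at least two stages")
    if counts.min() < 2:
        raise CohortError("every stage needs at least two samples")
    if counts.min() < 10:
        logger.warning("a stage has fewer than 10 samples; AUC may be unstable")

    rel = sub.relative_abundance()
    keep = np.flatnonzero(rel.mean(axis=0) > abundance_min)
    if keep.size == 0:
        raise CohortError("no taxa pass the abundance filter")
    X = rel[:, keep]
    feat_names = [sub.taxon_ids[j] for j in keep]

    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    aucs: list[float] = []
    imp_sum = np.zeros(X.shape[1])
    used = np.array(feat_names)
    for rep, (tr, te) in enumerate(splitter.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + rep, n_jobs=1
        ).fit(X[tr], y[tr])
        cols = np.arange(X.shape[1])
        if top_n is not None and top_n < X.shape[1]:
            cols = np.argsort(rf.feature_importances_)[::-1][:top_n]
            rf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed + rep, n_jobs=1
            ).fit(X[tr][:, cols], y[tr])
        proba = rf.predict_proba(X[te][:, cols])
        if len(classes) == 2:
            auc = roc_auc_score(y[te], proba[:, 1])
        else:
            auc = roc_auc_score(y[te], proba, multi_class="ovr", average="macro")
        aucs.append(float(auc))
        full_imp = np.zeros(X.shape[1])
        full_imp[cols] = rf.feature_importances_
        imp_sum += full_imp
    importances = (
        pd.DataFrame({"taxon_id": used, "importance": imp_sum / n_repeats})
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )
    return StageClassifierReport(
        features=feat_names,
        per_repeat_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        importances=importances,
        n_candidate_features=len(feat_names),
        scheme=f"{n_repeats}x stratified {int((1 - test_fraction) * 100)}/"
        f"{int(test_fraction * 100)} hold-out",
    )
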