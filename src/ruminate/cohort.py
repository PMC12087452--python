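"""Data model and I/O for longitudinal microbiome cohorts.

The pipeline operates on three aligned objects: a :class:`FeatureTable` of
integer counts (samples x taxa), a :class:`CohortDesign` describing each
sample (subject, day relative to calving, habitat, covariates, phenotypes),
and an optional rooted :class:`Phylogeny` over the taxa.  Everything
downstream (diversity, community-state typing, succession, assembly
partitioning, mediation) consumes these objects.

On-disk formats are plain TSV for tables and newick for trees, so fixtures
stay inspectable.  Feature tables default to the taxa-rows dialect common in
amplicon exports; the orientation is explicit in the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "CohortDesign",
    "Phylogeny",
    "AlignedCohort",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "rarefy",
    "align_tables",
]


class CohortError(ValueError):
    """Raised on malformed or inconsistent cohort inputs."""


@dataclass
class FeatureTable:
    """Integer count matrix, samples x taxa, with optional taxonomy.

    Parameters
    ----------
    sample_ids : sequence of str
        Ordered, unique sample identifiers (rows of ``counts``).
    taxon_ids : sequence of str
        Ordered, unique taxon identifiers (columns of ``counts``).
    counts : ndarray of int, shape (n_samples, n_taxa)
        Non-negative counts.  Every sample must have a positive total.
    taxonomy : mapping, optional
        ``taxon_id -> lineage string``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CohortError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise CohortError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if counts.size == 0:
            raise CohortError("empty table")
        if not np.issubdtype(counts.dtype, np.number):
            raise CohortError("non-numeric counts")
        if np.any(counts < 0):
            raise CohortError("negative counts")
        if not np.allclose(counts, np.round(counts)):
            raise CohortError("counts must be integers")
        self.counts = counts.astype(np.int64)
        for kind, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})[0]
                raise CohortError(f"duplicate {kind} id: {dup!r}")
        if np.any(self.counts.sum(axis=1) == 0):
            bad = [s for s, t in zip(self.sample_ids, self.counts.sum(axis=1)) if t == 0]
            raise CohortError(f"samples with zero total counts: {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Counts normalised to per-sample proportions (rows sum to 1)."""
        totals = self.sample_totals().astype(float)
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, keep: Sequence[str]) -> "FeatureTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise CohortError(f"unknown sample ids: {missing[:5]}")
        rows = [idx[s] for s in keep]
        return FeatureTable(list(keep), list(self.taxon_ids), self.counts[rows], self.taxonomy)

    def select_taxa(self, keep: Sequence[str]) -> "FeatureTable":
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in keep if t not in idx]
        if missing:
            raise CohortError(f"unknown taxon ids: {missing[:5]}")
        cols = [idx[t] for t in keep]
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in keep if t in self.taxonomy}
        return FeatureTable(list(self.sample_ids), list(keep), self.counts[:, cols], tax)


@dataclass
class CohortDesign:
    """Per-sample metadata: subject, day relative to calving, habitat, extras.

    ``day`` is an integer day on the cohort's sampling grid; negative values
    are prepartum.  ``habitat`` distinguishes compartments (e.g. rumen vs
    feces).  Any additional columns of the underlying frame are treated as
    covariates unless listed in ``phenotype_cols``.
    """

    frame: pd.DataFrame
    phenotype_cols: list[str] = field(default_factory=list)

    REQUIRED = ("sample_id", "subject_id", "day", "habitat")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise CohortError(f"design is missing required column {col!r}")
        frame = self.frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["day"] = frame["day"].astype(int)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CohortError(f"duplicate sample id: {dup!r}")
        key = frame[["subject_id", "day", "habitat"]]
        if key.duplicated().any():
            row = key[key.duplicated()].iloc[0]
            raise CohortError(
                f"duplicate (subject, day, habitat) triple: {tuple(row)}"
            )
        self.frame = frame.reset_index(drop=True)
        unknown = [c for c in self.phenotype_cols if c not in frame.columns]
        if unknown:
            raise CohortError(f"phenotype columns not in design: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def days(self) -> list[int]:
        """The ordered day grid observed in the design."""
        return sorted(self.frame["day"].unique())

    @property
    def covariate_cols(self) -> list[str]:
        skip = set(self.REQUIRED) | set(self.phenotype_cols)
        return [c for c in self.frame.columns if c not in skip]

    def subset(self, sample_ids: Sequence[str]) -> "CohortDesign":
        sub = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        order = {s: i for i, s in enumerate(sample_ids)}
        sub = sub.sort_values("sample_id", key=lambda c: c.map(order))
        return CohortDesign(sub.reset_index(drop=True), list(self.phenotype_cols))

    def indexed(self) -> pd.DataFrame:
        return self.frame.set_index("sample_id")


class Phylogeny:
    """Rooted tree with named tips and non-negative branch lengths."""

    def __init__(self, tree: TreeNode):
        self.tree = tree
        tips = [t.name for t in tree.tips()]
        if len(set(tips)) != len(tips):
            raise CohortError("duplicate tip names in tree")
        if any(t is None for t in tips):
            raise CohortError("unnamed tips in tree")
        for node in tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise CohortError("negative branch length")
        self.tip_names: list[str] = tips
        self._coph: DistanceMatrix | None = None

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        if isinstance(source, str) and ("(" in source or ";" in source):
            tree = TreeNode.read(StringIO(source), format="newick")
        else:
            tree = TreeNode.read(str(source), format="newick")
        return cls(tree)

    def to_newick(self, path: str | Path) -> None:
        self.tree.write(str(path), format="newick")

    def cophenetic(self) -> DistanceMatrix:
        """Tip-to-tip patristic distance matrix (cached)."""
        if self._coph is None:
            self._coph = self.tree.tip_tip_distances()
        return self._coph

    def cophenetic_for(self, taxa: Sequence[str]) -> np.ndarray:
        dm = self.cophenetic()
        idx = [dm.index(t) for t in taxa]
        return dm.data[np.ix_(idx, idx)]


@dataclass
class AlignedCohort:
    """A feature table, design and optional tree restricted to shared samples."""

    table: FeatureTable
    design: CohortDesign
    tree: Phylogeny | None
    dropped_samples: list[str]
    dropped_taxa: list[str]


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(
    path: str | Path,
    orientation: str = "taxa-rows",
    taxonomy_col: str | None = None,
) -> FeatureTable:
    """Read a TSV count table.

    ``orientation="taxa-rows"`` (the default amplicon-export dialect) expects
    taxa as rows and samples as columns; ``"samples-rows"`` the transpose.
    An optional taxonomy column (taxa-rows only) is split off into the
    table's taxonomy mapping.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise CohortError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise CohortError(f"empty table: {path}")
    taxonomy = None
    if taxonomy_col is not None and taxonomy_col in df.columns:
        taxonomy = {str(t): str(v) for t, v in df[taxonomy_col].items()}
        df = df.drop(columns=[taxonomy_col])
    if orientation == "taxa-rows":
        df = df.T  # -> samples x taxa
    try:
        counts = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"non-numeric counts in {path}: {exc}") from exc
    return FeatureTable(
        [str(s) for s in df.index], [str(t) for t in df.columns], counts, taxonomy
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, orientation: str = "taxa-rows"
) -> None:
    df = table.to_dataframe()
    if orientation == "taxa-rows":
        df = df.T
        df.index.name = "taxon_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_design(
    path: str | Path, phenotype_cols: Sequence[str] = ()
) -> CohortDesign:
    frame = pd.read_csv(path, sep="\t")
    pcols = [c for c in phenotype_cols if c in frame.columns]
    return CohortDesign(frame, list(pcols))


def write_design(design: CohortDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(
    table: FeatureTable, depth: int | str = "min", seed: int = 0
) -> FeatureTable:
    """Subsample every sample to a common depth without replacement.

    Draws are multivariate hypergeometric, so a taxon can never exceed its
    observed count and zero counts stay zero.  Samples whose total is below
    ``depth`` are dropped with a logged warning.  ``depth="min"`` uses the
    minimum sample total (the convention for rarefying to the shallowest
    library).
    """
    totals = table.sample_totals()
    if depth == "min":
        depth_i = int(totals.min())
    else:
        depth_i = int(depth)
    if depth_i <= 0:
        raise CohortError("rarefaction depth must be positive")
    keep_mask = totals >= depth_i
    if not keep_mask.any():
        raise CohortError(f"all samples are below rarefaction depth {depth_i}")
    dropped = [s for s, k in zip(table.sample_ids, keep_mask) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth_i, dropped[:5],
        )
    rng = np.random.default_rng(seed)
    kept_ids = [s for s, k in zip(table.sample_ids, keep_mask) if k]
    out = np.empty((len(kept_ids), table.n_taxa), dtype=np.int64)
    for row, i in enumerate(np.flatnonzero(keep_mask)):
        if totals[i] == depth_i:
            out[row] = table.counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(table.counts[i], depth_i)
    return FeatureTable(kept_ids, list(table.taxon_ids), out, table.taxonomy)


# ---------------------------------------------------------------------------
# alignment


def align_tables(
    table: FeatureTable,
    design: CohortDesign,
    tree: Phylogeny | None = None,
) -> AlignedCohort:
    """Restrict table/design (and taxa, when a tree is given) to shared IDs.

    Samples outside the intersection of table and design are dropped and
    reported; taxa absent from the tree are dropped only when a tree is
    supplied (they cannot enter phylogenetic analyses).
    """
    design_ids = set(design.sample_ids)
    shared = [s for s in table.sample_ids if s in design_ids]
    if not shared:
        raise CohortError("no shared sample ids between table and design")
    dropped_samples = sorted(
        (set(table.sample_ids) | design_ids) - set(shared)
    )
    table_out = table.select_samples(shared)
    design_out = design.subset(shared)
    dropped_taxa: list[str] = []
    if tree is not None:
        tips = set(tree.tip_names)
        keep_taxa = [t for t in table_out.taxon_ids if t in tips]
        if not keep_taxa:
            raise CohortError("no table taxa are present in the tree")
        dropped_taxa = [t for t in table_out.taxon_ids if t not in tips]
        if dropped_taxa:
            logger.warning(
                "align_tables: %d taxa absent from tree dropped for "
                "phylogenetic analyses", len(dropped_taxa),
            )
            table_out = table_out.select_taxa(keep_taxa)
    if dropped_samples:
        logger.warning("align_tables: %d sample(s) dropped", len(dropped_samples))
    return AlignedCohort(table_out, design_out, tree, dropped_samples, dropped_taxa)
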