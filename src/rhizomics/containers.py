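"""Core in-memory containers.

The universal input is a samples x taxa count table with aligned sample
metadata; phylogenies are scikit-bio ``TreeNode`` objects so cophenetic
distances, pruning and newick round-trips come from a standard library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import SchemaError

#: canonical niche order along the soil->root continuum
NICHE_ORDER = ("bulk", "rhizosphere", "rhizoplane", "endosphere")

METADATA_COLUMNS = ("sample_id", "cultivar", "niche", "treatment", "replicate")


@dataclass
class CommunityMatrix:
    """Samples x taxa abundance table.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and taxon ids as columns.
        Non-negative; integer reads unless it holds relative abundances.
    is_rarefied
        True once every row has been subsampled to a common depth.
    rarefaction_depth
        The common row sum after rarefaction, else None.
    """

    counts: pd.DataFrame
    is_rarefied: bool = False
    rarefaction_depth: int | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise SchemaError("duplicate sample or taxon identifiers")
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError("negative abundances")
        if self.is_rarefied and self.rarefaction_depth is not None:
            sums = self.counts.to_numpy().sum(axis=1)
            if not np.all(sums == self.rarefaction_depth):
                raise SchemaError("rarefied table with unequal row sums")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalize to proportions."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(self.counts.index[totals == 0])
            raise SchemaError(f"all-zero samples: {bad}")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "CommunityMatrix":
        missing = set(sample_ids) - set(self.counts.index)
        if missing:
            raise SchemaError(f"unknown samples: {sorted(missing)}")
        return replace(self, counts=self.counts.loc[list(sample_ids)])

    def subset_taxa(self, taxon_ids) -> "CommunityMatrix":
        missing = set(taxon_ids) - set(self.counts.columns)
        if missing:
            raise SchemaError(f"unknown taxa: {sorted(missing)}")
        return replace(self, counts=self.counts[list(taxon_ids)])

    def drop_empty_taxa(self) -> "CommunityMatrix":
        keep = self.counts.columns[(self.counts > 0).any(axis=0)]
        return replace(self, counts=self.counts[keep])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "CommunityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df)


def validate_metadata(metadata: pd.DataFrame, matrix: CommunityMatrix | None = None) -> pd.DataFrame:
    """Check the metadata schema and (optionally) its alignment with a table."""
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise SchemaError(f"metadata missing columns: {missing_cols}")
    if metadata["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in metadata")
    if matrix is not None:
        meta_ids = set(metadata["sample_id"])
        table_ids = set(matrix.sample_ids)
        if meta_ids != table_ids:
            raise SchemaError(
                f"metadata/table sample mismatch: only-meta={sorted(meta_ids - table_ids)[:5]}, "
                f"only-table={sorted(table_ids - meta_ids)[:5]}"
            )
    return metadata


def check_tree_covers(tree: TreeNode, taxa) -> None:
    """Raise MissingTipError if any taxon lacks a tip on the tree."""
    from .errors import MissingTipError

    tips = {t.name for t in tree.tips()}
    missing = set(taxa) - tips
    if missing:
        raise MissingTipError(missing)


def cophenetic_matrix(tree: TreeNode, taxa) -> np.ndarray:
    """Tip-to-tip patristic distance matrix aligned to ``taxa`` order."""
    check_tree_covers(tree, taxa)
    dm = tree.tip_tip_distances(endpoints=list(taxa))
    order = [dm.index(t) for t in taxa]
    return dm.data[np.ix_(order, order)]


@dataclass
class CdTable:
    """Per-plot cadmium measurements (mg/kg).

    One row per field plot (cultivar x treatment x replicate) with grain Cd,
    bulk-soil total Cd and CaCl2-extractable (available) soil Cd.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("cultivar", "treatment", "replicate", "grain_cd", "soil_total_cd", "soil_available_cd")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"Cd table missing columns: {missing}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CdTable":
        return cls(table=pd.read_csv(path, sep="\t"))
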