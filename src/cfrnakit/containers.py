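"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` that tracks which numeric space
the values live in (raw counts, CPM, log2(CPM+1), or corrected log2-CPM).
Every transformation in the pipeline checks and advances this tag, so a
stage can never silently receive data in the wrong space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class Space(str, Enum):
    """Numeric space of an expression matrix."""

    raw_counts = "raw_counts"
    cpm = "cpm"
    log2cpm1 = "log2cpm1"
    corrected = "corrected"


class SpaceMismatchError(ValueError):
    """Raised when an operation receives a matrix in the wrong space."""


class DegenerateSampleError(ValueError):
    """Raised when a sample is unusable (e.g. all-zero counts)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a space tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    space
        The numeric space the values are in.
    """

    data: pd.DataFrame
    space: Space = Space.raw_counts

    def __post_init__(self) -> None:
        if isinstance(self.space, str):
            self.space = Space(self.space)
        if not self.data.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if (np.asarray(self.data.values, dtype=float) < 0).any() and self.space in (
            Space.raw_counts,
            Space.cpm,
        ):
            raise ValueError(f"negative values not allowed in {self.space.value} space")
        if self.space is Space.raw_counts:
            vals = np.asarray(self.data.values)
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("raw counts must be integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_space(self, space: Space) -> None:
        if self.space is not space:
            raise SpaceMismatchError(
                f"expected matrix in {space.value} space, got {self.space.value}"
            )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.space)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :].copy(), self.space)


#: Fixed column vocabulary for the sample annotation table.
ANNOTATION_COLUMNS = [
    "sample_id",
    "subject_id",
    "cohort",
    "draw_index",
    "ga_collect_weeks",
    "ga_delivery_weeks",
    "outcome",
    "bmi",
    "maternal_age",
    "race",
    "qc_total_reads",
    "qc_dup_rate",
    "qc_actb_ct",
]

#: Gene biotype vocabulary (matches the coding-gene feature filter).
BIOTYPES = ("protein_coding", "pseudogene", "non_coding")


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from / written to GMT."""

    sets: dict = field(default_factory=dict)  # name -> (description, [gene ids])

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} has no members")

    def names(self):
        return list(self.sets)

    def members(self, name: str):
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {k: (d, list(m)) for k, (d, m) in self.sets.items()} == {
            k: (d, list(m)) for k, (d, m) in other.sets.items()
        }
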