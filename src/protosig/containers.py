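"""Core in-memory containers shared by every stage of the pipeline.

The central object is :class:`ExpressionMatrix`, a proteins × samples table of
log2 tumour/standard ratios backed by a :class:`pandas.DataFrame` in which
``NaN`` marks a missing (non-quantified) measurement.  Missing entries carry no
numeric meaning and are excluded from all statistics unless an operation
explicitly imputes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "CategoryMap",
    "FormatError",
    "ParameterError",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


class ParameterError(ValueError):
    """A parameter is outside its documented domain."""


def _find_duplicates(items) -> list:
    seen, dups = set(), []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Proteins × samples matrix of log2 (tumour / internal standard) ratios.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein identifiers with unique sample
        identifiers as columns.  ``NaN`` encodes a missing value.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup_p = _find_duplicates(self.data.index)
        if dup_p:
            raise FormatError(f"duplicate protein identifier(s): {dup_p}")
        dup_s = _find_duplicates(self.data.columns)
        if dup_s:
            raise FormatError(f"duplicate sample identifier(s): {dup_s}")
        self.data = self.data.astype(float)

    # -- convenience views ------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        """Dense float array (proteins × samples); missing entries are NaN."""
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array aligned with :attr:`values`; True where missing."""
        return np.isnan(self.data.to_numpy())

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy())

    def subset_proteins(self, protein_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(protein_ids)])

    def __eq__(self, other) -> bool:  # NaN-aware equality
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if not self.data.index.equals(other.data.index):
            return False
        if not self.data.columns.equals(other.data.columns):
            return False
        a, b = self.values, other.values
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))


@dataclass
class SampleAnnotation:
    """Assignment of each sample to one of k ≥ 2 class labels.

    ``classes`` preserves the order of first appearance in the source file;
    that order is the documented tie-break for multi-class prediction.
    """

    labels: pd.Series  # sample_id -> class label
    classes: tuple = field(default=None)

    def __post_init__(self) -> None:
        dup = _find_duplicates(self.labels.index)
        if dup:
            raise FormatError(f"duplicate sample identifier(s): {dup}")
        if self.classes is None:
            # order of first appearance
            self.classes = tuple(dict.fromkeys(self.labels))
        counts = self.labels.value_counts()
        small = [c for c in self.classes if counts.get(c, 0) < 2]
        if small:
            raise FormatError(f"class(es) with fewer than 2 samples: {small}")
        if len(self.classes) < 2:
            raise FormatError("at least 2 classes are required")

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    def class_members(self, label) -> list:
        if label not in self.classes:
            raise ParameterError(f"unknown class label: {label!r}")
        return list(self.labels.index[self.labels == label])

    def in_class_mask(self, sample_ids, label) -> np.ndarray:
        """Boolean mask over ``sample_ids`` marking members of ``label``."""
        if label not in self.classes:
            raise ParameterError(f"unknown class label: {label!r}")
        return self.labels.reindex(sample_ids).to_numpy() == label

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must be annotated exactly once."""
        missing = [s for s in matrix.sample_ids if s not in self.labels.index]
        if missing:
            raise FormatError(f"unannotated sample_id(s): {missing}")


@dataclass
class CategoryMap:
    """Named protein sets with an optional two-level parent hierarchy."""

    members: dict  # category_name -> frozenset of protein_ids
    parents: dict = field(default_factory=dict)  # leaf name -> parent name

    def __post_init__(self) -> None:
        self.members = {k: frozenset(v) for k, v in self.members.items()}
        empty = [k for k, v in self.members.items() if not v]
        if empty:
            raise FormatError(f"empty categor(ies): {empty}")
        # parent links must be acyclic and at most two levels deep: a parent
        # may never itself be a child
        children = set(self.parents)
        for child, parent in self.parents.items():
            if parent in children:
                raise FormatError(
                    f"hierarchy deeper than two levels at {child!r} -> {parent!r}"
                )

    @property
    def names(self) -> list:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def parent_members(self) -> dict:
        """Union of member sets per parent, deduplicated across leaves."""
        out: dict = {}
        for child, parent in self.parents.items():
            if child in self.members:
                out.setdefault(parent, set()).update(self.members[child])
        return {k: frozenset(v) for k, v in out.items()}
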