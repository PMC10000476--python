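"""Core in-memory containers shared across the pipeline stages.

All containers are thin, validated wrappers around pandas objects so that
every stage exchanges labelled matrices rather than bare arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "MarkerSet",
    "NormFactors",
    "ExpressionMatrix",
    "ZMatrix",
]


class ValidationError(ValueError):
    """Raised when an input container violates its structural contract."""


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer gene x sample count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample name. Values must be
        non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample names: {dups}")
        arr = df.to_numpy()
        if arr.size == 0:
            raise ValidationError("empty count matrix")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(arr != np.round(arr))[0]
            raise ValidationError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample total counts."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes])


@dataclass(frozen=True)
class SampleDesign:
    """Two-group sample design.

    ``groups`` maps sample id -> group label; exactly two levels are
    supported. ``reference`` is the control level; log2 fold changes are
    always treatment minus reference.
    """

    groups: pd.Series
    reference: str | None = None

    def __post_init__(self):
        g = self.groups.astype(str)
        levels = sorted(g.unique())
        if len(levels) != 2:
            raise ValidationError(f"exactly two group levels required, got {levels}")
        ref = self.reference if self.reference is not None else levels[0]
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} not among groups {levels}")
        if (g.value_counts() < 1).any():
            raise ValidationError("both groups must be non-empty")
        object.__setattr__(self, "groups", g)
        object.__setattr__(self, "reference", ref)

    @property
    def sample_ids(self) -> pd.Index:
        return self.groups.index

    @property
    def treatment(self) -> str:
        return next(l for l in sorted(self.groups.unique()) if l != self.reference)

    def samples_in(self, level: str) -> list[str]:
        return self.groups.index[self.groups == level].tolist()

    @classmethod
    def from_lists(cls, control, treatment, reference="C", treatment_label="E"):
        labels = pd.Series(
            [reference] * len(control) + [treatment_label] * len(treatment),
            index=list(control) + list(treatment),
        )
        return cls(labels, reference=reference)


@dataclass(frozen=True)
class MarkerSet:
    """A named cell-type marker gene set with an optional phenotype category."""

    name: str
    genes: tuple[str, ...]
    cell_type: str | None = None
    category: str | None = None

    def __post_init__(self):
        if not self.name:
            raise ValidationError("marker set needs a name")
        if len(self.genes) == 0:
            raise ValidationError(f"marker set {self.name!r} is empty")
        # normalize + dedupe preserving order
        from .io import normalize_symbol

        seen, out = set(), []
        for g in self.genes:
            s = normalize_symbol(g)
            if s not in seen:
                seen.add(s)
                out.append(s)
        object.__setattr__(self, "genes", tuple(out))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.genes)


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM scaling factors and raw library sizes.

    Factors multiply library sizes to give effective library sizes; they are
    rescaled so their geometric mean is 1.
    """

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self):
        if not (self.factors > 0).all():
            raise ValidationError("normalization factors must be positive")
        logf = np.log(self.factors.to_numpy(dtype=float))
        if abs(logf.mean()) > 1e-8:
            raise ValidationError("factors must have geometric mean 1")
        if not self.factors.index.equals(self.lib_sizes.index):
            raise ValidationError("factors and library sizes must share sample index")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass(frozen=True)
class ExpressionMatrix:
    """log2 counts-per-million matrix with the prior count that produced it."""

    values: pd.DataFrame
    prior_count: float

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class ZMatrix:
    """Gene x sample matrix of per-gene cross-sample z-scores.

    ``dropped`` records genes excluded for zero variance; ``source`` notes
    which expression matrix the z-scores came from.
    """

    values: pd.DataFrame
    dropped: tuple[str, ...] = ()
    source: str = "log2-CPM"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
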