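"""Core data containers shared across the pipeline.

The pipeline passes expression data around as a thin, validated wrapper
over a pandas DataFrame (genes in rows, samples in columns).  Expression
values are read-normalized abundances (RSEM / FPKM / RPKM-like): finite,
non-negative on the linear scale.  Gene and sample identifiers are opaque
strings and must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "SignatureMatrix",
    "SubtypeCall",
    "MarkerResult",
    "ConsensusResult",
    "ScorePanel",
    "ProsubtypeError",
    "ValidationError",
    "ParseError",
]


class ProsubtypeError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(ProsubtypeError):
    """A container or argument violated its contract."""


class ParseError(ProsubtypeError):
    """An input file could not be parsed."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows (index = gene IDs), samples in columns.
    scale : {"linear", "log2"}
        Values on the linear scale must be non-negative; log2 values may
        be negative but must be finite.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.data.index, "gene IDs")
        _check_unique(self.data.columns, "sample IDs")
        vals = self.data.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if vals.size and not np.isfinite(vals).all():
            raise ValidationError("expression values must be finite")
        if self.scale == "linear" and vals.size and (vals < 0).any():
            raise ValidationError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene IDs with an optional direction tag."""

    name: str
    genes: frozenset[str]
    direction: str = "none"  # up | down | none

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if self.direction not in ("up", "down", "none"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureMatrix:
    """Gene-by-cluster reference profile used as the deconvolution design.

    Each column is the arithmetic mean linear-scale expression of one
    reference cluster over the samples assigned to it.
    """

    data: pd.DataFrame  # genes x clusters

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "signature gene IDs")
        _check_unique(self.data.columns, "cluster names")
        if self.data.shape[1] < 2:
            raise ValidationError("signature needs >=2 clusters")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValidationError("signature values must be finite and non-negative")
        if (vals.sum(axis=1) == 0).any():
            raise ValidationError("signature contains all-zero gene rows")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cluster_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SubtypeCall:
    """Per-sample deconvolution result.

    ``pe`` holds the proportion estimate per reference cluster
    (non-negative, summing to 1); ``label`` is the argmax cluster when
    PEmax > 0.5 and the permutation p-value is significant, "mixed" when
    PEmax <= 0.5 and significant, and "unclassified" otherwise.
    """

    sample_id: str
    pe: pd.Series  # index = cluster names
    p_value: float
    label: str

    @property
    def pe_max(self) -> float:
        return float(self.pe.max())

    def __post_init__(self) -> None:
        arr = self.pe.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValidationError("PE entries must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValidationError("PE must sum to 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class MarkerResult:
    """One (gene, population) marker call.

    ``source`` records whether the call came from labeled single-cell
    data, the sorted-bulk fold-change rule, or both; ``p_adj`` is present
    only for single-cell calls (the bulk rule has no test).
    """

    gene_id: str
    source: str  # single_cell | bulk | both
    population: str  # cell-type name or "all_epithelia"
    fold_change: float
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("single_cell", "bulk", "both"):
            raise ValidationError(f"unknown source {self.source!r}")
        if not np.isfinite(self.fold_change):
            raise ValidationError("fold_change must be finite")
        if self.p_adj is not None and not (0.0 <= self.p_adj <= 1.0):
            raise ValidationError("p_adj must lie in [0, 1]")


@dataclass
class ConsensusResult:
    """Output of resampling consensus clustering.

    ``consensus`` maps each k to a symmetric sample-by-sample matrix of
    co-clustering frequencies; ``pac`` maps k to the proportion of
    ambiguously clustered pairs; ``assignment`` is the final cluster
    label per sample at ``chosen_k``.
    """

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]
    cosample_counts: dict[int, np.ndarray]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # k -> (grid, ecdf)
    pac: dict[int, float]
    chosen_k: int
    assignment: pd.Series  # sample_id -> cluster label


@dataclass
class ScorePanel:
    """Per-sample activity scores, raw and z-normalized across samples."""

    raw_scores: pd.DataFrame  # samples x score names
    scores: pd.DataFrame  # z-normalized, same shape

    def __post_init__(self) -> None:
        if list(self.raw_scores.index) != list(self.scores.index):
            raise ValidationError("raw and normalized panels must share samples")
        if list(self.raw_scores.columns) != list(self.scores.columns):
            raise ValidationError("raw and normalized panels must share score names")
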