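"""In-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a features x samples numeric
matrix (a pandas DataFrame) carrying optional per-feature gene symbols and
biotypes plus a ``scale`` tag that records whether values are raw RPKM or
log2-transformed.  The scale tag is what prevents the proteomics matrix —
which arrives already log2-scaled — from being capped or re-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RPKM = "rpkm"
LOG2 = "log2"

__all__ = [
    "RPKM",
    "LOG2",
    "ExpressionMatrix",
    "PathwayDB",
    "normalize_symbol",
]


def normalize_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol for case-insensitive joins."""
    return symbol.strip().upper()


@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix with feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.  Missing
        values (NaN) are permitted — TMT proteomics routinely has missing
        channels — and are excluded pairwise from statistics downstream.
    scale
        ``"rpkm"`` (non-negative abundances) or ``"log2"``.
    gene_symbols
        Optional Series mapping feature id -> gene symbol (upper-cased).
        Features without a symbol (most non-coding biotypes) carry NaN and
        are excluded from symbol-keyed joins such as pathway enrichment.
    biotypes
        Optional Series mapping feature id -> biotype category
        (e.g. ``protein_coding``, ``lincRNA``).
    """

    values: pd.DataFrame
    scale: str
    gene_symbols: pd.Series | None = None
    biotypes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in (RPKM, LOG2):
            raise ValueError(f"unknown scale tag {self.scale!r}; expected 'rpkm' or 'log2'")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite")
        if self.scale == RPKM and np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("RPKM-scale values must be non-negative")
        for name in ("gene_symbols", "biotypes"):
            meta = getattr(self, name)
            if meta is not None:
                setattr(self, name, meta.reindex(self.values.index))
        if self.gene_symbols is not None:
            sym = self.gene_symbols.dropna().astype(str).map(normalize_symbol)
            sym = sym[sym != ""]
            self.gene_symbols = sym.reindex(self.values.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def symbol_universe(self) -> set[str]:
        """All distinct gene symbols measurable on this platform."""
        if self.gene_symbols is None:
            return set()
        return set(self.gene_symbols.dropna())

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        idx = pd.Index(feature_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown feature ids: {list(missing[:5])}")
        return ExpressionMatrix(
            values=self.values.loc[idx],
            scale=self.scale,
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[idx],
            biotypes=None if self.biotypes is None else self.biotypes.loc[idx],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing[:5])}")
        return ExpressionMatrix(
            values=self.values[idx],
            scale=self.scale,
            gene_symbols=self.gene_symbols,
            biotypes=self.biotypes,
        )


@dataclass
class PathwayDB:
    """Pathway gene-set database (GMT-style): pathway id -> member symbols."""

    gene_sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __iter__(self):
        return iter(self.gene_sets)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.gene_sets[pathway_id]

    def items(self):
        return self.gene_sets.items()
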