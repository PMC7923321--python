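"""In-memory containers shared across the pipeline.

Expression is held genes x samples on a log2 scale, as exported by cell-line
panel databases. Sensitivity is one IC50 (Molar) per cell line together with
the -log10(Molar) value used as the regression target throughout: higher
-log10(IC50) means a lower inhibitory concentration, i.e. a more sensitive
line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

ANNOTATION_COLUMNS = ("tumor_type", "lineage")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with optional per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns are sample (cell line)
        names, entries are finite log2 expression values.
    sample_annotations
        DataFrame indexed by sample name with columns ``tumor_type`` and
        ``lineage``. May be empty when no annotations are known.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.sample_annotations.empty:
            self.sample_annotations = pd.DataFrame(
                index=self.values.columns, columns=list(ANNOTATION_COLUMNS), dtype=object
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in expression matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[:, samples].copy(),
            self.sample_annotations.reindex(samples),
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in expression matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[genes].copy(), self.sample_annotations.copy()
        )


@dataclass
class SensitivityTable:
    """Per-cell-line IC50 (Molar) and its -log10 transform, with labels.

    ``table`` is indexed by sample name and carries columns ``ic50_molar``,
    ``neglog10``, ``tumor_type`` and ``lineage``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ic50_molar", "tumor_type", "lineage"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sensitivity table missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample ids")
        ic50 = self.table["ic50_molar"].astype(float)
        bad = self.table.index[~(ic50 > 0) | ~np.isfinite(ic50)].tolist()
        if bad:
            raise ValidationError(f"non-positive or missing IC50 for samples: {bad[:5]}")
        self.table = self.table.copy()
        self.table["ic50_molar"] = ic50
        self.table["neglog10"] = -np.log10(ic50)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ic50_molar(self) -> pd.Series:
        return self.table["ic50_molar"]

    @property
    def neglog10(self) -> pd.Series:
        """-log10(Molar IC50); the training target (higher = more sensitive)."""
        return self.table["neglog10"]

    def subset(self, samples: list[str]) -> "SensitivityTable":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples not in sensitivity table: {missing[:5]}")
        return SensitivityTable(self.table.loc[samples].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways), as read from a GMT file."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def sets_containing(self, gene: str) -> list[str]:
        return [name for name, members in self.sets.items() if gene in members]


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction edges, as read from a SIF file.

    Self-loops are dropped and duplicate edges (either orientation)
    collapsed at construction.
    """

    edges: list[tuple[str, str]]
    interaction_types: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        types: dict[tuple[str, str], str] = {}
        for edge in self.edges:
            a, b = edge
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen[key] = None
                if edge in self.interaction_types:
                    types[key] = self.interaction_types[edge]
        self.edges = list(seen)
        self.interaction_types = types

    def __len__(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj
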