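"""Readers and writers for the text formats the pipeline touches.

Expression matrices use the tab-separated dialect exported by CellMinerCDB
(genes in rows, first column the gene symbol, header row of sample names).
Sensitivity tables are tab-separated with columns
``name / ic50_molar / tumor_type / lineage``. Gene sets are GMT, networks
are SIF; both are the standard three-plus-column whitespace formats.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    SensitivityTable,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

EXPRESSION_DIALECTS = ("cellminercdb_tsv",)
MISSING_POLICIES = ("error", "gene_median")


def read_expression_matrix(
    path: str | Path,
    dialect: str = "cellminercdb_tsv",
    missing_policy: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples log2 expression matrix.

    Parameters
    ----------
    path
        Tab-separated file, header row of sample names, first column gene
        symbols.
    dialect
        Only ``cellminercdb_tsv`` is supported.
    missing_policy
        ``error`` rejects files with empty/non-numeric cells;
        ``gene_median`` imputes empty cells with the per-gene median.
    """
    if dialect not in EXPRESSION_DIALECTS:
        raise FormatError(f"unknown expression dialect {dialect!r}")
    if missing_policy not in MISSING_POLICIES:
        raise FormatError(f"unknown missing policy {missing_policy!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed beyond parsing
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: header row has no sample columns")
    if df.index.isna().any() or any(str(g).strip() == "" for g in df.index):
        raise FormatError(f"{path}: blank or missing gene identifier")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample name(s): {dupes[:5]}")

    values = df.apply(pd.to_numeric, errors="coerce")
    missing_mask = values.isna() & ~df.isna()  # present but non-numeric
    empty_mask = df.isna()
    if missing_mask.to_numpy().any():
        gene = values.index[missing_mask.any(axis=1)][0]
        col = values.columns[missing_mask.loc[gene]][0]
        raise FormatError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
    if empty_mask.to_numpy().any():
        if missing_policy == "error":
            gene = values.index[empty_mask.any(axis=1)][0]
            col = values.columns[empty_mask.loc[gene]][0]
            raise FormatError(f"{path}: empty cell at gene {gene!r}, sample {col!r}")
        medians = values.median(axis=1)
        if medians.isna().any():
            gene = values.index[medians.isna()][0]
            raise FormatError(f"{path}: gene {gene!r} has no numeric values to impute from")
        values = values.apply(lambda row: row.fillna(medians[row.name]), axis=1)
        logger.warning(
            "%s: imputed %d empty cell(s) with per-gene medians",
            path,
            int(empty_mask.to_numpy().sum()),
        )
    return ExpressionMatrix(values.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write in the same TSV dialect ``read_expression_matrix`` accepts."""
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_sensitivity_table(path: str | Path) -> SensitivityTable:
    """Read a per-cell-line IC50 table (Molar) with tumor-type/lineage labels."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["name", "ic50_molar", "tumor_type", "lineage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df["name"] = df["name"].astype(str).str.strip()
    ic50 = pd.to_numeric(df["ic50_molar"], errors="coerce")
    bad = df["name"][ic50.isna() | (ic50 <= 0)].tolist()
    if bad:
        raise ValidationError(
            f"{path}: missing or non-positive IC50 for sample(s) {bad[:5]}"
        )
    table = pd.DataFrame(
        {
            "ic50_molar": ic50.to_numpy(float),
            "tumor_type": df["tumor_type"].astype(str).str.strip().to_numpy(),
            "lineage": df["lineage"].astype(str).str.strip().to_numpy(),
        },
        index=pd.Index(df["name"], name="name"),
    )
    return SensitivityTable(table)


def write_sensitivity_table(sens: SensitivityTable, path: str | Path) -> None:
    out = sens.table[["ic50_molar", "tumor_type", "lineage"]].copy()
    out.index.name = "name"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            n_dupes = 0
            for member in fields[2:]:
                member = member.strip()
                if not member:
                    continue
                if member in seen:
                    n_dupes += 1
                    continue
                seen.add(member)
                members.append(member)
            if n_dupes:
                logger.warning(
                    "%s:%d: set %r had %d duplicated member(s), deduplicated",
                    path, lineno, name, n_dupes,
                )
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a SIF file: ``source interaction target`` per line, undirected."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    types: dict[tuple[str, str], str] = {}
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: SIF line has {len(fields)} fields, expected 3"
                )
            a, kind, b = fields
            if a == b:
                n_loops += 1
                continue
            edges.append((a, b))
            types[(a, b)] = kind
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return InteractionNetwork(edges, types)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in net.edges:
            kind = net.interaction_types.get((a, b), "pp")
            fh.write(f"{a}\t{kind}\t{b}\n")


def align_samples(
    expr: ExpressionMatrix, sens: SensitivityTable
) -> tuple[ExpressionMatrix, SensitivityTable]:
    """Restrict both inputs to their common samples, in matching order.

    Order follows the expression matrix. Raises on an empty intersection.
    """
    common = [s for s in expr.sample_ids if s in set(sens.sample_ids)]
    if not common:
        raise ValidationError("expression and sensitivity tables share no samples")
    dropped_expr = len(expr.sample_ids) - len(common)
    dropped_sens = len(sens.sample_ids) - len(common)
    if dropped_expr or dropped_sens:
        logger.info(
            "align_samples: kept %d samples (dropped %d from expression, %d from sensitivity)",
            len(common), dropped_expr, dropped_sens,
        )
    return expr.subset_samples(common), sens.subset(common)


def exclude_lineage(sens: SensitivityTable, lineage: str) -> SensitivityTable:
    """Drop all samples of one lineage (e.g. blood-derived lines).

    A lineage absent from the table is a no-op with a warning.
    """
    mask = sens.table["lineage"] == lineage
    n = int(mask.sum())
    if n == 0:
        logger.warning("exclude_lineage: no samples with lineage %r", lineage)
        return SensitivityTable(sens.table.copy())
    logger.info(
        "exclude_lineage: removed %d %r sample(s), %d remain",
        n, lineage, len(sens.table) - n,
    )
    return SensitivityTable(sens.table.loc[~mask].copy())


def transform_scale(values, direction: str):
    """Convert between Molar IC50 and the -log10(Molar) sensitivity scale.

    ``to_neglog10`` requires strictly positive Molar inputs; the two
    directions are exact inverses (round-trip identity to ~1e-12 relative).
    """
    arr = np.asarray(values, dtype=float)
    if direction == "to_neglog10":
        if not (arr > 0).all():
            raise ValidationError("to_neglog10 requires strictly positive Molar values")
        return -np.log10(arr)
    if direction == "to_molar":
        return np.power(10.0, -arr)
    raise ValueError(f"unknown direction {direction!r}")


def neglog10_of_ic50(ic50_molar: float) -> float:
    """-log10 of a single Molar IC50 (e.g. 1e-7 M -> 7.0)."""
    if not ic50_molar > 0:
        raise ValidationError("IC50 must be positive")
    return -math.log10(ic50_molar)
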