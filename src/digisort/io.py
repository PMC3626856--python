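"""Readers and writers for expression tables, marker sets and result artifacts.

Expression tables are delimited text (TSV by default, CSV by extension) with
gene IDs in the first column and sample IDs in the header row.  Markers come
either as a two-column (gene, cell_type) table or as GMT gene-set lines.
All floats are serialized with 15 significant digits so write→read round
trips are lossless to well below 1e-9.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DeconvolutionResult,
    ExpressionMatrix,
    FrequencyMatrix,
    MarkerSet,
    SignatureMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.15g"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path: str | Path, transform: str = "none") -> ExpressionMatrix:
    """Read a genes x samples expression table in linear scale.

    Parameters
    ----------
    path
        Delimited table; first column gene IDs, header row sample IDs.
    transform
        ``"none"`` reads values as-is (they must be nonnegative);
        ``"antilog2"`` maps every entry x to 2**x, for log2-scale input.
        Mixing is additive only in linear space, so log-scale data must be
        exponentiated before deconvolution — this is never auto-detected.
    """
    if transform not in ("none", "antilog2"):
        raise ValidationError(f"unknown transform {transform!r}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ValidationError(f"malformed expression table {path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"expression table {path} has no data columns")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        rows = [str(df.index[i]) for i in sorted(set(np.where(np.isnan(values))[0]))][:5]
        raise ValidationError(f"missing values in expression table (rows {rows})")
    if transform == "antilog2":
        values = np.exp2(values)
    elif np.any(values < 0):
        rows = [str(df.index[i]) for i in sorted(set(np.where(values < 0)[0]))][:5]
        raise ValidationError(
            f"negative values in rows {rows}: input looks log-scaled; "
            "pass transform='antilog2'"
        )
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Index(gene_ids).duplicated(keep=False)
        logger.warning(
            "collapsing %d duplicate gene IDs by averaging their rows",
            int(dup.sum()) - len(set(np.array(gene_ids)[dup])),
        )
        frame = pd.DataFrame(values, index=gene_ids)
        frame = frame.groupby(level=0, sort=False).mean()
        gene_ids = [str(g) for g in frame.index]
        values = frame.to_numpy()
    return ExpressionMatrix(values, gene_ids, [str(s) for s in df.columns])


def read_markers(path: str | Path, dialect: str = "two_column") -> MarkerSet:
    """Read a marker-gene assignment.

    ``two_column``: rows of (gene_id, cell_type), tab- or comma-delimited by
    extension, no header.  ``gmt``: one line per cell type —
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Cell-type order is
    first-appearance order.
    """
    if dialect not in ("two_column", "gmt"):
        raise ValidationError(f"unknown marker dialect {dialect!r}")
    assignments: dict[str, list[str]] = {}
    order: list[str] = []
    text = Path(path).read_text()
    if dialect == "gmt":
        for ln, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {ln}: need name, description and at least one gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in assignments:
                raise ValidationError(f"cell type {name!r} appears twice in GMT file")
            assignments[name] = genes
            order.append(name)
    else:
        sep = _sep_for(path)
        for ln, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != 2:
                raise ValidationError(f"marker table line {ln}: expected (gene, cell_type)")
            gene, ct = parts[0].strip(), parts[1].strip()
            if ct not in assignments:
                assignments[ct] = []
                order.append(ct)
            assignments[ct].append(gene)
    return MarkerSet(assignments, order)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def write_result(result: DeconvolutionResult, out_dir: str | Path) -> dict[str, Path]:
    """Write signatures.tsv, frequencies.tsv and diagnostics.tsv to *out_dir*.

    Returns a name→path mapping of the files written.  ``diagnostics.tsv``
    has one row per gene (residual sum of squares and number of active
    bounds); scalar diagnostics go to ``diagnostics_summary.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signatures": out / "signatures.tsv",
        "frequencies": out / "frequencies.tsv",
        "diagnostics": out / "diagnostics.tsv",
        "summary": out / "diagnostics_summary.tsv",
    }
    write_matrix(result.signatures.to_frame(), paths["signatures"])
    freq_df = result.frequencies.to_frame()
    write_matrix(freq_df, paths["frequencies"])
    diag = result.diagnostics
    per_gene = pd.DataFrame(
        {
            "rss": diag.per_gene_rss,
            "active_bounds": diag.per_gene_active_bounds,
        },
        index=pd.Index(result.signatures.gene_ids, name="gene_id"),
    )
    write_matrix(per_gene, paths["diagnostics"])
    rows = {
        "frobenius_residual": diag.frobenius_residual,
        "condition_number_WWt": diag.condition_number,
        "n_genes_at_bound": diag.n_genes_at_bound,
        "bound_lower": result.signatures.bounds[0],
        "bound_upper": result.signatures.bounds[1],
    }
    if result.frequencies.gbar is not None:
        for ct, g in zip(result.frequencies.cell_type_order, result.frequencies.gbar):
            rows[f"gbar.{ct}"] = g
    pd.Series(rows, name="value").to_csv(paths["summary"], sep="\t", float_format=FLOAT_FMT)
    return paths


def read_signatures(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = df.to_numpy(dtype=float)
    lo = min(0.0, float(values.min(initial=0.0)))
    return SignatureMatrix(
        values, [str(g) for g in df.index], [str(c) for c in df.columns], (lo, float("inf"))
    )


def read_frequencies(path: str | Path) -> FrequencyMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return FrequencyMatrix(
        df.to_numpy(dtype=float), [str(c) for c in df.index], [str(s) for s in df.columns]
    )


def write_markers(markers: MarkerSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ct in markers.cell_type_order:
            for g in markers.assignments[ct]:
                fh.write(f"{g}\t{ct}\n")
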