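"""Core containers for marker-based expression deconvolution.

The mixing model is ``O = S @ W``: an observed genes x samples matrix ``O``
is the product of a genes x cell-types signature matrix ``S`` (per-type
expression in linear scale) and a cell-types x samples frequency matrix ``W``
whose columns lie on the probability simplex.  Everything here is a thin,
validated wrapper around a numpy array plus ordered identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "MarkerSet",
    "CollapsedMarkerMatrix",
    "FrequencyMatrix",
    "SignatureMatrix",
    "DeconvolutionDiagnostics",
    "DeconvolutionResult",
]

SIMPLEX_TOL = 1e-6


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Linear-scale expression, genes as rows, samples as columns.

    Values must be finite and nonnegative: mixing of cell populations is
    additive only on the linear scale, so log-transformed data has to be
    exponentiated before construction (see ``read_expression(transform=...)``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        self.gene_ids = _check_unique(self.gene_ids, "gene IDs")
        self.sample_ids = _check_unique(self.sample_ids, "sample IDs")
        n, p = self.values.shape
        if n != len(self.gene_ids) or p != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene IDs x {len(self.sample_ids)} sample IDs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite (no NA/inf)")
        if np.any(self.values < 0):
            raise ValidationError(
                "negative expression values: input looks log-scaled; "
                "re-read with transform='antilog2'"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class MarkerSet:
    """Assignment of marker genes to the cell type they are specific for.

    A marker is a gene highly expressed in exactly one of the k cell types;
    only the identities are needed, never the pure-type expression levels.
    Marker lists must be disjoint across cell types.
    """

    assignments: dict[str, list[str]]
    cell_type_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_type_order is None:
            self.cell_type_order = list(self.assignments)
        self.cell_type_order = _check_unique(self.cell_type_order, "cell types")
        if set(self.cell_type_order) != set(self.assignments):
            raise ValidationError("cell_type_order must match assignment keys")
        if len(self.cell_type_order) < 2:
            raise ValidationError("need at least 2 cell types")
        seen: dict[str, str] = {}
        for ct in self.cell_type_order:
            genes = [str(g) for g in self.assignments[ct]]
            if not genes:
                raise ValidationError(f"cell type {ct!r} has no marker genes")
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"marker {g!r} assigned to multiple cell types "
                        f"({seen[g]!r} and {ct!r})"
                    )
                seen[g] = ct
            self.assignments[ct] = genes

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_type_order)

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.assignments.values())

    def restrict_to(self, genes: Sequence[str]) -> tuple["MarkerSet", dict[str, list[str]]]:
        """Drop markers not present in *genes*; return (new set, dropped-by-type).

        Raises if any cell type loses all of its markers.
        """
        present = set(genes)
        kept: dict[str, list[str]] = {}
        dropped: dict[str, list[str]] = {}
        for ct in self.cell_type_order:
            kept[ct] = [g for g in self.assignments[ct] if g in present]
            dropped[ct] = [g for g in self.assignments[ct] if g not in present]
            if not kept[ct]:
                raise ValidationError(
                    f"cell type {ct!r} has no markers present in the expression matrix"
                )
        return MarkerSet(kept, list(self.cell_type_order)), dropped


@dataclass
class CollapsedMarkerMatrix:
    """Mean marker expression per cell type: k x p matrix of per-sample means."""

    values: np.ndarray
    cell_type_order: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k, p = self.values.shape
        if k != len(self.cell_type_order) or p != len(self.sample_ids):
            raise ValidationError("collapsed matrix shape inconsistent with IDs")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("collapsed marker means must be finite and >= 0")

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FrequencyMatrix:
    """Cell-type mixing proportions W: k x p, each column on the simplex.

    ``gbar`` holds the estimated mean marker expression per cell type
    (the diagonal of the collapsed marker signature) when W was estimated
    from markers; it is None when W was supplied externally.
    """

    values: np.ndarray
    cell_type_order: list[str]
    sample_ids: list[str]
    gbar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k, p = self.values.shape
        if k != len(self.cell_type_order) or p != len(self.sample_ids):
            raise ValidationError("frequency matrix shape inconsistent with IDs")
        if np.any(self.values < -SIMPLEX_TOL) or np.any(self.values > 1 + SIMPLEX_TOL):
            raise ValidationError("frequencies must lie in [0, 1]")
        colsums = self.values.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > SIMPLEX_TOL):
            bad = [self.sample_ids[j] for j in np.where(np.abs(colsums - 1) > SIMPLEX_TOL)[0]]
            raise ValidationError(f"frequency columns must sum to 1 (violated for {bad})")
        if self.gbar is not None:
            self.gbar = np.asarray(self.gbar, dtype=float)
            if self.gbar.shape != (k,):
                raise ValidationError("gbar must have one entry per cell type")
            if np.any(self.gbar <= 0):
                raise ValidationError("gbar entries must be strictly positive")

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_type_order, columns=self.sample_ids)


@dataclass
class SignatureMatrix:
    """Per-cell-type expression profiles S: n genes x k cell types.

    ``bounds`` records the (lower, upper) box used during estimation; entries
    are guaranteed to lie inside it (up to solver tolerance).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_type_order: list[str]
    bounds: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n != len(self.gene_ids) or k != len(self.cell_type_order):
            raise ValidationError("signature matrix shape inconsistent with IDs")
        t2, t1 = self.bounds
        if not t2 < t1:
            raise ValidationError(f"lower bound {t2} must be < upper bound {t1}")
        tol = 1e-6 * max(1.0, float(np.abs(self.values).max(initial=1.0)))
        if np.any(self.values < t2 - tol) or np.any(self.values > t1 + tol):
            raise ValidationError("signature entries violate the [t2, t1] bounds")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_type_order)

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_type_order.index(cell_type)
        except ValueError:
            raise ValidationError(f"cell type {cell_type!r} not in signature matrix") from None
        return self.values[:, j]


@dataclass
class DeconvolutionDiagnostics:
    """Fit diagnostics for a deconvolution run."""

    per_gene_rss: np.ndarray
    frobenius_residual: float
    condition_number: float  # of W @ W.T
    n_genes_at_bound: int
    per_gene_active_bounds: np.ndarray

    def __post_init__(self) -> None:
        self.per_gene_rss = np.asarray(self.per_gene_rss, dtype=float)
        if np.any(self.per_gene_rss < -1e-12):
            raise ValidationError("residual sums of squares must be >= 0")
        self.per_gene_rss = np.maximum(self.per_gene_rss, 0.0)
        total = float(self.per_gene_rss.sum())
        if not np.isclose(total, self.frobenius_residual**2, rtol=1e-8, atol=1e-10):
            raise ValidationError(
                "per-gene residuals do not sum to the squared Frobenius residual"
            )


@dataclass
class DeconvolutionResult:
    """Bundle of the two-step output: signatures S, frequencies W, diagnostics."""

    signatures: SignatureMatrix
    frequencies: FrequencyMatrix
    diagnostics: DeconvolutionDiagnostics
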