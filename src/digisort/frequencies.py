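"""Estimate the cell-type frequency matrix W from marker-gene identities.

Under the linear mixing model O = S W, restricting O to the markers of one
cell type and averaging gives a collapsed k x p matrix Os whose rows satisfy
Os[c, j] = gbar_c * W[c, j], where gbar_c is the (unknown) mean expression of
cell type c's markers in the pure type.  Because each column of W sums to 1,
the per-sample identities

    sum_c Os[c, j] / gbar_c = 1        (j = 1..p)

form a linear system in x_c = 1/gbar_c, solvable whenever the number of
samples is at least the number of cell types.  W then follows by dividing
each row of the collapsed matrix by its gbar and projecting columns back
onto the simplex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import (
    CollapsedMarkerMatrix,
    ExpressionMatrix,
    FrequencyMatrix,
    MarkerSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyEstimationOptions",
    "collapse_markers",
    "solve_gbar",
    "estimate_frequencies",
]


@dataclass
class FrequencyEstimationOptions:
    """Solver knobs for the frequency-estimation step.

    nonnegative_gbar
        Constrain the reciprocal weights x = 1/gbar to be >= 0 when solving
        the sum-to-one system (negative mean marker expression is physically
        meaningless).
    clip_and_renormalize
        Clip negative W entries to 0 and rescale each column to sum to 1, so
        the output always lies on the probability simplex.
    min_condition_warn
        Condition-number threshold for the collapsed matrix above which a
        collinearity warning is emitted.
    """

    nonnegative_gbar: bool = True
    clip_and_renormalize: bool = True
    min_condition_warn: float = 1e6

    def __post_init__(self) -> None:
        if self.min_condition_warn <= 0:
            raise ValidationError("min_condition_warn must be positive")


def collapse_markers(expr: ExpressionMatrix, markers: MarkerSet) -> CollapsedMarkerMatrix:
    """Average each cell type's marker rows of *expr* into a k x p matrix.

    Markers absent from the expression matrix are dropped with a warning; a
    cell type whose markers are all absent is an error.
    """
    retained, dropped = markers.restrict_to(expr.gene_ids)
    n_dropped = sum(len(v) for v in dropped.values())
    if n_dropped:
        detail = {ct: v for ct, v in dropped.items() if v}
        logger.warning("dropped %d markers absent from expression matrix: %s", n_dropped, detail)
    idx = expr.gene_index()
    rows = []
    for ct in retained.cell_type_order:
        gene_rows = [idx[g] for g in retained.assignments[ct]]
        rows.append(expr.values[gene_rows].mean(axis=0))
    return CollapsedMarkerMatrix(np.vstack(rows), list(retained.cell_type_order), list(expr.sample_ids))


def solve_gbar(
    collapsed: CollapsedMarkerMatrix,
    opts: FrequencyEstimationOptions | None = None,
) -> np.ndarray:
    """Solve the per-sample sum-to-one system for gbar (mean marker expression).

    Minimizes ``sum_j (sum_c x_c * Os[c, j] - 1)^2`` over ``x = 1/gbar``
    (with ``x >= 0`` by default) and returns ``gbar = 1/x``.  Requires at
    least as many samples as cell types; an exactly square system is accepted
    with a warning.
    """
    opts = opts or FrequencyEstimationOptions()
    k, p = collapsed.n_cell_types, collapsed.n_samples
    if p < k:
        raise ValidationError(
            f"underdetermined: need at least k={k} samples to solve for gbar, got p={p}"
        )
    if p == k:
        warnings.warn(
            "number of samples equals number of cell types: the sum-to-one "
            "system is exactly determined, estimates may be unstable",
            stacklevel=2,
        )
    zero_rows = np.where(~collapsed.values.any(axis=1))[0]
    if zero_rows.size:
        names = [collapsed.cell_type_order[i] for i in zero_rows]
        raise ValidationError(f"collapsed marker expression is all-zero for {names}")
    A = collapsed.values.T  # p x k
    sv = np.linalg.svd(A, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if sv[-1] <= max(k, p) * np.finfo(float).eps * sv[0]:
        raise ValidationError(
            f"collapsed marker matrix is rank deficient (condition number {cond:.3g}); "
            "cell types are collinear — refine the marker lists"
        )
    if cond > opts.min_condition_warn:
        warnings.warn(
            f"collapsed marker matrix is ill-conditioned (condition number {cond:.3g})",
            stacklevel=2,
        )
    b = np.ones(p)
    if opts.nonnegative_gbar:
        x, _ = optimize.nnls(A, b)
    else:
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
    bad = np.where(x <= 0)[0]
    if bad.size:
        names = [collapsed.cell_type_order[i] for i in bad]
        raise ValidationError(
            f"cell types {names} unidentifiable: optimal marker weight is "
            "non-positive (markers may not be expressed in these samples)"
        )
    return 1.0 / x


def estimate_frequencies(
    expr: ExpressionMatrix,
    markers: MarkerSet,
    opts: FrequencyEstimationOptions | None = None,
) -> FrequencyMatrix:
    """Estimate W from mixed-sample expression using marker identities only.

    Raw estimate: ``W[c, j] = Os[c, j] / gbar_c``.  With
    ``clip_and_renormalize`` (default) negative entries are clipped to 0 and
    each column rescaled to sum to 1, so the result lives on the simplex.
    """
    opts = opts or FrequencyEstimationOptions()
    collapsed = collapse_markers(expr, markers)
    gbar = solve_gbar(collapsed, opts)
    raw = collapsed.values / gbar[:, None]
    W = raw.copy()
    if opts.clip_and_renormalize:
        W = np.clip(W, 0.0, None)
        colsums = W.sum(axis=0)
        dead = np.where(colsums <= 0)[0]
        if dead.size:
            names = [collapsed.sample_ids[j] for j in dead]
            raise ValidationError(f"samples {names} have no detectable component")
        W = W / colsums
    return FrequencyMatrix(W, list(collapsed.cell_type_order), list(collapsed.sample_ids), gbar=gbar)
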