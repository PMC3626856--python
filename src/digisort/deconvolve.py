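"""Recover per-cell-type signature profiles by box-constrained least squares.

Given O (n genes x p samples) and W (k x p), the signature matrix S solves

    min_S ||O - S W||_F^2    s.t.   t2 <= S_ij <= t1

The Frobenius objective separates over genes, so the joint problem is solved
as n independent k-variable bounded least-squares problems (mathematically
identical, vastly cheaper).  Rows whose unconstrained normal-equations
solution already satisfies the box are accepted directly; the remainder go
through an active-set bounded solver (BVLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import (
    DeconvolutionDiagnostics,
    DeconvolutionResult,
    ExpressionMatrix,
    FrequencyMatrix,
    MarkerSet,
    SignatureMatrix,
    ValidationError,
)
from .frequencies import FrequencyEstimationOptions, estimate_frequencies

__all__ = ["DeconvolutionOptions", "deconvolve_expression", "run_dsa"]


@dataclass
class DeconvolutionOptions:
    """Bounds and solver controls for the signature-recovery step.

    t1, t2
        Upper and lower bounds on signature entries — the maximum and minimum
        measurable expression level of the platform.  Defaults (0, +inf):
        nonnegativity is the binding physical constraint; a finite ceiling
        (e.g. slightly above max(O)) can be supplied for saturating platforms.
    ridge
        Optional Tikhonov strength lambda >= 0 added to the per-gene normal
        matrix; required when W is rank deficient (near-collinear cell types).
    solver_tol
        Feasibility/optimality tolerance of the bounded solver.
    """

    t1: float = float("inf")
    t2: float = 0.0
    ridge: float = 0.0
    solver_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.t2 < self.t1:
            raise ValidationError(f"infeasible bounds: t2={self.t2} must be < t1={self.t1}")
        if self.ridge < 0:
            raise ValidationError("ridge strength must be >= 0")
        if self.solver_tol <= 0:
            raise ValidationError("solver_tol must be positive")


def _bounded_rows_solve(
    O: np.ndarray, W: np.ndarray, opts: DeconvolutionOptions
) -> tuple[np.ndarray, np.ndarray]:
    """Solve all per-gene bounded least-squares rows; return (S, active-bound counts)."""
    n, p = O.shape
    k = W.shape[0]
    lo, hi = opts.t2, opts.t1
    A = W.T  # p x k design shared by every gene
    if opts.ridge > 0:
        A = np.vstack([A, np.sqrt(opts.ridge) * np.eye(k)])
    G = A.T @ A
    sv = np.linalg.svd(G, compute_uv=False)
    if sv[-1] <= k * np.finfo(float).eps * sv[0]:
        raise ValidationError(
            "frequency matrix W is rank deficient: cell-type proportions are "
            "collinear across samples; supply more samples or set ridge > 0"
        )
    # Fast path: unconstrained normal-equations solution, accepted when inside the box.
    B = O @ W.T  # n x k  (ridge adds nothing to the RHS: target is 0)
    S_unc = np.linalg.solve(G, B.T).T
    tol = opts.solver_tol * max(1.0, float(np.abs(S_unc).max(initial=1.0)))
    inside = np.all((S_unc >= lo - tol) & (S_unc <= hi + tol), axis=1)
    S = np.clip(S_unc, lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
    active = np.zeros(n, dtype=int)
    bounds = (np.full(k, lo), np.full(k, hi))
    for g in np.where(~inside)[0]:
        b = O[g]
        if opts.ridge > 0:
            b = np.concatenate([b, np.zeros(k)])
        res = optimize.lsq_linear(A, b, bounds=bounds, method="bvls", tol=opts.solver_tol)
        S[g] = np.clip(res.x, lo, hi)
    btol = opts.solver_tol * max(1.0, float(np.abs(S).max(initial=1.0)))
    at_lo = np.isfinite(lo) & (S <= lo + btol)
    at_hi = np.isfinite(hi) & (S >= hi - btol)
    active = (at_lo | at_hi).sum(axis=1)
    return S, active


def deconvolve_expression(
    expr: ExpressionMatrix,
    freqs: FrequencyMatrix,
    opts: DeconvolutionOptions | None = None,
) -> SignatureMatrix:
    """Estimate S from O and W, one bounded least-squares problem per gene."""
    opts = opts or DeconvolutionOptions()
    if expr.sample_ids != freqs.sample_ids:
        raise ValidationError(
            "expression and frequency matrices must cover the same samples "
            "in the same order"
        )
    S, _ = _bounded_rows_solve(expr.values, freqs.values, opts)
    return SignatureMatrix(
        S, list(expr.gene_ids), list(freqs.cell_type_order), (opts.t2, opts.t1)
    )


def run_dsa(
    expr: ExpressionMatrix,
    markers: MarkerSet | None = None,
    known_freqs: FrequencyMatrix | None = None,
    opts: DeconvolutionOptions | None = None,
    freq_opts: FrequencyEstimationOptions | None = None,
) -> DeconvolutionResult:
    """Run the full two-step digital sorting pipeline.

    Step I estimates W from marker identities unless a known frequency
    matrix is supplied; step II recovers S by bounded least squares.
    Exactly one of *markers* / *known_freqs* must be given.
    """
    if (markers is None) == (known_freqs is None):
        raise ValidationError("provide exactly one of markers or known_freqs")
    opts = opts or DeconvolutionOptions()
    if markers is not None:
        freqs = estimate_frequencies(expr, markers, freq_opts)
    else:
        freqs = known_freqs
        if freqs.sample_ids != expr.sample_ids:
            raise ValidationError("known frequency matrix samples do not match expression")
    S, active = _bounded_rows_solve(expr.values, freqs.values, opts)
    resid = expr.values - S @ freqs.values
    per_gene_rss = np.einsum("ij,ij->i", resid, resid)  # data misfit only, ridge excluded
    WWt = freqs.values @ freqs.values.T
    sv = np.linalg.svd(WWt, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    diagnostics = DeconvolutionDiagnostics(
        per_gene_rss=per_gene_rss,
        frobenius_residual=float(np.sqrt(per_gene_rss.sum())),
        condition_number=cond,
        n_genes_at_bound=int((active > 0).sum()),
        per_gene_active_bounds=active,
    )
    signatures = SignatureMatrix(
        S, list(expr.gene_ids), list(freqs.cell_type_order), (opts.t2, opts.t1)
    )
    return DeconvolutionResult(signatures, freqs, diagnostics)
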