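"""Assessment of deconvolution output: ROC for fold-change detection and
accuracy of recovered signatures against ground truth.

The differential-expression protocol follows the reference-set construction
used for in-silico sorting benchmarks: genes whose *true* between-type ratio
exceeds a fold cutoff (in either direction) form the positive set; the
*estimated* between-type ratio, symmetrized as max(r, 1/r) so both increases
and decreases rank high, is swept over thresholds to trace the ROC curve.
The trapezoidal AUC equals the Mann-Whitney concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datatypes import DeconvolutionResult, SignatureMatrix, ValidationError
from .simulate import MixtureTruth

__all__ = [
    "RocResult",
    "AccuracyReport",
    "reference_de_labels",
    "ratio_scores",
    "roc_analysis",
    "accuracy_report",
    "signature_snr",
]

_PSEUDOCOUNT_SCALE = 1e-8


@dataclass
class RocResult:
    """ROC sweep over ratio-score thresholds."""

    thresholds: np.ndarray  # descending cutoffs
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_count: int
    negative_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError("AUC must lie in [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValidationError("ROC rates must be nondecreasing along the sweep")


@dataclass
class AccuracyReport:
    """Per-cell-type agreement between estimated and true signatures."""

    table: pd.DataFrame  # index: cell type; columns: pearson_r, mse, mean_abs_diff,
    #                      mean_true_frequency, snr

    def for_type(self, cell_type: str) -> pd.Series:
        return self.table.loc[cell_type]


def _pseudocount(values: np.ndarray) -> float:
    return _PSEUDOCOUNT_SCALE * max(float(np.abs(values).max(initial=0.0)), 1.0)


def reference_de_labels(
    true_sig: SignatureMatrix, type_a: str, type_b: str, fold: float = 2.0
) -> np.ndarray:
    """Binary per-gene labels: 1 iff the true a/b ratio exceeds *fold* in
    either direction (a small pseudocount guards zero entries)."""
    if not fold > 1:
        raise ValidationError("fold cutoff must be > 1")
    a = true_sig.column(type_a)
    b = true_sig.column(type_b)
    eps = _pseudocount(true_sig.values)
    ratio = (a + eps) / (b + eps)
    return ((ratio > fold) | (ratio < 1.0 / fold)).astype(int)


def ratio_scores(
    est_sig: SignatureMatrix, type_a: str, type_b: str, symmetric: bool = True
) -> np.ndarray:
    """Per-gene ratio score between two estimated profiles.

    With ``symmetric=True`` (default) the score is max(r, 1/r), so genes
    changed in either direction rank above unchanged genes; the raw
    one-sided ratio r is available with ``symmetric=False``.
    """
    a = est_sig.column(type_a)
    b = est_sig.column(type_b)
    eps = _pseudocount(est_sig.values)
    r = (a + eps) / (b + eps)
    return np.maximum(r, 1.0 / r) if symmetric else r


def roc_analysis(
    est_sig: SignatureMatrix, labels: np.ndarray, type_a: str, type_b: str
) -> RocResult:
    """ROC curve and AUC for recovering *labels* from estimated ratio scores."""
    labels = np.asarray(labels).astype(int)
    if labels.shape != (est_sig.n_genes,):
        raise ValidationError("labels must be one binary value per gene")
    npos, nneg = int(labels.sum()), int((1 - labels).sum())
    if npos == 0 or nneg == 0:
        raise ValidationError("ROC undefined: need both positive and negative genes")
    scores = ratio_scores(est_sig, type_a, type_b, symmetric=True)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(_sk_auc(fpr, tpr)),
        positive_count=npos,
        negative_count=nneg,
    )


def signature_snr(truth: MixtureTruth) -> np.ndarray:
    """Operational per-type signal-to-noise ratio of a simulated design.

    Signal for type c: its mean contribution to the observed mixture,
    mean_j W[c, j] * mean_g S[g, c].  Noise: the linear-scale standard
    deviation implied by the simulator's multiplicative log-normal model,
    sqrt(exp(sd^2) - 1) * mean(S @ W).  Infinite when noise_sd = 0.
    """
    S = truth.signatures.values
    W = truth.frequencies.values
    signal = S.mean(axis=0) * W.mean(axis=1)
    if truth.noise_sd == 0:
        return np.full(W.shape[0], np.inf)
    noise = np.sqrt(np.expm1(truth.noise_sd**2)) * float((S @ W).mean())
    return signal / noise


def accuracy_report(
    result: DeconvolutionResult | SignatureMatrix, truth: MixtureTruth
) -> AccuracyReport:
    """Per-cell-type Pearson r, MSE and mean |difference| of estimated vs
    true signatures, plus mean true frequency and operational SNR.

    *result* may be a full :class:`DeconvolutionResult` or a bare estimated
    :class:`SignatureMatrix`.
    """
    est = getattr(result, "signatures", result)
    true = truth.signatures
    if est.gene_ids != true.gene_ids:
        diff = set(est.gene_ids).symmetric_difference(true.gene_ids)
        raise ValidationError(f"gene IDs misaligned between estimate and truth: {sorted(diff)[:5]}")
    if est.cell_type_order != true.cell_type_order:
        raise ValidationError(
            f"cell types misaligned: {est.cell_type_order} vs {true.cell_type_order}"
        )
    snr = signature_snr(truth)
    rows = []
    for c, ct in enumerate(true.cell_type_order):
        e, t = est.values[:, c], true.values[:, c]
        if np.std(e) == 0 or np.std(t) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(e, t).statistic)
        rows.append(
            {
                "pearson_r": r,
                "mse": float(np.mean((e - t) ** 2)),
                "mean_abs_diff": float(np.mean(np.abs(e - t))),
                "mean_true_frequency": float(truth.frequencies.values[c].mean()),
                "snr": float(snr[c]),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(true.cell_type_order, name="cell_type"))
    return AccuracyReport(table)
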