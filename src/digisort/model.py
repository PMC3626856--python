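"""Model/Results interface for digital sorting.

``DigitalSortingModel`` binds an observed mixture to either a marker set
(frequencies will be estimated) or a known frequency matrix; ``fit()``
returns a ``DigitalSortingResults`` carrying the recovered signature matrix,
the frequency matrix, diagnostics and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    DeconvolutionResult,
    ExpressionMatrix,
    FrequencyMatrix,
    MarkerSet,
    ValidationError,
)
from .deconvolve import DeconvolutionOptions, run_dsa
from .frequencies import FrequencyEstimationOptions

__all__ = ["DigitalSortingModel", "DigitalSortingResults"]


class DigitalSortingModel:
    """Linear mixing model O = S W fitted by two-step digital sorting.

    Parameters
    ----------
    expression
        Observed mixed-sample expression (linear scale).
    markers
        Marker-gene assignment used to estimate the frequency matrix W;
        mutually exclusive with *known_frequencies*.
    known_frequencies
        Externally measured W (columns on the simplex); step I is skipped.
    t1, t2, ridge
        Bounds on signature entries and optional Tikhonov strength for the
        per-gene bounded least-squares step.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        markers: MarkerSet | None = None,
        known_frequencies: FrequencyMatrix | None = None,
        t1: float = float("inf"),
        t2: float = 0.0,
        ridge: float = 0.0,
        freq_options: FrequencyEstimationOptions | None = None,
    ) -> None:
        if (markers is None) == (known_frequencies is None):
            raise ValidationError("provide exactly one of markers or known_frequencies")
        self.expression = expression
        self.markers = markers
        self.known_frequencies = known_frequencies
        self.options = DeconvolutionOptions(t1=t1, t2=t2, ridge=ridge)
        self.freq_options = freq_options or FrequencyEstimationOptions()

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        markers: dict[str, list[str]] | MarkerSet | None = None,
        known_frequencies: pd.DataFrame | None = None,
        **kwargs,
    ) -> "DigitalSortingModel":
        """Build from a genes x samples DataFrame (and optionally a
        cell-types x samples frequency DataFrame)."""
        expr = ExpressionMatrix(
            expression.to_numpy(dtype=float),
            [str(g) for g in expression.index],
            [str(s) for s in expression.columns],
        )
        if isinstance(markers, dict):
            markers = MarkerSet({k: list(v) for k, v in markers.items()})
        freqs = None
        if known_frequencies is not None:
            freqs = FrequencyMatrix(
                known_frequencies.to_numpy(dtype=float),
                [str(c) for c in known_frequencies.index],
                [str(s) for s in known_frequencies.columns],
            )
        return cls(expr, markers=markers, known_frequencies=freqs, **kwargs)

    def fit(self) -> "DigitalSortingResults":
        result = run_dsa(
            self.expression,
            markers=self.markers,
            known_freqs=self.known_frequencies,
            opts=self.options,
            freq_opts=self.freq_options,
        )
        return DigitalSortingResults(self, result)


class DigitalSortingResults:
    """Fitted digital-sorting decomposition O ≈ S W."""

    def __init__(self, model: DigitalSortingModel, result: DeconvolutionResult) -> None:
        self.model = model
        self._result = result

    @property
    def result(self) -> DeconvolutionResult:
        return self._result

    @property
    def signatures(self):
        return self._result.signatures

    @property
    def frequencies(self):
        return self._result.frequencies

    @property
    def diagnostics(self):
        return self._result.diagnostics

    @property
    def signatures_frame(self) -> pd.DataFrame:
        return self._result.signatures.to_frame()

    @property
    def frequencies_frame(self) -> pd.DataFrame:
        return self._result.frequencies.to_frame()

    def predict(self) -> np.ndarray:
        """Reconstructed mixture S @ W."""
        return self._result.signatures.values @ self._result.frequencies.values

    def summary(self) -> str:
        res = self._result
        diag = res.diagnostics
        n, k = res.signatures.values.shape
        p = res.frequencies.n_samples
        O = self.model.expression.values
        denom = float(np.linalg.norm(O))
        rel = diag.frobenius_residual / denom if denom > 0 else np.nan
        lines = [
            "Digital sorting results",
            "=" * 55,
            f"genes: {n}   cell types: {k}   samples: {p}",
            f"frequency source: {'estimated from markers' if res.frequencies.gbar is not None else 'supplied'}",
            f"Frobenius residual ||O - SW||: {diag.frobenius_residual:.6g} "
            f"(relative {rel:.3%})",
            f"condition number of W W': {diag.condition_number:.4g}",
            f"genes with >=1 active bound: {diag.n_genes_at_bound} / {n}",
            "",
            "mean estimated frequency per cell type:",
        ]
        for c, ct in enumerate(res.frequencies.cell_type_order):
            row = res.frequencies.values[c]
            extra = ""
            if res.frequencies.gbar is not None:
                extra = f"   gbar={res.frequencies.gbar[c]:.6g}"
            lines.append(f"  {ct:>12s}: {row.mean():7.4f} (min {row.min():.4f}, max {row.max():.4f}){extra}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        n, k = self._result.signatures.values.shape
        return f"<DigitalSortingResults: {n} genes, {k} cell types>"
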