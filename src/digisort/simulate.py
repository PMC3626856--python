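"""Ground-truthed synthetic mixtures for benchmarking the pipeline.

Two built-in designs mirror classic deconvolution benchmarks:

``three_tissue``
    Three pure profiles (liver/brain/lung-like) mixed at 11 fixed proportion
    vectors, each replicated (default 3x), giving p = 33 samples.

``immune_dilution``
    Six immune-cell-like components whose abundances follow a decreasing
    ladder from 60% down to 0.1%, probing the detection limit for rare
    populations.  Per-sample weights are jittered around the ladder and
    re-sorted so component c is always the c-th most abundant, then
    renormalized — identical columns would make W rank deficient and the
    model unidentifiable.

True signatures are log-normal (log2-normal base, mean 6, sd 1.5 on the log2
scale) to mimic microarray dynamic range; each marker gene is ``marker_fold``
times higher in its own type than its base level (``marker_fold=inf`` zeroes
the off-type expression instead — the idealized marker used by exactness
tests).  Measurement noise is multiplicative log-normal in linear space,
mean-corrected so E[observed] = S @ W.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    FrequencyMatrix,
    MarkerSet,
    SignatureMatrix,
    ValidationError,
)

__all__ = ["DesignSpec", "MixtureTruth", "generate_truth", "subsample_markers",
           "write_truth", "read_truth",
           "THREE_TISSUE_SCHEDULE", "IMMUNE_DILUTION_LADDER"]

# 11 fixed mixing vectors (liver, brain, lung) used by the three-tissue design;
# stand-ins chosen to span pure-dominated to balanced compositions.
THREE_TISSUE_SCHEDULE: tuple[tuple[float, float, float], ...] = (
    (0.70, 0.25, 0.05),
    (0.25, 0.70, 0.05),
    (0.05, 0.25, 0.70),
    (0.70, 0.05, 0.25),
    (0.05, 0.70, 0.25),
    (0.25, 0.05, 0.70),
    (0.34, 0.33, 0.33),
    (0.50, 0.30, 0.20),
    (0.20, 0.50, 0.30),
    (0.30, 0.20, 0.50),
    (0.60, 0.20, 0.20),
)

# Decreasing abundance ladder spanning 60% down to 0.1% (sums to 1 exactly).
IMMUNE_DILUTION_LADDER: tuple[float, ...] = (0.6, 0.264, 0.1, 0.03, 0.005, 0.001)

_LOG2_MEAN = 6.0
_LOG2_SD = 1.5


@dataclass
class DesignSpec:
    """Parameters of a synthetic mixture design.

    ``marker_fold`` is the enrichment of a marker in its own cell type over
    its base expression (default 100: strongly but not perfectly specific;
    ``inf`` makes markers ideal).  ``proportion_jitter`` is the log-normal sd
    applied per sample around the design's proportion schedule.
    """

    design: str = "custom"
    n_genes: int = 5000
    k: int = 4
    markers_per_type: int = 10
    marker_fold: float = 100.0
    p: int = 12
    replicates: int = 3
    noise_sd: float = 0.1
    proportion_schedule: tuple[tuple[float, ...], ...] | None = None
    proportion_jitter: float = 0.3
    dirichlet_concentration: float = 10.0
    seed: int = 0
    noise_model: str = "lognormal"  # or "additive"

    def __post_init__(self) -> None:
        if self.design not in ("three_tissue", "immune_dilution", "custom"):
            raise ValidationError(f"unknown design {self.design!r}")
        if self.design == "three_tissue":
            self.k = 3
        elif self.design == "immune_dilution":
            self.k = 6
        if not self.marker_fold > 1:
            raise ValidationError("marker_fold must be > 1")
        if self.n_genes < self.k * self.markers_per_type:
            raise ValidationError("n_genes must be >= k * markers_per_type")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.design == "custom" and self.proportion_schedule is None:
            raise ValidationError("custom design requires a proportion_schedule")


@dataclass
class MixtureTruth:
    """A simulated mixture with its full ground truth."""

    signatures: SignatureMatrix
    frequencies: FrequencyMatrix
    markers: MarkerSet
    observed: ExpressionMatrix
    noise_sd: float
    seed: int
    spec: DesignSpec | None = None


def _base_signatures(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    return np.exp2(rng.normal(_LOG2_MEAN, _LOG2_SD, size=(n, k)))


def _frequencies_for(spec: DesignSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.design == "three_tissue":
        cols = [np.asarray(v, dtype=float)
                for v in THREE_TISSUE_SCHEDULE for _ in range(spec.replicates)]
        W = np.column_stack(cols)
    else:
        if spec.design == "immune_dilution":
            ladder = np.asarray(IMMUNE_DILUTION_LADDER, dtype=float)
            schedule = np.tile(ladder[:, None], (1, spec.p))
            if spec.proportion_jitter > 0:
                # weights drawn randomly but kept in decreasing order:
                # component c is always the c-th most abundant
                jitter = np.exp(rng.normal(0.0, spec.proportion_jitter, size=schedule.shape))
                W = -np.sort(-(schedule * jitter), axis=0)
            else:
                W = schedule.copy()
        else:
            sched = np.asarray(spec.proportion_schedule, dtype=float)
            if sched.ndim == 1:
                if sched.shape[0] != spec.k:
                    raise ValidationError("proportion schedule length must equal k")
                # per-sample compositions vary around the scheduled mean:
                # Dirichlet(conc * schedule) has mean exactly the schedule
                W = rng.dirichlet(spec.dirichlet_concentration * sched, size=spec.p).T
            else:
                if sched.shape[1] != spec.k:
                    raise ValidationError("each proportion vector must have length k")
                W = sched.T  # explicit per-sample vectors, used as-is
        W = W / W.sum(axis=0)
    colsums = W.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-9):
        raise AssertionError("internal error: proportion columns failed to renormalize")
    return W


def generate_truth(spec: DesignSpec) -> MixtureTruth:
    """Generate a :class:`MixtureTruth` deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    W = _frequencies_for(spec, rng)
    p = W.shape[1]
    n = spec.n_genes
    S = _base_signatures(rng, n, k)
    cell_types = [f"type{c + 1}" for c in range(k)]
    if spec.design == "three_tissue":
        cell_types = ["liver", "brain", "lung"]
    gene_ids = [f"gene{g + 1:05d}" for g in range(n)]
    assignments: dict[str, list[str]] = {}
    for c, ct in enumerate(cell_types):
        marker_rows = range(c * spec.markers_per_type, (c + 1) * spec.markers_per_type)
        assignments[ct] = [gene_ids[g] for g in marker_rows]
        for g in marker_rows:
            if np.isinf(spec.marker_fold):
                own = S[g, c]
                S[g, :] = 0.0
                S[g, c] = own
            else:
                S[g, c] *= spec.marker_fold
    markers = MarkerSet(assignments, list(cell_types))
    clean = S @ W
    if spec.noise_sd > 0:
        if spec.noise_model == "lognormal":
            # mean-corrected: E[exp(N(-s^2/2, s^2))] = 1
            factors = np.exp(rng.normal(-spec.noise_sd**2 / 2.0, spec.noise_sd, size=clean.shape))
            observed = clean * factors
        else:
            scale = spec.noise_sd * float(clean.mean())
            observed = np.clip(clean + rng.normal(0.0, scale, size=clean.shape), 0.0, None)
    else:
        observed = clean.copy()
    sample_ids = [f"sample{j + 1:03d}" for j in range(p)]
    return MixtureTruth(
        signatures=SignatureMatrix(S, gene_ids, list(cell_types), (0.0, float("inf"))),
        frequencies=FrequencyMatrix(W, list(cell_types), sample_ids),
        markers=markers,
        observed=ExpressionMatrix(observed, gene_ids, sample_ids),
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        spec=spec,
    )


def write_truth(truth: MixtureTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated mixture and its ground truth as plain TSV/YAML files."""
    from dataclasses import asdict

    import yaml

    from .io import write_markers, write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "observed": out / "observed.tsv",
        "true_signatures": out / "true_signatures.tsv",
        "true_frequencies": out / "true_frequencies.tsv",
        "markers": out / "markers.tsv",
        "spec": out / "spec.yaml",
    }
    write_matrix(truth.observed.to_frame(), paths["observed"])
    write_matrix(truth.signatures.to_frame(), paths["true_signatures"])
    write_matrix(truth.frequencies.to_frame(), paths["true_frequencies"])
    write_markers(truth.markers, paths["markers"])
    meta = asdict(truth.spec) if truth.spec is not None else {}
    meta.update({"noise_sd": truth.noise_sd, "seed": truth.seed})
    if meta.get("proportion_schedule") is not None:
        meta["proportion_schedule"] = [list(map(float, v)) for v in
                                       np.atleast_2d(meta["proportion_schedule"])]
    meta = {k: (float(v) if isinstance(v, (np.floating, float)) else
                int(v) if isinstance(v, (np.integer,)) else v)
            for k, v in meta.items()}
    paths["spec"].write_text(yaml.safe_dump(meta, sort_keys=True))
    return paths


def read_truth(truth_dir: str | Path) -> MixtureTruth:
    """Load a mixture written by :func:`write_truth`."""
    import yaml

    from .io import read_expression, read_frequencies, read_markers, read_signatures

    d = Path(truth_dir)
    meta = yaml.safe_load((d / "spec.yaml").read_text()) if (d / "spec.yaml").exists() else {}
    return MixtureTruth(
        signatures=read_signatures(d / "true_signatures.tsv"),
        frequencies=read_frequencies(d / "true_frequencies.tsv"),
        markers=read_markers(d / "markers.tsv", dialect="two_column"),
        observed=read_expression(d / "observed.tsv"),
        noise_sd=float(meta.get("noise_sd", 0.0)),
        seed=int(meta.get("seed", 0)),
        spec=None,
    )


def subsample_markers(truth: MixtureTruth, per_type: int, seed: int) -> MarkerSet:
    """Draw a uniform random subset of ``per_type`` markers per cell type."""
    if per_type < 1:
        raise ValidationError("per_type must be >= 1")
    rng = np.random.default_rng(seed)
    sub: dict[str, list[str]] = {}
    for ct in truth.markers.cell_type_order:
        pool = truth.markers.assignments[ct]
        if per_type > len(pool):
            raise ValidationError(
                f"requested {per_type} markers for {ct!r} but only {len(pool)} available"
            )
        pick = rng.choice(len(pool), size=per_type, replace=False)
        sub[ct] = [pool[i] for i in sorted(pick)]
    return MarkerSet(sub, list(truth.markers.cell_type_order))
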