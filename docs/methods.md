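# Methods

## Model and assumptions

`digisort` fits the linear mixing model `O = S W` (genes × samples =
genes × cell-types · cell-types × samples). The assumptions this rests on:

1. **Linearity on the natural scale.** mRNA quantities add when cell
   populations mix, so the model holds on the linear expression scale only.
   Log-transformed input must be exponentiated first (`transform="antilog2"`
   in the reader); this is never auto-detected, because silently guessing the
   scale of a matrix is how analyses go quietly wrong.
2. **Marker validity.** Each marker gene is highly expressed in exactly one
   of the k modelled cell types. Only marker *identities* are used — their
   pure-type expression level `ḡ_c` is estimated, not assumed, which is what
   removes the need for reference profiles and keeps cross-type fold-change
   estimates unbiased (a marker-normalization scheme would rescale every
   profile by its own markers' level).
3. **Complete composition.** The k modelled types account for (essentially)
   all of each sample; the column-simplex constraint on W is what turns the
   marker averages into absolute proportions.
4. **Known k and marker lists.** The package does not discover cell types or
   markers from data.

## Step I: proportions from markers

For cell type c, the marker rows of O are averaged into `Õ[c, j]`. Under the
model `Õ[c, j] = ḡ_c W[c, j] + (off-type contamination)`. The sum-to-one
identity per sample yields p equations in x = (1/ḡ₁ … 1/ḡ_k), solved by
**nonnegative least squares** (`scipy.optimize.nnls`): negative mean marker
expression has no physical meaning. Design choices:

* **p ≥ k required**; p = k is accepted with a warning (exactly determined,
  no averaging of errors). The recommended regime is p > k.
* **x_c = 0 at the optimum is an error**, naming the cell type: a zero
  reciprocal weight means the sample set carries no usable signal for that
  type's markers (in practice: the type is too rare or its markers too
  contaminated). This refusal is deliberate — see *Detection limit* below.
* **Rank-deficient collapsed matrices are an error** (with the condition
  number in the message) rather than a pseudo-inverse solve: a minimum-norm
  solution would silently redistribute proportions between collinear types.
  A condition number above `min_condition_warn` (default 1e6) warns.
* **Simplex projection.** Raw `W = Õ / ḡ` has nonnegative entries but its
  columns only sum to 1 exactly in the noise-free case; entries are clipped
  at 0 and each column renormalized (`clip_and_renormalize`, default on).
  The estimated `ḡ` is kept on the result (`FrequencyMatrix.gbar`).

## Step II: signatures by bounded least squares

Given W, `min_S ‖O − SW‖²_F` subject to `t₂ ≤ S ≤ t₁` separates into n
independent k-variable problems — mathematically identical to the joint
program and linear rather than quadratic in memory. Implementation:

* The shared normal matrix `W Wᵀ` (plus `λI` when `ridge > 0`) is factored
  once; every gene's **unconstrained** solution is computed in one BLAS call
  and accepted wherever it already satisfies the box (with no active bound
  the constrained and unconstrained optima coincide). Only violating rows go
  through the active-set **BVLS** solver (`scipy.optimize.lsq_linear`).
* Defaults `t₂ = 0`, `t₁ = ∞`: nonnegativity is the physically binding
  constraint; a finite ceiling (a platform's saturation level, e.g. slightly
  above `max(O)`) can be set when appropriate.
* **Rank-deficient W is an error unless `ridge > 0`** (opt-in Tikhonov
  regularization); the condition number of `W Wᵀ` is always reported.
* Diagnostics carry per-gene residual sums of squares (which sum exactly to
  the squared Frobenius residual), the count of genes with an active bound,
  and the condition number.

## Evaluation protocol

* **Reference labels.** A gene is a true positive for a pair of types when
  its true expression ratio exceeds the fold cutoff (default 2) *in either
  direction*. Ratios use a pseudocount `ε = 1e-8 · max(matrix)` so entries
  clamped to zero stay finite; the distortion is bounded and deterministic.
* **Score.** The estimated ratio r is symmetrized to `max(r, 1/r)`, so
  both increases and decreases rank above unchanged genes; a one-sided sweep
  cannot rank decreases. The raw one-sided ratio is also exposed.
* **ROC/AUC** via scikit-learn's threshold sweep; ties are handled by the
  trapezoidal rule, so the AUC equals the Mann–Whitney concordance
  probability (the unit tests verify this against brute-force pair
  counting).
* **Accuracy report**: per-type Pearson r, MSE and mean |Δ| between
  estimated and true signatures, the mean true frequency, and an
  **operational SNR** — mean contribution of the type to the mixture
  (`mean_j W[c,j] · mean_g S[g,c]`) divided by the linear-scale noise sd
  implied by the simulator (`sqrt(exp(σ²) − 1) · mean(SW)`). There is no
  canonical SNR for this problem; this definition is only computable when
  the generating noise parameters are known, and is reported for simulated
  data only.

## The simulators: what they emulate, and what they do not

`generate_truth` produces fully ground-truthed mixtures:

* **True signatures** are drawn i.i.d. log-normal (log2-scale mean 6,
  sd 1.5), mimicking microarray dynamic range (~3 orders of magnitude,
  heavy upper tail). Marker genes are `marker_fold`× their base level in
  their own type (default 100 — strongly but imperfectly specific;
  `marker_fold=inf` zeroes off-type expression, the idealized regime used
  by exactness tests).
* **three_tissue**: 3 types mixed at 11 fixed proportion vectors ×
  `replicates` (default 3, p = 33). The vectors span dominant-to-balanced
  compositions; they are documented stand-ins, not measured mixing ratios.
* **immune_dilution**: 6 types on a fixed decreasing ladder
  (0.6, 0.264, 0.1, 0.03, 0.005, 0.001 — 60% down to 0.1%). Per-sample
  weights are log-normal-jittered around the ladder and re-sorted so
  component c is always the c-th most abundant, then renormalized.
  Identical columns would make W rank-1 and the model unidentifiable, so
  sample-to-sample variation is required, not optional.
* **custom**: per-sample compositions drawn Dirichlet(`concentration` ×
  schedule), whose mean is exactly the schedule; `concentration` (default
  10) sets the spread. Explicit per-sample vectors may be given instead.
* **Noise** is multiplicative log-normal in linear space (consistent with
  the linearity assumption), **mean-corrected** by `e^{−σ²/2}` so
  `E[O] = SW` — without the correction the observed matrix would be biased
  upward by `e^{σ²/2}` (~0.5% at σ = 0.1). Additive Gaussian noise is
  available as an option.

Not emulated: probe saturation, batch effects, cross-hybridization,
count-based (Poisson-like) noise at low intensities, correlated expression
across genes, and markers that are wrong (assigned to the wrong type).
Passing tests on these simulations therefore demonstrate the estimator's
correctness and its noise/abundance limits under the stated model, not
robustness to annotation errors or platform artifacts.

## Detection limit for rare cell types

Averaging a rare type's markers gives `ḡ_c w + contamination`; at default
settings (`marker_fold = 100`) a component below ~1% contributes less to its
own marker average than the other 99% of the mixture does, and the
nonnegative sum-to-one solve pushes its weight to zero — step I then refuses
with an "unidentifiable" error rather than returning a fabricated
proportion. The detection-limit analysis in the acceptance suite therefore
supplies the *true* W and measures step II alone: per-type signature MSE
grows monotonically as true frequency falls (the leverage
`[(WWᵀ)⁻¹]_cc` grows by ~6 orders of magnitude along the 60%→0.1% ladder),
and the 0.1% component's recovered profile is statistically
indistinguishable from chance — assessed by **Spearman rank correlation
against an explicit gene-permutation null** (median permutation p ≈ 0.4
across simulations), while the abundant components are significant in every
run. Rank correlation is used because both profiles are heavy-tailed
log-normal: the permutation distribution of the linear-scale Pearson r is
extremely peaked with rare large excursions, and a modest permutation count
misreads negligible (~0.02) correlations as significant.

## Numerical choices

* Solver tolerance 1e-8 (BVLS); unconstrained fast-path acceptance uses the
  same tolerance scaled by the solution magnitude.
* Singularity threshold: smallest singular value ≤ `max(dim) · eps · largest`.
* TSV serialization at 15 significant digits (round trips well below the
  1e-9 documented guarantee).
* All randomness flows through `numpy.random.default_rng(seed)` from
  user-visible seeds; no global RNG state.

## Problem sizes in the shipped test and acceptance runs

The suite exercises: exactness at n = 300–1000 genes; the DE-AUC benchmark
at n = 5000 genes, k = 4, p = 12, 5 simulations; the dilution analysis at
n = 1000 genes over 40 simulations (40 gives the heavy-tailed mean-MSE
estimate a Monte Carlo error safely below the between-type ordering gaps);
the marker-count sweep at counts {1, 2, 5, 10, 20} over 100 simulations.
These sizes reproduce the qualitative and quantitative behaviors at desk
scale; nothing in the method is specific to them.

## Known limitations

* k must be supplied, and markers must exist (and be right) for every
  modelled type; there is no "remainder" component for unmodelled cell mass.
* Frequencies for components below ~1% are not estimable from markers under
  realistic contamination (by design, this errors rather than guessing).
* Missing values are rejected; the linear system and the bounded
  least-squares step have no principled treatment for them.
* The simplex projection (clip + renormalize) is a heuristic repair for
  noise-induced constraint violations, not a maximum-likelihood estimate on
  the simplex.
* With near-collinear cell types the per-gene problems are ill-conditioned;
  the package reports the condition number and offers ridge, but cannot
  manufacture identifiability.
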