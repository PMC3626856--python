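# digisort

**Marker-based digital sorting of bulk expression profiles.**

Bulk tissue transcriptomes are mixtures: the measured expression of every
gene is a weighted sum of its expression in each constituent cell type, with
weights equal to the cell-type proportions of the sample. `digisort`
decomposes such mixtures *in silico* — a computational analogue of physical
cell sorting — recovering both the mixing proportions and the cell-type
specific expression profiles, using nothing but a list of marker genes: for
each cell type, genes known to be highly expressed in that type and low in
all others. Neither the proportions nor the pure-type expression levels need
to be known in advance.

It is aimed at anyone analysing expression data from heterogeneous samples
(tumors and their microenvironment, blood, composite tissues) who has marker
gene lists but no matched pure-population reference profiles.

## The model

With *n* genes, *k* cell types and *p* samples, mixing is linear on the
untransformed expression scale:

```
O = S W
```

* `O` (*n × p*): observed mixed-sample expression (linear scale),
* `S` (*n × k*): per-cell-type signature profiles (unknown),
* `W` (*k × p*): cell-type proportions; every column lies on the probability
  simplex (unknown).

Estimation proceeds in two steps.

**Step I — proportions from markers.** Averaging the marker rows of `O` for
cell type *c* gives a collapsed matrix `Õ` with `Õ[c, j] = ḡ_c · W[c, j]`,
where `ḡ_c` is the (unknown) mean expression of *c*'s markers in the pure
type. Because each column of `W` sums to one, every sample contributes one
linear equation `Σ_c Õ[c, j] / ḡ_c = 1` in the unknowns `1/ḡ_c`. With at
least *k* samples the system is solved by nonnegative least squares, and
`W[c, j] = Õ[c, j] / ḡ_c` (clipped to ≥ 0 and column-renormalized under
noise). A known `W` can be supplied instead, skipping this step.

**Step II — signatures by constrained least squares.** Given `W`,

```
min_S ‖O − S W‖²_F    subject to    t₂ ≤ S_ij ≤ t₁
```

The objective separates by gene, so `S` is recovered as *n* independent
*k*-variable box-constrained least-squares problems (BVLS), with defaults
`t₂ = 0`, `t₁ = ∞` — expression cannot be negative.

The package also ships the evaluation protocol used to benchmark such
methods (ROC/AUC for detecting true >2-fold expression differences from
ratios of deconvolved profiles, per-type accuracy reports) and ground-truthed
mixture simulators (a 3-tissue design mixed at 11 proportions in triplicate,
and a 6-type immune "dilution" design with abundances from 60% down to 0.1%
that probes the detection limit for rare populations).

## Worked example

```python
from digisort import (DesignSpec, DigitalSortingModel, generate_truth,
                      accuracy_report)

truth = generate_truth(DesignSpec(design="three_tissue", n_genes=2000,
                                  markers_per_type=10, noise_sd=0.1, seed=7))
model = DigitalSortingModel(truth.observed, markers=truth.markers)
res = model.fit()
print(res.summary())
```

```
Digital sorting results
=======================================================
genes: 2000   cell types: 3   samples: 33
frequency source: estimated from markers
Frobenius residual ||O - SW||: 14424.8 (relative 8.285%)
condition number of W W': 5.243
genes with >=1 active bound: 49 / 2000

mean estimated frequency per cell type:
         liver:  0.3597 (min 0.0559, max 0.7119)   gbar=5690.06
         brain:  0.3215 (min 0.0523, max 0.7003)   gbar=16655.2
          lung:  0.3188 (min 0.0578, max 0.7134)   gbar=7425.73
```

The relative residual (~8%) matches the 10% multiplicative measurement noise
the simulation injected; the `gbar` values are the estimated mean marker
expression of each pure tissue; 49 genes touched the nonnegativity bound.
Comparing the deconvolved signatures against the true ones:

```python
print(accuracy_report(res.result, truth).table.round(4))
```

```
           pearson_r        mse  mean_abs_diff  mean_true_frequency     snr
cell_type
liver         0.9995   239.2585         5.9921               0.3582  2.9747
brain         0.9997  3809.4659         8.3769               0.3209  3.9258
lung          0.9994  1286.4765         7.5598               0.3209  3.0745
```

Each recovered profile correlates with its ground truth at r > 0.999 even
though no pure-tissue expression values were ever given to the model — only
which genes are markers of which tissue.

The same pipeline is available from the shell:

```sh
dsa simulate --design three_tissue --n-genes 2000 --noise-sd 0.1 --seed 7 -o truth/
dsa deconvolve --expr truth/observed.tsv --markers truth/markers.tsv -o fit/
dsa evaluate --est fit/ --truth truth/ -o report.tsv
dsa roc --est fit/ --truth truth/ --pair liver,brain
```

## Layout

* `digisort.model` — `DigitalSortingModel` / `DigitalSortingResults`, the
  fitting interface.
* `digisort.frequencies` — step I: marker collapse, the sum-to-one system,
  simplex projection.
* `digisort.deconvolve` — step II: per-gene bounded least squares; the
  functional `run_dsa` pipeline.
* `digisort.evaluate` — ROC/AUC fold-change detection, accuracy reports.
* `digisort.simulate` — ground-truthed mixture designs.
* `digisort.io` / `digisort.datatypes` — TSV/GMT readers and writers,
  validated containers.
* `digisort.cli` — the `dsa` command.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
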