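# divnoise

Quantifying **partitioning noise at cell division** — the cell-to-cell
variability in how a mother cell's components are split between its two
daughters — from high-throughput dye-dilution flow cytometry, validated
against single-cell time-lapse microscopy.

## The problem

When a proliferating cell divides, one daughter inherits a fraction *f*
of any given cellular component (cytoplasm, organelles, a fluorescent
dye), and its sibling inherits 1 − *f*. Because daughters are
exchangeable, the partition distribution Π(*f*) is symmetric about 1/2;
its variance σ<sub>f</sub>² is the *partitioning noise*, and the
**division asymmetry** is its coefficient of variation as a percent,
CV% = 100 · σ<sub>f</sub> / (1/2). Asymmetric partitioning feeds
phenotypic heterogeneity — notably in cancer cells — but measuring it by
microscopy requires manually tracking hundreds of divisions.

`divnoise` implements a population-level alternative. Cells are stained
with a non-endogenous dye (e.g. CellTrace), sorted to a narrow intensity
peak, and re-measured over several days. Each division halves the dye on
average, so generations appear as successively halved intensity peaks.
Exact moment dynamics of this dilution process link what a cytometer
sees to Π(*f*):

```
μ_g  = μ₀ / 2^g                                    (mean, any Π)
σ_g² = μ₀² (E[f²]^g − 4^(−g)) + σ₀² E[f²]^g,       E[f²] = σ_f² + 1/4
```

The mean carries no information about Π; the variance grows
geometrically with ratio E[*f*²], so fitting the per-generation variance
yields σ<sub>f</sub>. Under binomial segregation of N components with
bias *p* (probability a component goes to a given daughter),
σ<sub>f</sub>² = pq·Σ(N) + (p² + q²)/2 − 1/4 with Σ(N) = E[1/N]; for
large N this inverts to **p = 1/2 − σ<sub>f</sub>**.

## What the package provides

- `divnoise.partition` — partition distributions (delta, two-point,
  truncated Gaussian, symmetric double Gaussian, binomial limit), the
  exact moment dynamics, and the weighted least-squares estimator of
  σ<sub>f</sub> from a per-generation moment series.
- `divnoise.cytometry` — generation deconvolution of log2-intensity
  histograms by a hand-rolled 1-D Gaussian-mixture EM (means tied to the
  unit-log2 dilution comb up to a bounded shared offset; BIC component
  selection), conversion to linear moments, pooling across time points.
- `divnoise.microscopy` — inherited-fraction estimation from
  mother/daughter intensity traces via shared-slope log-linear fits,
  QC filtering (observation window, intensity–area Pearson filter),
  double-Gaussian fits of the empirical Π(*f*), size–fraction
  association.
- `divnoise.binomial` — the Σ(N) integral under delta and truncated
  lognormal mother-count models and the σ<sub>f</sub> ↔ bias mapping.
- `divnoise.simulate` — seeded lineage simulators (uncoupled lognormal
  cycle times, or sizer-coupled growth where one *f* splits both size
  and dye) and synthetic-data generators for cytometry time courses and
  microscopy division events, with ground-truth labels.
- `divnoise.io` + a `divnoise` CLI — FCS 3.0/3.1 and CSV readers,
  trace-table schema, YAML run configs, and the commands
  `simulate-cytometry`, `simulate-traces`, `fit-cytometry`,
  `fit-traces`, `bias-map`, `report`.

## Worked example

Simulate a 0–84 h dye-dilution time course with Gaussian partitioning
noise σ<sub>f</sub> = 0.07, then recover it:

```sh
$ divnoise simulate-cytometry --seed 9 --sigma-f 0.07 --n-lineages 900 \
      --events 5000 --out-dir run
seed=9 wrote run/cytometry.csv

$ divnoise fit-cytometry --input run/cytometry.csv --seed 9 --out-dir run
seed=9 sigma_f=0.0670 cv=13.4% -> run/cytometry_fit.json
```

The fit report shows `sigma_f = 0.067` (true value 0.07): a division
asymmetry of 13.4 CV%, i.e. a typical division splits the cytoplasm
about 53 : 47. The JSON also contains the diagnostic log2-mean slope
(here −0.985; −1 expected, since the dye halves per generation), the
per-generation moment series, a bootstrap standard error, and the
implied binomial bias `p = 0.433`. The same library call is
`divnoise.estimate_from_timecourse(snapshots)`.

For microscopy traces:

```sh
$ divnoise simulate-traces --seed 6 --sigma-f 0.1 --n-events 150 --out-dir run
$ divnoise fit-traces --input run/traces.csv --seed 6 --out-dir run
seed=6 sigma_f=0.1039 cv=20.8% -> run/traces_fit.json
$ divnoise report --cytometry-fit run/cytometry_fit.json \
      --traces-fit run/traces_fit.json --out-dir run
```

`report` merges both estimates into the population-vs-single-cell
comparison table.

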