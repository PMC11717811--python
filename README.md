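# gliamig

Quantification pipeline for postnatal glial-progenitor migration assays:

- **coloc** — per-cell marker-positivity scoring from a reporter label mask
  and a marker channel: Otsu/fixed binarization, whole-cell or membrane
  "donut" ring regions, nuclear (DAPI-mask) scoring against a reporter,
  overlap fractions with a strict `> 0.6` positivity rule, and percent
  positive over reporter-positive cells. Elastic alignment is replaced by
  rigid integer translation via cross-correlation.
- **migration** — explant/time-lapse geometry: net displacement
  `d = sqrt(dx^2 + dy^2)`, absolute lateral (X) and radial (Y) components,
  speed `v = d/t`, smoothing-spline white-matter curves with signed
  cortex-side distance queries, and automated migrated-cell counting
  (8-connected components, minimum-area filter, implant-ROI exclusion,
  cortex-mask subcounts).
- **gated_stats** — log-scale linear mixed models with litter and
  slice-within-litter random intercepts (own REML engine, cross-validated
  against statsmodels `MixedLM` in the tests), family-gated inference
  (per-family F-test with Satterthwaite denominator df; member-level Wald
  tests only behind open gates), per-slice `log(count+1)` count models with
  litter as the sole random effect, two-group t-tests, and a paired-t
  power / detectable-effect calculator based on noncentral-t root finding.
- **expression_qc** — scRNA-seq cell QC (keep cells with 200–5000 detected
  features and ≤ 25% mitochondrial counts; bounds inclusive because the
  exclusion rules are strict inequalities), `ln(1 + count/total * 10000)`
  normalization, and per-cluster marker statistics (log2 fold-difference,
  expressing fractions, two-sided Wilcoxon rank-sum, Bonferroni).
- **synthetic** — seeded generators for every input with ground truth
  attached: two-channel colocalization scenes with known per-cell
  co-expression flags, constant-speed time-lapse tracks, hierarchical
  explant experiments with log-normal displacements and Poisson per-slice
  counts, and sparse count matrices with planted QC failures.
- **pipeline / cli** — config-driven end-to-end runs with a JSON report.

## CLI

One entry point with subcommands:

```sh
gliamig simulate coloc --config params.yaml --seed 1 --out out/
gliamig coloc score --mask mask.tif --marker marker.tif --pattern membrane --threshold 0.6
gliamig migrate distances --points points.csv --out derived.csv
gliamig migrate count --image reporter.tif --center-x 500 --center-y 500 --radius 500
gliamig stats gate --records derived.csv --outcome lateral --alpha 0.05
gliamig stats power --n 5 --power 0.8
gliamig qc filter --counts-csv counts.csv --out filtered/
gliamig run --config run.yaml
```

Exit codes: 2 parameter error, 3 input error, 4 computation error.

A `run.yaml` for `gliamig run` holds `out_dir`, `seed`, and any of the
stage blocks `simulate`, `coloc`, `migrate`, `stats`, `qc`; stages run in
that order, later stages default to consuming earlier outputs, and every
run writes `report.json` with the parameters, seeds, and headline numbers.

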