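# octrepeat

Test–retest repeatability analysis of macular OCT intra-retinal layer
thickness estimates.

## The problem

Quantitative optical coherence tomography (OCT) studies — above all in
multiple sclerosis research — report mean thicknesses of individual retinal
layers (macular RNFL, GCL, IPL, the combined GCIP, INL, OPL, ONL).  The
published literature computes these means in wildly different ways: some
studies average a full 6 mm-diameter macular disc from a dense volume scan,
others a single fovea-centered B-scan, others a handful of manually sampled
points; Cirrus HD-OCT reports come from an elliptical annulus around the
fovea.  A *thickness estimate* — the rule (scan protocol × B-scan selection ×
region mask × averaging) that turns one segmented scan into one number —
strongly affects how repeatable that number is across repeated examinations,
and therefore how small a longitudinal change a clinical study can detect.

`octrepeat` implements twelve such estimates (A–L: ten Spectralis-style,
two Cirrus-style) as declarative, overridable recipes, evaluates them on
segmentation surface exports, and quantifies repeatability per estimate ×
layer. A synthetic cohort generator with known variance components makes
every stage testable without patient data.

## The statistics

With the eye as measurement unit and sessions as replicates, a one-way
ANOVA (`x_ij = μ + b_i + e_ij`) yields the between- and within-unit mean
squares MSB and MSW, and from them:

* **ICC(1,1)** = (MSB − MSW) / (MSB + (k−1)·MSW), single-measures
  intraclass correlation, with its exact F-based 95 % CI; for unbalanced
  designs k is replaced by k₀ = (N − Σnᵢ²/N)/(a−1).  Classification:
  \>0.9 excellent, 0.8–0.9 moderate, <0.8 insufficient.
* **Coefficient of repeatability** CR = 2.77·s_w with s_w = √MSW — the
  95 % bound on the absolute difference between two repeated measurements
  (2.77 is the conventional rounding of √2 × 1.96).
* **Bland–Altman analysis** over every unordered session pair: bias and
  1.96·SD limits of agreement.

## Worked example

Simulate a small mixed cohort (8 healthy controls with three sessions,
6 MS patients with two, both eyes) on one Spectralis and one Cirrus
protocol, evaluate every applicable estimate, and tabulate repeatability:

```python
from octrepeat import (CohortConfig, iter_cohort_volumes, builtin_estimates,
                       apply_all, repeatability_table, icc_grid, cr_grid)

cfg = CohortConfig(n_hc_subjects=8, n_ms_subjects=6,
                   protocols=("V-25-1024", "H-128-512"), seed=7)
volumes, truth = iter_cohort_volumes(cfg)
table = apply_all(builtin_estimates(cfg.resolved_protocols()), volumes,
                  layers=cfg.record_layers)
result = repeatability_table(table, cohort="mixed")
print(icc_grid(result).to_string())
print(cr_grid(result).to_string())
```

which prints (estimate A = 6 mm disc mean on the V-25-1024 volume,
J = 3-point sparse mean on the central B-scan, K = Cirrus 512×128 annulus —
only RNFL and GCIP exist on Cirrus):

```
                      RNFL               GCL               IPL              GCIP               INL               OPL               ONL
estimate
A         0.98 [0.96–0.99]  0.98 [0.96–0.99]  0.97 [0.94–0.98]  0.99 [0.97–0.99]  0.97 [0.95–0.99]  0.85 [0.73–0.92]  0.98 [0.96–0.99]
J         0.69 [0.49–0.83]  0.63 [0.40–0.79]  0.58 [0.35–0.77]  0.84 [0.71–0.92]  0.69 [0.49–0.83]  0.38 [0.11–0.62]  0.82 [0.69–0.91]
K         0.95 [0.91–0.98]                NA                NA  0.98 [0.96–0.99]                NA                NA                NA

           RNFL    GCL    IPL   GCIP   INL   OPL   ONL
estimate
A          2.48   2.43   2.37   2.81  2.52  2.31  2.69
J         10.10  12.00  10.92  10.04  9.88  9.55  8.77
K          3.47     NA     NA   3.63    NA    NA    NA
```

Read: the area-averaging estimate A is excellent (ICC ≈ 0.97–0.99) for
every layer except the OPL, and two repeated measurements differ by less
than ~2.5 µm with 95 % probability (CR).  The sparse-point estimate J is
an order of magnitude noisier (CR ≈ 9–12 µm) — too noisy to track the
~1 µm/year changes clinical studies care about.  The OPL is the least
repeatable layer throughout, because its apparent boundary moves with the
OCT beam's pupil entry position (Henle-fiber-layer reflectivity), not with
averaging extent.

The same analyses are available from the shell:

```bash
octrepeat simulate --seed 7 --out sim/            # long table + ground truth
octrepeat repeatability --table sim/long_table.tsv --cohort mixed --out rep/
octrepeat run --config study.json --out results/  # full report bundle
```

## Layout

```
src/octrepeat/
  geometry.py       scan protocols, coordinate grids, masks, thickness maps
  estimates.py      the estimate registry A–L and the evaluation engine
  repeatability.py  ANOVA components, ICC(1,1), CR, Bland–Altman
  simulate.py       synthetic cohorts with known variance components
  io.py             surface-export CSV and long-table TSV interchange
  pipeline.py       end-to-end study runs with manifests
  cli.py            the `octrepeat` command
docs/methods.md     model, noise components, defaults and their rationale
```
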