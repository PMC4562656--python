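# Methods

This note documents the models and numerical choices behind `octrepeat`:
what exactly is computed, what the synthetic cohort does and does not
emulate, and why the defaults are what they are.  No number quoted here is
asserted anywhere in the package without being recomputed by the tests or
by `scripts/acceptance.py`.

## Geometry model

A volume scan is an `(n_bscans, n_ascans)` grid of axial profiles over a
`width × height` mm area.  Sample positions are fencepost-spaced
(`linspace(0, extent, n)`), so 25 B-scans over 6 mm sit 0.25 mm apart with
the first and last on the area boundary.  The fovea is the coordinate
origin; by default it coincides with the scan-area center, and automatic
fovea detection is explicitly out of scope — the center is an input.

Axial segmentation positions are 0-based pixels from the image top,
increasing with depth.  Layer thickness = (outer − inner boundary) ×
axial scale (3.87 µm/px Spectralis, 1.96 µm/px Cirrus).  The GCIP
composite is delimited directly by the RNFL/GCL and IPL/INL boundaries,
which makes it *identically* the sum of the GCL and IPL maps where those
exist, and still well-defined on Cirrus scans, which segment no GCL/IPL
boundary.

Region masks are evaluated at A-scan cell centers: a cell belongs to a
disc or outer ellipse when its center satisfies the closed inequality
(≤), and to an annulus when it is additionally *strictly* outside the
inner ellipse.  This is the simplest deterministic rule; its area error
vanishes as grids refine, and all masks are bit-reproducible from (grid,
parameters).  Averages weight all included A-scans equally even though
the grids are anisotropic (B-scan spacing ≫ within-B-scan spacing): the
estimates being modelled are "means of all exported values", not
area-weighted integrals.  Missing cells are excluded from averages; an
estimate whose mask is more than 20 % missing (configurable) is flagged
with a warning.

Nearest-B-scan selection resolves an offset in mm to the closest B-scan,
with ties — including float-rounding near-ties on symmetric grids —
broken toward the lower index.

## The estimate registry

Estimates A–L are declarative recipes (protocol name, B-scan selector,
mask provenance, applicable layers) evaluated by one generic engine, so
reproducing any published variant is a configuration change.  What the
source literature fixes: A–C are 6 mm-disc means on three different
volume settings; A–E plus the Cirrus K/L average large areas; G–J are
single-B-scan based; K/L use the elliptical annulus with outer radii
2.4/2.0 mm and inner radii 0.6/0.5 mm and exist only for RNFL and GCIP.
Everything else (which of the five Spectralis settings backs which
estimate, the B-scan subset of F, the pair offsets of H, the three sample
points of J at (0, ±2) mm and the fovea) is a documented, overridable
default — the registry is versioned and the defaults are labelled
defaults.  Estimates record `n_cells` so reliability differences can be
related to averaging extent.

## Reliability statistics

One estimate × layer cell of the long table is a set of repeated values
per eye.  Both eyes enter as independent units (inter-eye correlation is
deliberately ignored to match the modelled study design; a subject-level
unit key would be a one-line change in `repeatability_table`).  Units
with a single session are dropped with a logged warning.

* MSB, MSW from the one-way fixed-effects ANOVA; `k_eff` = k for balanced
  designs and k₀ = (N − Σnᵢ²/N)/(a−1) otherwise.  The shipped mixed
  cohort is unbalanced by design (controls three sessions, patients two),
  so k₀ is the default path.
* ICC(1,1) = (MSB − MSW)/(MSB + (k_eff−1)·MSW).  Negative estimates are
  reported, not truncated to zero: the estimator ranges over
  (−1/(k_eff−1), 1], and truncation would bias simulation studies.
  MSW = 0 returns ICC = 1 with a degenerate CI.
* The 95 % CI comes from F = MSB/MSW with F-quantiles at α/2 on
  (a−1, N−a) df: bound = (F/f* − 1)/(F/f* + k_eff − 1).  Under normality
  and balance this interval is exact, which is what the coverage test
  (95 % ± 2 % over 2 000 designs) verifies.  A last-ulp guard clamps the
  bounds to bracket the point estimate in degenerate cases (MSB = 0).
* CR = 2.77 × √MSW.  The constant is fixed at the printed 2.77 rather
  than √2 × 1.96 = 2.7719… so that reproduced tables round identically.
* Bland–Altman uses every unordered session pair (j < l contributes
  ((xⱼ+xₗ)/2, xⱼ−xₗ)); three sessions yield three pairs.  Limits of
  agreement are bias ± 1.96·SD(diff); with pure session noise the LoA
  half-width equals 1.96·√2·σ_w ≈ CR, which a Monte-Carlo test checks.

Report cells round ICC and CR to two decimals, matching the precision at
which such tables are printed; full-precision sidecars are always written
alongside.  CIs are reported as (lower, upper).

## The synthetic cohort

The generator emulates a repeat-scan study: 15 healthy-control subjects ×
3 sessions and 13 MS/CIS patients × 2 sessions, both eyes, on five
Spectralis volume settings and the two standard Cirrus cubes.  One
subject roster serves both devices; since every estimate is analysed
within its own device's data, the identity of subjects across devices has
no statistical effect.  Only "V-25-1024" is fixed by the modelled
protocol taxonomy; the other four Spectralis designs (H-25-512 and
H-61-768 over 6×6 mm, H-19-512 over 9×4.5 mm, H-13-512 over 6×3 mm, with
plausible ART counts) are registry defaults.

Per eye, each layer's truth is a smooth radial population template
(inner-layer foveal depression, GCL perifoveal ring peaking near 1.7 mm
eccentricity, foveally peaked ONL; all values in [0, 120] µm) plus a
scalar between-eye deviation with per-layer SD `sigma_between`.  MS eyes
get GCL/IPL templates scaled by 0.85 (configurable) to emulate
inner-layer thinning.

Session noise has four components, each motivated by what changes when a
subject is re-seated and the device reset:

1. **Global offset** — a constant axial mis-segmentation per boundary
   surface, SD `sigma_offset/√2` per boundary so that every layer (the
   difference of two boundary errors) has session SD exactly
   `sigma_offset`.
2. **Correlated field** — stationary Gaussian segmentation error with
   pointwise layer SD `sigma_field` and Gaussian correlation
   exp(−d²/4ℓ²), ℓ = `field_correlation_mm`; realised per boundary
   (again /√2) by wrap-mode Gaussian smoothing of white noise with
   analytic variance normalisation, so the variance contract is exact up
   to kernel truncation.  Any smooth stationary field with this variance
   would do; variance, not spectrum, is the contract.
3. **Scan-window jitter** — the session's grid samples the retina at
   coordinates translated by a N(0, `jitter_sd_mm`²) shift, modelling
   imperfect re-placement without a follow-up function.
4. **HFL beam-angle artifact** — see below.

Putting noise on *boundaries* rather than layers matters: it makes the
GCIP exactly as repeatable as an elementary layer (as real tables show —
a naive independent-per-layer model would make the composite √2 worse)
and gives adjacent layers the anticorrelated errors that real boundary
mis-placements produce.

### The HFL artifact

Henle-fiber reflectivity depends on the beam's pupil entry position, so
the apparent OPL/ONL boundary shifts with beam placement.  Per session a
beam offset θ ~ U(−0.5, 0.5) is drawn and the boundary moves by
δ = A·θ·s(x, y), with s smooth, antisymmetric across the fovea along the
horizontal, |s| ≤ 1, peaking near ±1.3 mm eccentricity.  OPL gains δ, ONL
loses it; both floor at 0.5 µm, and wherever the floor is not hit the
OPL+ONL sum is conserved exactly.  With the default amplitude A = 50 µm,
two sessions at θ = ±0.4 differ pointwise by up to ~40 µm in OPL — the
magnitude real repeat B-scans can show.

Because s is antisymmetric, its *mean* over any centrally symmetric mask
(disc, annulus, rectangle, centered line) is exactly zero: the linear
artifact moves estimate means only through the flooring nonlinearity and
fovea-placement jitter.  The property test for "artifact degrades OPL but
not OPL+ONL" therefore samples at the field's peak (a single 1.3 mm
temporal point, away from the floor), where the shift is large and the
sum conserved exactly.  OPL's poor *relative* reliability under the
defaults is carried jointly by this artifact and by OPL's small
between-eye SD — anatomically the OPL varies little across healthy eyes,
and ICC is a relative index.

### Defaults and their calibration

| parameter | default | rationale |
|---|---|---|
| `sigma_between` (µm) | RNFL 5.5, GCL 6.5, IPL 5.5, INL 5.5, OPL 2.0, ONL 7.0 | plausible between-eye spread of macular layer means; GCIP follows as √(6.5²+5.5²) ≈ 8.5 |
| `sigma_offset` (µm) | 0.6 | sub-pixel global segmentation shift |
| `sigma_field` (µm) / ℓ (mm) | 6.5 / 0.18 | local segmentation error large pointwise but short-ranged, so area means suppress it strongly and sparse points do not |
| `jitter_sd_mm` | 0.1 | re-placement accuracy with an eye tracker but no follow-up |
| `hfl_amplitude_um` / θ range | 50 / ±0.5 | pointwise repeat-OPL differences up to ~40 µm |
| `ms_inner_scale` | 0.85 | inner-layer thinning in the patient group |

No quantitative within-session variance decomposition exists to copy, so
these were fixed once, by closed-form variance budgeting, to reproduce
the *qualitative* reliability ordering reported for real cohorts: area
estimates (A–E, K, L) with ICC > 0.9 and CR in the 1–4 µm band, broader
spread for F–J, the sparse-point estimate J above 8 µm CR for every
layer, and OPL the worst layer in ICC terms.  The back-of-envelope: an
area mean over region |R| of the correlated field keeps SD
σ_field·√(4πℓ²/|R|) ≈ 0.8 µm for the 6 mm disc, a 6 mm line keeps
σ_field·√(2√πℓ/L) ≈ 2.1 µm, and three ~independent points keep
σ_field/√3 ≈ 3.75 µm — which, with the offset in quadrature and ×2.77,
lands the three estimate families in the observed CR bands.

What the generator does **not** emulate: speckle or image formation,
segmentation-failure outliers and missing data, operator differences,
inter-eye correlation, floor effects of advanced atrophy, or pathology
beyond global inner-layer scaling.  Passing tests therefore demonstrate
the statistical machinery and the stated noise contracts — not that real
devices behave like the defaults.

## Problem sizes

The test suite and the acceptance script re-simulate everything at run
time.  Sizes were chosen to keep statistical power while staying fast:
variance-component recovery uses 200 replicates of the 60-eye × 3-session
design on the full V-25-1024 grid (the offset-noise criterion is
grid-size-independent, so one protocol suffices); CI coverage uses 2 000
balanced designs simulated at the measurement level (the estimate value
is sufficient, the image stage adds nothing under offset noise); the
ICC-vs-oracle sweep uses 10 000 random small datasets (n ≤ 5, k ≤ 3,
integer values 0–4, degenerate draws skipped); the qualitative-ordering
check runs the full default cohort once (56 Spectralis eyes, all seven
protocols).  Property tests on reduced 9×32 grids use the same code paths
as the full protocols.

## Determinism

Every random draw descends from the config seed through
`numpy.random.SeedSequence`; the streaming and materialised cohort
generators draw in identical order; θ and jitter are drawn even when
their amplitude is zero so that switching a component off does not shift
the remaining draws (enabling exact paired on/off comparisons); report
bundles are byte-identical across reruns of the same (config, seed), and
the run manifest (config, versions, output SHA-256s) is sufficient to
reproduce them.
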