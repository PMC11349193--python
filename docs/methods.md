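# Methods

## The measurement and the model

Extracellular-flux analyzers (Agilent Seahorse XF series) report two rates
per well and measurement cycle: the oxygen consumption rate (OCR, pmol
O2/min), a proxy for oxidative phosphorylation, and the extracellular
acidification rate (ECAR, mpH/min), dominated by glycolytic lactate/H+
efflux but contaminated by CO2-derived acid from the TCA cycle.  The two
rates live in incommensurate units; xflux converts both to ATP production
rates (JATP, pmol ATP/min) using the Mookerjee accounting so oxidative and
glycolytic output can be compared directly.

### State partitioning

The Mito Stress Test injects oligomycin (blocks ATP synthase), FCCP
(uncouples the membrane, driving maximal respiration) and
rotenone/antimycin A (block complexes I/III) in sequence, defining four OCR
states: `basal`, `uncoupled`, `maxresp`, `nonmito`.  The Glyco Stress Test
injects glucose, monensin and 2-deoxyglucose, defining the ECAR states
`no_glucose`, `glucose`, `max_glyc`, `twodg`.  The default scheme splits the
standard 12-measurement protocol into four equal windows of three; every
window and its aggregator are user-configurable because injection timing
varies between protocols.  The window aggregator is the mean, except the
FCCP and monensin phases default to the window maximum because the maximal
response is transient; `last` is available for single-timepoint
conventions.

### Oxidative ATP

From the four OCR states:

    mitochondrial OCR      = basal  − nonmito          (basal)
                           = maxresp − nonmito         (maximal)
    ATP-linked (coupled)   = basal  − uncoupled        (basal)
                           = maxresp − uncoupled       (maximal)

    JATP_ox = 2 · P/O_oxphos · OCR_coupled + 2 · P/O_TCA · OCR_mito

The factor 2 converts O2 to O atoms.  Maximal coupled OCR subtracts the
oligomycin-phase OCR, i.e. the proton leak is assumed unchanged between the
basal and FCCP phases; `max_coupled_mode="nonmito"` switches to subtracting
the rotenone/antimycin plateau instead.

### Glycolytic ATP

ECAR is first converted to a total proton efflux rate with the medium
buffering factor BF (mpH per pmol H+):

    PPR_tot  = ECAR / BF
    PPR_resp = OCR_mito · (max H+/O2) · 10^(pH−pK1) / (1 + 10^(pH−pK1))
    PPR_glyc = PPR_tot − PPR_resp

    JATP_glyc = PPR_glyc · ATP/lactate + 2 · P/O_glyc · OCR_mito

The logistic factor is the ionized fraction of CO2-derived acid at the assay
pH given the carbonic-acid pK1; the second JATP term credits glycolysis for
the ATP made while feeding pyruvate into mitochondrial oxidation.  Because
the Glyco Stress Test has no rotenone/antimycin phase, the
non-mitochondrial OCR needed for `OCR_mito` in the correction is borrowed
from the Mito assay at group level on the same plate (mean nonmito OCR of
the same experimental group); if no Mito data exists the correction falls
back to 0 and the quality report says so.  Subtraction of the pre-glucose
ECAR from the basal/maximal ECAR is available (`subtract_nonglycolytic`)
but off by default, since acidification before glucose may reflect either
non-glycolytic sources or residual media glucose and the attribution is
ambiguous.

Negative intermediate values (components, PPR_glyc) are propagated with
flags, never clipped: clipping would bias group statistics and hide QC
problems.

### Defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| `ph` | 7.4 | — | XF DMEM assay medium |
| `pk1` | 6.093 | — | carbonic acid at 37°C |
| `buffer_factor` | 0.1 | mpH / pmol H+ | XF DMEM |
| `max_h_per_o2` | 1.0 | H+ / O2 | glucose oxidation |
| `po_oxphos` | 2.486 | ATP / O | glucose, oxidative phosphorylation |
| `po_tca` | 0.121 | ATP / O | TCA substrate-level phosphorylation |
| `po_glyc` | 0.167 | ATP / O | glycolysis feeding oxidation |
| `atp_per_lactate` | 1.0 | ATP / lactate | glycolysis stoichiometry |

All are glucose-substrate values; other substrates require overriding
`max_h_per_o2` and the P/O ratios via `AssayConfig` (YAML-serializable).
With BF in mpH/pmol H+, JATP comes out in pmol ATP/min.

## Replicate statistics

Wells within a plate are technical replicates; plates are biological
replicates with substantial between-plate variation.  `summarize_ols` is
the closed-form intercept-only least-squares summary (sample mean, n−1
sample SD, t-based CI) — identical to an intercept-only OLS fit, with no
design matrix needed.  `summarize_lmm` fits

    value_ij = μ + plate_i + ε_ij ,  plate_i ~ N(0, σ²_b),  ε_ij ~ N(0, σ²_w)

by REML (statsmodels `MixedLM`).  The reported mean is the fixed intercept;
the CI is Wald-t with `n_plates − 1` denominator degrees of freedom (the
conservative conventional choice); the reported SD is the total SD
√(σ²_b + σ²_w).  When the default optimizer stalls at the σ²_b → 0 boundary
the fit is retried with Powell, which converges there and reproduces the
pooled-OLS collapse; a genuinely failed fit falls back to an OLS summary of
plate means, logged, never silent.  A single plate degrades to
`summarize_ols`.  Note the CI of the mixed model is intentionally wider
than the pooled-OLS CI even at the collapse point, because its degrees of
freedom count plates, not wells.  No multiple-testing adjustment is applied
anywhere; the summaries are descriptive.

The default CI level is 95% throughout.

## Synthetic plates

The fixture generator emulates the Wave rate-export dialect: long-format
rows of Measurement/Well/Group/Time/OCR/ECAR with the
`"<group> <ASSAY>"` Group convention, a 12-measurement three-injection
layout at 6.5 min cadence, and near-zero background wells.  Kinetics are
piecewise constant at the configured phase means — deliberately, so the
expected energetics have a closed form (`ground_truth_energetics`) that
bypasses parsing and partitioning entirely and serves as the second path of
a two-path oracle.  Noise is additive Gaussian: a per-plate shift common to
all wells of a plate (the minimal structure identifying the random
intercept) plus i.i.d. well-measurement noise.  Default phase means are
typical adherent-cell XF96 magnitudes at ~3×10⁴ cells/well (e.g. basal OCR
120, FCCP plateau 200 pmol O2/min for the OXPHOS-leaning group).

What the generator does **not** emulate: exponential transitions after
injections, within-cycle O2 tension decay, edge effects, drift, or outlier
wells.  Passing tests therefore demonstrate correctness of the conversion
and statistics pipeline, not robustness to instrument pathologies on real
plates.

## Numerical and I/O choices

- Excel float cells are serialized by the writing library at 16 significant
  digits — one short of float64 round-trip — and pandas' fast numeric
  inference is not correctly rounded.  The fixture writer emits exact
  decimal representations for rate/time cells and the reader converts with
  correctly-rounded `float()` (CSV uses `float_precision="round_trip"`), so
  write→read round trips are bit-exact.
- Blank OCR/ECAR cells become flagged NaNs; window aggregation skips them
  and reports the number of points actually used.
- Group labels split on the **last** whitespace run, so experimental group
  names may contain spaces; the assay token is case-folded to upper case.
- Background wells (configurable label, default `Background`) are excluded
  at read time and counted in the read report.
- Normalization divides rates by quantity/scale, with scale 1000 for cell
  counts and 1 for µg protein so normalized magnitudes stay near raw ones;
  re-normalizing a normalized table is an error, not a silent no-op.
- Plot functions never recompute statistics; each returns the tidy table it
  plotted, which re-renders to an identical figure under a fixed style.

## Problem sizes used in the automated checks

The statistical guarantees are exercised at sizes a desk workstation
handles in seconds: confidence-interval coverage with 2000 simulated groups
of 6 wells; mixed-model recovery with 2000 replicates of 6 plates × 8 wells
(plate SD 2, residual SD 1); two-path pipeline equivalence on 2-plate,
3-well noiseless fixtures across several seeds; lossless I/O on 50 random
single-plate fixtures.

## Known limitations

- P/O and H+/O2 defaults cover glucose oxidation only; mixed-substrate
  assays need user-supplied constants.
- The glycolytic respiratory correction borrows group-level nonmito OCR
  from the Mito assay; per-well matching across assays is not possible
  because the two stress tests run in different wells.
- Plate geometry is not validated; any Wave-format rate export parses.
- No outlier rejection or between-group hypothesis testing — the summaries
  are inputs to whatever inference framework the user prefers.
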