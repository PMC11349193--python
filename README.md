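# xflux

Scriptable analysis of Agilent Seahorse extracellular-flux experiments:
parse Wave rate exports, partition measurements into energetic states,
convert oxygen consumption (OCR) and extracellular acidification (ECAR)
into ATP production rates (JATP), summarize replicates with OLS or
mixed-effects statistics, and draw rate, bioenergetic-scope and ATP plots.

It is written for bench scientists and bioinformaticians who run Mito and
Glyco Stress Tests and want the whole pipeline — from the exported `.xlsx`
rate sheet to publishable group summaries — reproducible from a script or a
shell, with no spreadsheet steps.

## The calculation at the core

OCR (pmol O2/min) and ECAR (mpH/min) are converted to a common currency,
JATP (pmol ATP/min), following the Mookerjee framework:

- **Oxidative:** `J_ATP,ox = 2·(P/O)_oxphos·OCR_coupled + 2·(P/O)_TCA·OCR_mito`,
  with `OCR_coupled = basal − oligomycin` and `OCR_mito = basal − rot/antiA`
  (and the FCCP phase for maximal rates).
- **Glycolytic:** ECAR becomes a proton efflux rate `PPR = ECAR/BF`; the
  respiratory contribution `OCR_mito · (H+/O2)_max · 10^(pH−pK1)/(1+10^(pH−pK1))`
  is subtracted; the remainder maps onto lactate export plus a
  pyruvate-oxidation credit:
  `J_ATP,glyc = PPR_glyc·(ATP/lactate) + 2·(P/O)_glyc·OCR_mito`.

Defaults (`AssayConfig`) are the XF DMEM / glucose values: pH 7.4,
pK1 6.093 at 37 °C, buffering factor 0.1 mpH/pmol H+, P/O 2.486 / 0.121 /
0.167.  Every constant is overridable.  See `docs/methods.md` for the full
derivation, the replicate-statistics model and the design choices.

## Worked example

Simulate a two-plate experiment (two cell lines, Mito + Glyco Stress Tests,
four wells each, with well and plate noise), then run the full pipeline:

```python
import xflux as xf
from xflux.fixtures import write_experiment

spec = xf.default_fixture_spec(n_plates=2, well_count=4,
                               noise_sd_well=4.0, noise_sd_plate=6.0, seed=1)
write_experiment(spec, "plates/")          # Wave-dialect .xlsx files

table   = xf.read_data("plates/")          # merged long-format RateTable
scheme  = xf.default_scheme(table.n_measurements)
states  = xf.partition_data(table, scheme) # per-well state-level OCR/ECAR
result  = xf.get_energetics(states, xf.AssayConfig())
summary = xf.get_energetics_summary(result, level=0.95)
print(summary.round(2).to_string(index=False))
```

```
exp_group       quantity    mean    sd  ci_low  ci_high  n_wells  n_plates  level    method
  Group_1   atp_basal_ox  375.99 12.52  303.39   448.59        8         2   0.95 lmm_inter
  Group_1     atp_max_ox  796.07 10.07  750.83   841.32        8         2   0.95 lmm_inter
  Group_1 atp_basal_glyc  456.69 17.65  377.42   535.97        8         2   0.95 lmm_inter
  Group_1   atp_max_glyc  949.24 46.64  739.70  1158.78        8         2   0.95 lmm_inter
  Group_2   atp_basal_ox  215.22 17.70   60.99   369.44        8         2   0.95 lmm_inter
  Group_2     atp_max_ox  386.08 17.02  286.37   485.80        8         2   0.95 lmm_inter
  Group_2 atp_basal_glyc  779.83 27.64  579.27   980.39        8         2   0.95 lmm_inter
  Group_2   atp_max_glyc 1447.10 16.91 1371.14  1523.05        8         2   0.95 lmm_inter
```

Each row is one experimental group × JATP quantity in pmol ATP/min: Group_1
is OXPHOS-leaning (basal oxidative JATP ≈ 376, which doubles under FCCP),
Group_2 glycolysis-leaning (basal glycolytic JATP ≈ 780, rising to ≈ 1447
under monensin).  Because two plates are present, each summary comes from a
random-intercept mixed model (`lmm_inter`): the mean is the fixed
intercept, the SD is the total SD across plates and wells, and the 95% CI
uses plate-level degrees of freedom — which is why Group_2's basal
oxidative CI is wide despite eight wells.

Plots are one call each and return both the figure and the exact table
plotted:

```python
xf.rate_plot(table, "ocr", variance="sd", scheme=scheme).save("out/rate_ocr")
xf.bioscope_plot(summary).save("out/bioscope")
xf.atp_plot(summary).save("out/atp")
```

The same workflow runs from the shell:

```sh
xflux simulate --spec spec.yaml --out plates/
xflux run --input plates/ --out results/ --variance ci --level 0.95
```

`run` writes the merged rates, partitioned states, per-well energetics,
group summaries, plot data and images, a QC report (dropped background
wells, missing states, negative-rate flags) and the fully-resolved
configuration.

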