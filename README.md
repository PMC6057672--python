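# coccomorph

Coccolith morphometry and calcification ecology for *Emiliania huxleyi*,
the dominant calcifying phytoplankton of the modern ocean.

Field studies of coccolithophore calcification measure thousands of
individual coccoliths (the single calcite plates shed by each cell) on
cross-polarized light micrographs: below the first-order birefringence
plateau (~1.55 µm of calcite), grey level is proportional to calcite
thickness, so a calibrated image yields the mass of every plate. This
package implements that workflow end to end for people who study
coccolithophore calcification along environmental gradients — and, because
field micrographs are rarely shareable, it ships a synthetic generator
that renders ground-truth coccoliths into realistic polarized-light
rasters and lays them out along a virtual west–east basin transect, so
every stage of the pipeline is benchmarked against known truth.

## The quantities at the core

For each sample (station × depth):

- **M_s** — mean coccolith mass (pg), from background-subtracted grey
  summed over each segmented particle:
  `m = Σ (grey − bg)/gain · px² · ρ_c`, with ρ_c = 2.7 pg µm⁻³ the
  density of calcite.
- **L_c** — mean corrected length (µm). The bright tube of the coccolith
  dominates the birefringence image, so the segmented length
  underestimates the true distal shield length; a cross-instrument OLS
  calibration against SEM lengths corrects it. The published Type A
  coefficients `L_c = 0.585·L_apparent + 0.4537` ship as the fallback
  model; refitting on paired measurements is the default workflow.
- **C_i** — calcification index, the size-normalized calcification
  degree: `C_i = M_s / M_n` with `M_n = k_s · L_c³ · ρ_c` and
  k_s = 0.02 the shape constant of normally calcified Type A coccoliths.
- **Calcification varieties** — each Type A coccolith is assigned to
  A1 (slit length SL > tube width TW, low-calcified), A2 (SL ≈ TW),
  A3b (SL < TW, high-calcified) or A3a (central area nearly/completely
  closed, which takes precedence over the SL/TW rule); the four
  percentages of the Type A total sum to 100 by construction.
- **Ecology statistics** — tie-corrected Spearman rank correlations
  (exact permutation p for n ≤ 9, t approximation above) and canonical
  correspondence analysis (CCA) relating variety abundances to
  temperature, salinity, carbonate chemistry, nutrients and light.

## Worked example

```python
import coccomorph as cm

# the calcification index of two published province averages
cm.calcification_index(4.76, 3.45)   # -> 2.1466  (heavily calcified east)
cm.calcification_index(3.77, 3.25)   # -> 2.0337  (Atlantic inflow)

# the shipped length correction
cm.LengthCalibration.published().correct(3.0)   # -> 2.2087 µm

# a full synthetic study: 6 stations x 2 depths, one seed
config = cm.TransectConfig(n_stations=6, depths=(5.0, 100.0),
                           coccoliths_per_sample=100, seed=7)
result = cm.run_pipeline(config)
print(result.summaries[["station", "depth_m", "M_s_pg", "L_c_um",
                        "C_i", "A1_pct", "A3b_pct"]].round(2))
```

prints (stations run west → east):

```
 station  depth_m  M_s_pg  L_c_um  C_i  A1_pct  A3b_pct
       1      5.0    1.95    2.93 1.44   53.06     0.00
       1    100.0    2.70    3.04 1.78   28.89     0.00
       ...
       6      5.0    3.73    3.21 2.09    7.00    14.00
       6    100.0    3.89    3.19 2.22    0.00    36.00
```

Mean mass, corrected length and calcification index all increase
eastward while the low-calcified A1 variety gives way to the large,
heavily calcified A3b — the generator's configured niche structure,
recovered by measurement. The accompanying Spearman battery finds
A3b% vs salinity at ρ = 0.92 (p ≤ 0.01) and the CCA puts 73.5% of the
constrained inertia on axis 1.

The command line mirrors the workflow:

```
coccomorph simulate --seed 1 --stations 8 --out sim/
coccomorph measure-plm --image sim/st01_d005_f0.tif --optics sim/optics.yaml --out particles.csv
coccomorph all --seed 1 --stations 8 --out results/
```

## Layout

- `coccomorph.shapes` / `render` / `transect` — synthetic ground truth:
  parametric coccolith geometry with analytic mass, polarized-light
  rendering (linear grey↔thickness with saturation), environmental
  gradients and Gaussian niche responses.
- `coccomorph.imaging` — segmentation (Otsu or fixed threshold,
  intact/isolated filters) and per-particle mass/length measurement;
  SEM-style shape descriptors.
- `coccomorph.calibration` / `metrics` — the `LengthCalibration`
  estimator and the calcification index.
- `coccomorph.classify` — `VarietyClassifier` and variety bookkeeping.
- `coccomorph.stats` — Spearman battery and
  `CanonicalCorrespondenceAnalysis`.
- `coccomorph.pipeline` — the end-to-end seeded study; `coccomorph.cli`
  the command-line front end.
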