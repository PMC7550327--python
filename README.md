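# glycoscreen

Analysis pipeline for multiparameter genome-wide siRNA screens that read out
**cell viability** and **glycolysis** in melanoma cells under BRAF-inhibitor
treatment — from raw per-well plate measurements (nuclei counts, lactate-assay
absorbances) to normalized metrics, plate-level QC gates, bin-based hit
classification, drug-enhancer calls, expression triage and duplex-level
deconvolution validation.

It is written for screen informaticians and computational biologists who need
a tested, reusable implementation of this analysis — including a forward
simulator that generates screens with planted gene effects, so every stage can
be validated end to end without access to screening data.

## The screen design

Cells are seeded in 384-well plates (450 cells/well), transfected with an
arrayed siRNA SMARTpool library, and split into three arms with duplicate
plates each: a pre-treatment arm fixed at treatment start (**T0** count), a
vehicle arm (0.1% DMSO) and a drug arm (vemurafenib at its IC25), both read
out 48 h later (**T48** count plus media lactate). Controls sit in columns 2
and 23 of every plate — 16 non-targeting (siOTP-NT) wells, 8 PLK1 kill
controls, 8 PDK1 lactate controls — and column 24 holds media-only wells for
the lactate background.

## The statistics at the core

For each well, parameter and arm:

- **Lactate per cell** — media absorbance at 490 nm is converted through a
  linear standard curve `A = a + b·C` fitted to a 0–3.2 mM ladder; the
  plate's media-only column is subtracted as background, the 1:3 media
  dilution is corrected, and the concentration is divided by the same well's
  T48 count. Wells in the low-cell regime (T48 FC < 0.2) are excluded.
- **Fold change (FC)** — every value is normalized to the mean of the 16
  non-targeting wells on the same plate, so plate effects cancel.
- **deltaT** = T48 − T0, the change in cell number over treatment; negative
  values mean net cell death. Normalized per plate, averaged over replicates.
- **Robust Z** = (x − median) / (1.4826·MAD) over the library-gene
  population, per parameter and arm. Viability hits: Z < −1.5 (control-arm
  deltaT). Glycolysis hits: Z < −1.66 (control-arm lactate/cell), after
  low-cell filtering.
- **Severity bins** — viability `Hi → CV1 → CV2 → CV3 → LC` and lactate
  `LAC1 → … → LAC5` partition the FC axis. A **drug enhancer** is a gene
  whose drug-arm bin is ≥ 2 severity levels beyond its control-arm bin
  (equivalently, the enumerated pair table `cHi+dCV2/dCV3/dLC`,
  `cCV1+dCV3/dLC`, `cCV2+dLC`, and the LAC analogue).
- **QC** — replicate Pearson correlation on raw values; a plate fails when
  any control CV exceeds 30%; Z' = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|; SSMD on log2 FC.
- **Deconvolution** — each candidate SMARTpool's 4 duplexes are screened
  individually; a gene validates when ≥ 2/4 duplexes reproduce its primary
  bin, or — for glycolysis enhancers under assay-gain drift — fall below the
  NT-derived drug/control lactate ratio threshold (mean − 2·SD of NT ratios).

## Worked example

```python
import glycoscreen as gs

cfg = gs.SimulationConfig(n_genes=500)          # 2 library plates, 3 arms x 2 reps
sim = gs.simulate_screen(cfg, seed=7)           # measurements + planted truth
res = gs.analyze_primary(sim.measurements, sim.standards)

print(f"standard curve: slope={res.curve.slope:.4f} AU/mM")
print(f"replicate Pearson (raw counts, control arm): {res.screen_qc['pearson_count_control']:.3f}")
print(f"mean Z' (PLK1 vs NT counts, control arm):    {res.screen_qc['zprime_count_control']:.2f}")
for name, h in res.hits.items():
    print(f"{name}: {len(h.post_triage)} genes")
```

prints

```
standard curve: slope=0.2511 AU/mM
replicate Pearson (raw counts, control arm): 0.975
mean Z' (PLK1 vs NT counts, control arm):    0.87
viability_hit: 36 genes
glycolysis_hit: 25 genes
viability_enhancer: 43 genes
glycolysis_enhancer: 19 genes
```

The fitted slope recovers the generator's 0.25 AU/mM; duplicate plates
correlate at 0.97 on raw counts; the PLK1/NT dynamic range gives a strong
Z'; and the caller reports the four hit lists (here 33 of the 36 called
viability hits are planted truth — the simulator's labels are in
`sim.truth.labels`, so sensitivity and FDR can be computed directly).

The same flow is available from the shell:

```bash
glycoscreen simulate --out sim --seed 7 --override simulation.n_genes=500
glycoscreen run-primary --config cfg.yaml --out results
glycoscreen qc-report sim/screen_table.csv sim/standards.csv
```

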