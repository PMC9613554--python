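# alkaquant

Targeted LC–MS/MS quantification of pyrrolizidine alkaloids (PA), their
*N*-oxides (PANO) and tropane alkaloids (TA) in cow's milk, as a tested,
reusable pipeline.

PA/PANO are genotoxic plant toxins that carry over from contaminated feed
into milk at trace levels (sub-µg/L), so surveillance methods need
multi-analyte scheduled-MRM acquisition, matrix-matched calibration and
carefully validated detection limits. This package implements the complete
computational side of such a method for a 58-analyte panel (30 PA, 26 PANO,
atropine and scopolamine):

* **Synthetic chromatogram generator** — exponentially-modified-Gaussian
  peaks in 120-s scheduled-MRM windows with per-analyte process recovery,
  matrix ion suppression, baseline noise and the sample-preparation
  concentration factor (3 mL milk → 0.5 mL extract, factor 2.727), so every
  downstream stage is testable with known ground truth and no instrument
  data.
* **Peak processing** — robust baseline (median/MAD), apex detection with a
  3σ acceptance gate and retention-time tie-breaking for co-eluting isomers,
  trapezoidal integration, and the chromatographic statistics
  *R*ₛ = 2(t₂−t₁)/(w_B1+w_B2), *T* = wₓ/2f (at 5% height) and S/N.
* **Calibration** — unweighted OLS through all standard injections plus the
  point of origin, strict 80 < x < 120% back-calculation checks, Mandel's
  *F*-test linear-range delimitation, and the matrix effect
  SE = (1 − m_milk/m_solvent)·100%.
* **Detection limits** — the DIN 32645 calibration-curve procedure
  (α = 1%, k = 3, i.e. 33.3% uncertainty at the LOQ) on two low-level grids
  (0.01–0.12 and 0.2–1.2 ng/mL), with the analyte LOD taken from the less
  sensitive transition and the LOQ from the quantifier.
* **Quantification and reporting** — identity confirmation by retention time
  (±0.10 min) and ion ratio (±20%, relative) in duplicate injections,
  LOD/LOQ-censored concentrations in milk units (never recovery-corrected),
  sum contents with <LOQ detections counted at 0.5×LOQ, recovery/RSD_r
  validation tables, and dietary exposure / margin-of-exposure arithmetic
  (BMDL₁₀ = 237 µg/kg bw/day).

## Worked example

```python
import alkaquant as aq

panel = aq.load_default_panel().subset(["Ec", "At", "Lc"])
model = aq.MatrixRecoveryModel.default()      # Per-analyte recovery/suppression

cal   = aq.generate_calibration_batch(panel, model=model, seed=21)
fits  = aq.calibrate_batch(cal, panel)
lims  = aq.limits_from_batch(aq.generate_limits_series(panel, model, seed=22), panel)
refs  = aq.reference_values(cal, panel)

# a milk sample spiked with 0.5 µg/L atropine, analysed in duplicate
dups = [aq.simulate_injection(panel, {"At": 0.5}, model, seed=31 + d,
                              injection_id=f"s_d{d}") for d in range(2)]
report = aq.quantify_sample(dups, fits, lims, refs, panel)
at = report["results"]["At"]
print(at.status, at.conc, report["sum_ugL"])
```

prints

```
quantified 0.491 0.491
```

— atropine is confirmed in both duplicates, back-calculated against the
matrix-matched standards to 0.491 µg/L (within the repeatability of a single
simulated duplicate at this level; no recovery correction is applied), and,
being the only detected analyte, sets the sample's sum content. Erucifoline
and lasiocarpine come back `not_detected`.

The same stages are scriptable from the shell:

```bash
alkaquant simulate --design calibration --seed 7 --out traces.csv
alkaquant run --config manifest.yaml --out reports/
```

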