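# stonebeam

Plane-wave ultrasound simulation, spatial-coherence beamforming, and
kidney-stone shadow metrics.

Conventional B-mode ultrasound tends to over- or under-estimate kidney-stone
size, and the posterior acoustic shadow — often a better proxy for stone size
than the bright stone echo itself — can be faint at tissue depths.
`stonebeam` provides a self-contained synthetic test bed for comparing
beamforming strategies on this problem. It simulates raw plane-wave channel
data for speckle phantoms containing a rough, strongly reflecting stone and
its acoustic shadow, reconstructs images with four beamformers, and measures
stone contrast, contrast-to-noise ratio, speckle SNR, automated −6 dB stone
sizing, and blinded, segmentation-based shadow detection and width:

- **B-mode** — fixed-receive-focus delay-and-sum (the clinical baseline),
- **PWSF** — plane-wave synthetic focusing (dynamic receive focus, coherent
  angle compounding),
- **SLSC** — short-lag spatial coherence,
- **MLSC** — mid-lag spatial coherence, which suppresses diffuse speckle and
  raises stone contrast at the cost of erasing the shadow.

A statistics layer runs cohorts of phantoms and produces paired,
Bonferroni-corrected method comparisons. See `docs/methods.md` for the
models, their assumptions, and their limitations.

## Worked example

Simulate one 10 mm stone phantom at the study operating point, beamform it
with all four methods, and print the measurements:

```python
import stonebeam as sb

res = sb.run_phantom(width_mm=10.0, seed=1)

for rec in res.records:
    meas = res.shadow_measurements[rec.method]
    shadow = f"{meas.width_mm:.1f} mm" if meas.detected else "not detected"
    print(f"{rec.method:>5}: stone contrast {rec.contrast_dB:6.1f} dB, "
          f"CNR {rec.cnr_dB:5.1f} dB, SNR {rec.snr:5.2f}, "
          f"stone width {rec.measured_size_mm:5.1f} mm, shadow {shadow}")
```

Output:

```
bmode: stone contrast   16.7 dB, CNR   1.8 dB, SNR 10.87, stone width   9.8 mm, shadow 2.3 mm
 pwsf: stone contrast   27.2 dB, CNR   4.3 dB, SNR 39.78, stone width   9.7 mm, shadow 10.0 mm
 slsc: stone contrast   31.5 dB, CNR  24.0 dB, SNR 82.00, stone width  10.4 mm, shadow 11.4 mm
 mlsc: stone contrast   20.8 dB, CNR   0.8 dB, SNR 14.56, stone width   9.5 mm, shadow not detected
```

The pattern above is the study's central finding in miniature: every method
raises stone contrast over fixed-focus B-mode, but MLSC erases the posterior
shadow entirely, while the coherence and synthetic-focusing images keep it —
PWSF recovers the 10 mm shadow width exactly here, where B-mode's weak
shadow is badly undersized.

Cohort-level statistics:

```python
cohort = sb.run_cohort(seed=1)                 # 10 phantoms, widths 2-18 mm
tables = sb.cohort_tables(cohort)              # paired tests vs B-mode
print(tables["shadow"][["method", "delta_mean", "p", "alpha_adjusted"]])
print(tables["detection"])
```

## Command line

The same pipeline is scriptable via an INI file:

```ini
[study]
seed = 1
widths_mm = 5, 10
methods = bmode, pwsf, slsc, mlsc
```

```sh
stonebeam run-all --config study.ini --out results/
# or stage by stage:
stonebeam simulate --config study.ini --out results/   # HDF5 channel data
stonebeam beamform --config study.ini --out results/   # TIFF + PNG images
stonebeam measure  --config study.ini --out results/   # metrics CSV
stonebeam report   --config study.ini --out results/   # comparison CSVs
```

## Reproduction

- **Test suite** (unit, property and acceptance tests):

  ```sh
  python -m pytest -q tests/
  ```

- **Acceptance report** — recomputes the study's checkable quantities
  (pilot-cohort summary, Bonferroni thresholds, Rayleigh speckle statistics,
  van Cittert–Zernike coherence check, brute-force oracle equivalence,
  cohort direction-of-effect numbers, shadow-width recovery error, and the
  statistical core) and writes them to JSON:

  ```sh
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```

All simulations are deterministic given the seed; the cohort and acceptance
runs take a few minutes each on a single core.
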