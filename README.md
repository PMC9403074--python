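# aortaref

Z-score reference charts for the fetal ascending aorta: systolic diameter
(Dmax), diastolic diameter (Dmin), and diameter distensibility
DD = (Dmax − Dmin)/Dmin, conditioned on gestational age (GA), biparietal
diameter (BPD), or femur length (FL).

Fetal echocardiography increasingly reports vessel dimensions as z-scores
rather than raw millimetres, because both the expected size and its spread
change with gestation. Diameter distensibility — the relative
systolic–diastolic expansion of the aortic wall at the sinotubular
junction — is a blood-pressure-free surrogate for arterial elasticity and
*decreases* through gestation as the aortic wall matures, while the
diameters themselves grow. This package is for clinicians and researchers
who want to (a) score fetal measurements against published reference
equations, or (b) build such charts from their own cohorts.

## The model

Each chart is a pair of regressions in one predictor `x`:

```
mean:  μ(x) = Σ βk · x^k          (polynomial, degree ≤ 3)
SD:    σ(x) = a + b·x             (linear, strictly positive on the chart range)
z-score: z = (y − μ(x)) / σ(x)
```

Construction is the classical three-step procedure for heteroscedastic
reference intervals: (1) select the best polynomial mean model by adjusted
R²; (2) regress the residual SD on the predictor (per-week/per-5-mm bin
SDs, weighted by bin count, or absolute residuals with the half-normal
correction √(π/2)); (3) standardise every observation. |z| > 1.65 flags
the outer 10% of the reference population; percentile curves are
μ(x) + Φ⁻¹(p)·σ(x).

The package ships the published coefficient registry (9 mean + 9 SD
models). Three printed entries are typographically corrupt; they are
retained verbatim and accompanied by sanitized corrections (see
`aortaref/registry.py` and `docs/methods.md`), with sanitized as the
scoring default.

## Worked example

Score a 24-week fetus measuring Dmax 3.80 mm, Dmin 2.80 mm:

```python
import aortaref as ar

reg = ar.published_registry("sanitized")
rec = ar.BiometryRecord(ga=24.0, dmax=3.80, dmin=2.80)
for resp in ("Dmax", "Dmin", "DD"):
    r = ar.score_record(rec, resp, "GA", reg)
    print(f"{resp}: observed={r.observed:.4g} mean={r.predicted_mean:.4g} "
          f"sd={r.predicted_sd:.4g} z={r.z:+.2f} {r.band_flag}")
```

prints

```
Dmax: observed=3.8 mean=3.457 sd=0.397 z=+0.86 within_90
Dmin: observed=2.8 mean=2.614 sd=0.347 z=+0.54 within_90
DD: observed=0.3571 mean=0.3219 sd=0.0788 z=+0.45 within_90
```

i.e. all three measurements sit well inside the central 90% reference
band (distensibility 0.45 SD above the gestational mean). The matching
Dmax percentile lines at 24 weeks are 2.804 / 3.457 / 4.110 mm
(5th/50th/95th). The same operations are available from the shell:

```bash
aortaref simulate --n 490 --seed 7 --out cohort.csv
aortaref fit --input cohort.csv --response DD --predictor GA \
             --chart-out dd_ga.json --scored-out scored.csv
aortaref diagnose --input scored.csv --z-column z_DD_GA \
                  --x-column ga_weeks --out report.json
```

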