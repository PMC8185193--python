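# rtmeno

Ovarian dosimetry and fertility-horizon analysis for consolidation
radiotherapy in Hodgkin lymphoma.

When lymphoma below the diaphragm is irradiated, the ovaries receive dose
even when they are outside the target volume, depleting the resting
(non-growing) follicle pool and pulling menopause forward. Shrinking the
target from *involved-field* (IFRT) to *involved-site* (ISRT) radiotherapy
lowers that dose. This package quantifies what the smaller target buys a
patient, for radiation oncologists and trial statisticians working with
paired treatment plans:

- **DVH handling** — read, validate, convert (differential ↔ cumulative),
  rebin and merge dose-volume histograms from planning-system CSV exports
  (`rtmeno.dvh`).
- **Follicle survival** — the log-linear survival curve of the non-growing
  follicle (NGF) pool, log₁₀ *g*(*z*) = 2 − 0.15 *z* (*z* in Gy, *g* in %),
  averaged over the both-ovaries DVH in 0.1 Gy bins:
  *g* = Σᵢ 10^(2 − 0.15·½(dᵢ+dᵢ₊₁)) · vᵢ / v_total (`rtmeno.follicle`).
- **Menopause prediction** — the age-dependent NGF reserve
  log₁₀ *n* = −0.00019·age^2.452 + 5.717, its closed-form inversion to an
  *effective reproductive age*, and the predicted time to premature
  menopause *t* = max(0, 50.4 − r) (`rtmeno.menopause`).
- **Paired comparison** — per-organ dose summaries, surviving-NGF and
  per-age time-to-menopause tables with the exact two-sided sign test
  (`rtmeno.compare`).
- **Hormone regression** — ln FSH / ln LH on age(z), sex, age×sex,
  chemotherapy regimen and RT field location, with group summaries and
  prediction surfaces (`rtmeno.hormones`).
- **Synthetic cohorts** — seeded generators for paired-plan DVH cohorts and
  hormone cohorts with the statistical structure the analysis assumes
  (`rtmeno.simulate`), so the full pipeline runs without patient data.

## Worked example

```python
import rtmeno as rt

# 13 synthetic patients, each planned both ways (seeded, reproducible)
pairs = rt.simulate_paired_dvh_cohort(rt.DvhSimConfig(n_patients=13, seed=0))

ngf = rt.surviving_ngf_summary(pairs)
print(f"surviving NGF: IFRT {ngf.mean_ifrt:.1f}%  ISRT {ngf.mean_isrt:.1f}%  "
      f"p={ngf.test.p_two_sided:.6f}")

row18 = rt.compare_menopause(pairs)[0]
print(f"age 18: time gain {row18.mean_diff:.2f} y, p={row18.test.p_two_sided:.6f}")

print(f"LD50 = {rt.ld50():.3f} Gy")
print(f"t(18 y, g=11.87%) = {rt.time_to_menopause(18, 11.87).time_to_menopause:.2f} y")
```

prints

```
surviving NGF: IFRT 31.2%  ISRT 49.5%  p=0.000244
age 18: time gain 3.81 y, p=0.000244
LD50 = 2.007 Gy
t(18 y, g=11.87%) = 15.50 y
```

Reading: in every one of the 13 simulated patients the smaller ISRT target
delivers a lower ovarian dose, so the surviving fraction of the follicle
pool is higher and a woman treated at 18 keeps ≈ 3.8 extra years before
predicted menopause; with 13 unanimous paired differences the exact sign
test gives p = 2·(½)¹³ ≈ 0.000244. The survival curve's median lethal dose
is ≈ 2.0 Gy, and an 18-year-old retaining 11.87 % of her reserve has
≈ 15.5 years left to predicted menopause.

The same analyses are available from the shell:

```sh
rtmeno simulate dvh --n 13 --seed 0 --out dvh.csv
rtmeno compare-oar --dvh dvh.csv --out oar.csv
rtmeno compare-menopause --dvh dvh.csv --out menopause.csv
rtmeno report --seed 0 --out report/
```

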