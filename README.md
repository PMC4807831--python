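# petwashout

Simulation and analysis of carbon-11 point-source **biological washout** in
dynamic PET, aimed at hadron-therapy dose-monitoring studies.

PET verification of carbon-ion treatments images the β⁺ activity the beam
induces in tissue, but the signal is degraded by biological clearance
("washout") of the radionuclides. One way to measure washout without a beam is
to inject a ~1 µL deposit of a ¹¹C compound directly into the tissue of
interest and follow it with a dynamic acquisition on a high-resolution
preclinical scanner, once in the living animal and once after sacrifice. This
package provides that whole experiment *in silico* — a seeded synthetic
scanner — plus the analysis chain used on the real images, so that the
estimators can be validated by parameter recovery and applied to real
time-activity curves.

## Model

The measured activity of the deposit factorises into physics and biology,

```
A_meas(t) = A0 · C_bio(t) · A_phys(t),        A_phys(t) = exp(−λ_phys t)
```

and after decay correction the biological part is split into two single
exponentials:

```
alive:  C_bio(t) = C_tiss(t) · C_wash(t) = exp(−λ_tiss t) · exp(−λ_wash t)
dead:   C_bio(t) = C_tiss(t)             = exp(−λ_tiss t)
```

* **tissular component** (λ_tiss): passive, concentration-gradient-driven
  diffusion — the only channel left in dead tissue;
* **washout component** (λ_wash): perfusion-driven clearance, present only in
  living tissue.

Fitting the dead acquisition gives λ̂_tiss; fitting the alive one gives the sum
λ̂_tiss + λ̂_wash, and the decomposition returns λ̂_wash by subtraction.
Half-lives are T½ = ln2/λ. The classical three-exponential
(fast/medium/slow) washout mixture is also implemented, both as a forward
model and as a constrained fit.

## Worked example

```python
import petwashout as pw

iso, prot = pw.IsotopeSpec.c11(), pw.AcquisitionProtocol.default()
scanner, inj = pw.ScannerModel(), pw.InjectionSpec()
params = pw.TwoComponentParams.from_halflives(0.9e6, 2878.0, 330.0)  # brain

fits = {}
for cond in pw.Condition:
    activity = pw.frame_average_activity(params, cond, iso, prot)
    series = pw.render_frames(activity, scanner, inj, prot, noise=True, seed=42)
    roi = pw.select_roi(series)                      # >50% of first-frame max
    tac = pw.extract_tac(series, roi, isotope=iso, decay_correct=True)
    fits[cond] = pw.fit_single_exponential(tac)

dec = pw.decompose(fits[pw.Condition.ALIVE], fits[pw.Condition.DEAD])
print(dec.summary())
```

prints

```
Alive/dead washout decomposition (mode: subtraction)
========================================================
component       lambda [1/s]   half-life [s]
tissular         0.000240996         2876.18
alive total       0.00234463         295.632
washout           0.00210363           329.5
```

i.e. from a Poisson-noisy simulated pair generated with a tissular half-life
of 2878 s and a washout half-life of 330 s, the pipeline recovers 2876.2 s and
329.5 s. The alive curve decays with the *sum* of the two rates (combined
half-life ≈ 296 s).

A full multi-animal study (volumes, masks, TAC CSVs, per-animal fits, group
mean ± SD tables, plots, manifest) runs from the command line:

```
petwashout run --seed 1 --output-dir results_run
petwashout report --results results_run
```

`simulate`, `extract` and `fit` expose the individual stages; a YAML config
(see `PipelineConfig`) controls scanner, injection, protocol, study design and
fit options.

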