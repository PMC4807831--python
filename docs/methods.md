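# Methods

## The measurement being emulated

A point-like deposit (~1 µL) of a ¹¹C compound is injected directly into the
tissue of interest and followed by a dynamic acquisition on a high-resolution
preclinical PET scanner, started simultaneously with the injection. The same
measurement is performed in the living animal and again after sacrifice.
Because dead tissue has no perfusion, the dead-condition decay isolates the
tissular (passive diffusion) component; the alive-condition decay carries both
components, and the washout (perfusion) component follows by comparing the
two.

## Kinetic model

Measured activity factorises as `A_meas(t) = A0 · C_bio(t) · A_phys(t)` with
`A_phys(t) = exp(−λ_phys t)`. The ¹¹C physical half-life is fixed at
1223.4 s (20.39 min, standard nuclear data) and overridable through
`IsotopeSpec`, so other emitters (¹⁵O, ¹⁰C, ¹⁸F) can be modelled. Both
biological components are single exponentials:

* alive: `C_bio = exp(−(λ_tiss + λ_wash) t)`
* dead: `C_bio = exp(−λ_tiss t)`

λ = 0 is a valid parameter (no washout) whose half-life is reported as
infinite, making dead-condition curves a parameter subset of alive ones. The
three-exponential fast/medium/slow mixture is provided as an alternative
`C_bio` for forward evaluation and constrained fitting; the two-component
model is the default because a single biological exponential describes this
kind of data adequately and keeps the alive/dead decomposition identifiable
with 25 frames.

## Synthetic acquisitions

`ScannerModel` defaults emulate a high-resolution small-animal system:
1.5 mm PSF FWHM, 10% point-source sensitivity, 0.5 mm isotropic voxels on a
33³ grid (a 16.5 mm cube around the deposit; the analysis is source-local, so
simulating the whole field of view would only add empty voxels).
`AcquisitionProtocol.default()` is the 25-frame sequence 10×30 s, 5×60 s,
10×300 s (3600 s total). `InjectionSpec` defaults: activity drawn from
0.7–1.1 MBq (nominal 0.9 MBq), intrinsic source spread σ = 0.6 mm.

The deposit is rendered as a 3D Gaussian with variance σ_source² + σ_PSF²,
integrated exactly over each voxel (products of error-function differences)
and normalised to unit mass on the grid, so noiseless activity conservation is
exact. Rendering errors out when more than 10⁻⁶ of the source mass would fall
outside the grid. Expected counts per voxel per frame are
`weight · frame_activity · sensitivity · duration`; Poisson mode replaces the
expectations with seeded draws. The σ_source = 0.6 mm default makes the
rendered point-source FWHM √(1.5² + (2.3548·0.6)²) ≈ 2.06 mm (measured
≈ 2.10 mm after voxel-integration broadening), consistent with a ~1 µL sphere
(radius 0.62 mm) and with the 2–3 mm blur band observed on real
reconstructions of such deposits.

Frame values are the *time-average* of the decaying activity over the frame
(closed-form integral of exponentials), not midpoint evaluations — that is
what a scanner histogramming counts into a frame records, and it removes a
systematic of order (λΔt)²/24 on the 300 s frames.

Inter-animal variability is lognormal on each λ (keeps positivity) with CV
0.1 by default; this is a plausibility knob, not a measured quantity — the
across-animal spreads in real data fold in fit uncertainty and physiology that
the generator does not model. Study simulation draws each animal's λ_tiss
once and shares it between the paired alive/dead acquisitions (the same
animal is scanned twice), while the injected activity is drawn per
acquisition. All randomness flows from one integer seed via spawned
generators; reruns are bit-identical.

## Image analysis

**ROI.** The manual region drawing used on real scans is replaced by its
stated rule: all voxels strictly above 50% of the first-frame maximum. The
strict inequality plus a threshold below 1 guarantees a non-empty mask
containing the argmax voxel; for a point source the above-threshold set and
its connected component coincide. The mask is propagated unchanged to all
frames.

**TAC.** The ROI statistic is the voxel *sum* (sum vs mean differ by a
constant and cannot affect half-lives; the choice is recorded in provenance).
Counts are converted to activity by dividing by sensitivity and frame
duration. Decay correction divides each frame by the frame-averaged physical
factor referenced to t = 0 = injection = acquisition start — exact for
histogrammed counts, and recorded (with λ_phys) in the TAC provenance.

**FWHM.** Measured on the 1D profiles through the peak voxel along each axis,
with linear interpolation at half maximum, averaged over axes; a peak on the
grid boundary is an error.

## Fitting

`ExponentialDecayModel` fits `A·exp(−λt)` by bounded nonlinear least squares
(scipy `least_squares`, trf), initialised from the log-linear regression
slope of the positive samples; standard errors come from the local curvature
(Gauss–Newton covariance) with the usual residual-variance scaling. The model
predicts *frame-averaged* values whenever the TAC carries frame durations,
and — the one subtle numerical choice — when the TAC was decay-corrected with
frame-averaged factors the model predicts

```
A · favg(exp(−(λ+λ_phys)t)) / favg(exp(−λ_phys t))
```

per frame, i.e. it reproduces the correction rather than pretending the
corrected data are a clean exponential. The naive model differs by a
multiplicative tilt ≈ λ·λ_phys·Δt²/12 (≈0.1% on 300 s frames for tissular
rates, ~1% for alive-condition rates), which would consume most of a
sub-percent recovery budget; the consistent model recovers noiseless
generative constants to optimizer precision. A fitted λ whose total decay
over the window is below 10⁻¹² is reported as exactly 0 (infinite half-life)
rather than a denormal-scale artifact. Unweighted least squares is the
default; optional Poisson (inverse-variance) weighting is available since the
original analyses do not state a weighting scheme. A fit window `(t_min,
t_max)` restricts the frames used — the documented recipe for dead tumor
acquisitions, which show a pressure re-equilibration transient around 500 s,
is `t_min = 600 s`.

`MultiExponentialModel` (up to three components) uses variable projection:
the outer optimiser works on log-λ, the amplitudes are solved by non-negative
least squares at every step, and renormalising the amplitudes into an overall
A0 times simplex fractions makes the fraction-sum-to-1 constraint exact by
construction. λs are reported fast ≥ medium ≥ slow; near-identical components
are merged with fractions summed and flagged, and the smallest λ ratio is
returned as an identifiability diagnostic. A deterministic multi-start (decade
spreads around the log-linear slope) guards against local minima. With one
component the problem is the same least-squares problem as the single
exponential and is delegated to it.

`AliveDeadDecomposition` defaults to **subtraction** mode,
λ̂_wash = λ̂_alive − λ̂_dead, which is the reading consistent with the alive
curve being the *product* of the two exponentials; **direct** mode
(λ̂_wash = λ̂_alive) is provided because descriptions of such analyses are
sometimes read that way. λ̂_alive ≤ λ̂_dead yields a result flagged "no
detectable washout" with infinite half-life, not an exception. Group
summaries are arithmetic mean ± sample SD (n−1) of per-animal half-lives,
with SD = 0 by convention for n = 1.

## Tissue presets

Generative mean half-lives (seconds), stored in `presets.py` and used as
ground truth in recovery experiments: brain 2878 (tissular) / 330 (washout);
muscle 2132 / 361; tumor 2019 / 621; necrotic tumor washout 613 and active
tumor washout 418 (both with the tumor tissular component). These are
literature-derived means for ¹¹C carbonate in rat tissue, not quantities this
package measures.

## What passing tests do and do not show

The recovery experiments demonstrate that the estimator chain is consistent
and essentially unbiased *under the generator's assumptions*: a stationary
Gaussian source, ideal attenuation/scatter/normalisation corrections, pure
Poisson counting noise, mono-exponential biology. They do not validate those
assumptions against real tissue — real TACs can carry reconstruction
correlations, motion, the tumor pressure transient, and multi-exponential
behaviour the single-exponential fit would average over. Problem sizes were
chosen so the full suite runs in seconds: a 33³ half-millimetre grid around
the source, 25 frames, 20 Poisson replicates for the stochastic check — at
2.7×10⁶ first-frame counts the Poisson relative error is ~0.06%, so 20
replicates pin the mean recovery to well under a percent.

## Known limitations

No tomographic reconstruction, attenuation, scatter or randoms modelling; no
motion or partial-volume correction; no blood input function or compartmental
modelling (the source is local by design); no hierarchical across-animal
estimation — each animal is fitted independently and summarised.
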