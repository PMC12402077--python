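# Methods

This note documents the models, estimators, and numerical choices behind
`stellatrack`, and what the synthetic-data studies do and do not show.

## Synthetic movie model (`simcilia`)

**Geometry.** A scene holds near-straight stereocilium axes (polylines,
base → tip, tips pointing up) in a single focal plane, plus an apical
cell-body band at the base. Default pixel size is 0.1625 µm (a 6.5-µm
sCMOS pixel behind a 40× objective); vestibular stereocilia are straight
and up to ~10 µm long, which sets the default length range. There is no
z-dimension: the emulated acquisitions are single-plane.

**Motion regimes.** Molecules follow one of four kinetic models:

- *diffusive* — visible for a geometric number of frames at a random
  axial position, with per-frame survival p = 2^(−1/T½). A freely
  diffusing molecule traverses the excitation volume far faster than the
  100-ms exposure, so what the camera records is exactly this: a punctum
  that exists for one or a few frames and vanishes. Explicit Brownian
  motion is deliberately not simulated.
- *stationary* — fixed axial position, visible until photobleaching
  (geometric, survival 2^(−1/T½_bleach); default 61 frames, the measured
  photobleaching half-life of the dye).
- *processive* — per-molecule speed ~ Normal(mean, sd) truncated positive
  and run length ~ Normal(mean, sd) truncated positive; the molecule
  advances speed·Δt per frame until the run length is exhausted, the tip
  is reached, or it bleaches. Start frames and positions are staggered so
  the run fits in the movie and on the axis where possible; a run that
  cannot fit is truncated at the tip with a warning.
- *stepwise* — a pause-and-jump staircase: each frame an instantaneous
  jump of `step_size` occurs with probability q = 1 − 2^(−1/pause_half_life),
  giving exponential pauses and a net speed of q·step/Δt. Defaults
  (100 nm steps, 5-frame pauses) are package choices, recorded in the
  truth table; the kinetics of real staircases were not quantified in the
  source data.

**Photophysics and camera.** Each visible fluorophore emits a mean of
`photons_per_frame` photoelectrons (default 816, chosen so that one
fluorophore integrates to ≈408 ADU at the default gain of 2 e⁻/ADU — a
convenience calibration, not a measured value). Blinking is a two-state
Markov chain, off by default. Rendering places an in-focus Airy pattern
(the z = 0 Born & Wolf section; λ = 576 nm, NA = 0.8) at each emitter's
subpixel position, normalized to unit sum over its 21×21-px support so
photon totals are conserved exactly; applies Poisson shot noise to signal
plus background; adds Gaussian read noise; and converts to ADU
(`adu = e⁻/gain + offset`, quantized to uint16). Saturation is not
modeled.

**Background and the registration anchor.** Stereocilium shafts carry a
dim smooth diffuse rate; the apical band carries a much brighter
(default 25×) granular texture emulating the densely labeled cuticular
plate. This bright static structure matters: phase-only correlation
whitens the spectrum, so in a movie whose only content is a handful of
bright *moving* point sources, the correlation peaks at emitter-pair
displacement vectors and drift estimation fails. Real recordings are
dominated by static cell structure; the synthetic scenes must be too.

**Drift** is a per-frame (dy, dx) translation (cumulative Gaussian random
walk, default 0.05 px/frame) applied to emitter positions and the
background map.

## Drift correction (`registration`)

Two stages per frame pair:

1. **Phase-only correlation.** Normalized cross-power spectrum
   r = conj(F(ref))·F(mov)/|·|, inverse transformed; the integer peak is
   refined by a separable quadratic fit on its 3×3 neighborhood. A Hann
   window is applied by default (aperiodic live images); spectral bins
   below 10⁻¹² of the peak magnitude are zeroed. The peak search is
   bounded (default ±10 px in `estimate_drift`) because frame-to-frame
   stage drift is subpixel — this rejects the spurious emitter-pair peaks
   described above. The returned (dy, dx) is the content displacement of
   the moving image relative to the reference.
2. **Least-squares image matching.** Gauss–Newton minimization of
   Σ[ref(p) − mov(p+d)]² using cubic-spline resampling of the moving
   image and of its gradient fields. Linear interpolation is *not* used:
   the best linear blend of adjacent rows is systematically biased toward
   integer displacements (we measured a 40% underestimate of a 0.2-px
   shift), while the spline scheme is accurate to <10⁻³ px at every
   fractional offset. Divergence (residual increasing 3 iterations in a
   row) returns the initial estimate flagged unconverged.

`estimate_drift` chains frame-to-frame shifts cumulatively by default
(robust to slow content change such as bleaching, at the cost of
random-walk error accumulation — the drift-of-drift caveat); registering
everything to frame 0 is available. Correction resamples frame t at
p + d_t, filling exposed borders with the frame median.

## Puncta detection and photometry (`puncta`)

Detection is Laplacian-of-Gaussian at scale σ (default 1.3 px ≈ the Airy
core). A candidate local maximum is scored as
SNR = (LoG peak − local response median) / max(‖h‖₂·σ_raw, local response
MAD, frame response MAD), where ‖h‖₂ is the L2 norm of the
scale-normalized filter and σ_raw the robust pixel noise of a raw-image
annulus (MAD with IQR and quantization-floor fallbacks — pure-MAD
estimates collapse on quantized near-constant data). This is the noise
the matched filter actually sees, so blank frames produce essentially no
detections at the default threshold of 5 while bright diffuse regions do
not flood the detector. Maxima within 4σ (the Airy-ring zone) are merged
keeping the stronger; centers are refined by intensity-weighted centroid.
Measured localization noise at 2000 photons/frame is ~0.035 px (~6 nm).

Sum intensity integrates (pixel − background) over a circular aperture
(default radius 3 px); background is the median of a concentric annulus
(1.5–3× the aperture radius), robust to neighboring puncta. Absolute
photon recovery requires a wide aperture (the Airy rings hold ~10% of the
energy beyond 5 px); the default small aperture is the right choice for
*relative* photometry, which is what fluorophore counting needs.

Line profiles are sampled bilinearly at 1-px arclength steps (averaging
across the profile width), quadratically interpolated to a 0.1-px grid,
min-max normalized, aligned at their highest interior peak, and averaged;
the theoretical comparison curve is the in-focus Airy profile, and the
point-source verdict is an FWHM ratio within 1 ± 0.25 (FWHM by linear
interpolation of the half-maximum crossings).

## Fluorophore counting (`mixture`)

A k-component 1D Gaussian mixture fitted by EM: quantile-based
initialization (k quantile midpoints, pooled SD, equal weights), 10
jittered restarts, convergence at |Δ log-likelihood| < 10⁻⁸ per point or
500 iterations, components reported sorted by mean. The log-likelihood is
asserted non-decreasing at every step; a component collapsing onto a
single point aborts the restart. k is fixed at 3 by default (single
fluorophores, pairs, aggregates); a BIC scan is available as a diagnostic
report but is not used to choose k. Fitting is on the linear intensity
scale. The aggregate component is left free (its size and spread are not
constrained).

## Kymographs, tracking, and motion classification (`kymotrack`)

Kymographs sample each frame along the axis polyline at 1-px arclength
steps, taking the maximum across the line width; with nearest sampling
and a width of 1 along a pixel row the matrix reproduces the raw rows
bit-exactly. Linking is greedy nearest-neighbor with gap closing —
adequate at single-molecule labeling densities — and a CSV import path
accepts externally curated tracks in the same schema. Axial projection
maps each point to the arclength of its nearest polyline point; points
farther than 3 px from the axis are flagged and ignored by the
classifier.

The classifier implements the operational directionality rule:

- Per-interval displacement rates below `min_step_um` count as pauses
  (default 0.05 µm; the validation studies use 0.03 µm ≈ 4–5× their
  measured localization noise).
- A run extends in one direction while the trajectory stays within
  `backtrack_um` (default 0.15 µm, just under one kymograph distance bin)
  of its running extremum; sub-pixel reversals are invisible on a
  kymogram and are treated as localization noise, while a genuine
  reversal terminates the run at the extremum.
- A run qualifies as directional when it spans ≥ `min_run_frames` frames
  (default 4, i.e. "more than three frames in the same direction"; the
  rule's boundary is ambiguous and the parameter is exposed).
- Run endpoints are the extremal positions: the *last* attainment of the
  least-advanced and the *first* attainment of the most-advanced position
  — from where motion begins to where it ends, the excursion one would
  mark on a kymogram. This keeps slowly accumulating sub-threshold
  displacement inside the run while trimming stationary plateaus at both
  ends; the convention is its own dual under time reversal with direction
  flip (property-tested), and a single instantaneous relocation followed
  by parking does not qualify as directional.
- Within a directional run, pause-frame fraction ≤ 0.25 → *processive*,
  else *stepwise*. The source data distinguish these visually; the
  threshold is a package decision and is configurable.
- Tracks with qualifying runs in both directions, or with above-threshold
  movement in both directions and no qualifying run, are
  *excluded-random*; everything else is *stationary*. Classification is
  invariant under time reversal combined with direction flip.

Velocity per run is the endpoint slope |Δs|/Δt (the line one draws on a
kymogram), reported in nm/s; run length is |Δs| in µm. Per-cell event
frequencies are directional events per observed frame, with cells
observed fewer than 500 frames flagged and excluded.

## Dwell kinetics (`kinetics`)

Dwell times are the lengths of contiguous detected spans (gaps split
spans). Survival is S(t) = #{d ≥ t}/N at integer frames t ≥ 1; the
geometric dwell model gives S(t) = p^(t−1) with p = 2^(−1/T½), so an
unweighted one-phase decay fit (Levenberg–Marquardt, K initialized from a
log-linear regression, free Y0, plateau fixed at 0) recovers T½ = ln2/K
exactly in expectation — including sub-frame half-lives, which arise
naturally when the continuous decay is fitted to discrete survival. The
plateau is fixed at 0 by default (all molecules eventually disappear);
the free-plateau variant is available.

**Confidence intervals.** The survival points are cumulative fractions of
the same molecules and hence strongly correlated; the asymptotic CI from
the curve-fit covariance covers the true half-life only ~26% of the time
in simulation (binomial-weighted fitting does not fix this). When the
underlying durations are available, `fit_dwell_survival` therefore
reports a percentile-bootstrap CI over dwell resamples (1000 resamples by
default, seeded), which calibrates at ~95% coverage. The asymptotic CI
remains on `fit_one_phase_decay` for curve-only input, with this caveat.

Group comparison of decays uses the extra-sum-of-squares F-test (shared
fit to pooled points vs per-group fits; Bonferroni-adjusted p), which
calibrates to its nominal type-I error on model-plus-iid-noise curves.
Cohort scalars are compared with Student's t, one-way ANOVA with post-hoc
Tukey HSD, or pairwise Fisher exact tests on counts (scipy
implementations behind the module interface).

## Validation studies (`studies`) and their scope

Each study generates data at measured cohort parameters and recovers the
summary statistic through the full pipeline. Problem sizes: 10,000 dwells
× 10 seeds per dwell regime; 100–150 processive walkers (2 per movie,
96×128 px, 200 frames at 1 s) for the dimer-motor cohort; 40–60 walkers
at 100-ms frames for the fast-motor cohorts; 40 stepwise walkers (step
250 nm, per-molecule jump probability set to the drawn net speed); 5,000
mixture draws; 1,500 rendered puncta (isolated by construction, as in
the original calibration of 76 isolated puncta) for counting. Cohort
sizes are chosen so the drawn-cohort mean's sampling error is small
against the few-percent agreement the studies are meant to demonstrate.

Cohort summaries are per molecule: when a linked track yields several
runs, only its longest enters the cohort — run-level averaging would
weight slow molecules by their longer visibility.

Known estimator properties, measured in development and accepted as is:

- The stepwise endpoint slope conditions on jumps at the run boundaries,
  inflating the net speed by ~1/(n_jumps−1); movies are long enough
  (~35–40 jumps) to keep this ≲3%.
- Cohort run length recovers ~4–8% low: the final partial-frame step and
  endpoint detection each lose a fraction of a step, and walkers whose
  runs do not fit the movie or axis are truncated.
- Very slow walkers (≲ 15 nm/s at 1-s frames) fall below the pause
  threshold and are classified stationary, exactly as they would escape a
  kymogram reading.

What these studies do **not** show: performance on real recordings with
stereocilium motion, heterogeneous background, out-of-focus light, or
labeling density violations; the generator's molecules move strictly
along the axis, its PSF is the in-focus section only, and its background
texture is stationary. Passing studies demonstrate that the estimators
recover known inputs under the stated imaging model, not that the model
captures every property of live tissue.

## Degenerate inputs and tie-breaks

All-constant images raise an undefined-shift error in registration;
NaN drift estimates are interpolated over. Identical intensities abort
the mixture fit after all restarts degenerate. Zero separate-fit residual
in the F-test yields F = 0 when the shared fit is also perfect (p = 1).
Equal-distance linking conflicts resolve smallest-distance-first, then
first-come. Profile peak alignment uses the highest interior local
maximum; profiles without one are excluded with a warning.
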