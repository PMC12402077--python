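# stellatrack

Single-molecule motility analysis in hair-cell stereocilia.

Stereocilia are the actin-based mechanosensory protrusions of inner-ear
hair cells. Their actin filaments are uniformly oriented with barbed ends
at the tip, so a plus-end-directed myosin that is processive will walk
tipward; whether a given myosin construct does so — and how fast — can be
read out by sparse single-molecule labeling (HaloTag + sub-nanomolar dye
ligand) and single-plane light-sheet time-lapse imaging. `stellatrack`
implements the complete image-analysis workflow for such recordings, plus
a ground-truthed synthetic movie generator so every stage can be validated
without microscope data:

- **simcilia** — synthetic stereocilia movies: near-straight axes, four
  molecule motion regimes (one-frame diffusive dwellers, stationary
  binders, processive walkers, pause-and-jump stepwise walkers), Airy
  point-spread function, photobleaching/blinking, Poisson shot noise,
  camera read noise, lateral stage drift, and a per-molecule truth table.
- **registration** — lateral drift correction by phase-only correlation
  with subpixel peak localization, refined by least-squares image matching
  (Gauss–Newton on the translation).
- **puncta** — Laplacian-of-Gaussian spot detection, background-subtracted
  sum-intensity photometry, and point-source verification: averaged
  aligned line profiles compared with the in-focus Born & Wolf PSF
  I(r) = [2 J1(v)/v]², v = 2πNA·r/λ.
- **mixture** — fluorophore counting by a k-component 1D Gaussian mixture
  fitted with expectation–maximization (one fluorophore, two fluorophores,
  aggregates).
- **kymotrack** — kymograph extraction along stereocilium axes,
  nearest-neighbor track linking, projection onto the axis, and the
  operational motion classifier: a molecule is *directional* when it moves
  in the same direction for more than three frames; back-and-forth
  trajectories are *excluded* as random motion; directional runs are
  *processive* (continuous) or *stepwise* (staircase) by pause fraction.
  Velocities are endpoint slopes (nm/s), run lengths total excursions (µm).
- **kinetics** — dwell-time survival curves S(t) = P(dwell ≥ t), one-phase
  decay fits Y = (Y0 − plateau)·e^(−Kt) + plateau with T½ = ln2/K,
  extra-sum-of-squares F-tests between groups with Bonferroni correction,
  and cohort statistics (t-test, ANOVA + Tukey, pairwise Fisher exact).
- **pipeline / cli** — configuration, orchestration, artifact I/O and the
  `stellatrack` command-line tool.

## Worked example

Simulate a movie of processive walkers, then run the full pipeline:

```python
import numpy as np
from stellatrack import simcilia as sc
from stellatrack.pipeline import PipelineConfig, analyze_stack
from stellatrack.kymotrack import summarize_runs

scene = sc.make_scene(2, (9.0, 10.0), (96, 128), pixel_size_um=0.1625, seed=7)
motion = sc.MotionModel(kind="processive", speed_mean=101, speed_sd=53,
                        run_length_mean=2.3, run_length_sd=1.0)
photo = sc.Photophysics(photons_per_frame=2000, bleach_half_life=float("inf"))
camera = sc.CameraModel(frame_interval=1.0)
tracks = sc.simulate_tracks(scene, motion, photo, 4, 200, seed=8,
                            frame_interval_s=1.0)
drift = sc.random_walk_drift(200, seed=9)
stack = sc.render_movie(scene, tracks, photo, camera, drift_trace=drift,
                        seed=10, n_frames=200, background_photons=20)

cfg = PipelineConfig(axes_px=[scene.polyline_px(i) for i in range(2)],
                     frame_interval_s=1.0)
cfg.detect.update(threshold_snr=10.0, restrict_to_axes_px=4.0)
cfg.classify["min_step_um"] = 0.03
res = analyze_stack(stack, cfg.axes_px, cfg)
print("truth speeds :", [round(t.true_speed_nm_s, 1) for t in tracks])
print("recovered    :", summarize_runs(res["runs"]))
```

prints

```
truth speeds : [30.2, 91.0, 174.8, 180.8]
recovered    : {'n': 4, 'velocity_mean_nm_s': 112.29008037517647,
'velocity_sd_nm_s': 63.69998085697341, 'run_length_mean_um':
1.7267777819901893, 'run_length_sd_um': 0.86163400783263}
```

The four drawn walkers (truth mean 119 nm/s) are recovered as four
directional runs with cohort mean 112 nm/s — each run's endpoint slope
matches its molecule's drawn speed, and the spread reflects the wide
generating distribution. At cohort scale (the validation studies use 100
walkers) the recovered means converge on the generating 101 nm/s and
2.3 µm.

The same stages are available from the shell:

```sh
stellatrack simulate --out demo --seed 1 --kind processive
stellatrack register --in demo/movie.tif --out demo/movie_reg.tif --trace demo/drift.csv
stellatrack detect   --in demo/movie_reg.tif --out demo/detections.csv --snr 10
stellatrack count    --in demo/detections.csv --out demo/mixture.json --k 3
```

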