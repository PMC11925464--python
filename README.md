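# valveflow

Quantitative image analysis of *Drosophila* intracardiac valve function.

The larval *Drosophila* heart is a tube whose ventricle and aorta are
separated by a valve built from just two cells. When these cells are
malformed, the valve cannot fully open the lumen during systole and cardiac
performance drops. `valveflow` implements the complete quantitative toolkit
used to measure that drop from video recordings:

- **Dye angiography** — a tracer injected posteriorly is pumped anteriorly
  one discrete hemolymph packet per heartbeat; the mean intensity of an
  anterior ROI over the final stretch of a 30 s recording (the
  *accumulation index*) reads out pumping efficiency.
- **Oscillogram analysis** — the intensity trace of a peri-valve ROI peaks
  once per pump cycle and returns to baseline when the valve seals; peak
  detection yields cycle counts, closure quality and cardiac arrests.
- **Two-ROI velocimetry** — hemolymph velocity `v = d / ⟨Δt⟩`, where `d` is
  the separation of a posterior and an anterior aortic ROI and `Δt` the
  per-cycle delay between their intensity peaks.
- **Valve kinematics** — per-frame luminal gap between the two labelled
  valve cells (minimum boundary separation perpendicular to the tube axis),
  giving peak opening distance and close-to-close opening time.
- **Particle velocimetry** — detection and linking of injected fluorescent
  microparticles, with per-track peak speeds gated to the valve region;
  by kinematic continuity, speed × local lumen width is conserved, so a
  half-open valve doubles the local speed.
- **Morphometry** — Fourier-components myofiber directionality, threshold
  fiber density, polygon lumen area, and moments-ellipse shape descriptors
  including `roundness = 4·A / (π·major²)` for crawling-larva body shape.
- **Track metrics & statistics** — total distance, displacement, confinement
  ratio, mean/peak speed; unpaired two-tailed Student's *t* and two-sided
  Mann-Whitney *U* group comparisons with the conventional star thresholds.

Because the assays are defined on live recordings, the package ships a
first-class synthetic-data module (`valveflow.videogen`) that renders each
scene with full ground truth — beat times, valve gap, packet and particle
trajectories — so every analysis stage is validated by parameter recovery.

## Worked example

Generate a control-condition angiography recording (5.2 mm/s packets,
1 beat/s, 100 fps) and recover the aortic velocity from two 15×15 px ROIs:

```python
import numpy as np
from valveflow import videogen as vg, angiography as ang, pulsatility as pul
from valveflow.io import ROISpec

params = vg.SceneParams(duration=6.0, packet_velocity=5.2, beat_rate=1.0,
                        image_size=(48, 512), noise_sd=5.0, seed=11)
stack, truth = vg.generate_heart_video(params)
sub = ang.subtract_background(stack)          # first-frame subtraction

trace_post = ang.extract_trace(sub, ROISpec("posterior", 17, 93, 15, 15))
trace_ant = ang.extract_trace(sub, ROISpec("anterior", 17, 413, 15, 15))

features = pul.detect_cycles(trace_ant)
print(f"beats detected: {features.n_cycles} (truth: {len(truth.beat_times)})")
print(f"median cycle period: {np.median(features.cycle_periods):.2f} s")

distance_mm = (413 - 93) * params.pixel_size / 1000.0
est = pul.estimate_velocity(trace_post, trace_ant, distance_mm, n_cycles=3)
print(f"transit times: {est.transit_times} s over {est.distance:.1f} mm")
print(f"estimated velocity: {est.velocity:.2f} mm/s (truth: 5.2 mm/s)")
```

Output:

```
beats detected: 6 (truth: 6)
median cycle period: 1.00 s
transit times: [0.31 0.31 0.31] s over 1.6 mm
estimated velocity: 5.16 mm/s (truth: 5.2 mm/s)
```

Each dye packet takes three peaks' worth of transit samples to cross the
1.6 mm between the ROIs; the 0.8 % error is the one-frame quantisation of
peak timing at 100 fps.

The same assays are available from the shell:

```bash
valveflow simulate heart --config scene.yaml --seed 3 --out scene/
valveflow angiography --video scene/heart.tif --roi rois.yaml --out acc.csv
valveflow pulse --video scene/heart.tif --roi rois.yaml --distance-mm 1.6 --out pulse.json
valveflow stats --csv per_animal.csv --control control --out stats.csv
```

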