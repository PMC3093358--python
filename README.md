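# wormkymo

Quantification of *C. elegans* locomotion, neural calcium imaging, and
plate-assay behavior — the analysis layer used in worm thermosensation
studies — together with synthetic-data generators that make every stage
testable against ground truth without any recorded video.

The package is aimed at researchers who track single worms on assay plates
and need reproducible, scriptable versions of four classically hand-rolled
analyses:

1. **Curvature kymographs.** From single-worm video, each frame is
   segmented (Otsu threshold, largest component), skeletonized, and reduced
   to a K-point midline at equal arc-length spacing. Signed curvature is the
   wrapped difference of consecutive segment tangent angles, in degrees per
   body segment: for midline points $p_1,\dots,p_K$ with segment angles
   $\theta_i$, the map entry is $c_i = \mathrm{wrap}(\theta_{i+1}-\theta_i)$.
   Rows are frames, columns body positions; a 3×3 masked mean filter smooths
   the map, and frames where extraction fails because the worm touches
   itself (the omega pose) are masked and rendered white.
2. **Behavioral-state segmentation.** Frames are labeled FORWARD, BACKWARD,
   OMEGA, or UNKNOWN. Omega turns are detected from self-contact (skeleton
   cycle/branch) or midline self-proximity; crawl direction comes from the
   travel direction of the undulatory wave — the body shift $\delta^\*$
   maximizing the correlation between curvature profiles at $t$ and
   $t+\Delta$ (toward the tail ⇒ forward). Onset-to-onset inter-omega-turn
   durations are summarized per animal and per group.
3. **Ratiometric calcium quantification.** For a cameleon-expressing neuron
   the response is the YFP/CFP ratio $R_t = F_{535}/F_{480}$ expressed as
   percent change from a pre-stimulus baseline, $100\,(R_t - R_0)/R_0$; the
   per-animal summary is the signed post-stimulus extremum ("maximum ratio
   change from baseline") and groups are reported as mean ± SEM. A
   template-fit estimator (`fit_response_amplitude`) recovers response
   amplitudes without the extremum's noise bias. Puncta spacing along a
   neurite is histogrammed into sixteen equal-width classes.
4. **Plate-assay scoring.** Radial-gradient thermotaxis tracks are
   classified '17' / '20' / '25' / '17/25' by temperature-zone occupancy;
   the chemotaxis index is $CI = (N_{odor} - N_{ctrl})/N_{total}$; NaCl
   tracks are scored normal / partial / defective from entries into and
   dwell at the concentration peak.

The simulators (`wormkymo.simulate`) produce labeled posture sequences
(sine-wave gait, Poisson-timed omega turns and reversals), rasterized video,
stimulus-locked dual-channel fluorescence traces, and run-and-tumble plate
tracks — each with the ground truth the tests compare against.

Analysis stages are scikit-learn-style estimators (`MidlineExtractor`,
`CurvatureMapper`, `StateSegmenter`, `RatioQuantifier`,
`ThermotaxisClassifier`, `NaClClassifier`) with `fit`/`transform`/`predict`
and `get_params`/`set_params`; module-level functions wrap them for one-off
use.

## Worked example

```python
import numpy as np
from wormkymo import (SimulationConfig, simulate_posture_sequence, rasterize,
                      MidlineExtractor, StateSegmenter)
from wormkymo.segmentation import turn_statistics

cfg = SimulationConfig(duration_s=120.0, omega_rate_per_s=0.05,
                       reversal_rate_per_s=0.02, rng_seed=7)
posture = simulate_posture_sequence(cfg)                  # ground truth
stack = rasterize(posture, pixel_size_mm=0.02, image_shape=(128, 128))
midlines = MidlineExtractor().fit(stack).transform(stack)
seg = StateSegmenter(frame_rate_hz=stack.frame_rate_hz).fit(midlines)
stats = turn_statistics(seg.states_, window_s=120.0)

print("true omega onsets (s):", np.round(posture.omega_onsets_s(), 1))
print("detected onsets  (s):", np.round(stats.omega_onsets_s, 1))
print(f"mean inter-omega duration: {stats.mean_s:.1f} s (+/- {stats.sem_s:.1f} SEM)")
```

prints

```
true omega onsets (s): [14.2 34.7 46.  63.9 68.1]
detected onsets  (s): [14.3 34.8 46.2 64.1 68.2]
mean inter-omega duration: 13.5 s (+/- 3.7 SEM)
```

Every simulated omega turn is recovered from the rasterized video within
0.2 s of its true onset; the inter-omega durations are the onset-to-onset
gaps within the analysis window. `seg.curvature_map_` holds the kymograph
(`render_map` draws it with the forward/backward bars and white omega
stripes), and the per-frame labels give the time budget of each state —
here 90.0% FORWARD, 2.9% BACKWARD, 7.1% OMEGA.

Calcium traces work the same way:

```python
from wormkymo import (simulate_ratio_traces, RatioQuantifier, ratio_change,
                      fit_response_amplitude)

clean = simulate_ratio_traces(10, response_percent=17.0, noise_snr=np.inf, seed=3)
summary = RatioQuantifier().fit().summarize([s.data for s in clean])
# -> noiseless extremum: 17.0 +/- 0.0 % (n=10)

noisy = simulate_ratio_traces(10, response_percent=17.0, noise_snr=10.0, seed=3)
fits = [fit_response_amplitude(ratio_change(s.data)) for s in noisy]
# -> template-fit recovery at SNR 10: 17.9 +/- 1.2 % (n=10)
```

The noiseless extremum returns the injected 17% exactly; on noisy traces
the extremum is biased upward (the maximum of signal plus noise exceeds the
signal peak), so amplitude recovery uses the least-squares template fit,
which stays within sampling error of the injected value.

A CLI covers the same pipeline from the shell:

```bash
wormkymo simulate video --seed 11 --out run/sim
wormkymo analyze-video --in run/sim/stack.tif --out run/analysis
wormkymo simulate traces --seed 3 --out run/traces
wormkymo analyze-calcium run/traces/trace_*.csv --out run/calcium
wormkymo score-behavior run/tracks/track_*.csv --assay ttx --out run/scores
```

Each run writes a `manifest.json` with the canonical config, its hash, and
the SHA-256 of every output, so reruns are verifiably bit-identical.

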