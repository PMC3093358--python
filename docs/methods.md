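# Methods

This note documents the models and procedures implemented in `wormkymo`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions a user auditing results will want
to know.

## Synthetic locomotion model

The worm is an inextensible planar curve of length *L* (default 1.0 mm)
sampled at K = 50 points with exactly equal spacing. Posture is generated
from a body tangent-angle field

    theta(s, t) = psi(t) + (1 - b(t)) * A sin(2*pi*s/lambda - phi(t))
                + b(t) * sigma_k * Theta * max(0, 1 - s/0.7)

with body coordinate s in [0, 1] (0 = head). Defaults: amplitude
A = 0.6 rad, wavelength lambda = 0.9 body lengths, wave frequency 0.5 Hz,
crawl speed 0.15 mm/s, frame rate 30 Hz — typical values for an adult
animal crawling on agar; all are configurable in `SimulationConfig`.
The phase phi integrates +2*pi*f per second during forward crawling and
-2*pi*f during reversals, so the wave travels head→tail or tail→head
respectively while remaining continuous at state changes. Locomotion is
imposed kinematically: the centroid moves at the crawl speed along the
heading psi, head-first when forward, tail-first when backward.

Omega turns are scripted, not emergent: over an event of duration d
(default 2 s) the blend b(t) ramps 0→1→0 (trapezoid with 9% ramps), morphing
the sine gait into a stereotyped anterior curl of total tangent rotation
Theta = 6.0 rad distributed over the front 70% of the body. At full curl the
head approaches the posterior body to ~0.014 mm, far below one body width
(L/12 ≈ 0.083 mm), so segmentation of the rasterized pose genuinely fuses
and the extractor's self-contact criterion is exercised rather than
simulated. Simultaneously the heading psi rotates smoothly by a uniform
120–180° (random sign), giving the post-turn reorientation. Omega and
reversal onsets are independent Poisson processes; overlapping omega
intervals merge into one labeled event, an omega onset truncates an ongoing
reversal, and a reversal onset inside an omega is discarded — the three
states are exclusive and label every frame.

What the generator does **not** emulate: body mechanics or neural control,
self-occlusion other than the omega pose, stage jitter, uneven illumination,
background texture, multiple animals, and pauses. Tests passing on this
synthetic data therefore demonstrate correctness of the *geometry and logic*
of the pipeline (skeleton topology, wave-direction inference, event
statistics), not robustness to every imaging artifact of a real rig.

## Rasterization

Frames draw the worm as a filled tube: width maximal at mid-body
(L/12) and tapering to 40% at the tips via a sqrt-sine profile, rendered as
a union of discs along a densely resampled midline (< 0.5 px steps) on a
128×128 px frame at 0.02 mm/px by default. Each frame is centered on the
animal — the counterpart of a tracking stage keeping the worm in view — and
the mm offset of the frame origin is stored per frame (`offsets_mm`), so
downstream code can place midlines back into plate coordinates where net
displacement is meaningful. Optional Gaussian intensity noise is added on
top of a binary foreground (1) / background (0) image.

## Midline extraction

Per frame: threshold (Otsu by default; fixed value available), keep the
largest connected component, skeletonize (topological thinning), build the
8-connected pixel graph *without* spurious diagonal triangles (a diagonal
edge is only added when the two orthogonal pixels it would bridge are
absent), and prune side branches shorter than one body width (width
estimated from the mask as area / skeleton length). If the pruned skeleton
is a simple path with exactly two endpoints, the path is extended along its
end tangents to the mask boundary (skeletonization stops about one tip
radius short of the body end), pulled back by 0.2 × the mean body width
(the tip half-width, so the midline ends at the body tip rather than the
mask boundary), smoothed with a 3-point moving average, and resampled to
K = 50 points at equal arc length. On noiseless synthetic frames the
recovered length is within ~2% of truth and the mean point-to-curve error
is ~0.2 px.

Failure taxonomy (flagged, never guessed): a cycle in the skeleton ⇒
`self_contact`; more than two endpoints after pruning ⇒ `skeleton_branch`;
a path shorter than 70% of the running-median body length ⇒ `too_short`;
an empty mask ⇒ `no_worm`. These are exactly the signatures of the omega
pose, which is why omega frames appear as masked (white) stripes in the
kymograph.

Head/tail identity: within each contiguous run of valid frames, orientation
is chained by nearest-endpoint matching; the run's polarity is then set so
the head end leads the run's net centroid displacement. Polarity is *not*
carried across omega gaps — during a turn the animal reorients by more than
a right angle and the head visits the tail region, so endpoint matching
across the gap is unreliable (it mis-assigned roughly a third of runs in
development tests), whereas per-run displacement polarity is correct
whenever forward time dominates the run, which the exclusive-state model
guarantees between omegas. Runs with no net displacement fall back to
matching against the previous run and are flagged low-confidence.

## Curvature map

Curvature is reported in degrees per body segment at fixed K, which makes
values independent of animal size and matches the familiar ±30 display
range for crawling. Column i of the map is wrap(theta_{i+1} - theta_i) for
the K−1 segment tangent angles, K−2 columns in all, positive for
counter-clockwise rotation (the dorsoventral side is not identified, so the
sign convention is geometric). Invalid/omega frames are masked *first*;
then a 3×3 mean filter runs over the unmasked entries with masked neighbors
excluded and edge cells renormalized over the neighbors that exist. This
makes the filter exactly mean-preserving in the interior, idempotent on
constants, and incapable of bleeding values across the omega mask.
`render_map` draws time on x, body position on y (head up), a diverging
palette clipped to ±30, white masked columns, and black forward/backward
bars above/below the axis.

## State segmentation

Omega detection ORs two signals: extraction failure with a self-contact-type
reason, and — on valid midlines — any two points separated by more than 25%
of the body arc length lying within one body width. Candidate runs are
merged across gaps shorter than 0.3 s and runs shorter than 0.2 s are
dropped (one-to-few frame glitch immunity at 30 fps). On the 600-s noiseless
benchmark (omega rate 0.03/s) detection is exact: F1 = 1.0 at ±0.5 s onset
tolerance, count error 0.

Direction is the sign of the body shift delta* maximizing the Pearson
correlation between curvature profiles at t and t + Delta, searched over
±10 positions and averaged over a 1-s sliding window before the argmax;
shift toward the tail ⇒ FORWARD. Delta defaults to about a sixth of a
second of frames (5 at 30 fps): at the default gait the wave advances only
~0.7 positions per single frame, below the zero-shift correlation that
pixel-level extraction noise induces between near-simultaneous frames, while
over 5 frames it advances ~3.7 positions and the estimate is unambiguous.
Frames with peak correlation below 0.5 or zero shift are UNKNOWN, and
direction runs shorter than 0.5 s are absorbed into their surroundings, so
momentary wiggles never surface as intervals. Inter-omega-turn durations
are onset-to-onset differences within the first 1000 s (onset-to-onset is
invariant to any bias in the detector's event durations); animals with
fewer than two onsets report a missing mean, never zero. Group summaries
are means of per-animal means ± SEM.

## Ratiometric quantification

R = F535/F480; the baseline R0 is the mean over the 10 s ending at stimulus
onset (detected as the first departure of the temperature channel from its
initial level; without a stimulus channel, the first 10 s). The per-sample
response is 100 (R − R0)/R0 (raw-unit output is also kept), and the
per-animal summary is the signed post-baseline extremum, with `min` and
`abs` modes for inhibitory responses. Because the two channels are divided,
any gain or bleaching common to both cancels exactly; per-channel
exponential detrending exists but is off by default. The extremum of a
noisy trace is positively biased (expected maximum of signal plus noise),
and the bias is documented by test against a resimulation oracle rather
than hidden by smoothing; for *parameter recovery* the package provides
`fit_response_amplitude`, a least-squares fit of a peak-normalized
rise/decay double-exponential template with the onset fixed at the known
stimulus time, initialized by a coarse kinetics grid with the closed-form
linear amplitude. It is exact on noiseless traces and unbiased to within
sampling error at channel SNR 10.

Puncta profiles: a rolling-median baseline (4 µm window) is subtracted from
the calibrated 1-D intensity profile, peaks are detected by prominence, and
adjacent-center spacings are binned into sixteen equal-width classes over
0–8 µm by default (the class edges are always emitted alongside the
fractions, which normalize over the in-range spacings).

## Plate-assay scoring

Thermotaxis: the default plate maps radius to temperature linearly,
T(r) = 17 + 8 r/R on a 45-mm plate (a lookup table can replace it); zones
are 17 (< 18.5 °C), 20 (19–21 °C), 25 (> 23.5 °C). A zone is "visited" at
≥ 10% occupancy; visiting both 17 and 25 ⇒ '17/25', otherwise the visited
zone with the largest occupancy wins, and a track visiting no zone is
labeled by its largest occupancy and flagged low-confidence. Occupancies are
always reported so a different threshold can be applied post hoc — the
original scoring was by eye, and the 10% operationalization is this
package's choice. NaCl: entries into the 5-mm peak region count as distinct
when separated by ≥ 30 s outside; 'normal' ⇔ ≥ 2 entries or dwell ≥ 50% of
the assay, 'partial' ⇔ exactly one short visit, 'defective' ⇔ none. The
chemotaxis index is (N_odor − N_ctrl)/N_total on counts, with the scoring
geometry left to the caller. The track simulator's archetypes (stay-center,
stay-ring, stay-periphery, wander-both, approach-peak-k-times) are
run-and-tumble walks with drift toward a scheduled target; the wander-both
archetype uses a brisker default speed (0.35 mm/s) so a 1200-s assay
genuinely covers both ends of the plate.

## Reproducibility and problem sizes

Every stochastic function takes an explicit seed and identical seeds give
bit-identical outputs; pipeline runs write manifests with SHA-256 hashes of
all outputs, and a rerun of the same config reproduces the manifest hash
exactly. The test suite and the acceptance script use these problem sizes,
chosen to give tight statistical checks at interactive runtimes: a 600-s
30-fps 128×128 px video for end-to-end omega/direction benchmarks, a 150-s
video for shared round-trip fixtures, 20 animals × 1000 s for turn
statistics (against a 10,000-rep exponential-gap Monte-Carlo oracle),
n = 10 traces per imaging group, and 5 tracks per behavioral archetype.

## Known limitations

* The omega turn is a single stereotyped pose; shallow turns and pirouette
  sub-structure are out of scope, as are eigenworm decompositions.
* Direction inference needs a visible undulatory wave; a worm pausing or
  moving without bending is UNKNOWN by design.
* The curvature sign is geometric (CCW-positive), not dorsoventral.
* The thermotaxis gradient is radial and monotone; real plates have
  non-linear gradients, which the lookup-table hook accommodates but the
  defaults do not model.
* Fluorescence traces assume an immobilized animal: no motion artifacts or
  channel bleed-through.
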