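# Methods

## The measurement problem

Host-seeking *Aedes aegypti* females land on the odor- and heat-laced back
wall of a 15-cm mesh cage, walk and probe ("searching"), sit still
("stationary"), and launch escape takeoffs when a shadow sweeps the wall.
The assay films the wall in infrared (640×480 px, 30 fps; the IR-pass
filter makes the visible-light shadow invisible to the camera, so the
stimulus acts on the animals, never on the image) and asks, per recording:
who is landed, who is searching, who took off, and how much of the takeoff
response exceeds the spontaneous baseline.

This package implements that computation as a five-stage pipeline —
detection, tracking, behavioral classification, stimulus bookkeeping,
statistics — plus a synthetic cohort simulator and renderer that provide
exact ground truth for every stage.

## Detection

A per-interval background model (the pixel-wise median of 100 frames drawn
uniformly without replacement from each 30-s block; shorter final blocks
use all their frames) isolates moving foreground. For each frame the
pipeline takes |frame − background|, convolves with a
Laplacian-of-Gaussian at scale `log_sigma` = 2 px (matched to silhouettes
of 20–60 px², i.e. diameters of ~5–9 px), binarizes, extracts 8-connected
components, keeps those with area in [20, 60] px² inclusive, and reports
the response-weighted centroid (sub-pixel; on rendered blobs it differs
from the binary centroid by well under 0.5 px) and the peak response.

Two numerical choices matter here:

- **Signed response.** The LoG of a positive bump is a negative core
  surrounded by a positive ring. The pipeline thresholds the sign-flipped,
  zero-clipped response, keeping only the blob-matched core. Thresholding
  the magnitude instead keeps the ring, which under sensor noise fragments
  into 20–22 px² arcs that pass the area gate and flank every real insect
  with phantoms.
- **Response floor.** The binarization threshold is
  `max(percentile(response, 60), response_floor)` with a floor of 2.0
  response units. Insects cover well under 1% of the frame, so a pure
  rank-percentile threshold would mark a fixed 40% of all pixels — almost
  entirely noise — and connect it into clusters near the 8-connectivity
  percolation threshold; the floor is what makes the stage operational on
  sparse scenes. Under the default rendering conditions noise responses
  stay below ~0.4 while blob cores peak at 8–16, so the floor separates
  them with an order-of-magnitude margin. The percentile term still
  engages on dense scenes. A `min_activity` gate (99th percentile of
  |frame − background|) can short-circuit empty frames but is disabled by
  default: with realistic cohorts the 99th percentile of the difference
  image is always noise, and the floor already yields empty detection sets
  on empty frames.

Male mosquitoes barely move, so they never enter the motion foreground.
`detect_static_dark` instead band-passes the inverted frame directly
(difference of Gaussians at `log_sigma` and 4·`log_sigma`) and thresholds
at half the peak response (plus the same floor): the DoG core has no
bounding zero-crossing ring, so an absolute threshold alone would pass
components far larger than the insect. The same area gate and centroid
extraction follow. Broad dark regions are suppressed by the band-pass and
rejected by the gate.

## Tracking

Each track carries a 2-D constant-velocity Kalman filter (state x, y, vx,
vy in px and px/frame). Per frame: predict all active tracks; solve the
global rectangular assignment between predicted positions and detections
(Hungarian algorithm on Euclidean distances); then discard assigned pairs
at distance ≥ 10 px (strict bound — assignment first, gate second; a
`pre_gate` flag switches to gating the cost matrix for sensitivity
analysis). Matched tracks are measurement-updated (Joseph-form covariance
update); unmatched tracks coast on their prediction; a track invisible for
more than 6 consecutive frames is closed as a takeoff candidate with its
predicted-only tail trimmed, so it ends at its last observation — takeoff
time is the last observed frame, not an extrapolation. Unmatched
detections seed new tracks with zero velocity and a wide velocity prior
(25 px²/frame²): each landing is a new identity, and no re-identification
is attempted across takeoff and re-landing. Tracks spanning fewer than 30
frames (1 s) are dropped before any analysis.

Kalman noise defaults (process 1.0 px² position, 0.5 px²/frame² velocity;
measurement 1.0 px²) track the fastest classified walker (52 px/s
≈ 1.73 px/frame) with sub-pixel steady-state error and a noiseless
constant-velocity target to ≤ 0.01 px within 30 frames.

All track losses are takeoff candidates; the pipeline does not distinguish
occlusion loss from true takeoff (with the ~10 px gate and 6-frame
patience, occlusions shorter than ~0.2 s are bridged by prediction).

## Behavioral classification

Per-frame speed is the Euclidean displacement between consecutive frames
times fps (the first frame copies the second). A centered 31-frame (1-s)
moving median — shrinking windows at the track edges — smooths it; a frame
is *searching* when the median lies in [6, 52] px/s inclusive, else
*stationary*. The lower bound absorbs centroid jitter (rendered stationary
insects read ~1 px/s); the upper bound excludes takeoff lunges, since
walking above 52 px/s does not occur. Stationary gaps shorter than 30
frames between two searching bouts are relabeled searching, making the
flanking bouts one contiguous bout.

## Transition probabilities

Behavioral dynamics are summarized as a 2-s-bin transition matrix over
{stationary, searching, takeoff}. Bins of 60 contiguous frames
(`round(2·fps)` in general) are drawn uniformly over all (track,
start-frame) positions: any start on a track that ends in takeoff (bins
reaching the final frame score takeoff), and starts at least one bin
before the end of tracks censored by the video end (such starts would
otherwise be scored by an incomplete future and bias outcomes). A bin's
start state is the label of its first frame; its outcome is takeoff if the
track takes off inside the bin, else the alternative state if it occupies
a strict majority (> 50%) of the bin's frames, else the start state.
Probabilities are outcome frequencies conditioned on the start state
(pooled across videos of an experiment); a start state never sampled
yields an undefined (NaN) row rather than zeros. The default 50,000
sampled bins agree with exhaustive enumeration to within 0.01; an
`exhaustive` flag enumerates instead of sampling.

## Takeoff statistics

For each stimulus epoch the *response window* spans
[floor(t_start·fps), ceil((t_end + 1 s)·fps)) — the sweep plus one second.
The landed population is censused 500 ms before the window; the observed
takeoff rate is the fraction of that population with a takeoff event
inside the window. Replicates with fewer than 10 landed at the census are
excluded from any aggregate.

The *spontaneous baseline* scores windows of the same form placed
uniformly at random over times whose windows do not overlap any response
window, with three baseline-specific choices:

- **2-s windows.** Baseline windows default to the 2-s bin length rather
  than the stimulus-window length, so the baseline is a per-2-s takeoff
  rate and does not change with stimulus speed (a 1.25-s window would
  report ~0.083 for the same cohort whose 2-s rate is 0.13). It is
  configurable (`spont_window_s`).
- **Census at the window start.** A random baseline window has no stimulus
  onset to protect; keeping the 500-ms lead would multiply the baseline by
  the survival factor (1−p)^(0.5/2) ≈ 0.97 for no benefit.
- **Aged census.** Only insects tracked ≥ 30 frames at the census count.
  The minimum-track-length rule conditions every track's first second on
  survival; censusing younger tracks depresses the baseline by ~0.002
  absolute (measured over 200 simulated cohorts). Ageing the census puts
  all conditioning in the past, and the memoryless hazard then makes the
  estimator unbiased.

*Normalized takeoffs* is the observed rate minus the baseline mean: 0
means the stimulus did nothing, positive means evoked escape. It is
computed per replicate and aggregated as mean ± SEM over non-excluded
replicates. Note that published per-condition values are not always
reconcilable as a pooled subtraction; per-replicate subtraction with
heterogeneous baselines is the form implemented here.

*Participation* is the mean number of landed insects per frame.
Per-frame time series (percent landed, percent of landed searching, mean x
of landed) support the standard occupancy plots; frames with nobody landed
report missing values.

## Stimulus model

A stimulus epoch is an edge sweep: polarity (OFF edge = light→dark, ON
edge = dark→light, or full-field flash), speed in cm/s, travel direction,
and wall coverage ∈ (0, 1]. Duration is wall_extent × coverage / speed
(0.25 s for a full 15-cm wall at 60 cm/s); flashes have zero duration and
only a post-window. Named protocols: `standard_150s` (OFF 60 cm/s at 30
and 90 s, ON 4 cm/s at 60 and 120 s over 150 s), `fast_fast_1s_dark`
(four rapid OFF/ON pairs with exactly 1 s of dark between each pair),
`flash`, and `none`. A linear stage→pixel calibration (least squares over
(stage, edge-pixel) pairs, residual RMS reported) maps stage positions to
the shadow edge; `edge_position` is piecewise linear in time, clamped to
the sweep boundaries.

## The synthetic cohort

The simulator is an agent-based state machine at frame resolution.
Off-wall agents land as a Poisson process (0.04 /s initially; after a
takeoff they re-land after an exponential delay, mean 12 s — chosen so
that >60% re-land within 20 s and steady-state participation is ~17/30,
jointly matching the assay's reported re-landing and participation
figures). Landed agents run a two-state Markov chain with an absorbing
takeoff; searching agents walk with a per-bout speed drawn uniformly from
[10, 45] px/s (comfortably inside the classification band) and a smooth
random-walk heading with reflection at a 12-px wall margin and physical
exclusion below 16 px from another landed agent (insects do not
interpenetrate; exclusion also keeps rendered blobs separable).

**Hazard calibration.** The chain is parametrized by *scored* 2-s
probabilities — the exact quantities the transition estimator reports
(majority rule, any-takeoff rule) — with defaults 0.38
stationary→searching, 0.08 searching→stationary, 0.13 takeoff from either
state (per-state overrides available). An exact dynamic program over
(state, frames-in-alternative) maps per-frame hazards to scored bin
probabilities, and a least-squares inversion calibrates the four hazards
to the targets (residual < 1e-6; the DP doubles as an independent oracle
in the tests). Endpoint-scored and majority-scored probabilities differ
substantially (a switch at mid-bin flips the endpoint but not the
majority), which is why the naive geometric conversion is insufficient.
Setting the switch probabilities to `None` instead parametrizes the chain
by exponential bout means (stationary 2.1 s, searching 8 s); the two
parametrizations cannot hold simultaneously under majority scoring, and
the probability form takes precedence by default.

**Evoked responses.** At each epoch onset, every landed agent draws once
(per encounter, not per frame): takeoff with probability
p_evoked(state) × logistic((speed − 8)/3 cm/s) × polarity factor
(OFF 1.0, ON 0.4, flash-off 0.5, flash-on 0.02; defaults 0.87 stationary,
0.93 searching), with the takeoff placed at the moment the edge crosses
the agent's position plus a 0.05–0.35 s latency — agents beyond a partial
sweep's stopping point never fire, so half-wall coverage is less aversive
for free. Non-evoked agents facing a slow edge (< 15 cm/s) freeze
(probability 0.5) until 1 s after the sweep, pausing searching. The
logistic speed scaling and polarity factors are behavioral modeling
choices calibratable against speed-graded response data; they do not
affect the recovery tests, which set the evoked probabilities explicitly.

**Renderer.** Each landed agent is an anisotropic Gaussian dark spot
(σx ∈ [2.4, 2.7], σy ∈ [1.95, 2.1] px, random orientation, contrast
100–130 on a background of 200) with additive Gaussian noise (σ = 2) and
8-bit quantization. The half-depth silhouette of every default appearance
lies in [20, 60] px² (self-checked at render time; rendering out-of-band
blobs requires an explicit opt-out, used by the rejection tests). An
optional slow multiplicative illumination drift exists as a robustness
stressor and is off by default. The renderer draws only landed agents —
flying insects are bookkept, not rendered — and adds no legs, wings,
shadows, or compression artifacts.

**What the simulator does not emulate.** Real IR video contains partial
occlusions with merged silhouettes, appearance change with pose, debris,
reflections, non-Gaussian sensor noise, and flying insects crossing the
wall plane. Passing the recovery tests therefore demonstrates that the
pipeline is a faithful implementation of the method under the generative
model it states — not that the method achieves the same accuracy on
arbitrary real footage.

## Problem sizes and determinism

Recovery studies run at the study's native scale: 30-agent, 150-s cohorts
at 640×480/30 fps; detection fidelity is measured over ≥1,000 rendered
frames; transition recovery pools six cohorts and 50,000 sampled bins;
the baseline study uses 200 seeded cohorts with 500 sampled windows each;
the evoked study uses 18 replicates (six cages × three). Every stage —
simulation, rendering, background sampling, bin and window sampling — is
deterministic under its seed; identical seeds give bit-identical frames
and tables.

A note on classified transition matrices: the classification rules (1-s
median, merging of sub-second stationary gaps) erase short stationary
bouts, so a transition matrix computed from classified labels is not an
unbiased estimate of the underlying chain's scored probabilities — under
the default rates the stationary row shifts by up to ~0.06 (staying
probability up, switching probability down) while the searching row and
both takeoff columns are essentially unaffected. This is a property of
the classification definitions, present equally in any data they are
applied to; recovery tests therefore validate the bin-sampling estimator
against exact labels and bound the classified path separately.

## Known limitations

- All track losses are takeoff candidates; wall exits and long occlusions
  are not distinguished (the arena wall fills the frame, so edge exits do
  not arise in the intended footage).
- The rank-percentile threshold of the detection stage is only meaningful
  on dense scenes; on realistic sparse scenes the absolute response floor
  is doing the work (see above).
- Takeoffs ending wall visits shorter than 1 s are invisible to the
  pipeline by construction of the minimum-track-length rule; recovery is
  reported against the recoverable set.
- The stats layer implements estimation only; no hypothesis-testing layer
  (ANOVA/post-hoc) is included.
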