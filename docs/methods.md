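# Methods

This note documents the models, conventions and numerical choices behind
`spiderpld`, in the order the pipeline runs: stimulus construction, saccade
extraction, preference inference, and the virtual-spider validation study.

## Stimulus construction

All five stimulus classes derive from one digitized track of a walking
spider seen from the side: 27 labeled points (eyes, pedicel, spinneret,
and per leg the patella–femur joint, the metatarsus–tibia joint and the
tarsus tip) over 72 frames, with visibility flags for points occluded by
the body.

**Rescaling.** The track is scaled anisotropically (one factor per axis,
constant over frames) so the bounding box of a reference frame set —
frame 0 by default, the "full" first frame — spans exactly 170 × 60 px
about its center. Because the scale is frame-constant, leg extension in
other frames may exceed the box slightly; this is intended, and the box
containment rule below applies only where stated.

**Decomposition.** Each frame's bounding-box center (of the visible
points) defines the global center path; subtracting it leaves per-dot
local positions whose frame-to-frame differences are the local steps.
Integrating the steps from the frame-0 local positions and re-adding the
center path reconstructs the source exactly (checked to 1e-9 px).
Occlusion gaps are linearly interpolated per dot before differencing
(configurable to drop ever-invisible dots instead), so every dot's path is
defined everywhere while invisible dots are still never drawn.

**The five classes.**

- *biological*: one dot per anatomical point, positions as tracked.
- *scrambled*: first-frame dot positions drawn uniformly inside the
  170 × 60 box (the source does not specify the randomization region; the
  box is the natural domain), then each dot replays its biological local
  step sequence and the center path is re-added. Per-dot paths and global
  translation are bit-comparable to the biological display; only the
  configuration is destroyed.
- *random*: starts from the biological first frame; every transition keeps
  that dot's biological step length with direction uniform on [0, 2π).
  Draws landing outside the box are rejected and redrawn (budget 10,000
  per dot-transition, then an error naming dot and transition — steps are
  short relative to the box, so exhaustion indicates bad input).
- *silhouette*: same-leg joints joined into round-capped strokes (default
  width 3 px; the source calls it only a "thick" line), plus two body
  ellipses (cephalothorax, opisthosoma) each anchored edge-on at the
  per-frame stimulus center and tilted toward the eyes or spinneret dot.
- *ellipse*: one axis-aligned ellipse per frame, centered on the shared
  center path, aspect fixed at 170:60, sized so its rasterized black-pixel
  count matches the silhouette's that frame. The semi-axes are solved from
  the target area and refined by bisection on a scale factor; the match is
  held to ±1 % per frame (rasterization is integral, so "exactly equal" is
  read as design intent, not a bit constraint; in practice the bisection
  lands within a few pixels).

**Rasterization.** Pixel centers sit on integer coordinates; a pixel is
black when its center lies inside a round-capped stroke (distance to the
segment ≤ width/2) or inside an ellipse. Coordinates are floats
throughout; the stimulus-local origin is the box center, x rightward,
y upward, and the screen origin is the screen center. Tests cross-check
this rasterizer against an independent geometric one (shapely buffers).

**Presentation timeline.** A presentation is 270 display frames at 30 fps
(9 s): three movement blocks of 60 frames separated by two 45-frame
(1.5 s) static pauses. The 72 source frames are resampled to 60 display
frames per block by nearest-frame resampling; this is the one place the
printed numbers (72-frame loop, 45-frame pauses, 270 total, 8 s visible)
cannot all be taken literally, and the resampling is the choice that
satisfies every timeline number simultaneously (block length is
configurable). The stimulus enters fully off-screen and its leading box
edge crosses the screen edge exactly at frame 30 (1 s), giving an 8 s
visible span; it ends centered behind a 200 px-wide central occluder,
disappearing progressively. Global translation is constant-speed within
movement blocks (each block re-anchored over the current position), which
pins the entry frame exactly; an option follows the digitized
frame-by-frame walking speed instead. Right-side presentations are the
mirror image of left-side ones.

**Trials.** 300 s habituation, then 10 cycles of presentation + 30 s
pause: 690 s total. The more-biological stimulus of the pair enters
following one of the two semi-random side sequences (LRLRLLRRLR or its
complement); the other stimulus mirrors it. Four pre-generated
randomizations exist per stochastic stimulus kind; a subject's trials draw
them without replacement per kind, so no randomization repeats across a
subject's trials. Within a trial the variant is constant.

**Mirroring and seeds.** Mirroring is an involution and commutes with the
deterministic constructors (biological, silhouette, ellipse, composition).
For the seeded constructors the commutation holds for the deterministic
part (paths and magnitudes), not the draws themselves — mirroring an input
track does not mirror a random number stream. All randomness flows through
explicit integer seeds; identical seeds give bit-identical displays.

## Saccade extraction

Rotation traces carry per-frame radian increments about x (forward/
backward), y (sideways) and z (body turns) at 120 fps, in FicTrac-style
delimited files (configurable column map; lab-frame delta-rotation columns
by default) or plain CSV. Positive z is normalized to the spider's
leftward turn; a reader option flips camera handedness.

1. *Smoothing*: Butterworth low-pass, order 3, critical frequency 0.5
   (normalized), applied identically per axis. Zero-phase
   (forward–backward) by default, since peak times are aligned to stimulus
   events and a causal filter's group delay would bias them; a causal mode
   exists for strict reproduction of online processing.
2. *Cross-axis suppression*: S = sign(z) · max(0, |z| − |x| − |y|).
   Pure turns survive; coupled rotations (forward or curved walking)
   vanish. |S| ≤ |z| always.
3. *Peaks*: strict local extrema of S beyond ±0.001 in the trace's native
   radians-per-frame units. The threshold is stated per second in places
   but the deposited data's scale is per frame; the per-frame reading is
   the default and a units flag multiplies by the frame rate first.
   Plateaus count once at their first sample; no minimum inter-peak
   distance. The extractor is held equal to an exhaustive local-extrema
   scan in tests.
4. *Coding*: peaks during a presentation are signed +1 toward the
   more-biological stimulus of the pair given its entry side; the
   following 30 s pause keeps the same coding. Heights are reported in
   deg/s (rad/frame × fps × 180/π). Habituation peaks are dropped with a
   log entry. The stimulus angle at a peak is arctan(center offset ×
   0.248 mm / 140 mm), from the presentation's center-position profile.

Extraction order is smooth → suppress → threshold, matching the stated
processing order.

## Inference

Both models are linear mixed models (Gaussian, identity link — the
response is a continuous speed in deg/s) with a subject random intercept
and no random slopes, fitted by REML (statsmodels `MixedLM`; a
derivative-free optimizer runs first because gradient methods can stall on
a spurious zero-variance boundary with strongly clustered data).

- *speed vs angle*: |height| ~ angle × condition. The deviance-analysis
  table is term-wise Wald chi-square on the full fit; for the balanced
  designs generated here this coincides with the classical type-II table.
- *preference*: signed height ~ condition × period (during/between).

Post hoc contrasts are the estimated marginal means of each
condition-by-period cell tested against zero, with a Sidak family
adjustment — the same correction the standard marginal-means tooling
substitutes when a Tukey adjustment is requested for a non-pairwise
family. Degrees of freedom are n − p − (number of subjects), a
conservative stand-in for Satterthwaite. The single-stimulus control
(ellipse vs nothing) is summarized the same way; with one subject (as in
the original control) it degrades to per-period ordinary means, flagged by
the absent random-effect term.

Coding antisymmetry is exact: relabeling which stimulus is
"more biological" negates every signed height and hence every contrast.

## Virtual spider

The simulator is a policy model, not biomechanics. The agent walks
forward continuously (x = 0.005 rad/frame) with Gaussian wander on y and
z (3 × 10⁻⁴ rad/frame) and sensor noise (2 × 10⁻⁴ rad/frame per axis).
While stimuli are on screen, saccade events fire from a piecewise-constant
hazard in the stimulus angle: 1.2 s⁻¹ when |angle| ≥ 50° (the wide-angle
secondary-eye band where real detection concentrates) and 0.1 s⁻¹ below,
×1.5 for the high-contrast shape stimuli. Each event targets the
more-biological stimulus with probability π and rotates by the target's
current angle over 0.15 s with a cosine-bell angular-velocity profile
(smooth and unimodal; real saccade waveforms for this species are not
characterized, and nothing downstream depends on the shape). Spontaneous
saccades (random direction, 10–60° amplitude) fire at 0.05 s⁻¹ throughout,
which is what populates the between-stimulus periods. Overlapping events
queue with a 50 ms refractory gap rather than superposing. Subjects in a
study draw their π around the population value (s.d. 0.08), giving the
random intercept something real to absorb.

What this emulates: the timing structure of real trials (saccades
concentrate where stimuli cross the secondary-eye band), amplitude–angle
coupling, side coding, and between-subject heterogeneity. What it does
not: closed-loop visual feedback (the head is fixed, as in the apparatus),
gait dynamics in x/y beyond noise, heavy-tailed noise (an option exists),
or realistic saccade waveforms. Passing recovery tests therefore validates
the pipeline's bookkeeping and statistics, not any biological claim.

## Validation study sizes

The parameter-recovery study uses 20 subjects × 4 trials per preference
level π ∈ {0.3, 0.5, 0.7}, with trials simulated without the 300 s
habituation block — habituation contains no stimulus-driven events and its
peaks are dropped during coding, so omitting it changes nothing
downstream; it is simply the package's chosen problem size for the study.
Sign recovery uses 100 replicates per non-null π. The toy-walk stimulus
checks run on the full 72-frame, 27-point track, all four randomizations.
The peak-finder oracle runs on 1,000 random traces of length ≤ 1,000.

## Known limitations

- The ellipse pixel match is per-frame numeric, not closed-form; extremely
  sparse silhouettes (a few dozen pixels) can sit at the tolerance edge.
- Mixed-model degrees of freedom are approximate (see above); p-values for
  very small designs are correspondingly rough.
- The workbook reader matches columns by name heuristics; deposited files
  with unusual headers need an explicit column mapping.
- The travel profile across the screen is constant-speed within blocks by
  default; the digitized walking speed option changes stimulus angle
  timing by up to a few display frames.
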