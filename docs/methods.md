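# Methods

This note documents the models and procedures implemented in `stairgait`,
the defaults and why they were chosen, the numerical decisions, and the
limitations of the synthetic benchmark.

## Signal model and frames

A foot-worn IMU measures specific force **f** (accelerometer, in g) and body
rate **ω** (gyroscope, in dps) at 204.8 Hz. All module interfaces keep these
units; SI conversion (g → 9.81 m/s², dps → rad/s) happens only inside the
trajectory module.

The *body frame* (ml, pa, si) is defined per recording by the minimal
rotation that maps the mean accelerometer reading of pooled static windows
(≥ 1 s with ‖ω‖ < 2.5 dps) onto (0, 0, 1). Intervals are half-open, 0-based
sample ranges throughout. Degenerate alignment cases are fixed
deterministically: an anti-parallel mean acceleration rotates by π around
(1, 0, 0). A 25 ms guard margin is trimmed from each static window before
averaging because at motion onset the accelerometer reacts one sample before
the gyroscope threshold releases; without the guard a single moving sample
can bias the alignment by ~0.3 mrad, which is visible in the strapdown
integration. Left-foot data are mirrored onto the shared convention by
negating the ml axis of both accelerometer and gyroscope, making the
terminal-contact dip negative on both feet; the synthetic generator emits
left-foot data in exactly that mirrored convention, so the flip restores a
dynamically consistent signal.

Static windows are pooled per recording (per-bout pooling is available via
the function arguments); with a typical lead-in/lead-out standing phase this
is the most stable choice.

## Multiclass HMM segmentation

*Features* (51.2 Hz): decimate by 4, 4th-order Butterworth low-pass at 10 Hz
(zero-phase, so feature indices stay aligned with the raw signal for the
border mapping), then per axis the raw value and the slope of a least-squares
line in a centred 200 ms window (shrunken symmetric windows at the edges),
z-scored per walking bout with the parameters stored. Decimation precedes the
filter; the 10 Hz cut-off sits well below the 25.6 Hz post-decimation Nyquist
and doubles as the anti-alias stage. Inputs at other rates should be
resampled to 204.8 Hz first — every window length is defined in milliseconds
against this rate family.

*Sub-models*: one transition model (5 states; dense first row and first
column plus chain and last-state self-loop, i.e. any state may restart the
loop) and three stride models (20 states, strict left-right chains: self +
next transitions only). Emissions are 8-component diagonal-covariance
Gaussian mixtures, initialized per state from an equal-length partition of
each training sequence (k-means within the state pool, fixed seed). Each
training sequence is **one stride** (border to border): a left-right chain
models exactly one cycle; repetition arises only from the assembly edges.
Training runs exactly 10 Baum-Welch iterations (no early stopping); EM
preserves the structural zeros. With many mixture components on repetitive
data individual components can receive numerically zero responsibility; a
stabilized M-step resets such components to a weakly weighted broad Gaussian
and floors variances at 1e-3 (features are z-scored), so training never
produces NaNs on sparse data.

*Assembly*: the four transition matrices are joined block-diagonally and the
border edges are inserted — from **every** transition state into each stride
model's first state, from each stride model's last state into every
transition state, stride self-restarts, and level↔ascending /
level↔descending stride-to-stride edges. No direct ascending↔descending edge
exists. Each inserted edge receives the mean outgoing probability of its
source row before row renormalization; the initial state distribution is
uniform over transition states plus the three stride-start states. Decoding
is log-space Viterbi (hmmlearn); ties resolve toward the lower state index
by the implementation's argmax convention.

*Borders*: each border-edge crossing in the state path, multiplied by the
decimation factor and snapped to the gyr_ml minimum within ±150 ms (clipped
at the sequence edges). Post-filters keep strides with duration 0.4–2.5 s, a
border dip ≤ −20 dps and an in-stride swing peak ≥ +50 dps. Predicted class
labels are retained for diagnostics only; downstream stages use borders
alone, and the final stride type always comes from the spatial features.

Model persistence is a single versioned JSON file (transition matrix, state
class map, emission parameters, border edges).

## Gait events and temporal parameters

Evaluation order per stride: TC → swing max → MS → forward-acc max → IC (the
forward-acceleration search needs the MS bound). All filters are zero-phase
Butterworth (TC: 10 Hz order 5; swing/forward-acc/IC-fallback: 5 Hz order 5)
so detected extrema are not lag-shifted. "First prominent peak" is
implemented as the first local maximum with ≥ 20 dps prominence. The MS
search starts at the raw gyr_ml maximum of the stride (as printed, even
though the swing peak is detected on the filtered signal) and ties in window
energy resolve to the earliest window. The IC fallback derivative is the
central first difference of the filtered forward acceleration.

Temporal parameters are rational arithmetic on sample indices, so
swing + stance = stride holds exactly. The plausibility bounds
0.2 ≤ T_swing ≤ 1.0 s, 0.2 ≤ T_stance ≤ 1.5 s and 25 % ≤ swing/stride ≤ 60 %
are interpreted as closed intervals. Event-ordering violations flag the
stride invalid rather than aborting the bout.

## ZUPT + error-state Kalman filter + RTS

The ZUPT mask is the OR of: (i) every 150 ms window in which the deviation of
the acceleration norm from 1 g stays below 0.1 g, (ii) every 150 ms window
with RMS angular rate below 10 dps, and (iii) a 50 ms window centred on each
detected MS event ("centred" resolving the ambiguity of a window "around" the
event). All samples of a passing window are marked.

Orientation-update windows are maximal unions of 300 ms windows whose
per-axis accelerometer variance stays below 0.015 g²; updates are always
forced at the sequence start and end (best-effort statistics with a warning
when those regions are not quiet). The sequence is processed per subsequence
between update centres: attitude restarts from the gravity direction of the
10 Hz low-passed accelerometer (roll/pitch observable; yaw unobservable and
set to zero — only relative spatial parameters are needed, so no heading
correction), velocity restarts at zero (the windows are static by
construction), and position carries over so the stitched trajectory is
continuous and cumulative.

Within a subsequence the nominal state integrates open-loop: midpoint
gyroscope increments for the quaternion, trapezoidal integration for
velocity and position. The 9-dimensional error state (δp, δv, δθ with a
global small-angle attitude error) propagates with
F = [[I, I·dt, 0], [0, I, −[R f]×·dt], [0, 0, I]]; zero-velocity measurements
(H selecting δv, measurement −v_nominal) update the error state without
feeding it back. A Rauch–Tung–Striebel backward pass smooths the error-state
sequence, which is then applied once to correct the nominal trajectory —
hence no discontinuities at ZUPT onsets.

Noise defaults (the source method leaves them open; tuning against stair
height was the only option there, and these are conventional foot-mounted
MEMS figures, all exposed as arguments): gyroscope 0.02 dps/√Hz,
accelerometer 0.002 g/√Hz (converted to per-sample SDs at the sampling
rate), ZUPT measurement SD 0.01 m/s, initial attitude SD 0.5°, gravity
9.81 m/s². The world frame has z up, so stride height is positive for
ascent.

Spatial features per stride: S_d = p_d(MS_i) − p_d(MS_{i−1});
height = S_z, length = √(S_x²+S_y²), inclination = arctan(height/length) in
degrees (±90° with a flag when the length is zero). The first stride of a
sequence has no preceding MS and therefore no spatial estimate; it is
rejected downstream.

## Classification, bouts, DMOs

Thresholds are inclusive: ascending requires height ≥ +0.10 m AND inclination
≥ +6°, descending the mirrored bounds, everything else is level (ramps have
no class and count as level). Rejection: length outside 0.25–2.0 m or
invalid temporal parameters. Bout assembly chains strides with gaps ≤ 2.5 s;
same-type stair runs of ≥ 5 strides form stair bouts, and by default brief
level-walking interruptions inside the gap bound bridge a stair run without
becoming members (`merge_interruptions=False` restores the strict reading in
which any interruption terminates the run — the two published rules conflict
for the worked L_A-R_A-L_A-R_LW-L_LW-R_A-L_A sequence, so both behaviours are
available and the merging one is the default because it was introduced
explicitly to avoid splitting stair sequences at short landings). Too-short
stair runs are re-labelled level and only ever appear in level statistics.
Level bouts require two consecutive strides per foot with alternating feet.
DMO standard deviations use the population convention (divide by n).

## Synthetic data generator

The generator emulates the study conditions: three staircase geometries
(step rise/run 17.5/26.5 cm, 14.5/35 cm, 13/97 cm), steady-state double-step
strides (net rise = 2 × step rise) and single-step transition strides, three
speeds (stride duration 1.5 / 1.1 / 0.8 s; level stride length 1.0 / 1.3 /
1.5 m), a 21-task protocol grid per synthetic participant (3 staircases × 2
directions × 3 speeds + 3 combined walks), and ground-contact pressure
traces. Default sensor noise is deliberately conservative (0.01 g, 0.5 dps
white) so downstream tolerances measure the pipeline rather than the
generator; kinematic parameters vary per synthetic participant (±4 %
cadence, clearance and swing-amplitude jitter).

Per swing the sagittal pitch rate is three compactly supported polynomial
lobes — TC dip, swing peak (130 dps default), deep IC dip (≈ 2× the TC
dip) — overlapping so the gyroscope never falls silent mid-swing (otherwise
zero-velocity detectors would fire while the foot moves, which real rolling
feet never allow). The IC-dip amplitude is balanced against the sampled lobe
sums so the discretely integrated pitch returns to exactly zero each stride.
The horizontal displacement follows a smooth velocity bump spanning
10–100 % of the swing, with clearance added vertically; the sensor sits on a
lever arm (2 cm forward, 10 cm up) above the foot pivot, which produces the
realistic late-swing tangential accelerations. A small antisymmetric
"weight transfer" gyroscope wobble in early stance anchors the
minimum-energy (MS) window in late stance, and a 40 dps "termination
adjustment" one stride after the last TC closes the final stride the way a
real gait termination does.

Two consistency conventions make the generator exact at sample resolution:
the emitted accelerometer is the **discrete second difference** of the
ground-truth sensor position (plus gravity, rotated into the sensor frame),
so trapezoidal re-integration telescopes back to the trajectory; and the
ground-truth pitch is the **midpoint-rule integral** of the emitted
gyroscope, so the pipeline's orientation integration is exact as well. The
IC impact is a 9-sample position transient whose second difference is a
sharp spike with shallow flanks (zero sum and first moment), giving the
squared-forward-acceleration detector an unambiguous target, exactly as heel
impacts do in real signals. Insole loads are trapezoidal pulses spanning
exactly the ground-truth IC..TC contacts (ramp 6 samples, 95 % body weight
across toe/MTH/heel at 0.21/0.32/0.42, 0.3 kg lacing baseline per channel).

What passing the synthetic benchmark does **not** show: robustness to soft
tissue artefacts, sensor bias drift and scale errors, turning gait, handrail
use, pathological gait patterns, or staircases outside the modelled
geometries. Event ground truth for the swing and forward-acceleration maxima
is detector-relative by definition (filtered-signal argmax), so those two
events are asserted at ±50 ms while TC, IC and MS carry the strict ±2-sample
checks.

## Problem sizes used in the checks

The bundled checks run entirely on generated data: model training uses two
synthetic participants' task grids (≈ 1100 strides), the segmentation score
uses a 20-bout mixed-speed set, event timing uses ≈ 2000 noise-free strides
across six condition blocks, spatial accuracy uses a 100-stride mixed bout,
and the trajectory benchmark uses a 16-stride noise-free double-step ascent.
These sizes were chosen so each property is measured with comfortable
statistics while the whole suite remains quick to run on one CPU.
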