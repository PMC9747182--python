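# Methods

`neuropong` is a desk-scale simulator of a closed-loop multielectrode-array
(MEA) embodiment experiment: a simulated culture of spiking neurons is
"embodied" in a one-paddle Pong world through electrical stimulation
(perception) and spike readout (action), and the analysis battery used to
characterize such experiments is implemented over the simulator's logs.
This note records the model, the parameters that matter, the design
choices made where the design was genuinely open, and what the synthetic
culture does and does not show about real preparations.

## The closed loop

Every 10 ms (one 200-sample bin at the 20 kHz sampling rate) the loop runs:

1. **Culture step.** The virtual culture emits spike counts for the two
   motor regions (and, when raster recording is on, per-channel counts).
2. **Gain and decode.** Region counts are divided by a per-region
   correction factor (the region's exponentially smoothed firing rate over
   a 20 Hz target, clamped to [0.1, 10]); the larger corrected drive moves
   the paddle one step up (motor region 1) or down (motor region 2); a tie
   leaves it in place. No other weighting is applied.
3. **Game tick.** The ball advances at constant speed on the normalized
   100×100 field, reflecting specularly off the top/bottom walls and the
   opposing wall. Contact at the paddle plane within the paddle half-height
   is a hit; otherwise a miss ends the rally (except in the open-loop
   condition, where the ball bounces off the back wall and the session is
   one long rally with hits and misses still tallied).
4. **Stimulation.** During a rally the ball is encoded by place (height →
   one of 8 sites, equal bins bottom-to-top) and rate (distance from the
   opposing wall → 4–40 Hz linearly) at 75 mV. A hit triggers the
   predictable stimulus (all 8 sites, 100 Hz for 100 ms at 75 mV,
   suspending the sensory code); a miss triggers the unpredictable stimulus
   (150 mV pulses with exponential inter-pulse intervals at 5 Hz aggregate
   over random sites for 4 s, then a 4 s rest) with the game paused.
   The silent condition replaces both with matching stimulation-free gaps;
   the rest condition never stimulates.

All randomness derives from one session seed, forked into named substreams
(game, culture, feedback, bandit), so toggling one component does not
shift another's draws and a session's logs are byte-reproducible.

## The virtual culture

The culture is a deliberately minimal generative process — it makes no
biophysical claims. Its purpose is to let every closed-loop property be
attributed to the embodiment mechanics rather than model sophistication.

* **Baseline firing.** Per-channel homogeneous Poisson rates drawn
  log-normal (median 0.1 Hz, σ = 1), giving skewed rate maps and region
  sums near 30 Hz — the regime in which a 20 Hz gain target is meaningful.
  Real MEA rate maps are of this order. The two motor regions' rate sums
  are normalized to be exactly equal at `asymmetry = 0`, so the
  `asymmetry` parameter (a log-rate offset applied with opposite signs) is
  the only source of chronic motor imbalance.
* **Evoked responses.** A plastic coupling matrix `W` (stimulation site ×
  channel, clipped to [0, 1], initialized uniform [0.02, 0.05]) converts
  each pulse into expected extra spikes: `evoked_gain × W[site, channel]`
  spread over an exponential latency kernel (τ = 30 ms, unit mass).
  Stronger pulses scale linearly with amplitude. A fixed Gaussian
  footprint around each site adds a non-plastic local response in the
  sensory region so spatial analyses see realistic evoked maps.
* **Bursts.** Population events at ~0.1 Hz add a decaying rate boost to
  all channels (τ = 50 ms), mimicking the synchronized bursting of real
  cultures so that entropy and correlation analyses see synchrony.
* **Eligibility.** A covariance-style trace per (site, motor region):
  each bin, regions' counts are referenced to their own 60 s running mean,
  clipped to ±1 spike, and accumulated for every recently stimulated site
  (site recency trace saturating at 1, τ = 1 s; eligibility τ = 10 s,
  spanning a ball approach). Only sensory-labeled pulses tag sites —
  feedback bursts carry no site information. The clipping keeps population
  bursts and evoked common-mode activity (which hit both regions) from
  swamping the trace; the mean-referencing keeps chronic or slowly
  drifting rate offsets from masquerading as stimulus-locked structure.
* **Plasticity.** Feedback closes the credit window and consumes the
  eligibility:
  - *predictable* (hit): competitive Hebbian step with synaptic scaling —
    each site's total motor coupling is conserved while its motor-1/motor-2
    balance shifts by `eta_potentiate × (normalized eligibility
    difference)`, bounded per update. Whatever input→output mapping
    produced the hit is reinforced without runaway growth.
  - *unpredictable* (miss): zero-mean multiplicative noise on the motor
    couplings (scale `|W| + 0.02·w_max`; the additive floor keeps zeroed
    couplings explorable), destabilizing the mapping that produced the
    miss.
  - *silent gap*: the same perturbation at a smaller magnitude
    (`eta_silent < eta_perturb`). Applied for miss gaps only; the 100 ms
    hit gap is 2.5 % of the miss-gap duration and is treated as no-op.
  - *none*: no change. Rest sessions never stimulate, so eligibility
    decays to zero and the couplings stay fixed.

Learning therefore has two channels: a directional one (hits reinforce the
site→region balance that moved the paddle to the ball) and a selectional
one (maps that produce hits stop being perturbed — win-stay, lose-shift).
Under the stimulus condition both operate; under silent only weak
selection operates; in the open loop neither does. The observed ordering
of T2−T1 rally-length improvement (stimulus > silent ≥ no-feedback ≈ 0)
is an emergent consequence of these mechanics, not a hard-coded outcome —
but the parameter defaults were chosen so the mechanics operate in an
expressive regime (see "Parameter choices" below).

**Control profiles.** `media_only` (sparse noise detections, no evoked
response, no plasticity), `inactive_cells` (near-silent), and
`in_silico_random` (bypasses the culture entirely and emits i.i.d. motor
counts at 60 Hz per region — it moves the paddle far more than any other
profile while performing no better). `learner_mouse` is `learner_human`
with a lower evoked gain and potentiation rate.

## Signal chain

Voltage frames (µV, 20 kHz) pass through a causal 2nd-order Bessel
high-pass (100 Hz cutoff) per channel; the absolute value is smoothed by a
1st-order Bessel low-pass (1 Hz) to track the noise envelope; a spike is a
crossing of `k ×` envelope (default k = 6), stamped at the in-crossing
peak with its signed amplitude, with a 1 ms per-channel refractory hold
and a 2 s envelope warm-up during which no events are emitted. Filters are
discretized by bilinear transform with pre-warping at the cutoff
(magnitude-normalized), and run statefully so streamed chunks equal batch
filtering to float tolerance. The detector is scale-free: rescaling the
input voltage leaves event times unchanged.

Blinding: command-count mode drops every event within a configurable
window (default 100 samples = 5 ms) after any logged stimulation command,
on all channels; the older consensus mode (drop frames with more than 15
simultaneous detections above 75 mV) is retained for comparison but is
known to be the weaker scheme.

## Motor layouts and the bandit

The 1024 routed channels live on a 32×32 logical grid. Four ~100-channel
corner blocks form the motor regions (the right-hand blocks give one
electrode back to the sensory region so the split is exactly 626 sensory
+ 398 motor); five preset configurations counterbalance the block→region
assignment, with the diagonal split (configuration 3) as default. The 8
stimulation sites sit on the vertical midline of the sensory band,
bottom-to-top in place-code order. The exact geometry is a documented
configuration choice; only the 626/398/8 structure is fixed.

The EXP3 bandit selects a layout per rally. Rally score s maps to loss
`L = min(s, 10)/10 − 1 ∈ [−1, 0]` (an ace costs −1; ten or more hits cost
0); arms are drawn from `(1−γ)·w/Σw + γ/K` (γ = 0.1, exploration floor
γ/K); the chosen arm's weight is multiplied by `exp(γ·r̂/K)` with the
importance-weighted reward `r̂ = (L+1)/p`. Weights renormalize before
overflow. Bandit state is per-session, with the trace logged per rally.

## Analysis battery

* **Rally metrics**: average rally length (total hits / rallies), aces
  (zero-hit rallies), long rallies (strictly more than 3 hits), paddle
  distance. T1 = minutes 0–5, T2 = minutes 6–20 by rally end time; minute
  5–6 belongs to neither; shorter sessions scale the boundaries with a
  warning. Open-loop sessions are split on per-contact pseudo-rallies.
* **Clustered binary entropy**: 18 rectangular clusters of 50 neighbouring
  electrodes (a 6×3 tiling of 5×10 blocks over 900 of the 1024 channels);
  per cluster and 100 ms window, `p` = fraction of the 50 electrodes with
  ≥1 spike and `H_b(p) = −p log₂ p − (1−p) log₂(1−p)` with 0·log 0 = 0.
  Normalized entropy divides by the spike count over the same windows
  (zero-count windows → 0). Pre/post-feedback contrasts use 4 s windows
  around each feedback onset (matching the unpredictable-stimulus
  duration), skipping onsets without full windows.
* **Centre of activity (CA)**: firing-weighted centroid of electrode
  positions relative to the bottom-left corner. The plasticity score is
  the mean Euclidean distance of 5-min-window mean CAs (1 s CA bins)
  during gameplay to the centroid of the 10-min rest reference, compared
  with the rest windows' distance to their own centroid. Note the rest
  score is biased small by roughly (CA spread)/√(bins per window) because
  its centroid is estimated from the same data; null calibrations should
  compare like roles across independent draws.
* **DCT modes**: orthonormal 2-D type-II DCT of the 32×32 activity image;
  reported values are |coefficient| / mean activity for (u, v) ∈ {0,1,2}²,
  with u the vertical (row) and v the horizontal (column) frequency; the
  asymmetry modes are (0,1), (0,2), (1,0), (2,0). Mean-normalization makes
  the values invariant to rescaling the image.
* **Lagged cross-correlation**: Pearson correlation of 100 ms-binned
  counts at one bin of lag (sensory→motor); a Spearman variant serves the
  motor–motor synchrony analysis. Constant series are an error, not a 0.
* **Exclusive motor events**: fraction of 1 s bins in which above-noise
  events (amplitude below −5 µV) occur in exactly one motor region. With
  the default culture's ~30 Hz region rates every bin contains both
  regions, so this fraction is 0 for learner sessions; it discriminates
  sparser preparations.
* **Symmetry deviation**: z-score of a session's |motor1 − motor2|
  activity imbalance against a population of sessions.
* Cross-session summaries drop |Z| > 3.29 outliers; the first 10 s of
  stimulated gameplay sessions are excluded from raster statistics by
  default (toggleable).

## Parameter choices

| parameter | default | why |
|---|---|---|
| ball speed | field width / 6 s | unstated by the system constants; slow enough that a 1 unit/tick paddle can traverse the field during one approach |
| paddle half-height | 12.5 units (25 % of field) | unstated; makes chance interception ≈ 25–30 % |
| serve cone | ±60° about horizontal | excludes near-vertical serves that would never terminate |
| gain EMA τ | 60 s | corrects chronic imbalance; a fast EMA (∼10 s) empirically chases within-rally fluctuations and drives the paddle against the recent firing trend |
| gain clamp | [0.1, 10] | bounds the correction; at near-empty bins residual command skew remains even after correction (the discrete comparison is not symmetrizable by a multiplier) |
| evoked gain (learner) | 1.0 spikes/pulse per unit coupling | puts a fully laterally-sharpened site (total coupling ≈ 14) at ≈ 5–6 extra spikes/bin at 40 Hz — decisively expressible over the ≈ 0.7 spikes/bin baseline |
| η_potentiate / η_perturb / η_silent | 0.3 / 0.25 / 0.08 | bounded balance shift per hit; perturbation large enough to explore between hits; silent gap deliberately weaker |
| blinding window | 100 samples (5 ms) | covers the rendered artifact span |
| refractory / warm-up | 1 ms / 2 s | double-count prevention; 1 Hz envelope settling |
| session duration | 20 min (≤ 90 min hard cap) | matches the T1/T2 analysis frame; longer testing is not tolerated by real cultures |

## What the synthetic culture shows — and does not

Passing the closed-loop suites demonstrates that the *embodiment
mechanics* (coding, decoding, gain, feedback scheduling, logging,
analysis) behave as specified, and that the feedback protocol can steer a
plastic system with these update rules. It does not demonstrate anything
about biological neurons: the culture has no membrane dynamics, no
connectivity beyond an 8×1024 linear coupling, and its plasticity rules
were designed so that predictable/unpredictable feedback have reinforcing
and destabilizing effects respectively. Quantitative group statistics
from living-culture recordings (t-values, effect sizes) are out of reach
by construction and are not attempted.

Known limitations worth flagging:

* The asymmetry → performance relationship is non-monotone at moderate
  asymmetry: a pinned paddle still "corner-camps" for ≈ 0.4 average rally
  length, so the degradation (negative rank correlation over an asymmetry
  sweep) is real but weak in this model, whereas real preparations showed
  asymmetry beyond ≈ 1 SD abolishing performance.
* The silent condition's advantage over the open loop is small at 20
  simulated minutes (weak-perturbation selection is slow); the stimulus
  condition's advantage is large and consistent.
* Fast (region-count) session mode and raster-recording mode consume the
  culture's random stream differently, so the two modes of the same seed
  are internally consistent but not cross-identical.

## Problem sizes used in the shipped checks

Whole-session simulations run 20 simulated minutes (120 000 ticks) for
learning contrasts (20 seeds per learner condition, 10 per control), 10–11
minutes for raster-statistics sessions, and 30 s × 32–64 channels for
voltage-level detection fixtures. These sizes give stable means for every
reported quantity while keeping a full run in minutes on one CPU.
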