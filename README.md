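# neuropong

A desk-scale simulator of closed-loop MEA embodiment: a virtual spiking
culture plays one-paddle Pong through electrical stimulation and spike
readout, together with the analysis statistics used to characterize such
experiments.

Cultured neurons on a high-density multielectrode array can be "embodied"
in a game world: the ball's position is written into the culture as
electrical stimulation (place code over 8 sites for height, 4–40 Hz rate
code for distance), spikes detected in two predefined motor regions move
the paddle up or down, and the outcome of each rally is fed back as either
a predictable stimulus (synchronous 100 Hz burst after a hit) or an
unpredictable one (random-site 150 mV pulses after a miss). `neuropong`
re-creates that entire loop in software — game world, stimulus coding,
Bessel-filter spike detection with stimulation blinding, gain-normalized
motor decoding, an EXP3 bandit over motor-layout configurations — driven
by a configurable generative culture model with feedback-dependent
plasticity, plus non-learning control profiles (media-only noise, inactive
cells, a random in-silico paddle driver). It is aimed at people studying
closed-loop electrophysiology protocols who want a reproducible synthetic
testbed for the full software path.

## The loop in brief

Every 10 ms bin (200 samples at 20 kHz):

```
culture spikes ── gain-corrected region comparison ── paddle command
      ▲                                                     │
      └── place/rate-coded stimulation ◄── Pong game tick ◄─┘
                   + hit/miss feedback
```

Decoding is deliberately minimal: motor-region spike counts are divided by
a per-region correction factor (smoothed rate over a 20 Hz target) and
compared; the winner moves the paddle one step. Rally statistics follow
the standard definitions: average rally length = total hits / rallies,
aces = zero-hit rallies, long rallies = strictly more than 3 hits, with
the learning contrast taken between minutes 0–5 (T1) and 6–20 (T2) of a
session.

The analysis battery includes clustered binary entropy
(H_b(p) = −p log₂ p − (1−p) log₂(1−p) over 18 clusters of 50 electrodes in
100 ms windows), centre-of-activity functional plasticity, low-order 2-D
DCT spatial asymmetry modes, lagged cross-correlations, exclusive
motor-region events, and motor symmetry deviation. See
[docs/methods.md](docs/methods.md) for the model and every default.

## Worked example

```python
from neuropong.session_io import SessionConfig, run_session
from neuropong.metrics_analysis import split_timepoints
from neuropong.game_world import summarize_rallies

res = run_session(SessionConfig(condition="stimulus",
                                profile="learner_human", seed=9))
print(res.summary)
t1, t2 = split_timepoints(res.records, res.duration_ticks)
print(summarize_rallies(t1).average_rally_length,
      summarize_rallies(t2).average_rally_length)
```

prints

```
GameplaySummary(n_rallies=31, average_rally_length=1.548, aces=17,
                long_rallies=2, paddle_distance=35096.5)
0.429 3.900
```

A 20-minute closed-loop session under the stimulus condition produced 31
rallies averaging 1.55 hits each. The T1→T2 contrast (0.43 → 3.90 hits
per rally) is the within-session learning effect: by the second timepoint
the culture's stimulation-site→motor-region couplings have reorganized to
intercept the ball. The same seed under `condition="no_feedback"` shows no
such improvement, and the control profiles (`media_only`,
`inactive_cells`, `in_silico_random`) never improve regardless of
condition. Individual sessions vary considerably — learning is assessed
over seed batches (see `neuropong.session_io.run_batch`).

The same functionality is available from a shell:

```bash
neuropong simulate --config session.yaml --seed 9 --out runs/s9
neuropong analyze  --session runs/s9
neuropong replay   --session runs/s9      # verifies log → report integrity
neuropong batch    --plan plan.yaml --out results.csv
```

Sessions write deterministic CSV/JSON logs (rallies, events, stimulation,
bandit trace) plus an optional binary spike log with a JSON sidecar; the
same seed always produces byte-identical logs.

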