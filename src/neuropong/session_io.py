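"""Session orchestration, deterministic logging, and re-analysis.

A session couples the virtual culture to the game world through the
sensory-coding, motor-decoding and feedback stages, tick by tick:

    culture.step -> bin counts -> gain update -> decode -> game.tick
        -> sensory / feedback stimulation plans -> culture plasticity

Everything is driven by a single seed, forked into named substreams
(game, culture, feedback, bandit) so toggling one component never shifts
another's draws; two runs of the same config are byte-identical on disk.

Conditions: ``stimulus`` delivers the full sensory + predictable /
unpredictable feedback protocol; ``silent`` replaces the feedback stimuli
with matching stimulation-free gaps; ``no_feedback`` plays the sensory
stimulus open loop (one rally spans the session); ``rest`` runs the loop
with the paddle driven by spontaneous activity and no stimulation at all.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import metrics_analysis as ma
from .game_world import (GameConfig, GameEvent, GameplaySummary, PongGame,
                         RallyRecord, summarize_rallies)
from .layout_bandit import BanditState, rally_loss, select_arm, update
from .motor_decoding import (DEFAULT_LAYOUT_ID, LAYOUT_IDS, GainState,
                             decode, make_layout, update_gain)
from .sensory_coding import (SAMPLES_PER_TICK, FeedbackCondition,
                             SensorySequencer, StimPlan, StimPulse,
                             plan_feedback)
from .signal_chain import SpikeEvent, read_spike_log, write_spike_log
from .virtual_culture import VirtualCulture, get_profile

MAX_DURATION_MIN = 90  # cultures did not tolerate longer testing times

__all__ = ["SessionConfig", "SessionResult", "run_session", "rest_normalize",
           "analyze_session", "replay", "run_batch", "write_session",
           "load_session"]


@dataclass(frozen=True)
class SessionConfig:
    condition: str = "stimulus"
    profile: str = "learner_human"
    seed: int = 0
    duration_min: float = 20.0
    layout_id: int = DEFAULT_LAYOUT_ID
    use_bandit: bool = False
    record_spikes: bool = False
    asymmetry: Optional[float] = None
    exclude_first_10s: bool = True

    def __post_init__(self) -> None:
        FeedbackCondition(self.condition)
        if self.duration_min <= 0 or self.duration_min > MAX_DURATION_MIN:
            raise ValueError(f"duration must lie in (0, {MAX_DURATION_MIN}] min")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.layout_id not in LAYOUT_IDS:
            raise ValueError(f"layout_id must be one of {LAYOUT_IDS}")


@dataclass
class SessionResult:
    config: SessionConfig
    records: List[RallyRecord]
    events: List[GameEvent]
    summary: GameplaySummary
    stim_log: List[Tuple[int, int, float, str]]  # sample, site, mV, label
    feedback_onsets: List[int]  # sample index of each feedback window start
    bandit_trace: List[Tuple[int, int, int, float, float]]
    spike_events: Optional[List[SpikeEvent]]
    duration_ticks: int


def _rng_streams(seed: int) -> Dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("game", "culture", "feedback", "bandit")
    return {name: np.random.default_rng(child)
            for name, child in zip(names, root.spawn(len(names)))}


def run_session(config: SessionConfig,
                game_config: Optional[GameConfig] = None) -> SessionResult:
    """Execute the closed loop for the configured duration."""
    condition = FeedbackCondition(config.condition)
    rngs = _rng_streams(config.seed)
    if game_config is None:
        game_config = GameConfig(
            no_feedback=(condition is FeedbackCondition.NO_FEEDBACK))
    elif condition is FeedbackCondition.NO_FEEDBACK and not game_config.no_feedback:
        game_config = dataclasses.replace(game_config, no_feedback=True)

    layout = make_layout(config.layout_id)
    overrides = {} if config.asymmetry is None else {"asymmetry": config.asymmetry}
    profile = get_profile(config.profile, **overrides)
    culture = VirtualCulture(profile, layout, rngs["culture"])
    game = PongGame(game_config, rngs["game"], layout_id=layout.layout_id)
    sequencer = SensorySequencer(game_config.field_width,
                                 game_config.field_height)
    gain = GainState()
    bandit = BanditState(n_arms=len(LAYOUT_IDS)) if config.use_bandit else None

    n_ticks = int(round(config.duration_min * 60 * game_config.ticks_per_second))
    stimulated = condition in (FeedbackCondition.STIMULUS,
                               FeedbackCondition.SILENT,
                               FeedbackCondition.NO_FEEDBACK)

    stim_log: List[Tuple[int, int, float, str]] = []
    feedback_onsets: List[int] = []
    bandit_trace: List[Tuple[int, int, int, float, float]] = []
    spike_events: Optional[List[SpikeEvent]] = [] if config.record_spikes else None

    pause_until = -1          # game frozen through this tick (miss feedback)
    suppress_sensory_until = -1  # predictable window replaces sensory coding
    pending_feedback: Dict[int, List[StimPulse]] = {}

    def schedule(plan: StimPlan) -> None:
        for pulse in plan.pulses:
            tick_of = pulse.start_sample // SAMPLES_PER_TICK
            pending_feedback.setdefault(tick_of, []).append(pulse)
            stim_log.append((pulse.start_sample, pulse.site,
                             pulse.amplitude_mv, plan.label))

    for tick in range(n_ticks):
        sample = tick * SAMPLES_PER_TICK
        pulses: List[StimPulse] = pending_feedback.pop(tick, [])
        in_pause = tick <= pause_until

        if (stimulated and not in_pause and tick > suppress_sensory_until):
            plan = sequencer.plan_sensory(game.ball.x, game.ball.y, sample)
            for pulse in plan.pulses:
                stim_log.append((pulse.start_sample, pulse.site,
                                 pulse.amplitude_mv, plan.label))
            pulses.extend(plan.pulses)

        m1, m2, chan = culture.step(pulses, record=config.record_spikes)
        if spike_events is not None and chan is not None:
            spike_events.extend(culture.counts_to_events(chan, sample))
        gain = update_gain(gain, (m1, m2))

        if in_pause:
            continue

        command = decode((m1, m2), gain)
        events = game.tick(command.direction)

        for ev in events:
            if ev.kind == "paddle_hit":
                plan = plan_feedback("paddle_hit", condition, rngs["feedback"],
                                     start_sample=sample)
                if plan.duration_samples:
                    suppress_sensory_until = tick + plan.duration_samples \
                        // SAMPLES_PER_TICK
                    feedback_onsets.append(sample)
                schedule(plan)
                if plan.label == "predictable":
                    culture.apply_feedback("predictable")
            elif ev.kind == "miss" and condition in (FeedbackCondition.STIMULUS,
                                                     FeedbackCondition.SILENT):
                plan = plan_feedback("miss", condition, rngs["feedback"],
                                     start_sample=sample)
                pause_until = tick + plan.duration_samples // SAMPLES_PER_TICK
                feedback_onsets.append(sample)
                schedule(plan)
                culture.apply_feedback("unpredictable"
                                       if plan.label == "unpredictable"
                                       else "silent_gap")
                if bandit is not None:
                    rally = game.records[-1]
                    loss = rally_loss(rally.hits)
                    prob = bandit.probabilities()[rally.layout_id]
                    bandit_trace.append((len(bandit_trace), rally.layout_id,
                                         rally.hits, loss, float(prob)))
                    bandit = update(bandit, rally.layout_id, loss)
                    arm = select_arm(bandit, rngs["bandit"])
                    game.set_layout(arm)
                    culture.set_layout(make_layout(arm))

    records = game.finalize()
    summary = summarize_rallies(records, paddle_distance=game.paddle_distance,
                                long_rally_threshold=game_config.long_rally_threshold)
    return SessionResult(config=config, records=records, events=game.events,
                         summary=summary, stim_log=stim_log,
                         feedback_onsets=feedback_onsets,
                         bandit_trace=bandit_trace,
                         spike_events=spike_events, duration_ticks=n_ticks)


# -- normalization & analysis ---------------------------------------------

def rest_normalize(gameplay: GameplaySummary, rest: GameplaySummary
                   ) -> Dict[str, float]:
    """Each gameplay metric as percent change over the matched rest value;
    metrics with a zero rest denominator are omitted with a warning."""
    out: Dict[str, float] = {}
    for name in ("average_rally_length", "aces", "long_rallies",
                 "paddle_distance"):
        g, r = getattr(gameplay, name), getattr(rest, name)
        if r == 0:
            warnings.warn(f"rest value of {name} is zero; metric omitted",
                          stacklevel=2)
            continue
        out[name] = 100.0 * (g - r) / r
    return out


def analyze_session(result: SessionResult,
                    rest_result: Optional[SessionResult] = None
                    ) -> Dict[str, float]:
    """Per-session analysis report.

    Gameplay metrics are always present; raster statistics require the
    session to have recorded spikes, and the CA plasticity pair requires
    a matching rest recording.  The first 10 s of stimulated sessions are
    excluded from raster statistics when the config asks for it.
    """
    s = result.summary
    report: Dict[str, float] = {
        "avg_rally_length": s.average_rally_length,
        "aces": float(s.aces),
        "long_rallies": float(s.long_rallies),
        "paddle_distance": s.paddle_distance,
        "n_rallies": float(s.n_rallies),
    }
    if result.spike_events is None:
        return report

    layout = make_layout(result.config.layout_id)
    duration = result.duration_ticks * SAMPLES_PER_TICK
    start = 0
    if result.config.exclude_first_10s and \
            result.config.condition != FeedbackCondition.REST.value:
        start = 10 * 20_000
    ch, sm, amp = ma._as_arrays(result.spike_events)
    keep = sm >= start
    evs = (ch[keep], sm[keep] - start, amp[keep])
    dur = duration - start

    series = ma.clustered_entropy(evs, duration_samples=dur)
    report["mean_entropy"] = series.mean
    prepost = ma.pre_post_feedback_entropy(
        evs, [f - start for f in result.feedback_onsets], dur)
    for key in ("pre", "post"):
        vals = prepost[f"{key}_normalized"]
        report[f"normalized_entropy_{key}"] = float(vals.mean()) if len(vals) \
            else float("nan")

    img = ma.activity_image(evs)
    if img.mean() > 0:
        modes = ma.dct_modes(img)
        for (u, v) in ma.ASYMMETRY_MODES:
            report[f"dct_{u}{v}"] = modes[(u, v)]

    counts = ma.region_count_series(evs, layout, dur)
    for name, key in (("motor1", "xcorr_m1"), ("motor2", "xcorr_m2")):
        try:
            report[key] = ma.lagged_cross_correlation(counts["sensory"],
                                                      counts[name])
        except ValueError:
            report[key] = float("nan")
    report["exclusive_fraction"] = ma.exclusive_motor_events(evs, layout, dur)

    if rest_result is not None and rest_result.spike_events is not None:
        game_ca = ma.ca_series(evs, dur)
        rest_dur = rest_result.duration_ticks * SAMPLES_PER_TICK
        rest_ca = ma.ca_series(ma._as_arrays(rest_result.spike_events),
                               rest_dur)
        try:
            plast = ma.plasticity_score(game_ca, rest_ca)
            report["ca_plasticity_gameplay"] = plast.gameplay_score
            report["ca_plasticity_rest"] = plast.rest_score
        except ValueError:
            pass
    return report


# -- on-disk logs ----------------------------------------------------------

def write_session(result: SessionResult, out_dir,
                  report: Optional[Dict[str, float]] = None) -> Path:
    """Write the full deterministic log set for a session."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(result.config)
    (out / "config.json").write_text(json.dumps(cfg, sort_keys=True))

    rows = [{"rally_index": r.rally_index, "start_tick": r.start_tick,
             "end_tick": r.end_tick, "hits": r.hits,
             "layout_id": r.layout_id, "condition": result.config.condition,
             "outcome": "ace" if r.hits == 0 else "rally"}
            for r in result.records]
    pd.DataFrame(rows).to_csv(out / "rallies.csv", index=False)
    pd.DataFrame([{"kind": e.kind, "tick": e.tick} for e in result.events]
                 ).to_csv(out / "events.csv", index=False)
    pd.DataFrame(result.stim_log,
                 columns=["sample", "site", "amplitude_mV", "label"]
                 ).to_csv(out / "stimulation.csv", index=False)
    pd.DataFrame(result.bandit_trace,
                 columns=["round", "arm", "score", "loss", "prob_of_chosen"]
                 ).to_csv(out / "bandit.csv", index=False)
    json.dump({"feedback_onsets": result.feedback_onsets,
               "duration_ticks": result.duration_ticks,
               "paddle_distance": result.summary.paddle_distance},
              open(out / "session.json", "w"), sort_keys=True)
    if result.spike_events is not None:
        write_spike_log(out / "spikes.bin", result.spike_events)
    if report is not None:
        pd.DataFrame([report]).to_csv(out / "report.csv", index=False)
        (out / "report_manifest.json").write_text(json.dumps(
            {"exclude_first_10s": result.config.exclude_first_10s,
             "entropy_window_s": ma.ENTROPY_WINDOW_S,
             "ca_bin_s": ma.CA_BIN_S,
             "exclusive_bin_s": ma.EXCLUSIVE_BIN_S}, sort_keys=True))
    return out


def load_session(session_dir) -> SessionResult:
    """Rebuild a SessionResult from its on-disk logs."""
    d = Path(session_dir)
    cfg = SessionConfig(**json.loads((d / "config.json").read_text()))
    meta = json.loads((d / "session.json").read_text())
    rallies = pd.read_csv(d / "rallies.csv")
    records = [RallyRecord(rally_index=int(r.rally_index), hits=int(r.hits),
                           start_tick=int(r.start_tick),
                           end_tick=int(r.end_tick),
                           layout_id=int(r.layout_id))
               for r in rallies.itertuples()]
    events = [GameEvent(kind=str(r.kind), tick=int(r.tick))
              for r in pd.read_csv(d / "events.csv").itertuples()]
    stim = [tuple(r) for r in pd.read_csv(d / "stimulation.csv"
                                          ).itertuples(index=False)]
    bandit = [tuple(r) for r in pd.read_csv(d / "bandit.csv"
                                            ).itertuples(index=False)]
    spikes = None
    if (d / "spikes.bin").exists():
        spikes, _ = read_spike_log(d / "spikes.bin")
    summary = summarize_rallies(records,
                                paddle_distance=meta["paddle_distance"])
    return SessionResult(config=cfg, records=records, events=events,
                         summary=summary, stim_log=stim,
                         feedback_onsets=list(meta["feedback_onsets"]),
                         bandit_trace=bandit, spike_events=spikes,
                         duration_ticks=int(meta["duration_ticks"]))


def replay(session_dir) -> Dict[str, float]:
    """Re-run the analysis from the stored logs and check it reproduces
    the stored report exactly."""
    d = Path(session_dir)
    result = load_session(d)
    report = analyze_session(result)
    stored_path = d / "report.csv"
    if stored_path.exists():
        stored = pd.read_csv(stored_path,
                             float_precision="round_trip").iloc[0].to_dict()
        for key, val in report.items():
            ref = stored.get(key)
            if ref is None or (not (np.isnan(val) and np.isnan(ref))
                               and val != ref):
                raise ValueError(f"replay mismatch on {key}: {val!r} != {ref!r}")
    return report


# -- batch harness ---------------------------------------------------------

def run_batch(conditions, n_sessions: int, base_seed: int,
              profile: str = "learner_human", duration_min: float = 20.0,
              **config_kwargs) -> pd.DataFrame:
    """Run a conditions x sessions grid and return a tidy long table of
    per-session T1/T2 gameplay metrics (the three-condition experiment
    harness)."""
    rows = []
    for condition in conditions:
        for i in range(n_sessions):
            cfg = SessionConfig(condition=condition, profile=profile,
                                seed=base_seed + i,
                                duration_min=duration_min, **config_kwargs)
            res = run_session(cfg)
            recs = ma.event_rally_records(res.events) \
                if condition == "no_feedback" else res.records
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t1, t2 = ma.split_timepoints(recs, res.duration_ticks)
            lrt = GameConfig().long_rally_threshold
            for label, recs in (("T1", t1), ("T2", t2), ("all", res.records)):
                if not recs:
                    continue
                s = summarize_rallies(recs, long_rally_threshold=lrt)
                rows.append({"condition": condition, "profile": profile,
                             "session": i, "seed": cfg.seed,
                             "timepoint": label,
                             "avg_rally_length": s.average_rally_length,
                             "aces": s.aces, "long_rallies": s.long_rallies,
                             "n_rallies": s.n_rallies,
                             "paddle_distance": res.summary.paddle_distance})
    return pd.DataFrame(rows)
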