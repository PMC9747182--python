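"""Stimulus coding: game state -> timed biphasic pulse plans.

Ball position is conveyed to the culture through a combined place and rate
code over 8 stimulation sites embedded in the sensory region: the ball's
height selects the site (equal-width bins bottom-to-top by default) and
the ball's distance from the opposing wall sets the pulse frequency,
linear from 4 Hz (farthest) to 40 Hz (at the paddle wall), at 75 mV.

Rally outcomes map to feedback plans by condition:

* ``stimulus`` + miss  -> unpredictable: 4 s of 150 mV pulses at random
  sites with exponential inter-pulse intervals (5 Hz aggregate), then a
  4 s rest, before the next serve.
* ``stimulus`` + hit   -> predictable: all 8 sites synchronously at
  100 Hz for 100 ms at 75 mV, replacing sensory stimulation meanwhile.
* ``silent``           -> zero-pulse plans spanning the matching windows
  (the predictable hit stimulus is likewise withheld).
* ``no_feedback``      -> empty plan; the game is never interrupted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List

import numpy as np

SAMPLE_RATE = 20_000  # samples per second
SAMPLES_PER_TICK = 200  # 10 ms game bin

N_STIM_SITES = 8
SENSORY_AMPLITUDE_MV = 75.0
UNPREDICTABLE_AMPLITUDE_MV = 150.0
UNPREDICTABLE_RATE_HZ = 5.0
UNPREDICTABLE_DURATION_S = 4.0
UNPREDICTABLE_REST_S = 4.0
PREDICTABLE_RATE_HZ = 100.0
PREDICTABLE_DURATION_S = 0.1
RATE_CODE_MIN_HZ = 4.0
RATE_CODE_MAX_HZ = 40.0
DEFAULT_PHASE_DURATION_US = 200.0

__all__ = [
    "StimPulse", "StimPlan", "FeedbackCondition",
    "place_code", "rate_code", "SensorySequencer", "plan_feedback",
]


class FeedbackCondition(str, enum.Enum):
    STIMULUS = "stimulus"
    SILENT = "silent"
    NO_FEEDBACK = "no_feedback"
    REST = "rest"


@dataclass(frozen=True)
class StimPulse:
    """One square biphasic pulse (positive then negative phase)."""

    site: int  # stimulation site 0-7
    start_sample: int
    amplitude_mv: float
    phase_duration_us: float = DEFAULT_PHASE_DURATION_US
    label: str = "sensory"

    def __post_init__(self) -> None:
        if not 0 <= self.site < N_STIM_SITES:
            raise ValueError(f"site must be in [0, {N_STIM_SITES})")


@dataclass
class StimPlan:
    """Time-ordered pulse schedule with the window it occupies.

    ``duration_samples`` covers silent gaps too: a silent-feedback plan
    has zero pulses but a non-zero span during which the game is paused
    (miss) or sensory coding suspended (hit).
    """

    pulses: List[StimPulse] = field(default_factory=list)
    label: str = "none"  # sensory | predictable | unpredictable | silent_gap | none
    start_sample: int = 0
    duration_samples: int = 0

    def __post_init__(self) -> None:
        starts = [p.start_sample for p in self.pulses]
        if starts != sorted(starts):
            raise ValueError("pulses must be sorted by start_sample")
        if self.label in ("silent_gap", "none") and self.pulses:
            raise ValueError(f"{self.label} plan must contain no pulses")

    @property
    def end_sample(self) -> int:
        return self.start_sample + self.duration_samples


def place_code(ball_y: float, field_height: float,
               n_sites: int = N_STIM_SITES, invert: bool = False) -> int:
    """Map ball height to a stimulation site via equal-width bins.

    ``site = floor(ball_y / field_height * n_sites)``, clamped to the top
    site at the upper edge.  ``invert=True`` flips the bottom-to-top site
    order for arrays wired the other way.
    """
    if not 0 <= ball_y <= field_height:
        raise ValueError("ball_y outside the field")
    site = min(int(ball_y / field_height * n_sites), n_sites - 1)
    return (n_sites - 1 - site) if invert else site


def rate_code(distance_from_opposing_wall: float, field_width: float) -> float:
    """Pulse frequency in Hz, linear from 4 Hz at the opposing wall to
    40 Hz at the paddle wall."""
    if not 0 <= distance_from_opposing_wall <= field_width:
        raise ValueError("distance outside the field")
    span = RATE_CODE_MAX_HZ - RATE_CODE_MIN_HZ
    return RATE_CODE_MIN_HZ + span * (distance_from_opposing_wall / field_width)


class SensorySequencer:
    """Stateful pulse scheduler for the place/rate sensory stimulus.

    Re-evaluated every 10 ms game bin; the phase of the pulse train is
    carried across re-evaluations so crossing a place-code bin boundary or
    a rate change never doubles up pulses.
    """

    def __init__(self, field_width: float, field_height: float,
                 amplitude_mv: float = SENSORY_AMPLITUDE_MV,
                 invert_sites: bool = False) -> None:
        self.field_width = field_width
        self.field_height = field_height
        self.amplitude_mv = amplitude_mv
        self.invert_sites = invert_sites
        self._next_pulse: float = 0.0  # sample index of the next due pulse

    def reset_phase(self, clock_sample: int) -> None:
        self._next_pulse = float(clock_sample)

    def plan_sensory(self, ball_x: float, ball_y: float, clock_sample: int,
                     active: bool = True,
                     window_samples: int = SAMPLES_PER_TICK) -> StimPlan:
        """Pulses due in ``[clock_sample, clock_sample + window)`` for the
        current ball position; empty when no rally is active."""
        if not active:
            return StimPlan(label="none", start_sample=clock_sample,
                            duration_samples=window_samples)
        freq = rate_code(ball_x, self.field_width)
        site = place_code(ball_y, self.field_height, invert=self.invert_sites)
        interval = SAMPLE_RATE / freq
        end = clock_sample + window_samples
        if self._next_pulse < clock_sample:
            self._next_pulse = float(clock_sample)
        pulses = []
        while self._next_pulse < end:
            pulses.append(StimPulse(site=site,
                                    start_sample=int(round(self._next_pulse)),
                                    amplitude_mv=self.amplitude_mv))
            self._next_pulse += interval
        return StimPlan(pulses=pulses, label="sensory",
                        start_sample=clock_sample,
                        duration_samples=window_samples)


def plan_feedback(event_kind: str, condition: FeedbackCondition,
                  rng: np.random.Generator, start_sample: int = 0,
                  rest_duration_s: float = UNPREDICTABLE_REST_S) -> StimPlan:
    """Feedback plan for a ``paddle_hit`` or ``miss`` under a condition.

    See the module docstring for the per-condition protocols.  ``rest``
    sessions never deliver stimulation, so they return empty plans.
    """
    if event_kind not in ("paddle_hit", "miss"):
        raise ValueError("feedback follows only paddle_hit or miss events")
    condition = FeedbackCondition(condition)

    if condition in (FeedbackCondition.NO_FEEDBACK, FeedbackCondition.REST):
        return StimPlan(label="none", start_sample=start_sample)

    if event_kind == "miss":
        stim_span = int(UNPREDICTABLE_DURATION_S * SAMPLE_RATE)
        total_span = stim_span + int(rest_duration_s * SAMPLE_RATE)
        if condition is FeedbackCondition.SILENT:
            return StimPlan(label="silent_gap", start_sample=start_sample,
                            duration_samples=total_span)
        # unpredictable: random sites, exponential inter-pulse intervals
        mean_interval = SAMPLE_RATE / UNPREDICTABLE_RATE_HZ
        pulses = []
        t = float(start_sample) + rng.exponential(mean_interval)
        while t < start_sample + stim_span:
            site = int(rng.integers(0, N_STIM_SITES))
            pulses.append(StimPulse(site=site, start_sample=int(t),
                                    amplitude_mv=UNPREDICTABLE_AMPLITUDE_MV,
                                    label="unpredictable"))
            t += rng.exponential(mean_interval)
        return StimPlan(pulses=pulses, label="unpredictable",
                        start_sample=start_sample, duration_samples=total_span)

    # paddle_hit
    span = int(PREDICTABLE_DURATION_S * SAMPLE_RATE)
    if condition is FeedbackCondition.SILENT:
        return StimPlan(label="silent_gap", start_sample=start_sample,
                        duration_samples=span)
    period = int(SAMPLE_RATE / PREDICTABLE_RATE_HZ)
    pulses = [StimPulse(site=s, start_sample=start_sample + i * period,
                        amplitude_mv=SENSORY_AMPLITUDE_MV,
                        label="predictable")
              for i in range(int(PREDICTABLE_DURATION_S * PREDICTABLE_RATE_HZ))
              for s in range(N_STIM_SITES)]
    return StimPlan(pulses=pulses, label="predictable",
                    start_sample=start_sample, duration_samples=span)
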