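"""Single-paddle Pong world advanced once per 10 ms spike-count bin.

The play field is a normalized ``field_width x field_height`` rectangle
(default 100 x 100 units, origin bottom-left, y increasing upward).  The
ball travels at constant speed, reflecting specularly off the top/bottom
walls and off the wall opposing the paddle.  The paddle sits on the right
wall (``x = field_width``) and moves one ``paddle_step`` per tick in the
commanded direction.  A rally runs from a serve to the first miss; under
the open-loop (no-feedback) condition a miss instead reflects the ball off
the back wall and play continues, so the whole session is a single rally
while hits and misses are still tallied per contact event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "GameConfig",
    "BallState",
    "PaddleState",
    "GameEvent",
    "RallyRecord",
    "GameplaySummary",
    "serve",
    "PongGame",
    "summarize_rallies",
]


@dataclass(frozen=True)
class GameConfig:
    """Geometry and kinematics of the game world.

    ``ball_speed`` defaults to a wall-to-wall traverse of 6 s (600 ticks at
    100 ticks/s) for a horizontally moving ball; paddle geometry defaults
    are one-quarter field coverage and 1 unit of travel per tick.  All are
    configurable as none is pinned by the system constants.
    """

    field_width: float = 100.0
    field_height: float = 100.0
    ball_speed: float = 100.0 / 600.0  # units per tick
    paddle_half_height: float = 12.5
    paddle_step: float = 1.0
    ticks_per_second: int = 100  # 10 ms ticks
    long_rally_threshold: int = 3  # "long rally" = strictly more hits than this
    serve_cone_deg: float = 60.0  # launch angle drawn in +/- cone about horizontal
    no_feedback: bool = False  # open loop: misses bounce off the back wall

    def __post_init__(self) -> None:
        for name in ("field_width", "field_height", "ball_speed",
                     "paddle_half_height", "paddle_step", "ticks_per_second"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.paddle_half_height >= self.field_height / 2:
            raise ValueError("paddle_half_height must be < field_height/2")
        if self.long_rally_threshold < 1:
            raise ValueError("long_rally_threshold must be >= 1")
        if not 0 < self.serve_cone_deg < 90:
            raise ValueError("serve_cone_deg must lie in (0, 90)")


@dataclass
class BallState:
    x: float
    y: float
    vx: float
    vy: float

    @property
    def speed(self) -> float:
        return math.hypot(self.vx, self.vy)


@dataclass
class PaddleState:
    y: float


@dataclass(frozen=True)
class GameEvent:
    kind: str  # wall_bounce | paddle_hit | miss | serve
    tick: int


@dataclass
class RallyRecord:
    rally_index: int
    hits: int
    start_tick: int
    end_tick: int
    layout_id: int = 0


@dataclass(frozen=True)
class GameplaySummary:
    n_rallies: int
    average_rally_length: float
    aces: int
    long_rallies: int
    paddle_distance: float


def serve(rng: np.random.Generator, config: GameConfig) -> BallState:
    """Place the ball at field centre on a random launch vector.

    The launch angle is uniform in ``+/- serve_cone_deg`` about horizontal
    with a random horizontal direction, so near-vertical trajectories are
    excluded and ``vx`` is never zero.
    """
    angle = math.radians(rng.uniform(-config.serve_cone_deg, config.serve_cone_deg))
    direction = 1.0 if rng.random() < 0.5 else -1.0
    vx = direction * config.ball_speed * math.cos(angle)
    vy = config.ball_speed * math.sin(angle)
    return BallState(x=config.field_width / 2.0, y=config.field_height / 2.0,
                     vx=vx, vy=vy)


class PongGame:
    """Stateful game loop: one :meth:`tick` per 10 ms spike-count bin."""

    def __init__(self, config: GameConfig, rng: np.random.Generator,
                 layout_id: int = 0) -> None:
        self.config = config
        self.rng = rng
        self.tick_index = 0
        self.paddle = PaddleState(y=config.field_height / 2.0)
        self.records: List[RallyRecord] = []
        self.events: List[GameEvent] = []
        self.paddle_distance = 0.0
        self.layout_id = layout_id
        self._rally_start = 0
        self._rally_hits = 0
        self.ball = serve(rng, config)
        self.events.append(GameEvent("serve", 0))

    # -- helpers -----------------------------------------------------------

    def set_layout(self, layout_id: int) -> None:
        """Record the motor layout in force for subsequent rallies."""
        self.layout_id = layout_id

    def _move_paddle(self, command: str) -> None:
        cfg = self.config
        dy = {"up": cfg.paddle_step, "down": -cfg.paddle_step, "none": 0.0}[command]
        lo = cfg.paddle_half_height
        hi = cfg.field_height - cfg.paddle_half_height
        new_y = min(max(self.paddle.y + dy, lo), hi)
        self.paddle_distance += abs(new_y - self.paddle.y)
        self.paddle.y = new_y

    def _end_rally(self) -> None:
        self.records.append(RallyRecord(
            rally_index=len(self.records),
            hits=self._rally_hits,
            start_tick=self._rally_start,
            end_tick=self.tick_index,
            layout_id=self.layout_id,
        ))
        self._rally_hits = 0
        self._rally_start = self.tick_index

    def finalize(self) -> List[RallyRecord]:
        """Close the open rally (if any ticks elapsed) and return records."""
        if self.tick_index > self._rally_start:
            self._end_rally()
        return self.records

    # -- main step ---------------------------------------------------------

    def tick(self, paddle_command: str = "none") -> List[GameEvent]:
        """Advance one 10 ms step; returns the events raised during it."""
        b = self.ball
        if not all(math.isfinite(v) for v in (b.x, b.y, b.vx, b.vy, self.paddle.y)):
            raise ValueError("non-finite game state")
        cfg = self.config
        self.tick_index += 1
        t = self.tick_index
        out: List[GameEvent] = []

        self._move_paddle(paddle_command)
        b.x += b.vx
        b.y += b.vy

        # paddle wall (right) first: contact decides the rally
        if b.x >= cfg.field_width:
            if abs(b.y - self.paddle.y) <= cfg.paddle_half_height:
                out.append(GameEvent("paddle_hit", t))
                self._rally_hits += 1
                b.x = 2.0 * cfg.field_width - b.x
                b.vx = -b.vx
            else:
                out.append(GameEvent("miss", t))
                if cfg.no_feedback:
                    # open loop: ball bounces off the back wall, same rally
                    b.x = 2.0 * cfg.field_width - b.x
                    b.vx = -b.vx
                else:
                    self._end_rally()
                    self.ball = serve(self.rng, cfg)
                    out.append(GameEvent("serve", t))
                    b = self.ball
        elif b.x <= 0.0:
            out.append(GameEvent("wall_bounce", t))
            b.x = -b.x
            b.vx = -b.vx

        # top/bottom walls
        if b.y <= 0.0:
            out.append(GameEvent("wall_bounce", t))
            b.y = -b.y
            b.vy = -b.vy
        elif b.y >= cfg.field_height:
            out.append(GameEvent("wall_bounce", t))
            b.y = 2.0 * cfg.field_height - b.y
            b.vy = -b.vy

        self.events.extend(out)
        return out


def summarize_rallies(records: Sequence[RallyRecord],
                      paddle_distance: float = 0.0,
                      long_rally_threshold: int = 3) -> GameplaySummary:
    """Rally metrics: average rally length (total hits / rallies), aces
    (zero-hit rallies) and long rallies (strictly more hits than the
    threshold, default > 3)."""
    if not records:
        raise ValueError("no rally records")
    hits = [r.hits for r in records]
    return GameplaySummary(
        n_rallies=len(records),
        average_rally_length=sum(hits) / len(records),
        aces=sum(1 for h in hits if h == 0),
        long_rallies=sum(1 for h in hits if h > long_rally_threshold),
        paddle_distance=paddle_distance,
    )
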