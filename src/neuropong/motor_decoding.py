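"""Electrode layouts and spike-count -> paddle-command decoding.

The 1024 routed channels live on a 32x32 logical grid (row 0 at the
bottom, matching the game's y axis).  A layout assigns each channel to
the sensory region (626 channels, containing the 8 stimulation sites) or
to one of two motor regions built from four ~100-channel corner blocks;
the five shipped presets (configurations 0-4) counterbalance how the
blocks map to motor region 1 ("up") and motor region 2 ("down").
Configuration 3, a diagonal split, is the default.

Decoding is deliberately minimal: spike counts in the two motor regions
over each 10 ms bin are compared after dividing by a per-region gain
factor and the larger drive moves the paddle; a tie leaves it still.  The
gain factor is the region's exponentially smoothed firing rate over a
20 Hz target (clamped), which equalizes regions with chronically
different spontaneous rates — no other weighting or filtering is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .signal_chain import SpikeEvent

GRID_SIZE = 32
N_CHANNELS = GRID_SIZE * GRID_SIZE
N_SENSORY = 626
TARGET_RATE_HZ = 20.0
# slow homeostatic normalization: corrects chronic baseline imbalance
# without chasing within-rally firing fluctuations
DEFAULT_GAIN_TAU_S = 60.0
GAIN_CLAMP = (0.1, 10.0)
DEFAULT_LAYOUT_ID = 3
BIN_SAMPLES = 200  # 10 ms at 20 kHz

__all__ = [
    "ElectrodeLayout", "GainState", "PaddleCommand",
    "make_layout", "bin_spikes", "update_gain", "decode",
    "DEFAULT_LAYOUT_ID", "LAYOUT_IDS",
]

# Four corner blocks of the grid; C and D give back their outermost corner
# electrode to the sensory region so the region sizes land on 626 + 398.
_BLOCKS: Dict[str, List[int]] = {}


def _block(rows: range, cols: range, drop: Tuple[int, int] = None) -> List[int]:
    chans = [r * GRID_SIZE + c for r in rows for c in cols
             if (r, c) != drop]
    return chans


_BLOCKS["A"] = _block(range(0, 10), range(0, 10))                    # bottom-left
_BLOCKS["B"] = _block(range(22, 32), range(0, 10))                   # top-left
_BLOCKS["C"] = _block(range(0, 10), range(22, 32), drop=(0, 31))     # bottom-right
_BLOCKS["D"] = _block(range(22, 32), range(22, 32), drop=(31, 31))   # top-right

# layout_id -> (blocks of motor region 1 = "up", blocks of motor region 2)
_CONFIGS: Dict[int, Tuple[Tuple[str, str], Tuple[str, str]]] = {
    0: (("A", "B"), ("C", "D")),   # left vs right halves
    1: (("B", "D"), ("A", "C")),   # top vs bottom
    2: (("A", "C"), ("B", "D")),   # bottom vs top
    3: (("B", "C"), ("A", "D")),   # diagonal split (default)
    4: (("A", "D"), ("B", "C")),   # opposite diagonal
}
LAYOUT_IDS = tuple(sorted(_CONFIGS))

# 8 stimulation sites on the vertical midline of the sensory band,
# bottom-to-top so site index matches the place code.
_STIM_ROWS = (2, 6, 10, 14, 18, 22, 26, 30)
_STIM_COL = 16
STIM_CHANNELS = tuple(r * GRID_SIZE + _STIM_COL for r in _STIM_ROWS)


@dataclass
class ElectrodeLayout:
    """Region assignment for the 1024 routed channels."""

    layout_id: int
    region: np.ndarray  # per channel: "sensory" | "motor1" | "motor2"
    stim_sites: Tuple[int, ...] = STIM_CHANNELS

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=object)
        if self.region.shape != (N_CHANNELS,):
            raise ValueError(f"layout must assign exactly {N_CHANNELS} channels")
        if int(np.sum(self.region == "sensory")) != N_SENSORY:
            raise ValueError(f"sensory region must hold {N_SENSORY} channels")
        m1, m2 = self.motor1_channels, self.motor2_channels
        if len(m1) == 0 or len(m2) == 0:
            raise ValueError("motor regions must be non-empty")
        if np.intersect1d(m1, m2).size:
            raise ValueError("motor regions must be disjoint")
        if len(self.stim_sites) != 8:
            raise ValueError("exactly 8 stimulation sites required")
        if not all(self.region[c] == "sensory" for c in self.stim_sites):
            raise ValueError("stimulation sites must lie inside the sensory region")

    @property
    def motor1_channels(self) -> np.ndarray:
        return np.flatnonzero(self.region == "motor1")

    @property
    def motor2_channels(self) -> np.ndarray:
        return np.flatnonzero(self.region == "motor2")

    @property
    def sensory_channels(self) -> np.ndarray:
        return np.flatnonzero(self.region == "sensory")

    @staticmethod
    def coords(channel: np.ndarray | int) -> Tuple[np.ndarray, np.ndarray]:
        """(row, col) grid coordinates; row 0 is the bottom edge."""
        channel = np.asarray(channel)
        return channel // GRID_SIZE, channel % GRID_SIZE

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "layout_id": self.layout_id,
            "grid_size": GRID_SIZE,
            "stim_sites": list(self.stim_sites),
            "channels": [{"channel": c, "row": int(c // GRID_SIZE),
                          "col": int(c % GRID_SIZE), "region": str(r)}
                         for c, r in enumerate(self.region)],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ElectrodeLayout":
        payload = json.loads(Path(path).read_text())
        region = np.empty(N_CHANNELS, dtype=object)
        region[:] = None
        for entry in payload["channels"]:
            region[entry["channel"]] = entry["region"]
        if any(r is None for r in region):
            raise ValueError("layout file does not cover all channels")
        return cls(layout_id=payload["layout_id"], region=region,
                   stim_sites=tuple(payload["stim_sites"]))


def make_layout(layout_id: int = DEFAULT_LAYOUT_ID) -> ElectrodeLayout:
    """Build one of the five preset motor-region configurations."""
    if layout_id not in _CONFIGS:
        raise ValueError(f"unknown layout {layout_id}; presets are {LAYOUT_IDS}")
    m1_blocks, m2_blocks = _CONFIGS[layout_id]
    region = np.empty(N_CHANNELS, dtype=object)
    region[:] = "sensory"
    for b in m1_blocks:
        region[_BLOCKS[b]] = "motor1"
    for b in m2_blocks:
        region[_BLOCKS[b]] = "motor2"
    return ElectrodeLayout(layout_id=layout_id, region=region)


def bin_spikes(events: Sequence[SpikeEvent], layout: ElectrodeLayout,
               bin_start: int, bin_samples: int = BIN_SAMPLES
               ) -> Tuple[int, int, int]:
    """(motor1, motor2, sensory) spike counts for one 10 ms bin."""
    counts = {"motor1": 0, "motor2": 0, "sensory": 0}
    for ev in events:
        if not bin_start <= ev.sample_index < bin_start + bin_samples:
            raise ValueError("event outside the requested bin")
        counts[str(layout.region[ev.channel])] += 1
    return counts["motor1"], counts["motor2"], counts["sensory"]


@dataclass
class GainState:
    """Per-region smoothed firing rate and the derived correction factor.

    The correction factor is ``smoothed_rate / target`` clamped to
    ``GAIN_CLAMP``; drives are compared after dividing the instantaneous
    count by it, which normalizes chronic rate asymmetries away.
    """

    target_rate: float = TARGET_RATE_HZ
    tau_s: float = DEFAULT_GAIN_TAU_S
    rate_m1: float = TARGET_RATE_HZ
    rate_m2: float = TARGET_RATE_HZ

    def factor(self, rate: float) -> float:
        lo, hi = GAIN_CLAMP
        return float(np.clip(rate / self.target_rate, lo, hi))

    @property
    def factor_m1(self) -> float:
        return self.factor(self.rate_m1)

    @property
    def factor_m2(self) -> float:
        return self.factor(self.rate_m2)


@dataclass(frozen=True)
class PaddleCommand:
    direction: str  # up | down | none
    magnitude: int = 1

    def __post_init__(self) -> None:
        if self.direction == "none" and self.magnitude != 0:
            object.__setattr__(self, "magnitude", 0)


def update_gain(state: GainState, counts: Tuple[int, int],
                dt: float = 0.01) -> GainState:
    """Exponential-moving-average update of the two region rates."""
    alpha = dt / state.tau_s
    m1, m2 = counts
    return GainState(
        target_rate=state.target_rate, tau_s=state.tau_s,
        rate_m1=state.rate_m1 + alpha * (m1 / dt - state.rate_m1),
        rate_m2=state.rate_m2 + alpha * (m2 / dt - state.rate_m2),
    )


def decode(counts: Tuple[int, int], state: GainState) -> PaddleCommand:
    """Gain-corrected two-way comparison; ties do not move the paddle."""
    drive1 = counts[0] / state.factor_m1
    drive2 = counts[1] / state.factor_m2
    if drive1 > drive2:
        return PaddleCommand("up", 1)
    if drive2 > drive1:
        return PaddleCommand("down", 1)
    return PaddleCommand("none", 0)
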