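"""Raw voltage frames -> spike events.

The detection chain mirrors a real-time MEA readout: each channel is
high-pass filtered with a 2nd-order Bessel filter (100 Hz cutoff at the
20 kHz sampling rate), the absolute value of the filtered signal is
smoothed by a 1st-order low-pass Bessel filter (1 Hz cutoff) to track the
background-noise envelope, and a spike is declared wherever the filtered
magnitude exceeds ``k`` times the envelope (default ``k = 6``, the usual
"six sigma above noise" rule).  Both filters are discretized by the
bilinear transform with frequency pre-warping at the cutoff, and run
causally sample-by-sample, so streaming and whole-trace batch filtering
agree to floating-point tolerance.

Stimulation commands corrupt the readout, so events can be *blinded*:
every event inside a configurable window after a logged DAC command is
dropped on all channels (command-count blinding).  The older consensus
scheme — drop a frame when more than 15 channels show simultaneous large
(> 75 mV) detections — is retained for comparison.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .sensory_coding import SAMPLE_RATE

N_CHANNELS = 1024
DEFAULT_THRESHOLD_K = 6.0
DEFAULT_BLIND_WINDOW = 100  # samples (5 ms)
DEFAULT_REFRACTORY_S = 1e-3
DEFAULT_WARMUP_S = 2.0
CONSENSUS_COUNT = 15  # frame blinded when MORE than this many large events
CONSENSUS_AMPLITUDE_UV = 75_000.0  # 75 mV

__all__ = [
    "SpikeEvent", "SpikeDetector", "design_highpass", "design_envelope_lowpass",
    "apply_blinding", "write_spike_log", "read_spike_log",
]


@dataclass(frozen=True)
class SpikeEvent:
    channel: int
    sample_index: int
    amplitude: float  # signed, µV, at the crossing peak


def design_highpass(fs: float = SAMPLE_RATE) -> np.ndarray:
    """2nd-order Bessel high-pass, 100 Hz cutoff (-3 dB), as SOS."""
    return sps.bessel(2, 100.0, btype="highpass", fs=fs, output="sos",
                      norm="mag")


def design_envelope_lowpass(fs: float = SAMPLE_RATE) -> np.ndarray:
    """1st-order Bessel low-pass, 1 Hz cutoff, as SOS (unity DC gain)."""
    return sps.bessel(1, 1.0, btype="lowpass", fs=fs, output="sos", norm="mag")


class SpikeDetector:
    """Stateful per-channel filter chain and proportional thresholder.

    Feed voltage chunks of shape ``(n_samples, n_channels)`` to
    :meth:`process`; events accumulate in order.  The detector is scale
    free: multiplying the input by any positive constant scales filtered
    signal and envelope identically, leaving event times unchanged.
    """

    def __init__(self, n_channels: int = N_CHANNELS,
                 threshold_k: float = DEFAULT_THRESHOLD_K,
                 fs: float = SAMPLE_RATE,
                 refractory_s: float = DEFAULT_REFRACTORY_S,
                 warmup_s: float = DEFAULT_WARMUP_S) -> None:
        if threshold_k <= 0:
            raise ValueError("threshold multiplier must be positive")
        self.n_channels = n_channels
        self.k = threshold_k
        self.fs = fs
        self.refractory = max(int(round(refractory_s * fs)), 1)
        self.warmup = int(round(warmup_s * fs))
        self._hp_sos = design_highpass(fs)
        self._lp_sos = design_envelope_lowpass(fs)
        self._hp_zi = np.zeros((self._hp_sos.shape[0], 2, n_channels))
        self._lp_zi = np.zeros((self._lp_sos.shape[0], 2, n_channels))
        self._sample = 0  # absolute index of the next incoming sample
        # per-channel crossing state (crossings may span chunk borders)
        self._in_cross = np.zeros(n_channels, dtype=bool)
        self._peak_amp = np.zeros(n_channels)
        self._peak_idx = np.zeros(n_channels, dtype=np.int64)
        self._last_event = np.full(n_channels, -10**12, dtype=np.int64)

    # -- filter stages (exposed for direct testing) ------------------------

    def highpass_step(self, frames: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(frames)):
            raise ValueError("non-finite voltage input")
        out, self._hp_zi = sps.sosfilt(self._hp_sos, frames, axis=0,
                                       zi=self._hp_zi)
        return out

    def envelope_step(self, filtered: np.ndarray) -> np.ndarray:
        out, self._lp_zi = sps.sosfilt(self._lp_sos, np.abs(filtered), axis=0,
                                       zi=self._lp_zi)
        return out

    # -- detection ---------------------------------------------------------

    def process(self, frames: np.ndarray) -> List[SpikeEvent]:
        """Filter a chunk and return the spike events completed within it.

        An event is emitted when ``|filtered|`` falls back below the
        threshold, stamped at the in-crossing peak with its signed
        amplitude; a 1 ms per-channel refractory hold suppresses double
        counting.  No events are produced during the envelope warm-up.
        """
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        filtered = self.highpass_step(frames)
        envelope = self.envelope_step(filtered)
        start = self._sample
        self._sample += frames.shape[0]

        above = np.abs(filtered) > self.k * envelope
        events: List[SpikeEvent] = []
        for ch in np.flatnonzero(above.any(axis=0) | self._in_cross):
            events.extend(self._scan_channel(ch, filtered[:, ch],
                                             above[:, ch], start))
        events.sort(key=lambda e: (e.sample_index, e.channel))
        return events

    def _scan_channel(self, ch: int, x: np.ndarray, above: np.ndarray,
                      start: int) -> List[SpikeEvent]:
        events: List[SpikeEvent] = []
        prev = bool(self._in_cross[ch])
        aug = np.empty(len(above) + 1, dtype=bool)
        aug[0] = prev
        aug[1:] = above
        rises = np.flatnonzero(~aug[:-1] & aug[1:])   # crossing opens at x[i]
        falls = np.flatnonzero(aug[:-1] & ~aug[1:])   # closes before x[i]
        segments: List[Tuple[int, int, bool]] = []
        if prev:
            end = int(falls[0]) if len(falls) else len(x)
            segments.append((0, end, True))
            falls = falls[1:]
        for i, s0 in enumerate(rises):
            e0 = int(falls[i]) if i < len(falls) else len(x)
            segments.append((int(s0), e0, False))

        for seg_start, seg_end, continued in segments:
            if seg_start == seg_end:
                # crossing closed exactly at the chunk boundary
                amp, idx = float(self._peak_amp[ch]), int(self._peak_idx[ch])
                self._in_cross[ch] = False
            else:
                seg = x[seg_start:seg_end]
                j = int(np.argmax(np.abs(seg)))
                amp, idx = float(seg[j]), start + seg_start + j
                if continued:
                    if abs(self._peak_amp[ch]) >= abs(amp):
                        amp, idx = (float(self._peak_amp[ch]),
                                    int(self._peak_idx[ch]))
                    self._in_cross[ch] = False
            if seg_end == len(x) and above[-1]:
                # crossing continues into the next chunk
                self._in_cross[ch] = True
                self._peak_amp[ch], self._peak_idx[ch] = amp, idx
                break
            if (idx >= self.warmup
                    and idx - self._last_event[ch] >= self.refractory):
                events.append(SpikeEvent(channel=int(ch), sample_index=idx,
                                         amplitude=amp))
                self._last_event[ch] = idx
        return events


def apply_blinding(events: Sequence[SpikeEvent],
                   command_samples: Sequence[int],
                   window_samples: int = DEFAULT_BLIND_WINDOW,
                   mode: str = "command") -> List[SpikeEvent]:
    """Drop events attributable to stimulation artifacts.

    ``command`` mode removes every event, on any channel, whose sample
    index lies in ``[c, c + window)`` for some logged command sample
    ``c``.  ``consensus`` mode instead drops whole frames on which more
    than 15 simultaneous events exceed 75 mV.
    """
    if mode == "consensus":
        by_sample: dict = {}
        for ev in events:
            if abs(ev.amplitude) > CONSENSUS_AMPLITUDE_UV:
                by_sample[ev.sample_index] = by_sample.get(ev.sample_index, 0) + 1
        blinded = {s for s, n in by_sample.items() if n > CONSENSUS_COUNT}
        return [ev for ev in events if ev.sample_index not in blinded]
    if mode != "command":
        raise ValueError(f"unknown blinding mode: {mode}")
    cmds = np.asarray(command_samples, dtype=np.int64)
    if np.any(np.diff(cmds) < 0):
        raise ValueError("command log must be sorted")
    if cmds.size == 0:
        return list(events)
    out = []
    for ev in events:
        i = np.searchsorted(cmds, ev.sample_index, side="right") - 1
        if i >= 0 and ev.sample_index < cmds[i] + window_samples:
            continue
        out.append(ev)
    return out


# -- binary spike log ------------------------------------------------------

_RECORD = struct.Struct("<IHf")  # uint32 sample, uint16 channel, float32 µV


def write_spike_log(path, events: Sequence[SpikeEvent],
                    threshold_k: float = DEFAULT_THRESHOLD_K,
                    fs: float = SAMPLE_RATE) -> None:
    """Little-endian binary spike records plus a JSON sidecar."""
    path = Path(path)
    with open(path, "wb") as fh:
        for ev in events:
            fh.write(_RECORD.pack(ev.sample_index, ev.channel, ev.amplitude))
    sidecar = {"sample_rate": fs, "n_channels": N_CHANNELS,
               "threshold_k": threshold_k, "n_events": len(events),
               "record_format": "<u4 sample, <u2 channel, <f4 amplitude_uV"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_spike_log(path) -> Tuple[List[SpikeEvent], dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = path.read_bytes()
    if len(raw) % _RECORD.size:
        raise ValueError("truncated spike log")
    events = [SpikeEvent(channel=c, sample_index=s, amplitude=a)
              for s, c, a in _RECORD.iter_unpack(raw)]
    if sidecar.get("n_events") is not None and sidecar["n_events"] != len(events):
        raise ValueError("spike log does not match its sidecar")
    return events, sidecar
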