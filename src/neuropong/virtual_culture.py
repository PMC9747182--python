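"""Virtual spiking culture: the synthetic stand-in for a biological network.

This module does not model biophysics.  It is a deliberately minimal
generative process — per-channel baseline Poisson firing with a skewed
(log-normal) rate map, stimulation-evoked responses through a plastic
site-by-channel coupling matrix, occasional population bursts, and
eligibility-gated weight updates — so that closed-loop behaviour can be
attributed to the embodiment mechanics rather than to model
sophistication.

Plasticity follows the feedback semantics of the embodiment:

* ``predictable`` (after a hit)    -> potentiate couplings flagged by the
  stimulation-site x firing-region eligibility trace: reinforce whatever
  input->output mapping produced the hit.
* ``unpredictable`` (after a miss) -> zero-mean multiplicative noise on
  the couplings: destabilize the mapping that produced the miss.
* ``silent_gap``                   -> the same perturbation at a smaller
  magnitude.
* ``none``                         -> no change.

Non-learning control profiles mirror the experiment's controls: a
media-only bath (noise detections, no evoked response), electrically
inactive cells, and an in-silico driver that replaces the culture with
i.i.d. random motor counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .motor_decoding import ElectrodeLayout, N_CHANNELS
from .sensory_coding import (N_STIM_SITES, SAMPLE_RATE, SAMPLES_PER_TICK,
                             SENSORY_AMPLITUDE_MV, StimPulse)
from .signal_chain import SpikeEvent

DT = SAMPLES_PER_TICK / SAMPLE_RATE  # 10 ms bin

__all__ = ["CultureProfile", "VirtualCulture", "SyntheticRaster",
           "PROFILES", "get_profile", "synth_voltage"]


@dataclass(frozen=True)
class CultureProfile:
    """Generative parameters of a virtual culture.

    Rates are per channel in Hz; ``asymmetry`` is a log-rate offset
    applied with opposite signs to the two motor regions (0 = balanced).
    ``evoked_gain`` is the expected number of extra spikes a single pulse
    adds to a channel per unit coupling weight.  The three plasticity
    rates gate the feedback responses described in the module docstring.
    """

    name: str
    baseline_median_hz: float = 0.1
    baseline_sigma: float = 1.0
    asymmetry: float = 0.0
    evoked_gain: float = 1.0
    eta_potentiate: float = 0.0
    eta_perturb: float = 0.0
    eta_silent: float = 0.0
    burst_rate_hz: float = 0.1
    burst_amp: float = 0.05         # extra spikes/channel/bin at burst onset
    burst_tau_s: float = 0.05
    w_max: float = 1.0
    w_init: Tuple[float, float] = (0.02, 0.05)
    evoked_tau_s: float = 0.03      # latency kernel time constant
    site_trace_tau_s: float = 1.0   # stim-site recency window
    eligibility_tau_s: float = 10.0  # spans a whole ball approach
    random_drive_hz: float = 0.0    # per-region iid drive (in-silico control)
    is_random_driver: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))

    @classmethod
    def from_json(cls, path) -> "CultureProfile":
        payload = json.loads(Path(path).read_text())
        payload["w_init"] = tuple(payload["w_init"])
        return cls(**payload)


PROFILES = {
    "learner_human": CultureProfile(name="learner_human",
                                    eta_potentiate=0.3, eta_perturb=0.25,
                                    eta_silent=0.08),
    "learner_mouse": CultureProfile(name="learner_mouse", evoked_gain=0.8,
                                    eta_potentiate=0.2, eta_perturb=0.25,
                                    eta_silent=0.08),
    "media_only": CultureProfile(name="media_only", baseline_median_hz=0.02,
                                 baseline_sigma=0.5, evoked_gain=0.0,
                                 burst_rate_hz=0.0),
    "inactive_cells": CultureProfile(name="inactive_cells",
                                     baseline_median_hz=0.005,
                                     baseline_sigma=0.5, evoked_gain=0.0,
                                     burst_rate_hz=0.0),
    "in_silico_random": CultureProfile(name="in_silico_random",
                                       evoked_gain=0.0, burst_rate_hz=0.0,
                                       random_drive_hz=60.0,
                                       is_random_driver=True),
}


def get_profile(name: str, **overrides) -> CultureProfile:
    if name not in PROFILES:
        raise ValueError(f"unknown culture profile: {name!r}")
    prof = PROFILES[name]
    return replace(prof, **overrides) if overrides else prof


@dataclass
class SyntheticRaster:
    """Spike events with ground-truth provenance labels."""

    events: List[SpikeEvent]
    labels: List[str]  # "evoked" | "spontaneous", parallel to events

    def __post_init__(self) -> None:
        if len(self.events) != len(self.labels):
            raise ValueError("labels must partition the events")


class VirtualCulture:
    """Stateful generative culture bound to an electrode layout.

    :meth:`step` advances one 10 ms bin and returns (motor1, motor2)
    spike counts; pass ``record=True`` to additionally sample per-channel
    counts (needed for raster logging and the spatial analyses).  All
    randomness flows through the generator supplied at construction.
    """

    def __init__(self, profile: CultureProfile, layout: ElectrodeLayout,
                 rng: np.random.Generator) -> None:
        self.profile = profile
        self.layout = layout
        self.rng = rng
        p = profile

        mu = np.log(p.baseline_median_hz)
        self.baseline = rng.lognormal(mean=mu, sigma=p.baseline_sigma,
                                      size=N_CHANNELS)
        self._m1 = layout.motor1_channels
        self._m2 = layout.motor2_channels
        self._sens = layout.sensory_channels
        # the asymmetry parameter is the *only* source of chronic motor
        # imbalance: region rate sums are normalized to their common mean
        # and then offset by exp(+/- asymmetry)
        s1 = self.baseline[self._m1].sum()
        s2 = self.baseline[self._m2].sum()
        mean_sum = 0.5 * (s1 + s2)
        self.baseline[self._m1] *= np.exp(p.asymmetry) * mean_sum / s1
        self.baseline[self._m2] *= np.exp(-p.asymmetry) * mean_sum / s2

        # coupling weights: stimulation site x channel, motor columns active
        self.W = np.zeros((N_STIM_SITES, N_CHANNELS))
        lo, hi = p.w_init
        motor = np.concatenate([self._m1, self._m2])
        self.W[:, motor] = rng.uniform(lo, hi, size=(N_STIM_SITES, len(motor)))
        # fixed (non-plastic) local evoked response around each stim site
        self._sens_kernel = self._sensory_kernel()

        self.eligibility = np.zeros((N_STIM_SITES, 2))  # site x motor region
        self._site_trace = np.zeros(N_STIM_SITES)
        self._evoked = np.zeros(2)       # pending evoked spikes per region
        self._evoked_chan: Optional[np.ndarray] = None  # lazy, record mode
        self._burst = 0.0
        self._decay_ev = np.exp(-DT / p.evoked_tau_s)
        self._decay_site = np.exp(-DT / p.site_trace_tau_s)
        self._decay_elig = np.exp(-DT / p.eligibility_tau_s)
        self._decay_burst = np.exp(-DT / p.burst_tau_s) if p.burst_tau_s else 0.0
        self._refresh_sums()

        self._base_m1 = float(self.baseline[self._m1].sum()) * DT
        self._base_m2 = float(self.baseline[self._m2].sum()) * DT
        # running mean of region firing (spikes/bin) for the
        # covariance-style eligibility rule
        self._rate_ema = np.array([self._base_m1, self._base_m2])
        self._ema_alpha = DT / 60.0

    def set_layout(self, layout: ElectrodeLayout) -> None:
        """Re-bind to a different motor-region layout (the cells do not
        move; only the readout regions change).  Region-level traces are
        reset since they are defined relative to the regions."""
        self.layout = layout
        self._m1 = layout.motor1_channels
        self._m2 = layout.motor2_channels
        self._sens = layout.sensory_channels
        self._refresh_sums()
        self._base_m1 = float(self.baseline[self._m1].sum()) * DT
        self._base_m2 = float(self.baseline[self._m2].sum()) * DT
        self.eligibility[:] = 0.0
        self._evoked[:] = 0.0
        self._rate_ema = np.array([self._base_m1, self._base_m2])

    # -- internals ---------------------------------------------------------

    def _sensory_kernel(self) -> np.ndarray:
        """Gaussian footprint of each stimulation site over the sensory
        region (spikes per pulse per channel at unit evoked gain)."""
        rows, cols = ElectrodeLayout.coords(np.arange(N_CHANNELS))
        kern = np.zeros((N_STIM_SITES, N_CHANNELS))
        for s, ch in enumerate(self.layout.stim_sites):
            r0, c0 = ch // 32, ch % 32
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            k = np.exp(-d2 / (2 * 3.0 ** 2))
            k[self.layout.region != "sensory"] = 0.0
            kern[s] = 2.0 * k
        return kern

    def _refresh_sums(self) -> None:
        self._wsum = np.stack([self.W[:, self._m1].sum(axis=1),
                               self.W[:, self._m2].sum(axis=1)], axis=1)
        # within-region distribution of eligibility over channels
        share = np.zeros(N_CHANNELS)
        for chans in (self._m1, self._m2):
            tot = self.baseline[chans].sum()
            share[chans] = self.baseline[chans] / tot if tot > 0 else 1 / len(chans)
        self._share = share

    # -- stepping ----------------------------------------------------------

    def step(self, pulses: Sequence[StimPulse] = (), record: bool = False
             ) -> Tuple[int, int, Optional[np.ndarray]]:
        """Advance one 10 ms bin under the given stimulation.

        Returns ``(motor1_count, motor2_count, channel_counts)`` where
        ``channel_counts`` is ``None`` unless ``record`` is set.
        """
        p = self.profile
        rng = self.rng

        if p.is_random_driver:
            lam = p.random_drive_hz * DT
            m1 = int(rng.poisson(lam))
            m2 = int(rng.poisson(lam))
            chan = None
            if record:
                chan = np.zeros(N_CHANNELS, dtype=np.int64)
                chan[self._m1] = rng.multinomial(m1, np.full(len(self._m1),
                                                             1 / len(self._m1)))
                chan[self._m2] = rng.multinomial(m2, np.full(len(self._m2),
                                                             1 / len(self._m2)))
            return m1, m2, chan

        # traces: _evoked holds the *pending* evoked spike mass; every bin
        # a (1 - decay) fraction of it is released, so the latency kernel
        # integrates to exactly 1 over time.
        self._site_trace *= self._decay_site
        self._burst *= self._decay_burst

        for pulse in pulses:
            strength = pulse.amplitude_mv / SENSORY_AMPLITUDE_MV
            s = pulse.site
            if pulse.label == "sensory":
                # only the place/rate code tags eligibility: feedback
                # bursts carry no site-specific information.  The trace
                # saturates at 1 so it marks *where* the ball has been,
                # not how fast the rate code was pulsing there.
                self._site_trace[s] = 1.0
            self._evoked += p.evoked_gain * strength * self._wsum[s]
            if record:
                if self._evoked_chan is None:
                    self._evoked_chan = np.zeros(N_CHANNELS)
                self._evoked_chan += p.evoked_gain * strength * (
                    self.W[s] + self._sens_kernel[s])

        if p.burst_rate_hz > 0 and rng.random() < p.burst_rate_hz * DT:
            self._burst += p.burst_amp

        release = 1.0 - self._decay_ev
        chan = None
        if record:
            lam_chan = self.baseline * DT + self._burst
            if self._evoked_chan is not None:
                lam_chan = lam_chan + self._evoked_chan * release
                self._evoked_chan *= self._decay_ev
            self._evoked *= self._decay_ev
            chan = rng.poisson(lam_chan)
            m1 = int(chan[self._m1].sum())
            m2 = int(chan[self._m2].sum())
        else:
            lam1 = self._base_m1 + self._evoked[0] * release \
                + self._burst * len(self._m1)
            lam2 = self._base_m2 + self._evoked[1] * release \
                + self._burst * len(self._m2)
            self._evoked *= self._decay_ev
            m1 = int(rng.poisson(lam1))
            m2 = int(rng.poisson(lam2))

        # eligibility: coincidence of recent site activity with firing,
        # covariance form — each region's counts are referenced to its
        # own running mean so chronic or slowly drifting rate offsets do
        # not masquerade as stimulus-locked associations
        counts = np.array([m1, m2], dtype=float)
        self.eligibility *= self._decay_elig
        if self._site_trace.max() > 1e-9:
            # saturating increment: one bin can witness at most one
            # spike's worth of excess either way, so population bursts
            # and evoked clumps (which hit both regions) cancel instead
            # of swamping the trace
            excess = np.clip(counts - self._rate_ema, -1.0, 1.0)
            self.eligibility += np.outer(self._site_trace, excess) * DT
        self._rate_ema += self._ema_alpha * (counts - self._rate_ema)
        return m1, m2, chan

    # -- feedback-driven plasticity ---------------------------------------

    def apply_feedback(self, label: str) -> None:
        """Update couplings according to the feedback just delivered."""
        p = self.profile
        if label == "none":
            return
        if label == "predictable":
            if p.eta_potentiate == 0.0 or not self.eligibility.any():
                return
            # Competitive Hebbian step with synaptic scaling: each site's
            # total motor coupling is conserved, and the motor-1/motor-2
            # balance shifts toward the region whose firing coincided
            # with that site's stimulation.  The shift per update is a
            # bounded fraction (eta * normalized eligibility difference,
            # weighted by how recently the site was active), which keeps
            # single noisy rallies from overturning the map.
            diff = self.eligibility[:, 0] - self.eligibility[:, 1]
            scale = np.abs(diff).max()
            if scale <= 0:
                return
            wsum = self._wsum
            totals = wsum.sum(axis=1)
            balance = (wsum[:, 0] - wsum[:, 1]) / np.maximum(totals, 1e-12)
            balance = np.clip(balance + p.eta_potentiate * diff / scale,
                              -0.98, 0.98)
            target1 = totals * (1 + balance) / 2
            target2 = totals * (1 - balance) / 2
            s1 = target1 / np.maximum(wsum[:, 0], 1e-12)
            s2 = target2 / np.maximum(wsum[:, 1], 1e-12)
            self.W[:, self._m1] *= s1[:, None]
            self.W[:, self._m2] *= s2[:, None]
        elif label in ("unpredictable", "silent_gap"):
            eta = p.eta_perturb if label == "unpredictable" else p.eta_silent
            if eta == 0.0:
                return
            motor = np.concatenate([self._m1, self._m2])
            noise = self.rng.standard_normal((N_STIM_SITES, len(motor)))
            scale = np.abs(self.W[:, motor]) + 0.02 * p.w_max
            self.W[:, motor] += eta * noise * scale
        else:
            raise ValueError(f"unknown feedback label: {label!r}")
        np.clip(self.W, 0.0, p.w_max, out=self.W)
        self._refresh_sums()
        # feedback closes the credit-assignment window: eligibility is
        # consumed by the update and starts fresh for the next approach
        self.eligibility[:] = 0.0

    # -- raster / event helpers -------------------------------------------

    def labeled_raster(self, n_bins: int,
                       pulses_for_bin) -> SyntheticRaster:
        """Generate a raster with ground-truth provenance labels.

        Baseline/burst and stimulation-evoked spikes are sampled as
        separate Poisson draws so each event carries an exact
        "spontaneous" or "evoked" label — the fixture for validating the
        detection chain.  ``pulses_for_bin(i)`` supplies the stimulation
        for bin ``i``.
        """
        p = self.profile
        events: List[SpikeEvent] = []
        labels: List[str] = []
        for i in range(n_bins):
            pulses = pulses_for_bin(i)
            _ = self.step(pulses, record=True)  # advance evoked traces
            start = i * SAMPLES_PER_TICK
            base = self.rng.poisson(self.baseline * DT + self._burst)
            for ev in self.counts_to_events(base, start):
                events.append(ev)
                labels.append("spontaneous")
            if self._evoked_chan is not None:
                lam = self._evoked_chan * (1 - self._decay_ev)
                evoked = self.rng.poisson(lam)
                for ev in self.counts_to_events(evoked, start):
                    events.append(ev)
                    labels.append("evoked")
        order = np.argsort([e.sample_index for e in events], kind="stable")
        return SyntheticRaster(events=[events[i] for i in order],
                               labels=[labels[i] for i in order])

    def counts_to_events(self, chan_counts: np.ndarray, bin_start_sample: int
                         ) -> List[SpikeEvent]:
        """Spread per-channel bin counts into timed events with plausible
        signed amplitudes (most below the -5 µV noise criterion)."""
        events: List[SpikeEvent] = []
        active = np.flatnonzero(chan_counts)
        for ch in active:
            n = int(chan_counts[ch])
            offsets = self.rng.integers(0, SAMPLES_PER_TICK, size=n)
            amps = -np.abs(self.rng.normal(15.0, 5.0, size=n))
            for o, a in zip(np.sort(offsets), amps):
                events.append(SpikeEvent(channel=int(ch),
                                         sample_index=bin_start_sample + int(o),
                                         amplitude=float(a)))
        return events


def synth_voltage(events: Sequence[SpikeEvent], n_samples: int,
                  n_channels: int, noise_sigma: float,
                  rng: np.random.Generator,
                  snr: float = 8.0,
                  artifact_samples: Sequence[int] = (),
                  artifact_amplitude: float = 1000.0,
                  fs: float = SAMPLE_RATE) -> np.ndarray:
    """Render spike events as voltage frames for the detection chain.

    Each event contributes a stereotyped biphasic waveform (sharp
    negative peak, slower positive rebound) whose peak is ``snr`` times
    the noise standard deviation, summed linearly onto white Gaussian
    background noise.  Logged stimulation commands are rendered as large
    square artifacts on *all* channels, for blinding tests.
    """
    if noise_sigma > 0:
        frames = rng.normal(0.0, noise_sigma, size=(n_samples, n_channels))
    else:
        frames = np.zeros((n_samples, n_channels))

    # biphasic template, ~1.5 ms, peak normalized to -1
    t = np.arange(int(1.5e-3 * fs))
    wave = -np.exp(-0.5 * ((t - 6) / 3.0) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - 16) / 6.0) ** 2)
    wave /= np.abs(wave).max()
    amp = snr * noise_sigma if noise_sigma > 0 else snr

    for ev in events:
        start = ev.sample_index - 6  # align template peak with the event
        seg = slice(max(start, 0), min(start + len(wave), n_samples))
        wseg = wave[seg.start - start: seg.stop - start]
        frames[seg, ev.channel] += amp * wseg

    for s in artifact_samples:
        seg = slice(max(s, 0), min(s + 40, n_samples))
        frames[seg, :] += artifact_amplitude
    return frames
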