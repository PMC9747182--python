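"""Raster statistics for embodiment sessions.

Implements the analysis battery used to characterize closed-loop
sessions: clustered binary information entropy of spike rasters (18
rectangular clusters of 50 neighbouring electrodes, 100 ms windows),
spike-count-normalized entropy, pre/post-feedback entropy contrasts,
centre-of-activity (CA) functional-plasticity scores, low-order 2-D DCT
spatial modes, lagged cross-correlations between region count series,
exclusive motor-region events, motor-symmetry deviation scores, and the
T1/T2 (minutes 0-5 vs 6-20) session split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as scistats
from scipy.fft import dctn as _dctn

from .game_world import RallyRecord
from .motor_decoding import GRID_SIZE, N_CHANNELS, ElectrodeLayout
from .sensory_coding import SAMPLE_RATE
from .signal_chain import SpikeEvent

ENTROPY_WINDOW_S = 0.1
N_CLUSTERS = 18
CLUSTER_SIZE = 50
CA_BIN_S = 1.0
PLASTICITY_WINDOW_S = 300.0
EXCLUSIVE_BIN_S = 1.0
EXCLUSIVE_AMPLITUDE_UV = -5.0
OUTLIER_Z = 3.29
T1_END_MIN, T2_START_MIN, T2_END_MIN = 5.0, 6.0, 20.0

EventsLike = Union[Sequence[SpikeEvent], Tuple[np.ndarray, np.ndarray, np.ndarray]]

__all__ = [
    "binary_entropy", "default_cluster_scheme", "clustered_entropy",
    "normalized_entropy", "pre_post_feedback_entropy", "center_of_activity",
    "ca_series", "plasticity_score", "PlasticityResult", "activity_image",
    "dct_modes", "lagged_cross_correlation", "exclusive_motor_events",
    "symmetry_deviation", "split_timepoints", "filter_outliers",
    "EntropySeries",
]


def _as_arrays(events: EventsLike) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(channels, samples, amplitudes) from a SpikeEvent list or arrays."""
    if isinstance(events, tuple) and len(events) == 3:
        ch = np.asarray(events[0], dtype=np.int64)
        sm = np.asarray(events[1], dtype=np.int64)
        amp = np.asarray(events[2], dtype=float)
        return ch, sm, amp
    ch = np.fromiter((e.channel for e in events), dtype=np.int64,
                     count=len(events))
    sm = np.fromiter((e.sample_index for e in events), dtype=np.int64,
                     count=len(events))
    amp = np.fromiter((e.amplitude for e in events), dtype=float,
                      count=len(events))
    return ch, sm, amp


# -- entropy ---------------------------------------------------------------

def binary_entropy(p) -> np.ndarray:
    """Entropy of a Bernoulli(p) variable in shannons,
    ``-p log2 p - (1-p) log2 (1-p)`` with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        out = out - np.where(mask, q * np.log2(np.where(mask, q, 1.0)), 0.0)
    return out if out.ndim else float(out)


def default_cluster_scheme() -> List[np.ndarray]:
    """18 rectangular clusters of 50 neighbouring electrodes.

    A 6 x 3 tiling of 5-row x 10-column blocks over rows 0-29 and columns
    0-29 of the 32 x 32 channel grid (900 of the 1024 routed channels).
    The exact physical membership is a configuration choice; only the
    18 x 50 structure is fixed.
    """
    clusters = []
    for tile_r in range(6):
        for tile_c in range(3):
            rows = range(tile_r * 5, tile_r * 5 + 5)
            cols = range(tile_c * 10, tile_c * 10 + 10)
            clusters.append(np.array([r * GRID_SIZE + c
                                      for r in rows for c in cols]))
    return clusters


def _validate_scheme(scheme: Sequence[np.ndarray]) -> None:
    if len(scheme) != N_CLUSTERS:
        raise ValueError(f"scheme must define exactly {N_CLUSTERS} clusters")
    seen: set = set()
    for cl in scheme:
        if len(cl) != CLUSTER_SIZE:
            raise ValueError(f"each cluster must hold {CLUSTER_SIZE} electrodes")
        if seen & set(int(c) for c in cl):
            raise ValueError("clusters must be disjoint")
        seen |= set(int(c) for c in cl)


@dataclass
class EntropySeries:
    """Per-window, per-cluster binary entropies (shannons) plus the
    matching per-window spike counts over the clustered electrodes."""

    values: np.ndarray  # (n_windows, n_clusters)
    spike_counts: np.ndarray  # (n_windows,)
    window_s: float = ENTROPY_WINDOW_S

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def clustered_entropy(events: EventsLike,
                      scheme: Optional[Sequence[np.ndarray]] = None,
                      duration_samples: Optional[int] = None,
                      window_s: float = ENTROPY_WINDOW_S,
                      start_sample: int = 0) -> EntropySeries:
    """Local binary entropy of each cluster in consecutive windows.

    For every cluster and 100 ms window, ``p`` is the fraction of the
    cluster's 50 electrodes with at least one spike in the window; the
    entropy is ``binary_entropy(p)``.
    """
    scheme = default_cluster_scheme() if scheme is None else list(scheme)
    _validate_scheme(scheme)
    ch, sm, _ = _as_arrays(events)
    if duration_samples is None:
        if len(sm) == 0:
            raise ValueError("empty session and no duration given")
        duration_samples = int(sm.max()) - start_sample + 1
    win = int(round(window_s * SAMPLE_RATE))
    n_windows = max(int(np.ceil(duration_samples / win)), 1)

    keep = (sm >= start_sample) & (sm < start_sample + n_windows * win)
    ch, sm = ch[keep], sm[keep]
    w_idx = (sm - start_sample) // win
    # channel-activity matrix: did channel c spike in window w?
    active = np.zeros((n_windows, N_CHANNELS), dtype=bool)
    active[w_idx, ch] = True

    cluster_idx = np.stack(scheme)  # (18, 50)
    p = active[:, cluster_idx].sum(axis=2) / CLUSTER_SIZE  # (n_windows, 18)
    clustered = np.isin(ch, cluster_idx.ravel())
    counts = np.bincount(w_idx[clustered], minlength=n_windows).astype(float)
    return EntropySeries(values=binary_entropy(p), spike_counts=counts,
                         window_s=window_s)


def normalized_entropy(entropy, spike_counts):
    """Entropy divided by the spike count over the same windows; windows
    (or sessions) with zero spikes yield 0 by convention."""
    entropy = np.asarray(entropy, dtype=float)
    counts = np.asarray(spike_counts, dtype=float)
    if entropy.shape != counts.shape:
        raise ValueError("entropy and spike counts must align")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(counts > 0, entropy / np.where(counts > 0, counts, 1.0),
                       0.0)
    return out if out.ndim else float(out)


def pre_post_feedback_entropy(events: EventsLike,
                              feedback_samples: Sequence[int],
                              duration_samples: int,
                              window_s: float = 4.0,
                              scheme: Optional[Sequence[np.ndarray]] = None
                              ) -> Dict[str, np.ndarray]:
    """Mean (and spike-normalized) clustered entropy in the ``window_s``
    seconds before vs after each feedback onset.

    Onsets without a full pre and post window inside the session are
    skipped; with no usable onsets all arrays come back empty.  Rest
    sessions can pass matched virtual timepoints as ``feedback_samples``.
    """
    win = int(round(window_s * SAMPLE_RATE))
    pre_m, post_m, pre_n, post_n = [], [], [], []
    for onset in feedback_samples:
        onset = int(onset)
        if onset - win < 0 or onset + win > duration_samples:
            continue
        pre = clustered_entropy(events, scheme, duration_samples=win,
                                start_sample=onset - win)
        post = clustered_entropy(events, scheme, duration_samples=win,
                                 start_sample=onset)
        pre_m.append(pre.mean)
        post_m.append(post.mean)
        pre_n.append(normalized_entropy(pre.mean, pre.spike_counts.sum()))
        post_n.append(normalized_entropy(post.mean, post.spike_counts.sum()))
    return {"pre": np.array(pre_m), "post": np.array(post_m),
            "pre_normalized": np.array(pre_n),
            "post_normalized": np.array(post_n)}


# -- centre of activity ----------------------------------------------------

def center_of_activity(counts: np.ndarray, x: np.ndarray, y: np.ndarray,
                       ref: Tuple[float, float] = (0.0, 0.0)
                       ) -> Tuple[float, float]:
    """Firing-weighted centroid of electrode positions relative to the
    reference corner: ``CA = sum_k F_k [X_k - R_X, Y_k - R_Y] / sum_k F_k``."""
    counts = np.asarray(counts, dtype=float)
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if counts.shape != x.shape or counts.shape != y.shape:
        raise ValueError("counts and coordinates must align")
    total = counts.sum()
    if total <= 0:
        raise ValueError("centre of activity undefined for all-zero counts")
    rx, ry = ref
    return (float(np.dot(counts, x - rx) / total),
            float(np.dot(counts, y - ry) / total))


def ca_series(events: EventsLike, duration_samples: int,
              bin_s: float = CA_BIN_S) -> np.ndarray:
    """Per-bin CA trajectory on the 32x32 grid (NaN rows for empty bins)."""
    ch, sm, _ = _as_arrays(events)
    win = int(round(bin_s * SAMPLE_RATE))
    n_bins = max(duration_samples // win, 1)
    rows, cols = ElectrodeLayout.coords(np.arange(N_CHANNELS))
    out = np.full((n_bins, 2), np.nan)
    keep = sm < n_bins * win
    b_idx = sm[keep] // win
    ch = ch[keep]
    for b in np.unique(b_idx):
        counts = np.bincount(ch[b_idx == b], minlength=N_CHANNELS)
        out[b] = center_of_activity(counts, cols, rows)
    return out


@dataclass(frozen=True)
class PlasticityResult:
    gameplay_score: float
    rest_score: float
    gameplay_distances: np.ndarray
    rest_distances: np.ndarray


def plasticity_score(gameplay_ca: np.ndarray, rest_ca: np.ndarray,
                     window_s: float = PLASTICITY_WINDOW_S,
                     bin_s: float = CA_BIN_S) -> PlasticityResult:
    """CA-drift plasticity metric.

    The gameplay score is the mean Euclidean distance of mean CAs over
    consecutive 5-min gameplay windows to the centroid of all rest-period
    CAs; the rest score is the same computed for the rest windows against
    their own centroid.  Requires at least 10 min of each.
    """
    bins_per_window = int(round(window_s / bin_s))
    for name, ca in (("gameplay", gameplay_ca), ("rest", rest_ca)):
        if len(ca) < 2 * bins_per_window:
            raise ValueError(f"{name} record must cover at least "
                             f"{2 * window_s / 60:.0f} minutes")
    rest_centroid = np.nanmean(rest_ca, axis=0)

    def window_means(ca: np.ndarray) -> np.ndarray:
        n = len(ca) // bins_per_window
        return np.array([np.nanmean(ca[i * bins_per_window:
                                       (i + 1) * bins_per_window], axis=0)
                         for i in range(n)])

    gd = np.linalg.norm(window_means(gameplay_ca) - rest_centroid, axis=1)
    rd = np.linalg.norm(window_means(rest_ca) - rest_centroid, axis=1)
    return PlasticityResult(gameplay_score=float(gd.mean()),
                            rest_score=float(rd.mean()),
                            gameplay_distances=gd, rest_distances=rd)


# -- spatial modes ---------------------------------------------------------

def activity_image(events: EventsLike) -> np.ndarray:
    """Per-electrode spike counts as a (rows, cols) image of the grid."""
    ch, _, _ = _as_arrays(events)
    counts = np.bincount(ch, minlength=N_CHANNELS)
    return counts.reshape(GRID_SIZE, GRID_SIZE).astype(float)


def dct_modes(image: np.ndarray) -> Dict[Tuple[int, int], float]:
    """Low-order 2-D type-II DCT coefficients of the activity image.

    Returns ``|coefficient| / mean activity`` for index pairs (u, v) with
    u, v in {0, 1, 2}, where u is the vertical (row) frequency and v the
    horizontal (column) frequency.  The four pure asymmetry modes used in
    correlation analyses are (0,1), (0,2), (1,0) and (2,0).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("need a non-empty 2-D activity image")
    mean = image.mean()
    if mean == 0:
        raise ValueError("zero mean activity")
    coef = _dctn(image, type=2, norm="ortho")
    return {(u, v): float(abs(coef[u, v]) / mean)
            for u in range(3) for v in range(3)}


ASYMMETRY_MODES = ((0, 1), (0, 2), (1, 0), (2, 0))


# -- correlations & events -------------------------------------------------

def lagged_cross_correlation(series_a: np.ndarray, series_b: np.ndarray,
                             lag_bins: int = 1,
                             method: str = "pearson") -> float:
    """Correlation of ``a(t)`` with ``b(t + lag)`` on equal-length binned
    count series (default one 100 ms bin of lag).  ``method='spearman'``
    gives the rank-based variant used for motor-motor synchrony."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D series")
    if lag_bins < 0:
        raise ValueError("lag must be non-negative")
    if lag_bins:
        a, b = a[:-lag_bins], b[lag_bins:]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant series")
    if method == "pearson":
        return float(scistats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(scistats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def region_count_series(events: EventsLike, layout: ElectrodeLayout,
                        duration_samples: int, bin_s: float = 0.1
                        ) -> Dict[str, np.ndarray]:
    """Binned spike counts per region (sensory, motor1, motor2)."""
    ch, sm, _ = _as_arrays(events)
    win = int(round(bin_s * SAMPLE_RATE))
    n_bins = max(duration_samples // win, 1)
    keep = sm < n_bins * win
    ch, sm = ch[keep], sm[keep]
    out = {}
    for name in ("sensory", "motor1", "motor2"):
        chans = np.flatnonzero(layout.region == name)
        mask = np.isin(ch, chans)
        out[name] = np.bincount(sm[mask] // win, minlength=n_bins).astype(float)
    return out


def exclusive_motor_events(events: EventsLike, layout: ElectrodeLayout,
                           duration_samples: int,
                           bin_s: float = EXCLUSIVE_BIN_S,
                           amplitude_uv: float = EXCLUSIVE_AMPLITUDE_UV
                           ) -> float:
    """Fraction of 1 s bins with above-noise activity (amplitude below
    -5 µV) in exactly one motor region but not the other."""
    ch, sm, amp = _as_arrays(events)
    win = int(round(bin_s * SAMPLE_RATE))
    n_bins = max(duration_samples // win, 1)
    keep = (sm < n_bins * win) & (amp < amplitude_uv)
    ch, sm = ch[keep], sm[keep]
    b_idx = sm // win
    m1 = np.isin(ch, layout.motor1_channels)
    m2 = np.isin(ch, layout.motor2_channels)
    has1 = np.zeros(n_bins, dtype=bool)
    has2 = np.zeros(n_bins, dtype=bool)
    has1[b_idx[m1]] = True
    has2[b_idx[m2]] = True
    return float(np.mean(has1 ^ has2))


def symmetry_deviation(activity_m1: float, activity_m2: float,
                       population_mean: float, population_sd: float) -> float:
    """Z-scored deviation of a session's motor-activity imbalance from a
    population of sessions: ``(|a1 - a2| - mean) / sd``."""
    if population_sd <= 0:
        raise ValueError("population SD must be positive")
    return float((abs(activity_m1 - activity_m2) - population_mean)
                 / population_sd)


def filter_outliers(values: np.ndarray, z: float = OUTLIER_Z) -> np.ndarray:
    """Drop entries with |Z| above the threshold (default 3.29)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        return values
    return values[np.abs((values - values.mean()) / sd) <= z]


# -- session split ---------------------------------------------------------

def event_rally_records(events, layout_id: int = 0) -> List[RallyRecord]:
    """Pseudo-rally records from the hit/miss event stream.

    Splits the contact events at every miss, so open-loop (no-feedback)
    sessions — where the game logs a single wall-to-wall rally but still
    tallies hits and misses per contact — become comparable with
    terminating rallies.  For closed-loop sessions this reproduces the
    logged rally records.
    """
    records: List[RallyRecord] = []
    hits = 0
    start = 0
    for ev in events:
        if ev.kind == "paddle_hit":
            hits += 1
        elif ev.kind == "miss":
            records.append(RallyRecord(rally_index=len(records), hits=hits,
                                       start_tick=start, end_tick=ev.tick,
                                       layout_id=layout_id))
            hits = 0
            start = ev.tick
    return records


def split_timepoints(records: Sequence[RallyRecord],
                     session_duration_ticks: int,
                     ticks_per_second: int = 100
                     ) -> Tuple[List[RallyRecord], List[RallyRecord]]:
    """Assign rallies (by end tick) to T1 = [0, 5) min and T2 = [6, 20]
    min; the minute in between belongs to neither.  Shorter sessions
    scale the boundaries proportionally, with a warning."""
    if not records:
        raise ValueError("empty session")
    full = T2_END_MIN * 60 * ticks_per_second
    scale = 1.0
    if session_duration_ticks < full:
        scale = session_duration_ticks / full
        warnings.warn("session shorter than 20 min: T1/T2 boundaries scaled "
                      f"by {scale:.3f}", stacklevel=2)
    t1_end = T1_END_MIN * 60 * ticks_per_second * scale
    t2_start = T2_START_MIN * 60 * ticks_per_second * scale
    t2_end = T2_END_MIN * 60 * ticks_per_second * scale
    t1 = [r for r in records if r.end_tick < t1_end]
    t2 = [r for r in records if t2_start <= r.end_tick <= t2_end]
    return t1, t2
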