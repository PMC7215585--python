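"""Plasticity summaries, burstiness scoring, burst detection and culture QC.

The network-level plasticity readout compares two probing sessions: for every
connection of the "before" map, the PSTH area is re-measured on the "after"
session and the relative change (percent) is computed. Positive changes are
summed into P (each capped at 101%), negative changes into N, and the
potentiation-to-depression ratio R = P/|N| summarizes the network: R > 1 is
network-level LTP, R < 1 LTD.

The burstiness index BI = (f - top_frac) / (1 - top_frac), where f is the
fraction of all spikes contained in the most active ``top_frac`` of 1-s bins,
scores how burst-dominated a recording is (0 = not bursting, 1 = maximal).
The default 15% corresponds to one ~300-ms burst per 6.7-s inter-burst
interval occupying its own 1-s bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpikeData
from .probing import ConnectivityMap, DetectionParams, reprobe_map
from .stimuli import StimulusSchedule

__all__ = [
    "EfficacyChangeSummary",
    "BurstSet",
    "SnbDetectParams",
    "QCResult",
    "compare_maps",
    "burstiness_index",
    "adaptive_top_frac",
    "detect_snbs",
    "culture_qc",
    "firing_rate_map",
]


@dataclass
class EfficacyChangeSummary:
    """Per-connection efficacy changes and the network P/N/R summary."""

    per_connection: pd.DataFrame  # pre, post, rel_change_pct, capped_pct, latency_delta_ms
    P: float
    N: float
    R: float  # NaN when N == 0
    n_skipped: int = 0

    @property
    def r_defined(self) -> bool:
        return not np.isnan(self.R)

    def to_dict(self) -> dict:
        return {
            "P": self.P,
            "N": self.N,
            "R": None if np.isnan(self.R) else self.R,
            "n_connections": int(len(self.per_connection)),
            "n_skipped": self.n_skipped,
        }


@dataclass
class BurstSet:
    """Detected burst intervals (start_ms, end_ms) with participation counts."""

    intervals: np.ndarray  # (n, 2)
    n_electrodes: np.ndarray  # per-burst participating electrodes

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.n_electrodes = np.asarray(self.n_electrodes, dtype=int)
        if self.intervals.size:
            if np.any(self.intervals[:, 1] <= self.intervals[:, 0]):
                raise ValueError("burst end must exceed start")
            if np.any(np.diff(self.intervals[:, 0]) < 0):
                raise ValueError("burst intervals must be ordered")
            if np.any(self.intervals[1:, 0] < self.intervals[:-1, 1]):
                raise ValueError("burst intervals must be disjoint")

    def __len__(self) -> int:
        return int(self.intervals.shape[0])

    def frequency_hz(self, duration_s: float) -> float:
        return len(self) / duration_s

    def mean_ibi_s(self) -> float:
        """Mean onset-to-onset inter-burst interval, NaN with < 2 bursts."""
        if len(self) < 2:
            return float("nan")
        return float(np.diff(self.intervals[:, 0]).mean() / 1000.0)

    def overlaps(self, lo_ms: float, hi_ms: float) -> bool:
        """Whether any burst interval intersects [lo_ms, hi_ms)."""
        if len(self) == 0:
            return False
        return bool(np.any((self.intervals[:, 0] < hi_ms) & (self.intervals[:, 1] > lo_ms)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_ms": self.intervals[:, 0],
                "end_ms": self.intervals[:, 1],
                "n_electrodes": self.n_electrodes,
            }
        )


def compare_maps(
    map_before: ConnectivityMap,
    map_after: ConnectivityMap | None,
    spikes_after: SpikeData,
    schedule_after: StimulusSchedule,
    params: DetectionParams = DetectionParams(),
    cap_pct: float = 101.0,
) -> EfficacyChangeSummary:
    """Network efficacy change between two probings.

    For every connection detected in ``map_before`` the PSTH area is recomputed
    on the after-session for the same (pre, post) pair, whether or not it is
    independently re-detected there (``map_after`` is accepted for provenance
    but the recomputation is authoritative). Relative change is
    (area_after - area_before) / area_before * 100; positive changes above 100
    enter P as ``cap_pct`` (101 by default); N sums the negative changes;
    R = P/|N| (NaN when N = 0). Latency change is the re-estimated peak lag
    minus the before latency.
    """
    after = reprobe_map(map_before, spikes_after, schedule_after, params)
    after_by_pair = after.by_pair()
    rows = []
    n_skipped = 0
    for c in map_before.connections:
        if c.psth_area == 0:
            warnings.warn(f"connection ({c.pre}, {c.post}) has zero before-area; skipped")
            n_skipped += 1
            continue
        a = after_by_pair.get((c.pre, c.post))
        if a is None:
            n_skipped += 1
            continue
        rel = (a.psth_area - c.psth_area) / c.psth_area * 100.0
        capped = min(rel, cap_pct) if rel > 0 else rel
        rows.append(
            {
                "pre": c.pre,
                "post": c.post,
                "area_before": c.psth_area,
                "area_after": a.psth_area,
                "rel_change_pct": rel,
                "capped_pct": capped,
                "latency_delta_ms": a.latency_ms - c.latency_ms,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pre",
            "post",
            "area_before",
            "area_after",
            "rel_change_pct",
            "capped_pct",
            "latency_delta_ms",
        ],
    )
    pos = df.loc[df["capped_pct"] > 0, "capped_pct"]
    neg = df.loc[df["capped_pct"] < 0, "capped_pct"]
    P = float(pos.sum())
    N = float(neg.sum())
    R = float("nan") if N == 0 else P / abs(N)
    return EfficacyChangeSummary(df, P, N, R, n_skipped)


# ---------------------------------------------------------------------------
# Burstiness


def burstiness_index(
    spikes: SpikeData, bin_s: float = 1.0, top_frac: float = 0.15
) -> float:
    """BI = (f - top_frac)/(1 - top_frac), f = spike fraction in the top bins.

    All electrodes are pooled into ``bin_s`` bins; f is the fraction of spikes
    contained in the most active ``top_frac`` of bins. 0 means no bursting at
    all, 1 maximal burstiness (every spike inside the top bins).
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    if spikes.duration_ms < bin_s * 1000.0 / top_frac:
        raise ValueError("recording too short for the requested top fraction")
    pooled = spikes.pooled()
    if pooled.size == 0:
        raise ValueError("no spikes in recording")
    bin_ms = bin_s * 1000.0
    n_bins = int(np.ceil(spikes.duration_ms / bin_ms))
    counts, _ = np.histogram(pooled, bins=n_bins, range=(0.0, n_bins * bin_ms))
    n_top = max(1, int(round(top_frac * n_bins)))
    top = np.sort(counts)[::-1][:n_top]
    f = top.sum() / counts.sum()
    return float((f - top_frac) / (1.0 - top_frac))


def adaptive_top_frac(ibi_est_s: float, bin_s: float = 1.0, floor: float = 0.15) -> float:
    """Top-bin fraction adapted to fast-bursting cultures.

    Keeps one-burst-per-top-bin occupancy: with an estimated inter-burst
    interval shorter than bin_s/floor (6.7 s at defaults) the fraction grows to
    bin_s / IBI, otherwise it stays at ``floor``.
    """
    if ibi_est_s <= 0 or not np.isfinite(ibi_est_s):
        return floor
    return float(min(0.99, max(floor, bin_s / ibi_est_s)))


# ---------------------------------------------------------------------------
# Burst detection


@dataclass(frozen=True)
class SnbDetectParams:
    """Population-rate threshold burst detector parameters.

    Burst bins exceed ``rate_threshold_mult`` times the median nonzero
    population rate and have at least ``min_electrode_frac`` of electrodes
    active; adjacent burst bins within ``merge_gap_ms`` merge into one
    interval; intervals shorter than ``min_duration_ms`` are discarded.
    """

    rate_bin_ms: float = 10.0
    rate_threshold_mult: float = 5.0
    min_electrode_frac: float = 0.25
    min_duration_ms: float = 100.0
    merge_gap_ms: float = 100.0


def detect_snbs(
    spikes: SpikeData, params: SnbDetectParams = SnbDetectParams()
) -> BurstSet:
    """Detect synchronized network bursts from the population firing rate."""
    if spikes.duration_ms <= 0:
        raise ValueError("empty recording")
    bin_ms = params.rate_bin_ms
    n_bins = int(np.ceil(spikes.duration_ms / bin_ms))
    pop = np.zeros(n_bins, dtype=np.int64)
    active_per_bin = np.zeros(n_bins, dtype=np.int64)
    n_electrodes = 0
    for e in spikes.electrode_ids():
        t = spikes.get(int(e))
        n_electrodes += 1
        if t.size == 0:
            continue
        idx = np.minimum((t / bin_ms).astype(int), n_bins - 1)
        pop += np.bincount(idx, minlength=n_bins)
        active_per_bin += (np.bincount(idx, minlength=n_bins) > 0).astype(np.int64)
    nz = pop[pop > 0]
    if nz.size == 0:
        return BurstSet(np.empty((0, 2)), np.empty(0, dtype=int))
    thr = params.rate_threshold_mult * np.median(nz)
    min_elec = int(np.ceil(params.min_electrode_frac * n_electrodes))
    burst_bins = np.flatnonzero((pop > thr) & (active_per_bin >= min_elec))
    if burst_bins.size == 0:
        return BurstSet(np.empty((0, 2)), np.empty(0, dtype=int))

    gap_bins = int(np.ceil(params.merge_gap_ms / bin_ms))
    starts = [burst_bins[0]]
    ends = []
    for a, b in zip(burst_bins[:-1], burst_bins[1:]):
        if b - a > gap_bins:
            ends.append(a + 1)
            starts.append(b)
    ends.append(burst_bins[-1] + 1)

    intervals = []
    counts = []
    for s, e in zip(starts, ends):
        lo, hi = s * bin_ms, e * bin_ms
        if hi - lo < params.min_duration_ms:
            continue
        n_part = sum(
            1
            for el in spikes.electrode_ids()
            if _has_spike_in(spikes.get(int(el)), lo, hi)
        )
        intervals.append((lo, min(hi, spikes.duration_ms)))
        counts.append(n_part)
    if not intervals:
        return BurstSet(np.empty((0, 2)), np.empty(0, dtype=int))
    return BurstSet(np.asarray(intervals), np.asarray(counts))


def _has_spike_in(t: np.ndarray, lo: float, hi: float) -> bool:
    a = np.searchsorted(t, lo)
    b = np.searchsorted(t, hi)
    return b > a


# ---------------------------------------------------------------------------
# Culture QC


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    snb_frequency_hz: float = float("nan")

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def culture_qc(
    bursts: BurstSet,
    duration_s: float,
    rdm_R: float | None = None,
    freq_bounds_hz: tuple[float, float] = (0.05, 0.2),
    rdm_r_max: float = 0.2,
) -> QCResult:
    """Exclusion rules for cultures.

    A culture fails when its spontaneous burst frequency exceeds 0.2 Hz (too
    active) or falls below 0.05 Hz (too quiet), or — when an RDM-suppression
    efficacy ratio is supplied — when the random-dot stimulation failed to
    depress the network (R > 0.2).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    freq = bursts.frequency_hz(duration_s)
    reasons = []
    if freq > freq_bounds_hz[1]:
        reasons.append(f"too active: SNB frequency {freq:.3f} Hz > {freq_bounds_hz[1]} Hz")
    if freq < freq_bounds_hz[0]:
        reasons.append(f"too quiet: SNB frequency {freq:.3f} Hz < {freq_bounds_hz[0]} Hz")
    if rdm_R is not None and rdm_R > rdm_r_max:
        reasons.append(f"bursting not suppressed by RDMs: R {rdm_R:.3f} > {rdm_r_max}")
    return QCResult(passed=not reasons, reasons=reasons, snb_frequency_hz=freq)


# ---------------------------------------------------------------------------
# Firing-rate maps


def firing_rate_map(
    spikes: SpikeData, bin_ms: float = 100.0, top_frac: float = 0.15
) -> dict[int, float]:
    """Per-electrode firing rate (Hz) averaged over that electrode's top bins.

    Each electrode's spike counts in ``bin_ms`` bins are converted to rates and
    the mean over its most active ``top_frac`` of bins is reported — a map of
    within-burst firing when bursts dominate the recording.
    """
    if spikes.duration_ms <= 0:
        raise ValueError("empty recording")
    n_bins = int(np.ceil(spikes.duration_ms / bin_ms))
    n_top = max(1, int(round(top_frac * n_bins)))
    bin_s = bin_ms / 1000.0
    out: dict[int, float] = {}
    for e in spikes.electrode_ids():
        t = spikes.get(int(e))
        if t.size == 0:
            out[int(e)] = 0.0
            continue
        counts, _ = np.histogram(t, bins=n_bins, range=(0.0, n_bins * bin_ms))
        top = np.sort(counts)[::-1][:n_top]
        out[int(e)] = float(top.mean() / bin_s)
    return out
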