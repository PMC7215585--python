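"""Cross-correlogram (CCH) connectivity probing.

A probing session stimulates every grid position repeatedly with random-dot
frames while recording all electrodes. For each (stimulus position, electrode)
pair the cross-correlation histogram between the binarized electrode spike
series i(t) and the stimulus onset series j(t),

    cch(tau) = sum_t i(t) * j(t - tau),

is searched over positive lags. A sharp peak at lag tau_p means the electrode
consistently responds a fixed delay after that position is stimulated. The
peak value k is tested against a Poisson null with mean lambda (the mean of
cch over the searched lags): P(k) = exp(-lambda) * lambda**k / k!. A directed
connection is drawn when P(k) falls below the significance threshold AND the
electrode responds in at least half of the stimulation trials. Connection
efficacy is the area under the poststimulus time histogram (PSTH); latency is
tau_p.

Notes on conventions (all exposed as parameters):

* The stimulus series marks the frame *onset* bin only, so in the
  deterministic limit the CCH peak equals the number of responding trials.
* Lags are searched over 0-100 ms (one probing frame); lambda is the mean of
  cch over that searched range.
* P(k) is the Poisson pmf at k; an upper-tail variant is available via
  ``tail=True`` for users who prefer a survival-function test.
* A trial "responds" when the electrode spikes within +/- ``resp_window_ms``
  of onset + tau_p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .core import ElectrodeGrid, SpikeData
from .stimuli import StimulusSchedule

__all__ = [
    "Correlogram",
    "Connection",
    "ConnectivityMap",
    "DetectionParams",
    "binarize",
    "cross_correlogram",
    "poisson_peak_pvalue",
    "compute_psth",
    "detect_connection",
    "build_connectivity_map",
    "reprobe_map",
    "connectivity_summary",
]


@dataclass
class Correlogram:
    lags_ms: np.ndarray
    counts: np.ndarray

    @property
    def peak_value(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0

    @property
    def peak_lag_ms(self) -> float:
        # Ties resolve to the smallest lag.
        return float(self.lags_ms[int(np.argmax(self.counts))])

    @property
    def lam(self) -> float:
        return float(self.counts.mean()) if self.counts.size else 0.0


@dataclass
class Connection:
    """A detected directed stimulus-position -> electrode connection."""

    pre: int
    post: int
    latency_ms: float
    peak_per100: float
    p_value: float
    psth_area: float
    psth_peak: float
    n_responding_trials: int
    n_trials: int

    def to_dict(self) -> dict:
        return {
            "pre": self.pre,
            "post": self.post,
            "latency_ms": self.latency_ms,
            "peak_per100": self.peak_per100,
            "p_value": self.p_value,
            "psth_area": self.psth_area,
            "psth_peak": self.psth_peak,
            "n_responding_trials": self.n_responding_trials,
            "n_trials": self.n_trials,
        }


@dataclass
class ConnectivityMap:
    connections: list[Connection]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(c.pre, c.post) for c in self.connections]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (pre, post) pairs in connectivity map")

    def __len__(self) -> int:
        return len(self.connections)

    def pairs(self) -> set[tuple[int, int]]:
        return {(c.pre, c.post) for c in self.connections}

    def by_pair(self) -> dict[tuple[int, int], Connection]:
        return {(c.pre, c.post): c for c in self.connections}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.connections])

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "connections": [c.to_dict() for c in self.connections],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityMap":
        return cls(
            [Connection(**c) for c in d["connections"]], dict(d.get("metadata", {}))
        )


@dataclass(frozen=True)
class DetectionParams:
    """Connection-detection parameters.

    ``p_threshold`` defaults to 1e-6: higher (1e-5) admits too many connections
    (constantly firing channels pair with nearly every position), lower (1e-7)
    too few, inflating the variance of downstream network statistics.
    """

    bin_ms: float = 1.0
    lag_min_ms: float = 0.0
    lag_max_ms: float = 100.0
    p_threshold: float = 1e-6
    resp_window_ms: float = 5.0
    psth_window_ms: float = 100.0
    psth_bin_ms: float = 1.0
    tail: bool = False  # True: upper-tail Poisson probability instead of the pmf


# ---------------------------------------------------------------------------
# Primitives


def binarize(event_times: np.ndarray, duration_ms: float, bin_ms: float = 1.0) -> np.ndarray:
    """Binary time series: entry 1 iff at least one event falls in the bin."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    t = np.asarray(event_times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > duration_ms):
        raise ValueError("events outside [0, duration_ms]")
    n_bins = int(np.ceil(duration_ms / bin_ms)) if duration_ms > 0 else 0
    out = np.zeros(n_bins, dtype=np.uint8)
    if t.size:
        idx = np.minimum((t / bin_ms).astype(int), n_bins - 1)
        out[idx] = 1
    return out


def cross_correlogram(
    response_series: np.ndarray,
    stimulus_series: np.ndarray,
    lag_range_ms: tuple[float, float] = (0.0, 100.0),
    bin_ms: float = 1.0,
) -> Correlogram:
    """cch(tau) = sum_t i(t) j(t - tau) over the requested lag range."""
    i = np.asarray(response_series, dtype=np.int64)
    j = np.asarray(stimulus_series, dtype=np.int64)
    if i.shape != j.shape:
        raise ValueError("series must have equal length and binning")
    n = i.size
    lag_bins = np.arange(
        int(round(lag_range_ms[0] / bin_ms)), int(round(lag_range_ms[1] / bin_ms)) + 1
    )
    counts = np.zeros(lag_bins.size, dtype=np.int64)
    if n:
        for m, L in enumerate(lag_bins):
            if L >= 0:
                if L < n:
                    counts[m] = int(np.dot(i[L:], j[: n - L]))
            else:
                if -L < n:
                    counts[m] = int(np.dot(i[: n + L], j[-L:]))
    return Correlogram(lag_bins * bin_ms, counts)


def poisson_peak_pvalue(peak: int, lam: float, tail: bool = False) -> float:
    """Chance of a correlogram peak of ``peak`` under a Poisson null of mean ``lam``.

    Computed in log space: exp(k log lam - lam - log k!). With ``tail=True``
    returns P(X >= k) instead of the pmf.
    """
    if peak < 0:
        raise ValueError("peak must be a non-negative integer")
    k = int(peak)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    if tail:
        # P(X >= k) = regularized lower incomplete gamma P(k, lam).
        return float(special.gammainc(k, lam)) if k > 0 else 1.0
    return float(np.exp(k * np.log(lam) - lam - special.gammaln(k + 1)))


def compute_psth(
    post_spikes: np.ndarray,
    stim_onsets: np.ndarray,
    window_ms: float = 100.0,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, float, float]:
    """Per-trial-normalized PSTH, its area (spikes/trial) and peak bin height.

    Spikes in [onset, onset + window) are pooled over trials and divided by the
    trial count; the area is the summed per-trial count over the window.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    onsets = np.asarray(stim_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("compute_psth needs at least one trial")
    spikes = np.asarray(post_spikes, dtype=float)
    n_bins = int(np.ceil(window_ms / bin_ms))
    hist = np.zeros(n_bins)
    for t0 in onsets:
        lo, hi = np.searchsorted(spikes, [t0, t0 + window_ms])
        if hi > lo:
            rel = spikes[lo:hi] - t0
            idx = np.minimum((rel / bin_ms).astype(int), n_bins - 1)
            np.add.at(hist, idx, 1.0)
    hist /= onsets.size
    return hist, float(hist.sum()), float(hist.max())


def _count_responding_trials(
    post_spikes: np.ndarray,
    stim_onsets: np.ndarray,
    latency_ms: float,
    resp_window_ms: float,
) -> int:
    spikes = np.asarray(post_spikes, dtype=float)
    lo = stim_onsets + latency_ms - resp_window_ms
    hi = stim_onsets + latency_ms + resp_window_ms
    a = np.searchsorted(spikes, lo)
    b = np.searchsorted(spikes, hi, side="right")
    return int(np.sum(b > a))


def detect_connection(
    post_spikes: np.ndarray,
    stim_onsets: np.ndarray,
    duration_ms: float,
    params: DetectionParams = DetectionParams(),
) -> Connection | None:
    """Test one (position, electrode) pair; returns a Connection or None.

    The connection is drawn iff the Poisson peak test passes ``p_threshold``
    AND the electrode responds (a spike within tau_p +/- resp_window) in at
    least ceil(n_trials / 2) trials.
    """
    onsets = np.asarray(stim_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one stimulus onset")
    i = binarize(post_spikes, duration_ms, params.bin_ms)
    j = binarize(onsets, duration_ms, params.bin_ms)
    cch = cross_correlogram(i, j, (params.lag_min_ms, params.lag_max_ms), params.bin_ms)
    return _evaluate_pair(cch, post_spikes, onsets, params)


def _evaluate_pair(
    cch: Correlogram,
    post_spikes: np.ndarray,
    onsets: np.ndarray,
    params: DetectionParams,
    pre: int = -1,
    post: int = -1,
) -> Connection | None:
    k, tau_p, lam = cch.peak_value, cch.peak_lag_ms, cch.lam
    p = poisson_peak_pvalue(k, lam, tail=params.tail)
    n_trials = onsets.size
    min_resp = int(np.ceil(n_trials / 2))
    n_resp = _count_responding_trials(post_spikes, onsets, tau_p, params.resp_window_ms)
    if p >= params.p_threshold or n_resp < min_resp:
        return None
    _, area, peak_h = compute_psth(
        post_spikes, onsets, params.psth_window_ms, params.psth_bin_ms
    )
    return Connection(
        pre=pre,
        post=post,
        latency_ms=tau_p,
        peak_per100=100.0 * k / n_trials,
        p_value=p,
        psth_area=area,
        psth_peak=peak_h,
        n_responding_trials=n_resp,
        n_trials=n_trials,
    )


# ---------------------------------------------------------------------------
# Whole-map construction


def _onset_bins_by_position(
    schedule: StimulusSchedule, bin_ms: float
) -> dict[int, np.ndarray]:
    out: dict[int, list[int]] = {}
    for f in schedule.frames:
        b = int(f.onset_ms / bin_ms)
        for p in f.positions:
            out.setdefault(p, []).append(b)
    return {p: np.asarray(v, dtype=np.int64) for p, v in out.items()}


def build_connectivity_map(
    spikes: SpikeData,
    schedule: StimulusSchedule,
    params: DetectionParams = DetectionParams(),
) -> ConnectivityMap:
    """Evaluate every (stimulus position, electrode) pair of a probing session.

    The CCH of all positions against one electrode is computed with a single
    vectorized gather over the onset bins, then the Poisson test screens the
    pairs; the trial-response criterion and PSTH are evaluated only for the
    survivors.
    """
    if schedule.frames and spikes.duration_ms + 1e-9 < (
        schedule.frames[-1].onset_ms + schedule.frames[-1].on_ms
    ):
        raise ValueError("recording shorter than the stimulation schedule")
    lag_bins = np.arange(
        int(round(params.lag_min_ms / params.bin_ms)),
        int(round(params.lag_max_ms / params.bin_ms)) + 1,
    )
    pos_bins = _onset_bins_by_position(schedule, params.bin_ms)
    positions = sorted(pos_bins)
    if not positions or spikes.n_spikes == 0:
        return ConnectivityMap([], {"n_positions": len(positions)})

    n_bins = int(np.ceil(spikes.duration_ms / params.bin_ms))
    pad = int(lag_bins.max()) + 1

    counts_per_pos = np.array([pos_bins[p].size for p in positions])
    uniform = counts_per_pos.min() == counts_per_pos.max()
    if uniform:
        onset_mat = np.stack([pos_bins[p] for p in positions])  # (P, n_reps)
        gather_idx = onset_mat[:, :, None] + lag_bins[None, None, :]

    connections: list[Connection] = []
    for e in spikes.electrode_ids():
        st = spikes.get(int(e))
        if st.size == 0:
            continue
        i = np.zeros(n_bins + pad, dtype=np.uint8)
        idx = np.minimum((st / params.bin_ms).astype(int), n_bins - 1)
        i[idx] = 1
        if uniform:
            cch_all = i[gather_idx].sum(axis=1, dtype=np.int64)  # (P, L)
        else:
            cch_all = np.stack(
                [i[pos_bins[p][:, None] + lag_bins[None, :]].sum(0) for p in positions]
            )
        k = cch_all.max(axis=1)
        lam = cch_all.mean(axis=1)
        # Vectorized Poisson screen; exact p recomputed for survivors.
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(lam > 0, k * np.log(lam) - lam - special.gammaln(k + 1), 0.0)
        cand = np.flatnonzero((lam > 0) & (logp < np.log(params.p_threshold)))
        for ci in cand:
            p_idx = positions[ci]
            onsets = pos_bins[p_idx].astype(float) * params.bin_ms
            cch = Correlogram(lag_bins * params.bin_ms, cch_all[ci])
            conn = _evaluate_pair(cch, st, onsets, params, pre=int(p_idx), post=int(e))
            if conn is not None:
                connections.append(conn)
    meta = {
        "n_positions": len(positions),
        "n_electrodes": int(spikes.electrode_ids().size),
        "params": {
            "bin_ms": params.bin_ms,
            "lag_min_ms": params.lag_min_ms,
            "lag_max_ms": params.lag_max_ms,
            "p_threshold": params.p_threshold,
            "resp_window_ms": params.resp_window_ms,
            "psth_window_ms": params.psth_window_ms,
            "psth_bin_ms": params.psth_bin_ms,
        },
    }
    return ConnectivityMap(connections, meta)


def reprobe_map(
    ref_map: ConnectivityMap,
    spikes: SpikeData,
    schedule: StimulusSchedule,
    params: DetectionParams = DetectionParams(),
) -> ConnectivityMap:
    """Re-measure latency/PSTH of a reference pair set on another session.

    Every (pre, post) pair of ``ref_map`` is re-evaluated on the new session
    whether or not it would be independently re-detected there; this anchors
    before/after comparisons on a fixed connection set.
    """
    pos_bins = _onset_bins_by_position(schedule, params.bin_ms)
    lag_range = (params.lag_min_ms, params.lag_max_ms)
    out: list[Connection] = []
    n_bins = int(np.ceil(spikes.duration_ms / params.bin_ms))
    cache: dict[int, np.ndarray] = {}
    for c in ref_map.connections:
        onset_bins = pos_bins.get(c.pre)
        if onset_bins is None:
            continue
        onsets = onset_bins.astype(float) * params.bin_ms
        st = spikes.get(c.post)
        if c.post not in cache:
            vec = np.zeros(n_bins, dtype=np.uint8)
            if st.size:
                idx = np.minimum((st / params.bin_ms).astype(int), n_bins - 1)
                vec[idx] = 1
            cache[c.post] = vec
        j = np.zeros(n_bins, dtype=np.uint8)
        j[onset_bins] = 1
        cch = cross_correlogram(cache[c.post], j, lag_range, params.bin_ms)
        k, tau_p, lam = cch.peak_value, cch.peak_lag_ms, cch.lam
        _, area, peak_h = compute_psth(st, onsets, params.psth_window_ms, params.psth_bin_ms)
        out.append(
            Connection(
                pre=c.pre,
                post=c.post,
                latency_ms=tau_p,
                peak_per100=100.0 * k / onsets.size,
                p_value=poisson_peak_pvalue(k, lam, tail=params.tail),
                psth_area=area,
                psth_peak=peak_h,
                n_responding_trials=_count_responding_trials(
                    st, onsets, tau_p, params.resp_window_ms
                ),
                n_trials=onsets.size,
            )
        )
    return ConnectivityMap(out, {"reprobed_from": ref_map.metadata})


# ---------------------------------------------------------------------------
# Summaries


def connectivity_summary(
    cmap: ConnectivityMap,
    geometry: ElectrodeGrid,
    stim_grid_shape: tuple[int, int] = (16, 16),
    distance_bin_um: float = 200.0,
) -> dict:
    """Distance, latency and peak histograms over the detected connections.

    Stimulus-position coordinates are laid on the electrode plane (both grids
    cover the array area), distances binned at the electrode pitch.
    """
    if len(cmap) == 0:
        return {
            "n_connections": 0,
            "distance_hist": pd.DataFrame(
                columns=["bin_lo_um", "bin_hi_um", "count", "latency_mean_ms", "latency_sd_ms"]
            ),
            "latency_ms": np.empty(0),
            "peak_per100": np.empty(0),
        }
    nr, nc = stim_grid_shape
    er, ec = geometry.shape
    extent_x = (ec - 1) * geometry.pitch_um
    extent_y = (er - 1) * geometry.pitch_um

    pre_idx = np.array([c.pre for c in cmap.connections])
    rows, cols = np.divmod(pre_idx, nc)
    pre_xy = np.stack(
        [cols * extent_x / max(nc - 1, 1), rows * extent_y / max(nr - 1, 1)], axis=-1
    )
    post_xy = geometry.coords_um(np.array([c.post for c in cmap.connections]))
    dist = np.hypot(*(pre_xy - post_xy).T)
    lat = np.array([c.latency_ms for c in cmap.connections])
    peak = np.array([c.peak_per100 for c in cmap.connections])

    edges = np.arange(0.0, dist.max() + distance_bin_um, distance_bin_um)
    if edges.size < 2:
        edges = np.array([0.0, distance_bin_um])
    which = np.clip(np.digitize(dist, edges) - 1, 0, edges.size - 2)
    rows_out = []
    for b in range(edges.size - 1):
        in_bin = which == b
        rows_out.append(
            {
                "bin_lo_um": edges[b],
                "bin_hi_um": edges[b + 1],
                "count": int(in_bin.sum()),
                "latency_mean_ms": float(lat[in_bin].mean()) if in_bin.any() else np.nan,
                "latency_sd_ms": float(lat[in_bin].std(ddof=0)) if in_bin.any() else np.nan,
            }
        )
    return {
        "n_connections": len(cmap),
        "distance_hist": pd.DataFrame(rows_out),
        "distance_um": dist,
        "latency_ms": lat,
        "peak_per100": peak,
    }
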