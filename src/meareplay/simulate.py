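"""Ground-truth spiking-network simulator.

The simulator emulates the phenomenology of a dense dissociated cortical
culture on an MEA under optogenetic stimulation:

* sparse asynchronous **background** firing (homogeneous Poisson per electrode);
* periodic **synchronized network bursts** (SNBs): network-wide high-frequency
  firing events lasting a few hundred milliseconds, recurring every 5-10 s;
* **stimulus-evoked responses**: each directed connection from a stimulus grid
  position to an electrode fires at most one spike per stimulation with a
  per-connection response probability and a ~30 ms latency;
* **plasticity transforms**: multiplicative response-probability changes
  mimicking high-frequency tetanization (hub-clustered potentiation, or
  network-wide depression in burst-saturated cultures) and random-dot-movie
  stimulation (network-wide depression with burst suppression);
* optional **replay bias**: during SNBs, per-electrode rate gains proportional
  to the electrode's evoked response to a stored pattern, so that spontaneous
  bursts statistically resemble the trained response.

This is a phenomenological generator, not a biophysical model; it exists so
that every analysis in the package can be validated against known ground truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core import ElectrodeGrid, SpikeData
from .stimuli import PatternMask, StimulusSchedule

__all__ = [
    "Synapse",
    "SNBParams",
    "GroundTruthNetwork",
    "make_default_network",
    "simulate_spontaneous",
    "simulate_evoked",
    "apply_tetanus_plasticity",
    "apply_rdm_ltd",
    "arm_replay_bias",
    "detect_spikes_threshold",
]


@dataclass
class Synapse:
    """Directed stimulus-position -> electrode connection."""

    pre: int
    post: int
    response_prob: float
    latency_mean_ms: float = 30.0
    latency_sd_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must be in [0, 1]")
        if self.latency_mean_ms <= 0:
            raise ValueError("latency_mean_ms must be positive")


@dataclass
class SNBParams:
    """Synchronized-network-burst generator parameters.

    Inter-burst gaps are Normal(ibi_mean_s, ibi_sd_s) truncated to exceed the
    burst duration (bursts never overlap). During a burst every electrode fires
    Poisson at ``within_rate_hz * participation[e]`` (times the replay gain for
    the armed pattern, if any).
    """

    ibi_mean_s: float = 6.7
    ibi_sd_s: float = 1.5
    duration_ms: float = 300.0
    within_rate_hz: float = 150.0
    participation: np.ndarray | None = None  # per-electrode gain, grid order

    def __post_init__(self) -> None:
        if self.ibi_mean_s <= 0:
            raise ValueError("ibi_mean_s must be positive")
        if self.participation is not None:
            self.participation = np.asarray(self.participation, dtype=float)
            if np.any(self.participation < 0):
                raise ValueError("participation gains must be >= 0")


@dataclass
class GroundTruthNetwork:
    """Simulator state: geometry, connections, background/SNB/replay parameters."""

    stim_grid_shape: tuple[int, int] = (16, 16)
    geometry: ElectrodeGrid = field(default_factory=ElectrodeGrid)
    connections: list[Synapse] = field(default_factory=list)
    background_rate_hz: float = 0.5
    snb: SNBParams = field(default_factory=SNBParams)
    replay_bias: dict[str, np.ndarray] | None = None
    armed_pattern: str | None = None

    def __post_init__(self) -> None:
        if self.background_rate_hz < 0:
            raise ValueError("background_rate_hz must be >= 0")
        n_stim = self.stim_grid_shape[0] * self.stim_grid_shape[1]
        active = set(self.geometry.active_ids.tolist())
        for c in self.connections:
            if not 0 <= c.pre < n_stim:
                raise ValueError(f"connection pre {c.pre} outside stimulus grid")
            if c.post not in active:
                raise ValueError(f"connection post {c.post} not an active electrode")

    def participation(self) -> np.ndarray:
        p = self.snb.participation
        if p is None:
            p = np.ones(self.geometry.n_positions)
        return p

    def true_pairs(self) -> set[tuple[int, int]]:
        return {(c.pre, c.post) for c in self.connections}

    def copy(self) -> "GroundTruthNetwork":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "stim_grid_shape": list(self.stim_grid_shape),
            "geometry": self.geometry.to_dict(),
            "background_rate_hz": self.background_rate_hz,
            "snb": {
                "ibi_mean_s": self.snb.ibi_mean_s,
                "ibi_sd_s": self.snb.ibi_sd_s,
                "duration_ms": self.snb.duration_ms,
                "within_rate_hz": self.snb.within_rate_hz,
                "participation": None
                if self.snb.participation is None
                else self.snb.participation.tolist(),
            },
            "connections": [
                {
                    "pre": c.pre,
                    "post": c.post,
                    "response_prob": c.response_prob,
                    "latency_mean_ms": c.latency_mean_ms,
                    "latency_sd_ms": c.latency_sd_ms,
                }
                for c in self.connections
            ],
            "replay_bias": None
            if self.replay_bias is None
            else {k: v.tolist() for k, v in self.replay_bias.items()},
            "armed_pattern": self.armed_pattern,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthNetwork":
        snb = d["snb"]
        bias = d.get("replay_bias")
        return cls(
            stim_grid_shape=tuple(d["stim_grid_shape"]),
            geometry=ElectrodeGrid.from_dict(d["geometry"]),
            connections=[Synapse(**c) for c in d["connections"]],
            background_rate_hz=float(d["background_rate_hz"]),
            snb=SNBParams(
                ibi_mean_s=snb["ibi_mean_s"],
                ibi_sd_s=snb["ibi_sd_s"],
                duration_ms=snb["duration_ms"],
                within_rate_hz=snb["within_rate_hz"],
                participation=None
                if snb["participation"] is None
                else np.asarray(snb["participation"]),
            ),
            replay_bias=None if bias is None else {k: np.asarray(v) for k, v in bias.items()},
            armed_pattern=d.get("armed_pattern"),
        )


def make_default_network(
    seed: int = 0,
    n_connections: int = 200,
    response_prob_range: tuple[float, float] = (0.5, 0.95),
    background_rate_hz: float = 0.5,
    latency_mean_ms: float = 30.0,
    latency_sd_ms: float = 1.0,
    snb: SNBParams | None = None,
    stim_grid_shape: tuple[int, int] = (16, 16),
    geometry: ElectrodeGrid | None = None,
) -> GroundTruthNetwork:
    """A randomly wired culture with defaults matching a mature preparation.

    Connections are unique (pre, post) pairs drawn uniformly over stimulus
    positions and active electrodes; response probabilities are uniform over
    ``response_prob_range``; SNB participation gains are LogNormal around 1.
    """
    rng = np.random.default_rng(seed)
    geometry = geometry or ElectrodeGrid()
    n_stim = stim_grid_shape[0] * stim_grid_shape[1]
    active = geometry.active_ids

    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_connections:
        pre = int(rng.integers(n_stim))
        post = int(active[rng.integers(active.size)])
        pairs.add((pre, post))
    conns = [
        Synapse(
            pre,
            post,
            float(rng.uniform(*response_prob_range)),
            latency_mean_ms,
            latency_sd_ms,
        )
        for pre, post in sorted(pairs)
    ]
    if snb is None:
        part = np.ones(geometry.n_positions)
        part[active] = rng.lognormal(mean=0.0, sigma=0.3, size=active.size)
        snb = SNBParams(participation=part)
    return GroundTruthNetwork(
        stim_grid_shape=stim_grid_shape,
        geometry=geometry,
        connections=conns,
        background_rate_hz=background_rate_hz,
        snb=snb,
    )


# ---------------------------------------------------------------------------
# Simulation


def _draw_burst_onsets(
    rng: np.random.Generator, duration_ms: float, snb: SNBParams
) -> np.ndarray:
    """Burst onset times: truncated-normal inter-onset gaps, no overlap."""
    onsets = []
    t = 0.0
    gap_floor = snb.duration_ms  # gaps must exceed the burst duration
    while True:
        gap = rng.normal(snb.ibi_mean_s * 1000.0, snb.ibi_sd_s * 1000.0)
        while gap <= gap_floor:
            gap = rng.normal(snb.ibi_mean_s * 1000.0, snb.ibi_sd_s * 1000.0)
        t += gap
        if t + snb.duration_ms > duration_ms:
            break
        onsets.append(t)
    return np.asarray(onsets)


def _replay_gains(net: GroundTruthNetwork) -> np.ndarray | None:
    if net.armed_pattern is None or not net.replay_bias:
        return None
    return net.replay_bias.get(net.armed_pattern)


def simulate_spontaneous(
    net: GroundTruthNetwork,
    duration_s: float,
    seed: int = 0,
    return_bursts: bool = False,
):
    """Spontaneous activity: Poisson background plus periodic SNBs.

    With ``return_bursts=True`` also returns the ground-truth (start, end)
    burst intervals in ms, for validating burst detectors.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if net.background_rate_hz < 0 or net.snb.within_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    duration_ms = duration_s * 1000.0
    active = net.geometry.active_ids
    part = net.participation()
    gains = _replay_gains(net)

    onsets = _draw_burst_onsets(rng, duration_ms, net.snb)
    spikes: dict[int, list[np.ndarray]] = {int(e): [] for e in active}

    # Background
    rate = net.background_rate_hz
    if rate > 0:
        for e in active:
            n = rng.poisson(rate * duration_s)
            if n:
                spikes[int(e)].append(rng.uniform(0.0, duration_ms, size=n))

    # Bursts
    burst_dur_s = net.snb.duration_ms / 1000.0
    for t0 in onsets:
        for e in active:
            r = net.snb.within_rate_hz * part[e]
            if gains is not None:
                r *= gains[e]
            n = rng.poisson(r * burst_dur_s)
            if n:
                spikes[int(e)].append(t0 + rng.uniform(0.0, net.snb.duration_ms, size=n))

    out = {
        e: np.sort(np.concatenate(v)) if v else np.empty(0) for e, v in spikes.items()
    }
    data = SpikeData(out, duration_ms, net.geometry)
    if return_bursts:
        intervals = np.stack([onsets, onsets + net.snb.duration_ms], axis=-1) if onsets.size else np.empty((0, 2))
        return data, intervals
    return data


def simulate_evoked(
    net: GroundTruthNetwork,
    schedule: StimulusSchedule,
    seed: int = 0,
    with_snbs: bool = False,
) -> SpikeData:
    """Stimulus-evoked activity for a schedule, on top of background (and SNBs).

    For every frame and every connection whose presynaptic position is lit, the
    postsynaptic electrode emits at most one spike, with probability
    ``response_prob * frame.intensity`` (clipped to 1), at
    onset + Normal(latency_mean, latency_sd). Frame intensity models the
    stimulus luminance, which experiments tune to balance the baseline
    responses elicited by different patterns.
    """
    if schedule.grid_shape != net.stim_grid_shape:
        raise ValueError(
            f"schedule grid {schedule.grid_shape} does not match network grid "
            f"{net.stim_grid_shape}"
        )
    rng = np.random.default_rng(seed)
    duration_ms = schedule.total_duration_ms
    active = net.geometry.active_ids

    # Per-position (onset, intensity) lists (computed once).
    pos_onsets: dict[int, list[tuple[float, float]]] = {}
    for f in schedule.frames:
        for p in f.positions:
            pos_onsets.setdefault(p, []).append((f.onset_ms, f.intensity))

    evoked: dict[int, list[np.ndarray]] = {}
    for c in net.connections:
        trials = pos_onsets.get(c.pre)
        if not trials:
            continue
        onsets = np.asarray([t[0] for t in trials])
        gain = np.asarray([t[1] for t in trials])
        # One uniform and one latency drawn per trial regardless of outcome:
        # raising response_prob only adds responses, keeping detection monotone.
        u = rng.random(onsets.size)
        lat = rng.normal(c.latency_mean_ms, c.latency_sd_ms, size=onsets.size)
        fired = u < np.minimum(1.0, c.response_prob * gain)
        if not fired.any():
            continue
        t = onsets[fired] + np.clip(lat[fired], 0.0, None)
        t = t[t <= duration_ms]
        if t.size:
            evoked.setdefault(c.post, []).append(t)

    # Background (and optional SNBs) over the same window.
    base_net = net if with_snbs else _without_bursts(net)
    bg = simulate_spontaneous(base_net, duration_ms / 1000.0, seed=int(rng.integers(2**31)))

    out: dict[int, np.ndarray] = {}
    for e in active:
        parts = [bg.get(int(e))]
        parts.extend(evoked.get(int(e), []))
        out[int(e)] = np.sort(np.concatenate(parts))
    return SpikeData(out, duration_ms, net.geometry)


def _without_bursts(net: GroundTruthNetwork) -> GroundTruthNetwork:
    quiet = net.copy()
    quiet.snb = SNBParams(
        ibi_mean_s=net.snb.ibi_mean_s,
        ibi_sd_s=net.snb.ibi_sd_s,
        duration_ms=net.snb.duration_ms,
        within_rate_hz=0.0,
        participation=net.snb.participation,
    )
    return quiet


# ---------------------------------------------------------------------------
# Plasticity transforms


def _lit_stim_positions(net: GroundTruthNetwork, pattern: PatternMask) -> set[int]:
    """Pattern lit cells mapped onto the network stimulus grid (proportional)."""
    pr, pc = pattern.grid_shape
    nr, nc = net.stim_grid_shape
    lit: set[int] = set()
    for idx in pattern.lit_positions():
        r, c = divmod(idx, pc)
        rr = min(nr - 1, int(r * nr / pr))
        cc = min(nc - 1, int(c * nc / pc))
        lit.add(rr * nc + cc)
    return lit


def apply_tetanus_plasticity(
    net: GroundTruthNetwork,
    pattern: PatternMask,
    hub_threshold: int = 1,
    potentiation_gain: float = 1.8,
    depression_gain: float = 0.8,
    bursty: bool = False,
) -> GroundTruthNetwork:
    """Plasticity induced by high-frequency pattern tetanization.

    Non-bursty regime: connections whose presynaptic position is lit by the
    pattern AND whose postsynaptic electrode receives at least ``hub_threshold``
    lit inputs are potentiated (response_prob * potentiation_gain, capped at 1).
    Bursty regime: burst-saturated cultures instead undergo network-wide
    depression (every response_prob * depression_gain).
    """
    if potentiation_gain <= 0 or depression_gain <= 0:
        raise ValueError("gains must be positive")
    new = net.copy()
    if bursty:
        for c in new.connections:
            c.response_prob = c.response_prob * depression_gain
        return new
    lit = _lit_stim_positions(net, pattern)
    lit_inputs_per_post: dict[int, int] = {}
    for c in new.connections:
        if c.pre in lit:
            lit_inputs_per_post[c.post] = lit_inputs_per_post.get(c.post, 0) + 1
    for c in new.connections:
        if c.pre in lit and lit_inputs_per_post.get(c.post, 0) >= hub_threshold:
            c.response_prob = min(1.0, c.response_prob * potentiation_gain)
    return new


def apply_rdm_ltd(
    net: GroundTruthNetwork,
    depression_factor: float,
    ibi_stretch: float = 3.0,
) -> GroundTruthNetwork:
    """Network-wide depression after prolonged random-dot-movie stimulation.

    Every response probability is multiplied by ``depression_factor``; burst
    occurrence is suppressed by stretching the mean inter-burst interval by
    ``ibi_stretch``.
    """
    if not 0 < depression_factor <= 1:
        raise ValueError("depression_factor must be in (0, 1]")
    if ibi_stretch < 1:
        raise ValueError("ibi_stretch must be >= 1")
    new = net.copy()
    for c in new.connections:
        c.response_prob = c.response_prob * depression_factor
    new.snb.ibi_mean_s = net.snb.ibi_mean_s * ibi_stretch
    return new


def arm_replay_bias(
    net: GroundTruthNetwork,
    pattern: PatternMask,
    strength: float = 0.8,
) -> GroundTruthNetwork:
    """Store a pattern as the replay target for subsequent SNBs.

    The per-electrode gain during bursts is a convex blend between uniform and
    the electrode's expected evoked response to the pattern (normalized to unit
    mean over active electrodes): gain = (1 - strength) + strength * resp/mean.
    ``strength=0`` leaves bursts unbiased.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must be in [0, 1]")
    new = net.copy()
    lit = _lit_stim_positions(net, pattern)
    resp = np.zeros(net.geometry.n_positions)
    for c in net.connections:
        if c.pre in lit:
            resp[c.post] += c.response_prob
    active = net.geometry.active_ids
    mean = resp[active].mean()
    gains = np.ones(net.geometry.n_positions)
    if mean > 0:
        gains[active] = (1.0 - strength) + strength * resp[active] / mean
    if new.replay_bias is None:
        new.replay_bias = {}
    new.replay_bias[pattern.name] = gains
    new.armed_pattern = pattern.name
    return new


# ---------------------------------------------------------------------------
# Threshold spike detection (demonstration-scale)


def detect_spikes_threshold(
    voltage_trace: np.ndarray,
    noise_sigma_estimate: float,
    multiplier: float = 6.0,
    fs_hz: float = 20_000.0,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Times (ms) of negative-going threshold crossings in a voltage trace.

    The threshold is ``-multiplier * noise_sigma_estimate`` (the conventional
    6-sigma rule); after each crossing a refractory lockout suppresses
    re-triggering on the same waveform.
    """
    trace = np.asarray(voltage_trace, dtype=float)
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if trace.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(trace)):
        raise ValueError("voltage trace must be finite")
    thr = -multiplier * noise_sigma_estimate
    below = trace < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.insert(crossings, 0, 0)
    lockout = int(round(refractory_ms * fs_hz / 1000.0))
    kept = []
    last = -lockout - 1
    for i in crossings:
        if i - last > lockout:
            kept.append(i)
            last = i
    return np.asarray(kept, dtype=float) / fs_hz * 1000.0
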