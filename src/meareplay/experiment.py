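"""End-to-end simulated learning experiments.

Two paradigms are reproduced against the ground-truth simulator:

* **conventional**: probe - baseline - probe - tetanus - probe - testing - probe,
  applied to a burst-dominated culture (the tetanus drives network-wide
  depression and no burst replay of the trained pattern is armed);
* **rdm**: probe - baseline - probe - RDM - probe - tetanus - probe - testing -
  probe, where prolonged random-dot stimulation first depresses the network
  and suppresses bursting, the tetanus then selectively potentiates the
  trained pattern's connections, and subsequent bursts are biased toward the
  stored pattern (replay).

Between consecutive phases a probing session measures the connectivity map;
each phase's network efficacy change R = P/|N| is computed on the baseline
map's pair set, comparing consecutive probing sessions. The baseline and
testing phases present all three candidate patterns; a per-bin SVM decoder
trained on those responses classifies burst bins of the pre-baseline and
post-learning spontaneous recordings, yielding the replay ratios and the
familiarity metrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__ as _version
from .plasticity import (
    SnbDetectParams,
    burstiness_index,
    compare_maps,
    culture_qc,
    detect_snbs,
)
from .probing import DetectionParams, build_connectivity_map, reprobe_map
from .replay import (
    classify_snb_bins,
    extract_trials,
    familiarity_delta,
    pattern_response_summary,
    train_pattern_classifier,
)
from .simulate import (
    GroundTruthNetwork,
    apply_rdm_ltd,
    apply_tetanus_plasticity,
    arm_replay_bias,
    simulate_evoked,
    simulate_spontaneous,
)
from .stimuli import balance_luminance, make_pattern, make_probing_schedule, make_test_schedule

__all__ = ["ExperimentConfig", "ExperimentResult", "QCFailure", "run_experiment"]


class QCFailure(RuntimeError):
    def __init__(self, reasons: list[str]):
        super().__init__("; ".join(reasons))
        self.reasons = reasons


@dataclass
class ExperimentConfig:
    """Tunable parameters of a simulated experiment (defaults per protocol)."""

    pattern_names: tuple[str, str, str] = ("car", "dog", "human")
    trained_pattern: str = "human"
    # Probing movie
    probe_n_reps: int = 20
    probe_dots_per_frame: int = 5
    probe_frame_ms: float = 100.0
    probe_on_ms: float = 40.0
    # Test sessions
    test_trials_per_pattern: int = 10
    test_interval_s: float = 10.0
    test_on_ms: float = 100.0
    trial_window_ms: float = 200.0
    trial_bin_ms: float = 10.0
    pre_exclusion_s: float = 1.0
    # Spontaneous recordings
    qc_duration_s: float = 600.0
    replay_recording_s: float = 300.0
    # Plasticity transforms
    rdm_depression_factor: float = 0.3
    rdm_ibi_stretch: float = 3.0
    hub_threshold: int = 1
    potentiation_gain: float = 1.8
    depression_gain: float = 0.8
    replay_bias_strength: float = 0.8
    # Analysis parameters
    detection: DetectionParams = field(default_factory=DetectionParams)
    snb_detect: SnbDetectParams = field(default_factory=SnbDetectParams)
    skip_qc: bool = False

    def patterns(self, grid_shape: tuple[int, int]):
        """Luminance-balanced pattern masks on the stimulation grid."""
        return balance_luminance([make_pattern(n, grid_shape) for n in self.pattern_names])


@dataclass
class ExperimentResult:
    paradigm: str
    qc: dict
    burstiness: float
    phase_R: dict  # phase name -> P/N/R summary dict
    n_connections_baseline: int
    firing_rate: dict  # per pattern mean/SEM at baseline and testing
    firing_rate_delta: float
    replay_before: dict
    replay_after: dict
    replay_delta: float
    replay_ratio_change: float
    dropped_trials: dict
    manifest: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "paradigm": self.paradigm,
                "qc": self.qc,
                "burstiness": self.burstiness,
                "phase_R": self.phase_R,
                "n_connections_baseline": self.n_connections_baseline,
                "firing_rate": self.firing_rate,
                "firing_rate_delta": _nan_none(self.firing_rate_delta),
                "replay_before": self.replay_before,
                "replay_after": self.replay_after,
                "replay_delta": _nan_none(self.replay_delta),
                "replay_ratio_change": _nan_none(self.replay_ratio_change),
                "dropped_trials": self.dropped_trials,
                "manifest": self.manifest,
            },
            sort_keys=True,
        )


def _nan_none(x: float):
    return None if (x is None or (isinstance(x, float) and np.isnan(x))) else x


def run_experiment(
    paradigm: str,
    net: GroundTruthNetwork,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Run one simulated learning experiment end to end."""
    if paradigm not in ("conventional", "rdm"):
        raise ValueError("paradigm must be 'conventional' or 'rdm'")
    cfg = config or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(64))

    patterns = cfg.patterns(net.stim_grid_shape)
    by_name = {p.name: p for p in patterns}
    trained = by_name[cfg.trained_pattern]
    controls = [n for n in cfg.pattern_names if n != cfg.trained_pattern]

    # --- Pre-run: spontaneous recording, burstiness, culture QC -------------
    rest = simulate_spontaneous(net, cfg.qc_duration_s, seed=next(seeds))
    bursts_rest = detect_snbs(rest, cfg.snb_detect)
    bi = burstiness_index(rest)
    qc = culture_qc(bursts_rest, cfg.qc_duration_s)
    if not qc.passed and not cfg.skip_qc:
        raise QCFailure(qc.reasons)

    # Pre-baseline continuous recording for the "before" replay readout.
    pre_rec = simulate_spontaneous(net, cfg.replay_recording_s, seed=next(seeds))

    def probe(current_net: GroundTruthNetwork):
        sched = make_probing_schedule(
            current_net.stim_grid_shape,
            cfg.probe_n_reps,
            cfg.probe_dots_per_frame,
            cfg.probe_frame_ms,
            cfg.probe_on_ms,
            seed=next(seeds),
        )
        spk = simulate_evoked(current_net, sched, seed=next(seeds), with_snbs=False)
        return sched, spk

    def test_session(current_net: GroundTruthNetwork):
        sched, labels = make_test_schedule(
            patterns, cfg.test_trials_per_pattern, cfg.test_interval_s, cfg.test_on_ms,
            seed=next(seeds),
        )
        spk = simulate_evoked(current_net, sched, seed=next(seeds), with_snbs=True)
        bursts = detect_snbs(spk, cfg.snb_detect)
        tensor = extract_trials(
            spk, sched, labels, cfg.trial_window_ms, cfg.trial_bin_ms,
            bursts, cfg.pre_exclusion_s,
        )
        return tensor

    sessions: list[tuple] = []  # (schedule, spikes) per probing, in order
    phase_R: dict[str, dict] = {}

    # --- Probe 0 and baseline phase ----------------------------------------
    sched0, spk0 = probe(net)
    map0 = build_connectivity_map(spk0, sched0, cfg.detection)
    sessions.append((sched0, spk0))

    baseline_tensor = test_session(net)
    baseline_summary = pattern_response_summary(baseline_tensor)
    clf_base = train_pattern_classifier(baseline_tensor, mode="pool_all")
    bursts_pre = detect_snbs(pre_rec, cfg.snb_detect)
    replay_before = classify_snb_bins(
        clf_base, pre_rec, bursts_pre, cfg.trial_bin_ms, cfg.trained_pattern
    )

    def phase_r(name: str, current_net: GroundTruthNetwork) -> None:
        """Probe now; R on the baseline pair set vs the previous session."""
        sched, spk = probe(current_net)
        prev_sched, prev_spk = sessions[-1]
        before = reprobe_map(map0, prev_spk, prev_sched, cfg.detection)
        summary = compare_maps(before, None, spk, sched, cfg.detection)
        phase_R[name] = summary.to_dict()
        sessions.append((sched, spk))

    phase_r("baseline", net)

    # --- RDM pre-stimulation (rdm paradigm only) ----------------------------
    rdm_R = None
    if paradigm == "rdm":
        net = apply_rdm_ltd(net, cfg.rdm_depression_factor, cfg.rdm_ibi_stretch)
        phase_r("rdm", net)
        rdm_R = phase_R["rdm"]["R"]
        qc_rdm = culture_qc(bursts_rest, cfg.qc_duration_s, rdm_R=rdm_R)
        if not qc_rdm.passed and not cfg.skip_qc:
            raise QCFailure(qc_rdm.reasons)

    # --- Learning (50-Hz tetanus with the trained pattern) ------------------
    net = apply_tetanus_plasticity(
        net,
        trained,
        hub_threshold=cfg.hub_threshold,
        potentiation_gain=cfg.potentiation_gain,
        depression_gain=cfg.depression_gain,
        bursty=(paradigm == "conventional"),
    )
    if paradigm == "rdm":
        net = arm_replay_bias(net, trained, cfg.replay_bias_strength)
    phase_r("tetanus", net)

    # --- Testing phase ------------------------------------------------------
    testing_tensor = test_session(net)
    testing_summary = pattern_response_summary(testing_tensor)
    x_f = testing_summary[cfg.trained_pattern]["mean_total"]
    x_c1 = testing_summary[controls[0]]["mean_total"]
    x_c2 = testing_summary[controls[1]]["mean_total"]
    fr_delta = familiarity_delta(x_f, x_c1, x_c2) if x_f > 0 else float("nan")

    clf_test = train_pattern_classifier(testing_tensor, mode="pool_all")
    post_rec = simulate_spontaneous(net, cfg.replay_recording_s, seed=next(seeds))
    bursts_post = detect_snbs(post_rec, cfg.snb_detect)
    replay_after = classify_snb_bins(
        clf_test, post_rec, bursts_post, cfg.trial_bin_ms, cfg.trained_pattern
    )

    phase_r("testing", net)

    fr_dict = {
        "baseline": {
            k: {"mean_total": v["mean_total"], "sem_total": v["sem_total"], "n_trials": v["n_trials"]}
            for k, v in baseline_summary.items()
        },
        "testing": {
            k: {"mean_total": v["mean_total"], "sem_total": v["sem_total"], "n_trials": v["n_trials"]}
            for k, v in testing_summary.items()
        },
    }
    manifest = {
        "seed": int(seed),
        "paradigm": paradigm,
        "version": _version,
        "config": _config_dict(cfg),
    }
    return ExperimentResult(
        paradigm=paradigm,
        qc={"passed": qc.passed, "reasons": qc.reasons, "snb_frequency_hz": qc.snb_frequency_hz,
            "rdm_R": rdm_R},
        burstiness=bi,
        phase_R=phase_R,
        n_connections_baseline=len(map0),
        firing_rate=fr_dict,
        firing_rate_delta=fr_delta,
        replay_before=replay_before.to_dict(),
        replay_after=replay_after.to_dict(),
        replay_delta=replay_after.delta,
        replay_ratio_change=(
            replay_after.ratios.get(cfg.trained_pattern, 0.0)
            - replay_before.ratios.get(cfg.trained_pattern, 0.0)
        ),
        dropped_trials={
            "baseline": len(baseline_tensor.dropped_trials),
            "testing": len(testing_tensor.dropped_trials),
        },
        manifest=manifest,
    )


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    return d
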