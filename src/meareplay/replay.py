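"""Pattern-response analysis, the familiarity metric and SNB replay decoding.

Pattern-evoked trials are cut into a trials x electrodes x time-bins count
tensor (10-ms bins by default). Familiarity is quantified with the normalized
contrast

    Delta = ((x_f - x_c1) + (x_f - x_c2)) / (2 * x_f),

where x_f is the network response to the familiar (trained) pattern and
x_c1, x_c2 the responses to the two control patterns; x may be a firing-rate
mean or an SNB replay ratio.

Replay decoding follows the pooling-all-sample scheme: every 10-ms bin of
every trial becomes one training instance (the per-electrode spike-count
vector labeled by its trial's pattern), so the instance count stays well above
the electrode count. The trained multiclass SVM (linear kernel, C = 1,
one-vs-one) then classifies the 10-ms bins of a continuous spontaneous
recording that fall inside detected synchronized network bursts; the per-class
fraction of classified burst bins is the replay ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .core import SpikeData
from .plasticity import BurstSet
from .stimuli import StimulusSchedule

__all__ = [
    "TrialTensor",
    "ReplaySummary",
    "PatternClassifier",
    "extract_trials",
    "pattern_response_summary",
    "familiarity_delta",
    "train_pattern_classifier",
    "classify_snb_bins",
    "accuracy_timecourse",
]


@dataclass
class TrialTensor:
    """Spike counts per (trial, electrode, time bin) with per-trial labels."""

    counts: np.ndarray  # (n_trials, n_electrodes, n_bins)
    labels: np.ndarray  # (n_trials,) pattern names
    bin_ms: float
    window_ms: float
    electrode_ids: np.ndarray
    dropped_trials: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.labels = np.asarray(self.labels)
        if self.counts.ndim != 3:
            raise ValueError("counts must be trials x electrodes x bins")
        if self.counts.shape[0] != self.labels.size:
            raise ValueError("labels must align with trials")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        n_bins = self.counts.shape[2]
        if abs(n_bins * self.bin_ms - self.window_ms) > 1e-6:
            raise ValueError("bins * bin_ms must equal window_ms")

    @property
    def n_trials(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[2])

    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def subset(self, idx: np.ndarray) -> "TrialTensor":
        return TrialTensor(
            self.counts[idx], self.labels[idx], self.bin_ms, self.window_ms,
            self.electrode_ids,
        )

    def instances(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to per-bin instances: (X, y, time_bin_index)."""
        n_t, n_e, n_b = self.counts.shape
        X = self.counts.transpose(0, 2, 1).reshape(n_t * n_b, n_e)
        y = np.repeat(self.labels, n_b)
        tbin = np.tile(np.arange(n_b), n_t)
        return X, y, tbin


@dataclass
class ReplaySummary:
    """Per-class classified-SNB-bin ratios and the familiarity metric."""

    ratios: dict[str, float]
    n_snb_bins: int
    delta: float  # NaN when the trained-pattern ratio is zero or undefined
    trained_pattern: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.ratios.values())
        if self.n_snb_bins < 1:
            raise ValueError("need at least one classified SNB bin")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")

    def to_dict(self) -> dict:
        return {
            "ratios": self.ratios,
            "n_snb_bins": self.n_snb_bins,
            "delta": None if np.isnan(self.delta) else self.delta,
            "trained_pattern": self.trained_pattern,
        }


# ---------------------------------------------------------------------------
# Trial extraction and summaries


def extract_trials(
    spikes: SpikeData,
    schedule: StimulusSchedule,
    labels: list[str],
    window_ms: float = 200.0,
    bin_ms: float = 10.0,
    bursts: BurstSet | None = None,
    pre_exclusion_s: float = 1.0,
) -> TrialTensor:
    """Cut pattern presentations into a labeled count tensor.

    Noisy trials are dropped and logged: any trial with a detected burst
    intersecting ``[onset - pre_exclusion_s, onset + window_ms)``. The
    exclusion covers the response window as well as the pre-onset span — a
    synchronized burst during the stimulus corrupts the evoked response at
    least as badly as one shortly before it. Raises if every trial of some
    pattern is dropped.
    """
    onsets = schedule.onsets()
    if onsets.size != len(labels):
        raise ValueError("labels must align with schedule frames")
    if onsets.size > 1 and window_ms > np.min(np.diff(onsets)):
        raise ValueError("window does not fit between consecutive stimuli")
    n_bins = int(round(window_ms / bin_ms))
    if abs(n_bins * bin_ms - window_ms) > 1e-9:
        raise ValueError("window_ms must be a multiple of bin_ms")
    eids = spikes.electrode_ids()

    kept_idx, dropped = [], []
    excl_ms = pre_exclusion_s * 1000.0
    for k, t0 in enumerate(onsets):
        if bursts is not None and bursts.overlaps(t0 - excl_ms, t0 + window_ms):
            dropped.append({"trial": k, "onset_ms": float(t0), "label": labels[k]})
            continue
        kept_idx.append(k)
    kept_labels = [labels[k] for k in kept_idx]
    for lbl in set(labels):
        if lbl not in kept_labels:
            raise ValueError(f"all trials of pattern {lbl!r} were dropped as noisy")

    counts = np.zeros((len(kept_idx), eids.size, n_bins), dtype=np.int64)
    edges = np.arange(n_bins + 1) * bin_ms
    for ei, e in enumerate(eids):
        t = spikes.get(int(e))
        for ti, k in enumerate(kept_idx):
            lo, hi = np.searchsorted(t, [onsets[k], onsets[k] + window_ms])
            if hi > lo:
                rel = t[lo:hi] - onsets[k]
                counts[ti, ei], _ = np.histogram(rel, bins=edges)
    return TrialTensor(
        counts, np.asarray(kept_labels), bin_ms, window_ms, eids, dropped
    )


def pattern_response_summary(tensor: TrialTensor) -> dict[str, dict]:
    """Per-pattern population PSTH and total spikes/trial (mean +/- SEM).

    The population PSTH sums counts over electrodes and averages over trials;
    the total is the full-window spike count per trial. With a single trial the
    SEM is reported as 0 with ``sem_defined=False``.
    """
    out: dict[str, dict] = {}
    for lbl in tensor.classes():
        sel = tensor.labels == lbl
        if not sel.any():
            continue
        sub = tensor.counts[sel]  # (n, e, b)
        pop_psth = sub.sum(axis=1).mean(axis=0)  # per time bin, spikes/trial
        totals = sub.sum(axis=(1, 2)).astype(float)
        n = totals.size
        sem_defined = n > 1
        sem = float(totals.std(ddof=1) / np.sqrt(n)) if sem_defined else 0.0
        out[lbl] = {
            "psth": pop_psth,
            "mean_total": float(totals.mean()),
            "sem_total": sem,
            "sem_defined": sem_defined,
            "n_trials": int(n),
        }
    return out


def familiarity_delta(x_f: float, x_c1: float, x_c2: float) -> float:
    """Normalized familiarity contrast Delta = ((x_f-x_c1)+(x_f-x_c2))/(2 x_f)."""
    if x_f <= 0:
        raise ValueError("familiar-pattern response must be positive")
    return ((x_f - x_c1) + (x_f - x_c2)) / (2.0 * x_f)


# ---------------------------------------------------------------------------
# SVM decoding


@dataclass
class PatternClassifier:
    """A trained per-bin pattern decoder (wraps a multiclass SVM)."""

    svm: SVC
    classes: list[str]
    electrode_ids: np.ndarray
    bin_ms: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(X)


def train_pattern_classifier(
    tensor: TrialTensor,
    mode: str = "pool_all",
    split_frac: float = 0.6,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> PatternClassifier | tuple[PatternClassifier, TrialTensor]:
    """Train the per-bin SVM decoder.

    ``pool_all`` trains on every bin of every trial (the pooling-all-sample
    scheme). ``split`` holds out ``1 - split_frac`` of the *trials* (split at
    the trial level so held-out bins are from unseen presentations) and returns
    the held-out tensor alongside the classifier.
    """
    if len(tensor.classes()) < 2:
        raise ValueError("need at least two pattern classes")
    if mode not in ("pool_all", "split"):
        raise ValueError("mode must be 'pool_all' or 'split'")
    if mode == "pool_all":
        X, y, _ = tensor.instances()
        svm = SVC(C=C, kernel=kernel, decision_function_shape="ovo")
        svm.fit(X, y)
        return PatternClassifier(svm, tensor.classes(), tensor.electrode_ids, tensor.bin_ms)

    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for lbl in tensor.classes():
        idx = np.flatnonzero(tensor.labels == lbl)
        rng.shuffle(idx)
        n_train = max(1, int(round(split_frac * idx.size)))
        n_train = min(n_train, idx.size - 1) if idx.size > 1 else n_train
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train = tensor.subset(np.sort(np.asarray(train_idx)))
    held = tensor.subset(np.sort(np.asarray(test_idx)))
    X, y, _ = train.instances()
    svm = SVC(C=C, kernel=kernel, decision_function_shape="ovo")
    svm.fit(X, y)
    clf = PatternClassifier(svm, tensor.classes(), tensor.electrode_ids, tensor.bin_ms)
    return clf, held


def _bin_continuous(
    spikes: SpikeData, bin_ms: float, electrode_ids: np.ndarray
) -> np.ndarray:
    n_bins = int(np.floor(spikes.duration_ms / bin_ms))
    X = np.zeros((n_bins, electrode_ids.size), dtype=np.int64)
    for ei, e in enumerate(electrode_ids):
        t = spikes.get(int(e))
        if t.size == 0:
            continue
        idx = (t / bin_ms).astype(int)
        idx = idx[idx < n_bins]
        if idx.size:
            X[:, ei] = np.bincount(idx, minlength=n_bins)
    return X


def classify_snb_bins(
    clf: PatternClassifier,
    spikes: SpikeData,
    bursts: BurstSet,
    bin_ms: float = 10.0,
    trained_pattern: str | None = None,
) -> ReplaySummary:
    """Classify the burst bins of a continuous recording.

    The recording is binned into per-electrode count vectors; a bin belongs to
    a burst when its midpoint lies inside a detected burst interval. The
    summary reports the per-class fraction of classified burst bins and, when
    ``trained_pattern`` is given, the familiarity Delta over those ratios
    (NaN when the trained-pattern ratio is zero).
    """
    if len(bursts) == 0:
        raise ValueError("no bursts to classify")
    X = _bin_continuous(spikes, bin_ms, clf.electrode_ids)
    mids = (np.arange(X.shape[0]) + 0.5) * bin_ms
    in_burst = np.zeros(mids.size, dtype=bool)
    for lo, hi in bursts.intervals:
        in_burst |= (mids >= lo) & (mids < hi)
    if not in_burst.any():
        raise ValueError("no recording bins fall inside the burst intervals")
    pred = clf.predict(X[in_burst])
    n = int(in_burst.sum())
    ratios = {c: float(np.mean(pred == c)) for c in clf.classes}

    delta = float("nan")
    if trained_pattern is not None:
        controls = [c for c in clf.classes if c != trained_pattern]
        x_f = ratios.get(trained_pattern, 0.0)
        if x_f > 0 and len(controls) == 2:
            delta = familiarity_delta(x_f, ratios[controls[0]], ratios[controls[1]])
    return ReplaySummary(ratios, n, delta, trained_pattern)


def accuracy_timecourse(
    tensor: TrialTensor,
    n_replicas: int = 10,
    split_frac: float = 0.6,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> dict:
    """Held-out decoding accuracy per post-stimulus time bin.

    The split-train-classify cycle is repeated over ``n_replicas`` reseeded
    splits; mean and SEM of per-bin accuracy are reported together with the
    chance level (1 / number of classes).
    """
    n_bins = tensor.n_bins
    accs = np.full((n_replicas, n_bins), np.nan)
    for r in range(n_replicas):
        clf, held = train_pattern_classifier(
            tensor, mode="split", split_frac=split_frac, seed=seed + r, C=C, kernel=kernel
        )
        if held.n_trials == 0:
            raise ValueError("held-out set is empty")
        Xh, yh, tbin = held.instances()
        pred = clf.predict(Xh)
        for b in range(n_bins):
            sel = tbin == b
            accs[r, b] = float(np.mean(pred[sel] == yh[sel]))
    mean = accs.mean(axis=0)
    sem = accs.std(axis=0, ddof=1) / np.sqrt(n_replicas) if n_replicas > 1 else np.zeros(n_bins)
    return {
        "time_ms": (np.arange(n_bins) + 0.5) * tensor.bin_ms,
        "accuracy_mean": mean,
        "accuracy_sem": sem,
        "chance": 1.0 / len(tensor.classes()),
        "n_replicas": n_replicas,
    }
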