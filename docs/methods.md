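# Methods

This note documents the models, analysis conventions, parameter defaults and
known limitations of `meareplay`. It is written for users who need to know
exactly what each number means before trusting it on their own recordings.

## Recording model

A recording is a set of per-electrode sorted spike-timestamp arrays
(milliseconds) on a 16 × 16 electrode grid with 200-µm pitch whose four corners
carry no electrode (252 active sites — the standard 256-well commercial
layout). Electrodes and stimulus-grid positions are addressed by 0-based
row-major index; timestamps are float milliseconds throughout. Spike TSV and
HDF5 files carry the duration and geometry in their headers, so files are
self-describing and round-trip exactly.

## Stimulation schedules

* **Probing movie** — every position of the stimulation grid appears exactly
  `n_reps` times (default 20), `dots_per_frame` (5) distinct positions per
  100-ms frame, light on 40 ms. The generator shuffles the multiset of
  position slots, packs it into frames, and repairs within-frame duplicates by
  swapping with a compatible later slot; balance is exact by construction, and
  a property test tallies it by brute force. The default session is 1024
  frames (~1.7 min) carrying 5120 position-stimulation events.
* **RDM** — frames refresh at 10 Hz, each lighting 25 of 100 dots on a 10 × 10
  grid for 50 ms, chosen uniformly without replacement per frame.
* **Tetanus** — the full pattern pulsed at 50 Hz, 50% duty (10 ms on / 10 ms
  off), 60 one-second trains at 9-s intervals; pulses sit at exact multiples of
  the period (no jitter).
* **Test session** — each candidate pattern presented `n_trials_per` times
  (10) in seeded random order, 100-ms illumination, 10-s intervals, with
  per-trial labels.

### Pattern masks

The three built-in patterns ("car", "dog", "human") are procedural line-drawing
stand-ins rendered at any grid size (50 × 50 by default, 16 × 16 for the
simulated experiments). They are deliberately constructed with near-equal
lit-cell counts and near-equal pairwise overlaps: if two masks share many
cells, their evoked responses correlate and multiclass decoding becomes
structurally biased toward the third pattern, contaminating the
unbiased-replay null. `balance_luminance` additionally scales each pattern's
intensity by `min_lit / lit`, equalizing the expected number of stimulated
connections — the in-silico analogue of tuning stimulus luminance until each
pattern elicits the same baseline network response.

## Ground-truth simulator

The simulator is phenomenological: it generates the statistical structure the
analyses consume, not membrane dynamics.

* **Background**: homogeneous Poisson per electrode, default 0.5 Hz
  (inter-burst windows in burst-dominated cultures are nearly silent, with
  sparse asynchronous firing).
* **SNBs**: onset gaps Normal(6.7 s, 1.5 s) truncated to exceed the burst
  duration (300 ms), so bursts never overlap; within a burst each electrode
  fires Poisson at 150 Hz × a per-electrode participation gain
  (LogNormal, σ = 0.3). These defaults produce a burstiness index near 0.86
  and an SNB rate near 0.15 Hz for the default culture — a mature,
  burst-dominated preparation inside the QC band.
* **Evoked responses**: a directed connection (stimulus position → electrode)
  fires at most one spike per stimulation, with probability
  `response_prob × frame intensity` (clipped at 1), at
  onset + Normal(30 ms, 1 ms). One uniform and one latency variate are drawn
  per trial regardless of outcome, so raising `response_prob` only adds
  responses — this makes detection monotonicity testable. The 1-ms latency SD
  reflects that correlogram peaks normalized to 100 trials approach 100 in
  this preparation, which requires near-millisecond response alignment; larger
  jitter would spread the 1-ms-binned correlogram peak and defeat the printed
  Poisson test at 20 trials.
* **Plasticity transforms** are instantaneous multiplicative edits of
  `response_prob`: tetanization either potentiates connections whose
  presynaptic dot is lit by the pattern and whose postsynaptic electrode
  collects at least `hub_threshold` lit inputs (gain 1.8, capped at 1), or — in
  the burst-saturated regime — depresses every connection by 0.8 (placing the
  relative-change histogram near −20%). RDM stimulation multiplies every
  probability by 0.3 and stretches the mean inter-burst interval 3× (burst
  suppression). `hub_threshold` defaults to 1: at the default wiring density
  (200 connections over 256 × 252 possible pairs) almost no electrode collects
  two lit inputs from one pattern, so higher thresholds select nothing;
  denser networks can raise it to study hub-clustered potentiation.
* **Replay bias**: arming a pattern sets per-electrode burst-rate gains
  `(1 − s) + s · r_e / mean(r)`, where `r_e` is the electrode's expected evoked
  response to the pattern and `s` (default 0.8) the bias strength; `s = 0`
  leaves bursts unbiased.

What the generator does **not** emulate: spike waveforms (except for the
demonstration-scale 6σ threshold detector), multi-spike evoked bursts,
latency drift, electrode crosstalk, slow nonstationarity of excitability, or
spontaneous plasticity drift. Passing tests therefore demonstrate that the
analyses recover the statistical structure they target, not robustness to
every artifact of real recordings.

## Connectivity inference conventions

* The stimulus series marks the frame *onset* bin only; in the deterministic
  limit the correlogram peak equals the number of responding trials, matching
  the per-100-trials peak normalization.
* Lags are searched over 0–100 ms (one probing frame); λ is the mean of
  cch(τ) over the searched lags. Ties at the peak resolve to the smallest lag.
* P(k) is the Poisson **pmf** evaluated in log space (an upper-tail variant is
  available via `tail=True`); λ = 0 yields P = 1 for k = 0 and 0 otherwise.
* Detection requires P(k) < 10⁻⁶ — higher thresholds flood the map via
  constantly firing channels, lower ones starve it and inflate the variance of
  network statistics — and responses in at least ⌈n_trials/2⌉ trials (10 of
  20), where a trial responds if a spike falls within τ_p ± 5 ms of its onset.
* PSTH efficacy uses a 100-ms post-onset window at 1-ms bins; area is in
  spikes/trial.
* `build_connectivity_map` screens all pairs with a vectorized correlogram
  gather and recomputes exact p-values, trial responses and PSTHs only for
  pairs passing the Poisson screen; results are identical to the pairwise
  routine.

## Plasticity comparison

`compare_maps` anchors on the pair set detected in the *before* map and
re-measures PSTH area and peak lag for those pairs on the after-session whether
or not they would be independently re-detected — after strong network-wide
depression most connections fall below the detection threshold, and any
matching scheme that requires re-detection would discard exactly the
depressed population under study. Relative changes are percentages of the
before-area; each positive change enters P capped at 101, N sums the negative
changes, R = P/|N|, and R is reported as NaN (never infinity) when N = 0.
Zero-area before-connections are skipped with a warning.

In `run_experiment`, each phase's R uses the *baseline* map's pair set with
areas measured on the two probing sessions flanking the phase. Treatments act
instantaneously in the simulator, so the "5 minutes after treatment" settle
interval of a wet-lab protocol has no simulated counterpart.

## Bursts, burstiness, QC

The SNB detector thresholds the population rate in 10-ms bins at 5× the median
nonzero rate, additionally requiring ≥ 25% of electrodes active in the bin;
adjacent burst bins within 100 ms merge, and intervals shorter than 100 ms are
dropped. On simulator output the detected intervals overlap ground truth with
mean Jaccard ≥ 0.8.

BI pools all electrodes into 1-s bins; the default 15% top-bin fraction
corresponds to one burst-occupied bin per 6.7-s inter-burst interval. For
faster-bursting cultures `adaptive_top_frac` grows the fraction to
`bin_s / IBI`, preserving one-burst-per-top-bin occupancy. Culture QC fails
preparations with SNB rates above 0.2 Hz or below 0.05 Hz, and (when an RDM
suppression ratio is supplied) RDM-resistant cultures with R > 0.2.

## Trials, decoding, familiarity

Pattern trials are cut into trials × electrodes × 10-ms-bin count tensors over
a 200-ms post-onset window (covering the informative 30–120 ms span with
margin). Noisy trials are excluded when a detected burst intersects
[onset − 1 s, onset + window): the exclusion extends through the response
window because a burst *during* the stimulus inflates that trial's count
roughly twenty-fold and corrupts per-pattern means far more than a pre-onset
burst does.

The decoder is a multiclass SVM (linear kernel, C = 1, one-vs-one — the cited
library's defaults; exposed in config) trained on pooled per-bin instances:
each 10-ms bin of each trial is one instance labeled by its trial's pattern,
keeping the instance count well above the 252-dimensional feature space.
Zero-spike bins are retained. Split-mode training holds out complete trials
(not bins), so held-out instances come from unseen presentations;
`accuracy_timecourse` repeats the split over reseeded replicas (default 10)
and reports per-bin mean ± SEM against the 1/n_classes chance level.

Burst bins of a continuous recording (bin midpoint inside a detected burst
interval) are classified and summarized as per-class ratios; the familiarity
metric Δ applies to these ratios exactly as to firing rates, with the trained
pattern as x_f. A ratio-based Δ is NaN when no burst bin is assigned to the
trained pattern. On unbiased simulations the per-class ratios are strongly
winner-take-all within a single seed (burst vectors lie far outside the
training distribution, so one class tends to capture most bins) but the winner
is seed-random and the across-seed means are uniform; per-seed replay ratios
should accordingly be interpreted only relative to controls or across
sessions, exactly as the Δ metric does.

## Simulated paradigms

`run_experiment` reproduces two protocols against the simulator, with a probing
session around every phase:

* **conventional**: probe – baseline – probe – tetanus(bursty) – probe –
  testing – probe;
* **rdm**: probe – baseline – probe – RDM – probe – tetanus(+replay arming) –
  probe – testing – probe.

Baseline recording precedes RDM treatment; the pre-baseline spontaneous
recording is decoded with the baseline-trained classifier and the post-learning
recording with the testing-trained classifier. QC gates the run at the start
(SNB-rate band) and, for the RDM paradigm, after the RDM phase (R ≤ 0.2).
Problem sizes used by the test suite and the acceptance script — 300-s QC and
180-s replay recordings, 10 seeds per paradigm with the trained pattern
rotating across the three built-ins — keep a full two-paradigm comparison to a
few minutes while leaving every sign test well determined.

## Numerical and degenerate-input conventions

* All randomness flows through `numpy.random.default_rng`; every simulator and
  scheduler takes an explicit seed, and `run_experiment` spawns per-phase
  seeds from one `SeedSequence`, so identical seeds give bit-identical result
  JSON.
* Events exactly at the recording end fall into the last bin; schedule frames
  must not overlap (onset(k+1) ≥ onset(k) + on(k)).
* Empty series produce all-zero correlograms with λ = 0; zero-trial PSTHs,
  zero-spike BI inputs and single-pattern test schedules raise errors; an
  SEM over one trial is reported as 0 with a `sem_defined=False` flag.
* R = P/|N| with N = 0 is NaN, serialized as JSON null.

## Known limitations

* The built-in patterns are geometric stand-ins; the original line drawings
  are not published, and only grid size, distinctness and balance are modeled.
* The Poisson peak test is applied to the pmf exactly as printed; it is not
  strictly monotone in signal strength under latency jitter (an added response
  can raise λ without raising the peak), and inhibitory connections (troughs)
  are out of scope.
* Efficacy comparisons assume stable electrode identity across sessions; no
  spike sorting is performed, and unit-level analyses are out of scope.
* The simulator's plasticity is a static multiplicative edit; it cannot model
  gradual recovery, metaplasticity, or the partial re-potentiation observed
  over hours in real cultures.
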