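# Methods

## Detection model

A complex patient-ventilator interaction (CP-VI) is an episode, over a 3-min
span, of >50 % change in respiratory rate relative to the patient's baseline
rate and/or >30 % asynchronous breaths of any type (ineffective expiratory
effort, double cycling, premature cycling, prolonged cycling, reverse
triggering). Both phenomena disrupt the quasi-periodicity of the airway flow
and pressure waveforms, so a window-level irregularity statistic can detect
them without segmenting individual breaths — the central assumption of this
package. The statistic is Sample Entropy (SampEn): the negative log of the
conditional probability that two `m`-sample template vectors within
Chebyshev tolerance `r` of each other remain within tolerance when extended
by one sample. Template starts range over `i = 1..N-m` for both the `m`- and
`(m+1)`-length counts and self-matches are excluded (Richman–Moorman); with
identical index ranges the normalisation constants cancel and
`SampEn = -ln(ΣA_i / ΣB_i)`.

Detection is personalised: each 15-min segment's feature (mean or maximum of
the smoothed SampEn series) is compared, as a percent change (PC), with the
patient's own baseline — the running minimum of the feature over preceding
segments, initialised from the first segment. A segment is flagged when
`PC > Th` (strict; a tie at exactly `Th` is negative). Consequences worth
noting:

- the first segment always has PC = 0 and can never be flagged; if it may
  itself contain a CP-VI, `baseline_warmup=k` seeds the baseline from the
  minimum over the first `k` segments instead;
- the baseline absorbs a segment's value only *after* the segment is
  scored, so detection is causal and streaming-compatible;
- detection is scale-free: rescaling all SampEn values leaves every PC and
  every flag unchanged.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `m` | embedding dimension (samples) | 2 (flow), 4 (paw) | grid 1..20 |
| `r_factor` | tolerance, × window SD | 0.2 | grid 0.1–0.4; SD is per window, population convention |
| `window_s` | sliding-window length | 30 s (N = 1200 at 40 Hz) | |
| `overlap_frac` | window overlap | 0.5 (15-s stride) | windows start at t = 0; only complete windows are evaluated |
| `ema_span` | smoothing span (periods) | 8 | α = 2/(span+1), first-value initialisation; off switch for unsmoothed comparison |
| `Th` | detection threshold on PC | 25 % (flow), 30 % (paw) | grid 15–50 % |
| segment length | labelling/detection unit | 15 min | 3-min truth windows tile it exactly |
| analysis rate | after decimation | 40 Hz | zero-phase FIR (cutoff 16 Hz) before integer downsampling |

Degenerate cases: a window with zero SD has no meaningful scaled tolerance
and yields an undefined (NaN) value, as does a window where no template pair
matches at `m` or `m+1`; capping at an arbitrary large value would inject
spurious dynamics into the series. The EMA skips undefined points (carrying
its state) and leaves them undefined. A segment with fewer than 10 defined
points is unevaluable: it is excluded from scoring and leaves the baseline
untouched. MCC with a zero denominator factor is defined as 0; 0/0 accuracy
ratios (e.g. PPV with no positive predictions) are reported as NaN and
excluded from aggregation.

## Optimisation

Settings are fitted by repeated holdout: 15 random 70/30 splits of the
pooled labelled segments (92 segments split 64/28 under the
`round(0.7·n)` convention), mean MCC per combination on the optimisation
subsets, argmax selection, and per-repetition reporting of MCC,
sensitivity, specificity, accuracy, PPV and NPV on the validation subsets
(median and IQR). Design choices made where the procedure was genuinely
open:

- **Split unit** is the segment; patient-grouped splitting is available via
  the corpus structure but not the default, since the pooled-segment design
  is the one being reproduced.
- **Ties** at equal mean MCC are broken towards the smaller `m`, then `r`,
  then `Th` (parsimony; a tolerance and threshold no larger than necessary).
- **Seeding**: one master seed spawns the 15 repetition seeds via
  `numpy.random.SeedSequence`; every combination and feature is evaluated on
  identical splits, and the whole procedure is bit-reproducible.
- **Caching**: PC does not depend on `Th`, and the all-dimensions entropy
  kernel (one O(N²) diagonal pass per window and tolerance yields the match
  counts for every `m` simultaneously) makes the 20×4 (m, r) grid cost no
  more entropy work than its largest `m`. A cache-vs-direct equality test
  guards this path.
- The `r`-sensitivity scan (step 0.01 around the selected `r`) reuses the
  same splits so curve differences reflect the tolerance alone.

## Synthetic ventilator waveforms

The generator emulates what the detector needs to be tested against, not
lung mechanics in full. Breaths are single-compartment templates: PSV —
first-order rise to a pressure plateau (PEEP + support) with decelerating
inspiratory flow; ACV — near-square inspiratory flow with a ramping
pressure; passive exponential expiration whose amplitude is solved so
inhaled and exhaled volumes balance. Breath-to-breath timing jitter
(lognormal, SD 3 %) and amplitude jitter (3 %) make the signal
quasi-periodic; additive Gaussian noise (2 % of each channel's half
peak-to-peak amplitude) models the sensor floor.

Scripted events:

- `rr_change`: the target rate moves to a multiple of baseline with
  elevated timing variability (SD 6 %), as in distressed breathing;
- `asynchrony_cluster`: a target fraction of breaths is replaced by
  asynchronous morphologies. Ineffective efforts and reverse triggering add
  expiratory flow bumps with pressure dips; double cycling stacks two
  inspirations; premature/prolonged cycling shorten/stretch the inspiratory
  time. Morphologies also perturb timing as their clinical counterparts do
  (a missed trigger prolongs the interval only under patient-cycled PSV;
  premature cycling hastens the next breath). Clusters additionally carry
  the signatures of elevated respiratory drive — timing variability and
  mean rate rising with cluster severity — which is what makes them visible
  to a window-entropy statistic on the almost piecewise-flat ACV flow
  waveform, whose entropy responds to breath density and timing rather than
  to isolated shape deflections.

An adaptive thinning rule keeps each cluster's realized asynchronous
fraction within a few percent of its target, so the ground-truth label
(derived purely from the realized breath log: a 3-min window is positive iff
its mean realized rate deviates >50 % from the configured baseline rate or
>30 % of its breaths are asynchronous; a 15-min segment inherits positivity
from any overlapping window) matches the intended severity class.

**Benchmark corpus.** The detection benchmark (30 recordings × 60 min,
alternating PSV/ACV, baseline rate U(13, 20) bpm, half of the recordings
CP-VI-positive) grades event severities so that the class margin of the
percent change on `SE-Flow_max` brackets the 25 % threshold: negative
recordings carry one sub-threshold rate drift (×1.16–1.28 — a hard negative
landing at PC ≈ 20–24) and sometimes a mild cluster (6–12 % asynchronous);
positive recordings carry brief weak clusters just above the 30 % limit
(36–46 %, PC ≈ high 20s–40s), strong clusters (55–85 %), large rate rises
(×1.7–2.2), and occasionally a large rate *fall*, which satisfies the CP-VI
definition but lowers no-entropy — a deliberate, physiologically real
failure mode that keeps every grid cell imperfect. Events sit on the 3-min
truth grid, interior to segments 2–4 and ending ≥3 min before the next
boundary so that straddling windows and EMA memory cannot leak an event's
entropy into a neighbouring segment; the first segment is always event-free
to provide a clean personal baseline.

**What passing tests do and do not show.** The corpus exercises the
detector's mechanism (irregularity rise over a personal baseline) under
controlled severities; it does not contain cardiogenic oscillations,
secretions, suction events, sensor drift, mode changes or circuit leaks,
and its asynchrony morphologies are parametric sketches. Performance on it
bounds nothing about clinical recordings; it demonstrates correctness of
the pipeline and recoverability of a known operating point, not clinical
accuracy.

## Numerical notes

- Entropy kernel: numba-compiled; run lengths of consecutive sample matches
  along each diagonal give, per pair, the maximal matching template length,
  binned into histograms whose suffix sums are the `B_m`/`A_m` counts for
  all `m` at once. Verified against an independent O(N²) double-loop oracle
  to 1e-10 and against the analytic i.i.d. Gaussian limit
  `-ln(2Φ(r/√2) − 1)`.
- Decimation: symmetric FIR (`20·q+1` taps, cutoff 0.8 × target Nyquist)
  applied with `filtfilt` (zero phase), then every q-th sample; output
  length `floor(n/q)`.
- CSV I/O is round-trip exact (`float_precision="round_trip"` on read).
- Problem sizes in the test-suite and acceptance runs (30 recordings of
  60 min; 100–200 oracle series; 20 Gaussian replicates of 10⁴ samples)
  were chosen as the smallest sizes at which the holdout optimisation's
  selection behaviour is stable across seeds.

## Known limitations

- The rate-fall pathway of the CP-VI definition is largely invisible to the
  entropy rise + positive-threshold design (slower regular breathing is not
  less regular); such events are labelled positive by the truth function
  and counted as misses.
- A CP-VI in the very first segment corrupts the personal baseline
  (mitigated, not solved, by `baseline_warmup`).
- EDF support is read-only, and channel mapping is by label substring.
- Proportional-assist modes and breath-to-breath variability features are
  out of scope.
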