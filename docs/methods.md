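# Methods

## The problem and the data

A 24-hour Holter recording is reduced to its sinus beat-to-beat
intervals (RR, in ms, as a surrogate for the sinus PP interval).
Escape beats carry no information about sinus-node output, so an
interval terminated by a non-sinus beat is merged into its successor
(`merge_nonsinus`), recovering the true duration of each sinus pause
while conserving elapsed time.  The input dialects — one interval per
line with an optional trailing `*` escape flag, or `clock,interval`
CSV — are package conventions emulating a Holter software export; no
vendor format is parsed.  Intervals are stored as floating ms (the
simulator is continuous) but written back as integers whenever exact.

A note on the escape-flag encoding: a `*` marks the beat *ending* the
flagged interval, so the recording's first beat is implicitly sinus;
only a trailing escape run can produce the dropped-boundary warning.

## Holter variables

Pauses are intervals strictly exceeding 2, 3, and 4 s, counted on the
merged (sinus-only) series.  `cRMSSD` is RMSSD divided by mean RR —
the standard rate correction, chosen because raw RMSSD scales with
cycle length; it is dimensionless and invariant under uniform time
rescaling.  Two quantities have no universal definition in Holter
software, so explicit windowed conventions are used and exposed:

* minimum HR = 60000 / (maximum mean RR over a sliding 60 s window of
  interval ends) — an instantaneous minimum would simply equal the
  longest pause;
* time < 50 bpm = number of consecutive 60 s elapsed-time bins whose
  time-weighted mean instantaneous rate is below 50 bpm, so pauses
  spanning whole minutes count those minutes as slow.

The stable/sleep window is the contiguous run of 1–6 whole clock hours
inside 22:00–07:00 maximizing `rank(low mean HR) + rank(high pause>2s
count)`, with a disqualifying penalty when the hour-to-hour
coefficient of variation of mean RR exceeds 0.5 (the automated stand-in
for a visual pattern-stability check; threshold configurable).  Ties
break to the earlier start, then the longer window, so a featureless
recording yields the full six hours from 22:00.  An hour counts as
covered when at least 30 min of it was recorded.

## Poincaré cluster metrics

The plot pairs each interval with its successor.  The line-of-identity
(LOI) band is |y − x| ≤ 40 ms; occupancy histograms with 20 ms bins
along x (for the LOI) and y (for off-line points) are thresholded at
max(2, 0.1 % of all points) before taking extrema, operationalizing
the visual rule of reading only the dense part of the cloud: an
isolated stray point never moves a boundary.  All three constants are
parameters of `cluster_metrics` and should be reported with any
measurement.  The shortest horizontal deviation is the minimum y of
dense off-band points; it is `nan` when no off-line arm exists.  On
simulator output this measurement sits at the bottom edge of the
off-band respiratory scatter (uniform interval noise pushes some
near-line pairs just outside the 40 ms band) rather than on the 2×
block arm; the class direction (SND below HP/LSM) is unaffected.

## The density-grid classifier

Triples of consecutive intervals are binned into 60 ms cubic cells
spanning [0, 6000) per axis — 100³ = 10⁶ cells, stored sparsely.  A
cell's label is the class with the highest *per-class normalized*
count (count / class total): normalization prevents the largest
training class from annexing shared cells; a raw-count mode is kept
behind a flag for sensitivity checks.  Empty cells and out-of-grid
triples abstain.  Per recording, each interval collects the votes of
the up-to-three triples containing it; assignment is the plurality
ignoring abstentions, with exact ties broken by the fixed class order
(balanced < HP/LSM < SND) — one concrete realization of "averaging"
disagreeing rolling votes.  The recording diagnosis is the class with
the largest interval fraction; the abstention fraction is reported but
never diagnosed.

## The sine-feature network

Features are sin(2π·f·RRⱼ) for the dyadic frequency ladder
f = 1/(75·2ᵏ) ms⁻¹, k = 0..7 (periods 75–9600 ms), plus RRⱼ/6000
linear terms — 27 features per triple, the linear terms making the map
injective on the working range (disable with `include_linear=False`
for a strictly sinusoidal map).  The network is input → 64 ReLU units
→ 3 linear outputs, trained with mini-batch gradient descent
(learning rate 0.01, batch 256, 2000 epochs by default) on the squared
error against one-hot targets; no softmax, staying with a plain
quadratic loss.  Initialization is He-scaled Gaussian from a seeded
generator; training is bit-reproducible per seed, the per-epoch loss
trajectory is stored in the model file, and a non-finite loss aborts
with the offending epoch.  Analytic gradients are verified against
central finite differences in the test suite.  None of the
hyperparameters are canonical; all are recorded in the saved model.

## The exit-block simulator

Vagal tone is

    vt(t) = 0.08 + (1/8)(1 + sin 2πt/4000) + (3/8)(1 − tanh(cos(2πt/P)·s))

with P = 24 h and shape s = 1: a floor of 0.08 (parasympathetic drive
never vanishes), a 4 s respiratory oscillation (15 cycles/min), and a
circadian wave lowest at model time 0 and highest at 12 h.  The
circadian term's printed form was unrecoverable from the source
typography; this reconstruction keeps the stated amplitudes and the
rise-and-fall-over-24 h behavior, stays within (0, 1.2), and every
constant is a `SimParams` field open to inspection.

Internal beats advance by `Tint = T0 + 400·vt(t) + Trand·u` with u
uniform on [0, 1); `Trand` is 40 ms after a conducted beat and `Tb`
after a blocked one ("previous beat" meaning the previous
internal-clock beat, since the noise term feeds the internal
equation).  Each beat is blocked with probability
`clip(ebpsf·(vt − 0.6), 0, 1)` evaluated at its own firing time.  A
blocked beat consumes its interval but emits nothing, so conducted RR
intervals are exact sums of consecutive internal intervals and total
time is conserved — the property that produces integer-multiple
interval bands.

Wall-clock anchoring: model time 0 maps to 14:30, placing the
circadian vagal peak at 02:30, inside the sleep-search span.  Labeled
cohorts default to a start at model time 10 h (00:30 clock) so that
even one-hour recordings run at high vagal tone, where the phenotypes
actually differ; all recordings of a cohort share the start time so
class contrasts are phenotype effects, not phase effects.

What the generator emulates: banded tachograms, Poincaré clustering,
pause-count and cRMSSD separation between phenotypes, circadian and
respiratory modulation.  What it does not: sympathetic surges and
exercise tachycardia, heart-rate-fragmentation microstructure,
Wenckebach/decremental conduction timing, overdrive suppression,
artifact and ectopy.  Tests passing on simulated cohorts therefore
demonstrate the pipeline and the exit-block mechanism, not clinical
performance on real recordings.

One structural consequence: the line-of-identity *range* is
[T0 + 400·vt_min, T0 + 400·vt_max] plus noise for every preset, and T0
shifts both ends equally, so the simulated SND and HP/LSM phenotypes
have essentially identical LOI ranges (≈ 352 ms) even though real SND
dogs show a markedly smaller range than HP/LSM dogs.  The real-world
contrast comes from physiology the model deliberately omits (HP/LSM
dogs still reach very short cycles under sympathetic drive).  The
corresponding directional check is kept in the acceptance suite and
fails honestly on simulated data.

## Experiment protocol and problem sizes

The mechanism round trip trains both classifiers on 3 one-hour
recordings per phenotype (9 recordings, ≈ 36 000 triples) and
evaluates on 9 disjoint-seed recordings; the network is trained for
800 epochs there, where the loss trajectory has long plateaued.
Directional cohort statistics use 5 independent seeds × 3 phenotypes ×
24 h and compare per-class medians over seeds.  Seeds are fixed in the
tests and derived from `--seed` in `scripts/acceptance.py`.

## Numerical and degenerate-input choices

* Strict inequalities at pause thresholds; half-open cell bins
  [m·60, (m+1)·60) with 6000 excluded.
* Argmax ties anywhere resolve to the fixed class order.
* `crmssd` requires ≥ 2 intervals; classification requires ≥ 3;
  empty recordings contribute nothing to training.
* Grid training errors if any class is absent; the probability clamp
  caps `ebpsf·(vt − vth)` at 1.
* Models persist as JSON (sparse cell map with geometry header;
  network weights with frequencies, seed, and hyperparameters).
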