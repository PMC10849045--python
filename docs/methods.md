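# Methods

## Detection model

A miniature synaptic event is modelled as a transient deviation from a
locally estimated baseline: a rise to an extremum followed by a
single-exponential return. Detection makes three assumptions: the sampling
is uniform; one polarity (`direction`) holds for the whole analysis; and the
baseline immediately preceding an event is informative unless the user says
otherwise (the fixed-left-window option exists precisely for baselines
corrupted by structured interference).

The automatic scan covers each sweep independently with windows of width
`auto_diameter_ms` advanced by half a window, taking each window's global
extremum as a candidate. Sweeps are never concatenated: a candidate whose
measurements would straddle a sweep boundary is meaningless, and per-sweep
scanning keeps results independent of sweep order.

### Onset and baseline

From a candidate peak the scan walks backward, comparing sample `i` against
the mean of the `ma_window` samples before it. The first visited sample
strictly on the opposite side of that mean from the peak is the last
pre-event sample; the mean there is the baseline value. Two numerical
choices matter:

* **Tie handling.** Equality with the moving average continues the scan
  (strict crossing). On a perfectly flat synthetic baseline no strict
  crossing exists near the event, so after the crossing (or the scan floor)
  the onset additionally skips forward over any run of samples exactly equal
  to the crossing sample. On real or noisy data exact ties never occur and
  the skip is a no-op; on noise-free traces it recovers the true onset to
  within one sample.
* **No-crossing fallback.** If the scan reaches the start of the sweep
  without a crossing, the onset is placed after the first `ma_window`
  samples, whose mean becomes the baseline, and the event carries a
  `baseline_warning` flag.

In `fixed_left_window` mode the baseline is the mean of a window of
`fixed_window_ms` ending `fixed_offset_ms` left of the peak, and the onset
is the latest pre-peak sample strictly below that constant. Under mains hum,
setting the offset to roughly one hum period puts peak and baseline window
at the same hum phase, cancelling the hum in the amplitude; that guidance is
followed by the hum benchmark (offset 20 ms, window 2 ms).

### Candidate merging and screening order

Half-overlapping windows revisit the same event, and noise riding an event's
top or decay can put different windows' extrema on different samples of one
event. Candidates are therefore merged when a candidate's backward onset
scan walks past the previous candidate's peak — both describe the same
event, and the larger extremum is kept. A genuinely separate later event
never merges (its onset lies after the earlier peak); that case belongs to
the compound logic.

Filters are checked in the fixed order amplitude → rise → half-width → τ,
and a violation stops further analysis of that candidate. Amplitude and
rise need nothing right of the peak, so they are screened first; only
candidates surviving that screen take part in decay fitting, and only their
onsets bound the previous event's fit span. This matters: sub-threshold
noise candidates would otherwise truncate real events' decay fits. A
candidate whose extremum lies below its own baseline (after direction
adjustment) is always rejected as `amplitude`, even with no bounds set.

### Kinetics

* Amplitude: `|y_peak − baseline|` at the sampled extremum.
* 10–90 % rise and the rising 50 % crossing: the latest linear-interpolated
  crossings of `baseline + 0.1/0.5/0.9·amplitude` before the peak.
* Half-width: rising 50 % crossing to the first falling 50 % crossing after
  the peak; undefined (NaN) when the decay never returns to 50 % before the
  next event's onset or the sweep end. Undefined values fail any bound set
  on that quantity.
* Decay: least-squares fit of `B·e^(−t/τ)` (Levenberg–Marquardt, two free
  parameters, baseline fixed) to the samples from the peak to the earliest
  of the next surviving candidate's onset, the sweep end and
  `decay_fit_max_ms`. When `decay_fit_max_ms` is unset the span is five
  times the 1/e time read off the trace (50 ms when the trace never reaches
  1/e). Initial values are `B = amplitude` and τ = the 1/e estimate. The
  alternative `one_over_e` method reports the interpolated time to fall to
  `amplitude/e`, which coincides with the fit on true single exponentials.
  Fits with fewer than 5 samples, non-convergence, or non-positive τ yield
  NaN.

### Compound events

Two candidates closer than `min_peak_separation_ms` are split when some
sample between the peaks comes within `valley_percent` of the earlier
amplitude toward the earlier baseline; the deepest such point becomes the
later onset. The later event's baseline is the chain's root baseline plus
the **sum of the fitted decays of every earlier chain member** extrapolated
to the later peak. Subtracting only the immediately preceding event's
scalar baseline would freeze earlier residuals at their old values and
overestimate the level by ≈`e^(−Δ/τ)` per chain step (a few percent in a
20 Hz train); summing the fitted decays keeps train amplitudes within ~1 %
on clean summed traces. When the earlier event has no usable fit, its 1/e
estimate is used; failing that, the later extremum is treated as part of
the earlier decay and dropped.

## Synthetic recordings

The generator reproduces standard mock-recording conditions at 10 kHz
(dt = 0.1 ms, so the 100–500-sample spacers span 10–50 ms):

* **Biexponential events** `A'(1 − e^(−t/τ₁))e^(−t/τ₂)` with
  τ₁ ~ U(2, 10) ms, τ₂ ~ U(2, 15) ms, evaluated to `t_max = 5(τ₁+τ₂)` so the
  tail falls below `e⁻⁵` ≈ 1 % before the next spacer. `A'` is set per event
  so the curve's maximum equals an amplitude drawn from U(0.5, 2.5) — the
  maximum of this shape depends on both time constants, so the target
  amplitude cannot be imposed directly. True 10–90 % rise and 1/e decay
  times are computed from the analytic curve by bisection (10⁻⁹ ms), not
  from τ₁ and τ₂, since both constants shift the peak. Note the stated
  parameter ranges imply peak offsets in [2 ln 2, 10 ln 2.5] ≈ [1.4, 9.2] ms
  and 1/e times of ≈3.2–21.8 ms; the nominal "2–10 ms" and "5–20 ms"
  descriptions hold for the bulk of draws, not for every draw.
* **Sharp events**: linear rise over `t_rise` to `A`, then `A·e^(−t/τ)`,
  evaluated to 5τ past the peak; rise and decay truths are exact
  (0.8·t_rise and τ). The default sampler draws `t_rise` ~ U(0.5, 3) ms
  (the order of real voltage-clamp mEPSC rises), τ ~ U(5, 25) ms and
  amplitude ~ U(0.5, 2.5), matching the hum-benchmark conditions.
* **Noise**: a 0.02-amplitude, 1 ms-period sine; correlated noise formed by
  summing 11 consecutive iid N(0, σ) draws per sample (default σ = 0.02/5;
  interior sd √11·σ, lag-k autocorrelation (11−k)/11; edge sums truncate to
  existing samples); and 0.2-amplitude hum at 20 ms period (50 Hz). For the
  hum benchmark σ is raised to `0.1/(3√11)` so the summed noise's ±3 sd
  excursion is ±0.1 and the combined event-free span is ≈0.6 peak-to-peak,
  matching the stated noise scale of that test (the two printed noise
  scales for this condition are inconsistent; the benchmark follows the
  peak-to-peak figure and exposes σ as a parameter).

What the generator does **not** emulate: amplifier/filter transfer
functions, Poisson event timing, event-rate or amplitude drift, seal
instability, stimulus artifacts, and overlap beyond the spacer rule
(compound tests build summed traces explicitly). Passing benchmarks
therefore show the measurement pipeline is accurate under calibrated noise,
not that detection thresholds transfer to any given rig's recordings.

## Benchmarks

Four scenarios pair a generator configuration with detection parameters:
`biexp_sine`, `biexp_correlated`, `sharp_correlated` (200 events each;
moving-average baseline, `ma_window` 100 samples = 10 ms, `auto_diameter`
20 ms, minimum amplitude 0.3 — well above the ≤0.03 sine/correlated noise
excursions and below the smallest 0.5 event) and `sharp_hum` (142 events;
fixed-left-window baseline at the hum period, same amplitude filter, noise
floor ±0.1 so 0.3 sits at three summed-noise sd).

Detections are matched to ground truth greedily by nearest peak time within
2 ms (far below the ≥10 ms event spacing). Under heavy hum the apparent
extremum of a slowly decaying event can sit on a hum crest up to ~18 ms
after the true peak; such a detection is still that event, so the hum
scenario additionally attributes a detected peak lying inside a true
event's extent `[onset, onset + t_rise + 5τ]` to that event (one-to-one,
nearest first). A false positive "at the hum extrema" is an accepted
detection outside every event extent (`n_spurious`); duplicates inside an
already-matched event's extent are reported separately. Accuracy is the
squared Pearson correlation between true and estimated onset time,
amplitude, 10–90 % rise and τ over matched pairs; counts satisfy
`n_true = n_matched + n_missed` and `n_detected = n_matched + n_false_positive`.

Problem sizes (200/142 events per run, 10⁴ draws for generator marginals,
10⁶ samples for noise statistics) keep every benchmark deterministic under
a fixed seed and fast enough to be re-run routinely.

## Preprocessing and evoked statistics

The boxcar filter is a centred moving average with reflect padding (length
preserved, no edge droop). The Bessel low-pass (magnitude-normalised) is
applied forward–backward, i.e. zero-phase: a causal pass would delay onsets
and bias rise measurements downstream; the price is an effective doubling
of the order, which is documented rather than hidden. Both commute with
adding a constant. Baseline subtraction removes one scalar per sweep (whole
mean, window mean, or fixed value). Sweep averaging is a pointwise mean
with no alignment — meaningful only for pre-aligned (evoked) sweeps.
Evoked summaries report each sweep's min/max (optionally within a window)
and their across-sweep mean and sample (N−1) standard deviation; a single
sweep yields sd 0 with a flag.

## Known limitations

* The backward moving-average onset has a lag of ≈ slope·`ma_window`/2·dt
  under baseline drift; drift *toward* the event polarity can suppress the
  crossing entirely (the event then carries the no-crossing warning). Short
  averaging windows mitigate this at the cost of noise sensitivity.
* Amplitudes are read at the sampled extremum: for cusp-like events the
  discretization error is up to `A·dt/t_rise`, which no sample-reading
  detector avoids; smooth-peaked events are exact to O(dt²) curvature.
* Only single-exponential decays are fitted; multi-exponential kinetics
  show up as span-dependent τ.
* ABF reading requires the optional `pyabf` dependency and is read-only;
  CSV is the canonical interchange format and stores no sampling rate, so
  `dt` must be supplied.
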