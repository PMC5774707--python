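# Methods

## Model

A Type A (neurogenic) spontaneous action potential is modelled as a linear
superposition of four stereotyped components, each stored as a normalized
template sampled at a fixed interval `dt`:

```
Y(n) ≈ a·S(n − n_d) + b·A(n) + c·H1(n) + d·H2(n)
```

* `S` — sEJP template, baseline-zeroed, unit peak.  The sEJP is the
  passive depolarization produced by a spontaneous neurotransmitter
  release; a suprathreshold one triggers the spike and persists under it.
* `A` — native-AP template, baseline-zeroed, unit peak.  The nAP is the
  voltage-gated response alone; it is never observable in isolation and is
  estimated by subtraction.
* `H1`, `H2` — slow and very slow AHP templates, baseline-zeroed, unit
  trough (−1).  Both start at the peak of `A` (template field `h_offset`
  allows a different convention; the default is 0).

Assumptions inherited from the superposition framework: components add
linearly; the sEJP underlying an AP has the same shape as the subthreshold
sEJPs of the same cell, only amplified; G0 APs contain exactly S and A;
sAHP and vsAHP are mutually exclusive within one AP; templates are not
stretched or compressed in time.

Fitting solves, for each integer delay `n_d` in `[n₁, n₂]` (onset to peak
of `Y`), the unconstrained least-squares problem for `(a, b, c, d)` and
keeps the delay with the smallest Euclidean residual (ties to the smaller
delay).  The normal-equations form `X = (CᵀC)⁻¹CᵀY` is solved via an
orthogonal-decomposition routine with the identical solution; the design's
condition number is recorded, and a condition number above 1e10 raises a
singular-design error naming the collinear columns.  Coefficients are
unconstrained by default, mirroring the defining equations; the
`nonnegative_ahp` config flag switches to bounded least squares with
`c, d ≥ 0`.

## Detection and landmarks

All landmark logic lives in `event_detection` and every numeric choice is
config-exposed (`AnalysisConfig`), because the method's verbal definitions
("double peak", "end of first repolarization", "end of signal") need
quantitative criteria:

* **Onset threshold** — hard RMP + 1 mV rule (baseline noise SD in these
  recordings runs up to ~0.9 mV and is rounded up to the next integer mV).
* **Event gating** — an event is a run of the smoothed trace above
  threshold lasting ≥ 10 ms (`min_event_ms`); runs closer than 100 ms are
  merged (`merge_gap_ms`), since the fast AHP can dip the trace below
  threshold mid-event.  The gate makes detection robust: single noise
  samples above threshold never spawn events.
* **Slope profile** — first difference of a 15-sample moving average
  (7.5 ms at the default `dt` = 0.5 ms).  Raw derivatives of noisy traces
  have no readable double peak; the moving average suppresses the slope
  noise to ~0.1 mV/ms while the junction-potential slope bump (~0.5 mV/ms
  for a 13 mV underlying sEJP) survives.
* **Double-peak test** — at least two local maxima (boundary maxima count)
  whose heights exceed `double_peak_minor_frac` = 0.008 of the global
  rising-slope maximum, separated by a valley below 0.8 of the smaller
  peak.  The minor fraction is small by physics: the spike's smoothed peak
  slope (~7 mV/ms) is an order of magnitude above the junction-potential
  bump, so a 20%-style criterion would reject every genuine convex foot.
  Type B APs are excluded by the 50 ms onset-to-peak bound before this
  test matters.
* **EoF** — the slope-profile valley between the two largest admissible
  rising-phase slope maxima.
* **EoFR** — first post-peak index where the repolarization slope falls
  below 10% of its maximum, or the RMP re-crossing, whichever is earlier.
* **EoS** — start of the first ≥ 50 ms run (`eos_quiet_ms`) of the
  smoothed trace inside the ±threshold band around RMP.
* **AHP duration** — from the start of the first sustained (≥ 20 ms)
  excursion below RMP − threshold/2 after EoFR, to EoS; zero when no such
  excursion exists.  G1 ⇔ duration ≥ 100 ms.  Measuring from the excursion
  start rather than from EoFR keeps G0 APs with a plain ADP tail from
  acquiring a phantom AHP.
* **Features** (amplitude, half-width, AP duration, 10–90% rise, 90–10%
  fall) are measured on the raw trace with linearly interpolated level
  crossings; smoothing would clip the sharp spike peak and bias amplitude
  and half-width.

## Template extraction

Foot matching follows the differentially weighted distance exactly as
defined: `d1` is an unsquared Euclidean norm in mV over the first halves,
`d2` a dimensionless sum of squared relative errors over the second
halves, and `D = d1 + d2` mixes units exactly as the defining equations
do — implemented literally, not "fixed".  The 1000-point multiplier grid
spans the open interval (1, 1.5) inset by half a step.  Odd foot lengths
give the first half the extra sample.  Near-zero (< 0.1 mV) second-half
foot samples reject the pair rather than regularize the division.  Visual
match curation is replaced by an automatic rule: accept when the residual
foot's mean |value| is below 3 baseline-noise SDs.

Prototype averaging uses two conventions worth noting:

* **Ragged means.**  Event vectors end at their own EoS, so trimming an
  ensemble to the shortest member lets a single small, short event clip
  everyone (observed to cut the nAP template before its fast-AHP
  recovery).  Instead, vectors are averaged index-wise up to the
  75th-percentile length; each index averages the vectors that reach it.
  Signals converge to baseline, so early-ending vectors simply stop
  contributing.
* **Peak anchoring.**  nAP estimates are averaged anchored at their peaks,
  not their onsets.  Onset-detection jitter is 1–3 samples, onset-to-peak
  spans vary with the sEJP delay, and the spike flank moves tens of mV per
  sample — onset-aligned averaging audibly smears the spike (and did, in
  development: template-fit RMSE dropped from ~3.8 mV to ~0.9 mV with peak
  anchoring).  sEJP vectors are smooth and stay onset-aligned.  For the
  same reason, G1–G0 peak alignment and the fit's template anchor are
  refined over a few integer shifts (±3 and ±2 samples); sub-sample
  interpolation is never used.

G1–G0 match acceptance quantifies "residual energy comparable to noise
energy" as: window energy ≤ `energy_factor` (default 2) × `L·(σ₁² + σ₂²)`,
with `σᵢ` each AP's baseline noise SD in its normalized units — the
expected residual energy of two independent noisy signals over an L-sample
window.  Residual energies for classification are computed over the
post-EoFR tail (the matching window is constrained near zero by the
acceptance rule, so only the tail is informative).  Normalized AP windows
are extended past EoS by the quiet-run length — provably event-free by the
EoS definition — so slow AHPs whose shallow recovery ends inside the noise
band keep their full time course.

## Thresholds and evaluation

The RMSE between two APs is computed over the first AP's active window
(onset → EoS) after peak alignment by an integer shift; samples of the
second AP outside its own window count as baseline zero (both vectors are
baseline-subtracted and have returned to the noise band there).  The
threshold pool contains every detected AP, Type A and Type B.  An AP whose
10-nearest RMSE spread exceeds `purity_factor` (default 5) times the
median spread is dropped from threshold estimation (the automatic
counterpart of visually discarding mixed-class neighbourhoods); it falls
back to the universal threshold.  APs in the pool are scored against their
specific threshold, APs outside it against the universal T.

When fitting a detected AP, the window is anchored so the nAP template's
peak row lands on the detected peak; if the AP's onset-to-peak span
exceeds the template's pre-peak span, the template front is zero-padded
(the nAP foot is negligible that far before the peak) so peak alignment is
never sacrificed to the onset bound.

## Synthetic data

The generator emulates the statistical regime the analysis was designed
for, through the same forward model the analysis inverts.  Shape families
were chosen for closed-form landmarks, giving the tests analytic oracles:

* sEJP: double exponential `k·(e^{−t/τ_d} − e^{−t/τ_r})`, τ_r = 14 ms,
  τ_d = 20 ms, unit-peak-scaled.  The 10–90% rise is ~9.5 ms — within one
  SD of the observed 22.3 ± 13.9 ms population mean but below it, a
  deliberate compromise: this shape family cannot produce a 22 ms rise
  together with a fast decay, and a slowly decaying sEJP creates an ADP
  hump that physically masks the slow AHP's below-RMP excursion, breaking
  the G0/G1 split.  The observed fall-time statistic is a known
  typesetting duplication of the amplitude row and is treated as free.
  Per-event tau jitter: ±10% (lognormal-ish multiplicative), understating
  real shape variability.
* nAP: exponential (accelerating, concave) foot over 24 ms, raised-cosine
  repolarization over 19 ms to a −4 mV fast AHP, exponential recovery
  (τ = 35 ms).  The 24 ms upstroke keeps the spike's slope takeoff clear of
  the junction-potential slope bump so the double-peak valley is
  resolvable for delays up to `nd_max_ms` = 8 ms at noise SD 0.5 mV.
  Composite half-width ≈ 9.7–11.8 ms.
* Slow AHPs: negative raised cosines, 200 ms (sAHP) and 300 ms (vsAHP).
  Trough depths are drawn as a fraction of the AP amplitude
  (0.055 ± 0.007 and 0.10 ± 0.005) rather than independent mV values:
  independent draws crossed with the 7.6 mV amplitude SD make the
  normalized residual energies overlap, and the midpoint energy threshold
  cannot separate two populations that the tissue shows as distinct with
  no intermediates.
* Events arrive as a thinned Poisson stream with ≥ 300 ms of quiet between
  events (rates: 3 sEJP/min, 1.2 Type A/min, 0.1 Type B/min over 10-minute
  default recordings).  Subthreshold sEJP amplitudes are N(9.23, 3.56)
  truncated to (1 mV, 12 mV); each Type A AP draws its underlying sEJP
  amplitude `a` from the suprathreshold tail (> 12 mV) of the same
  distribution and its composite peak amplitude from N(52.49, 7.60)
  truncated above 20 mV, with `b` set so the composite peak matches.
  G1 fraction 0.42; vsAHP share among G1 0.22.  Baseline: RMP −43 mV,
  white Gaussian noise SD 0.5 mV by default (up to 0.9 supported).

What the generator does **not** emulate: colored/1-f noise, electrode
drift, overlapping events, amplitude-correlated shape changes, sEJP
summation under one AP, and real Type B pacemaking dynamics (Type B events
are a ramp foot plus spike, present only so the classifier and threshold
pool see them).  Tests passing on this data therefore demonstrate that the
machinery is correct and self-consistent under the model's assumptions —
not that real recordings satisfy those assumptions; replication
efficiencies on real tissue should be expected to fall well below the
near-100% values the pipeline reaches on model-consistent input.

## Problem sizes

The test suite and the acceptance script run on cohorts of 8–12 cells of
10 simulated minutes each (roughly 150–350 APs per cohort), 200-draw
recovery experiments and 200-trial detection experiments; these sizes give
stable statistics (binomial SE on a 95% rate at n = 200 is ~1.5%) while a
full run stays in the minutes range on one CPU.

## Known limitations

* The delay interval passed to the fit comes from detected landmarks;
  grossly mis-detected onsets shrink the searchable delay range.
* The midpoint energy threshold `E_th = (E_max + E_min)/2` is sensitive to
  the extremes of the accepted-residual pool; a single outlier residual
  can shift it substantially.  It is implemented as defined.
* Specific thresholds assume ≥ 11 APs in the pool; smaller pools raise.
* With an empty sAHP or vsAHP category the model degrades to three (or
  two) components; fits still run, with the missing coefficients pinned
  to zero.
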