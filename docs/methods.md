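# Methods

`gaitforce` analyzes walking gait from in-shoe vertical ground reaction
force (vGRF) recordings of the kind produced by 8-pressure-sensor
insoles sampled at 100 Hz, as used in clinical studies of Parkinson's
disease. This note documents the processing model, the synthetic data
generator that stands in for clinical recordings in all tests, the
numerical conventions, and the known limitations.

## Signal model and processing chain

Each shoe reports eight sensor forces; the per-foot vGRF `Fz` is their
row-wise sum and the total `Fz,tot` is the sum over both feet. The chain
is, in contractual order:

1. **Noise floor.** Samples of the per-foot summed signal strictly below
   20 N are set to zero. The floor is applied to `Fz`, not to individual
   sensor channels, and is idempotent.
2. **Low-pass filter.** 4th-order Butterworth, 15 Hz cutoff, applied
   forward–backward (`scipy.signal.filtfilt`). The zero-phase pass was
   chosen so that gait events are not delayed by filter phase; it
   doubles the effective order and squares the magnitude response, which
   the filter tests check against the analytic `|H(f)|²`.
3. **Startup trim.** The first 5 s are discarded (acceleration from
   standstill); times are not re-zeroed.
4. **Turn exclusion.** Straight-walking analysis excludes turn strides.
   Clinical studies often identify turns manually; here an automated,
   parameter-light proxy is used: a stride is flagged when its duration
   deviates from the per-subject median by more than `k = 3` scaled
   median absolute deviations (MAD × 1.4826), and each flagged run is
   expanded by one neighboring stride per side, because the strides
   entering and leaving a turn are partly irregular. With fewer than 5
   strides the rule degrades to "keep all" with a warning. This
   approximates, and does not replicate, manual turn removal.

Body-weight normalization uses `g = 9.80665 m/s²`.

## Events and stride assembly

Foot-strike (FS) is the first sample at or above the 20 N threshold
after a sub-threshold run; toe-off (TO) the first sample strictly below
it after a supra-threshold run (the strict-< mirrors the noise-floor
semantics). Events are reported at sample resolution — no sub-sample
interpolation — so at 100 Hz all event times are multiples of 10 ms.
Any stance or swing shorter than 100 ms is merged into its neighbors
(debounce); the shortest plausible double support at these walking
speeds is ~100–150 ms, so genuine phases are never merged. A stance
already in progress at the first retained sample, or truncated by the
end of the recording, is discarded, so each foot's sequence starts at
FS and ends at TO.

Because the operational event is a 20 N crossing of the processed
signal, detected events differ from the biomechanical contact instant
by the threshold-crossing time (~2 ms at typical amplitudes) plus the
grid quantization and a sub-sample perturbation from filtering the
denoised onset; on noise-free synthetic walks every detected event
stays within two samples of the true contact and matches an
independently computed oracle exactly.

A stride frame is the event quintuple (FS, contralateral TO,
contralateral FS, TO, next FS); a frame violating the normal-walking
ordering `fs < cTO < cFS < to < next_fs` (e.g. running-like flight, a
missing contralateral event) is marked invalid with a reason, counted
in the QC report, and excluded from summaries — never silently dropped.

## Variables

Temporal: stride time (FS→next FS), stance (FS→TO), single support
(cTO→cFS, equal to the contralateral swing), double support
(FS→cTO leading, cFS→TO trailing), each also as % of stride.

**Double-support convention.** One stride contains two double-support
occurrences. Three conventions are supported via
`double_support_mode`:

* `"mean"` (default): the average of the leading and trailing
  components — one number per stride at the conventional ~13–14% of
  stride magnitude.
* `"sum"`: both components (~27% of stride).
* `"lead"`: the component initiated by the stride's own foot-strike.

A consequence worth knowing: when left/right asymmetry enters through
stance timing, the leading and trailing components shift in opposite
directions by the same amount, so their mean is *identical* for the two
feet and the double-support symmetry index under `"mean"` is ~0 by
construction. `"lead"` is the only convention under which a
double-support asymmetry is expressible; its magnitude is
indistinguishable from `"mean"` on symmetric gait.

Kinetic (all in BW): `Fz,peak1`/`Fz,peak2` are the maxima of the first
and second halves of stance (split at 50% of stance duration, earliest
sample on ties). The half-window definition stays defined on flat or
single-peaked pathological stances, unlike prominence-based peak
pickers. `Fz,tot,peak` is the maximum of the two-foot total over the
reference foot's own stance window. The weight-transfer pair uses
strict local maxima: the front foot's first local maximum at/after its
FS (`Fz,peak front`) and the back foot's last local maximum at/before
its TO (`Fz,peak back`); `ΔFz` is their signed difference and `gwt` the
signed time between them (the magnitude `|gwt|` is summarized too,
since some studies quote a duration). Strides with no local maximum in
the search window keep NaN there and are noted in QC.

Per subject: for each variable the per-foot mean across included
strides is computed first; the reported mean is the left/right average,
the coefficient of variation `CV = 100·sd/mean` (n−1 sample SD,
configurable) is computed per foot and averaged, and the symmetry index

    SI = |x_R − x_L| / (0.5·(x_R + x_L)) · 100

is computed from the two per-foot means (absolute difference: SIs are
averaged across subjects, and signed values would cancel). A subject
needs at least 2 included strides per foot, else it is excluded from
cohort tables with a QC entry.

## Group statistics

Subjects are speed-matched by keeping walking speeds in the inclusive
band 1.0–1.3 m/s (self-selected speed is a strong confounder of nearly
every gait variable). Scalar variables use pooled-variance unpaired
two-sided Student's t-tests; associations use Pearson correlation; no
correction is applied across the many scalar variables (each table row
is a separate univariate question, reported with its own p).

**1D SPM.** Stance segments are linearly interpolated onto a 101-point
0–100% grid; one mean curve per subject enters the test (pooling
strides would pseudo-replicate). The statistic is the pointwise pooled
two-sample t; the family-wise critical threshold is the (1−α) quantile
(k-th order statistic, k = ⌈(1−α)·B⌉) of the permutation distribution
of max|t| over group-label reassignments. All `C(n, n_a)` labelings are
enumerated when their number does not exceed `n_perm` (default 10 000);
otherwise `n_perm` Monte-Carlo permutations are drawn from a stated
seed, with the observed labeling included in the null set. The
permutation threshold was chosen over random-field theory because it is
assumption-light, fully specifiable, and exactly testable by
enumeration on small groups; its family-wise false-positive rate is
verified by simulation to sit at the nominal α. Grid points with zero
pooled variance (e.g. the exactly-zero force at foot-strike on
noise-free curves) are dropped from the maximum with a warning and
report t = 0.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes,
with exact pre-noise ground truth; it does not simulate musculoskeletal
dynamics.

* **Stance profile.** `f(u) = A·(sin πu + r·sin 3πu)` on normalized
  stance position `u ∈ [0,1]`; zero at FS and TO, and for `r > 1/9` the
  canonical two-peak shape. Peak location/value follow from
  `cos πu + 3r cos 3πu = 0`, recoverable by root finding — the tests'
  analytic oracle. The profile is symmetric about midstance, so
  simulated loading and push-off peaks are equal and `ΔFz ≈ 0`; real
  gait is front-loaded.
* **Timing.** Alternating foot-strikes with step durations
  `Normal(stride_mean/2, σ)`, `σ` scaled by √2 so the stride time (two
  independent steps) has exactly the requested CV. Each stance lasts
  `(0.5 + dsf)` of the local stride (`dsf` = double-support fraction,
  default 0.135), making double support emergent from stance overlap
  and the phase-accounting identity `ds_lead + single_support +
  ds_trail + swing = stride` exact by construction.
* **Asymmetry.** `asymmetry_offset_ms` lengthens the left stance by
  half the offset and shortens the right by the other half, which
  yields a single-support L/R difference equal to the offset and the
  clinically observed SI ordering (double support > single support >
  stance > stride). A pure step-duration offset provably produces *no*
  single-support asymmetry in this event geometry, which is why the
  offset acts on stance duration.
* **Channels, noise, transients.** Each foot's force is split over 8
  sensor channels by configurable nonnegative weights summing to 1,
  with i.i.d. Gaussian channel noise truncated at 0 N (default SD 2 N).
  A linear startup ramp occupies the first 2 s; if `turn_every_s > 0`,
  segments of three strides with 1.5× inflated duration are inserted
  periodically, mimicking corridor turns (force-only data carry no
  heading, so a turn is detectable only through timing). Toe-offs at
  turn boundaries are clamped into the physically valid window
  (positive double support on both sides).
* **Cohorts.** Group presets carry the magnitudes typical of
  speed-matched Parkinson vs. control cohorts: stride 1071 ± 81 vs
  1107 ± 80 ms (between-subject SD), within-subject CV 2.2 vs 2.1%,
  stance 63.7 vs 63.1% of stride, profile amplitudes chosen so the
  first force peak is ~1.38 vs ~1.34 BW, single-support SI ~6.5 vs
  ~4.1%, and matching demographics/clinical-score distributions.
  Walking speeds are drawn uniformly in a configurable band (default
  the 1.0–1.3 m/s selection band) so the speed filter is exercised.
  Per-stride amplitude jitter exists but defaults to 0: no
  within-subject force-variability model is asserted.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: anteroposterior/mediolateral forces,
front-loaded (asymmetric-in-shape) force curves, freezing-of-gait or
festination episodes, sensor drift and calibration error, within-stride
phase jitter (sub-phase CVs equal the stride CV in simulation, whereas
clinical sub-phase CVs run higher), or per-foot amplitude asymmetry
(force SIs are ~0 in simulation unless configured).

## Numerical conventions and problem sizes

* Event times at sample resolution; all tolerances on event-derived
  quantities are stated in samples (10 ms).
* CV uses the n−1 sample SD; SI uses absolute differences; both are
  undefined (NaN in tables, error in the scalar API) for non-positive
  means/sums.
* Ties in peak extraction break to the earliest sample.
* Force-record text I/O uses 2 decimals for times and forces (the 10 ms
  / 0.01 N grid); round-trips are exact to that precision.
* The test suite and the acceptance script use 60–90 s walks (~55–75
  retained strides per subject, the scale of corridor protocols),
  cohorts of 54 + 39 subjects, 200-repetition null calibrations with
  2000 permutations, and 10 000 permutations for the final SPM — sizes
  chosen to exercise every code path at realistic stride counts while
  keeping a full run in minutes on one CPU.

## Known limitations

* Turn exclusion is a statistical proxy; strides that are irregular for
  other reasons (hesitation, stumble) are excluded with the same label.
* The 20 N event definition inherits a small systematic widening of
  stance (~1 sample per boundary) from zero-phase filtering of the
  floored signal; stride times are unaffected (both strikes shift
  equally).
* `Fz,tot,peak` timing is bimodal on perfectly symmetric simulated gait
  (the two double-support humps tie within noise); clinical curves are
  front-loaded and do not show this degeneracy.
* The permutation SPM reports a single family-wise threshold for max|t|
  and contiguous suprathreshold clusters; it does not compute
  cluster-extent p-values.
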