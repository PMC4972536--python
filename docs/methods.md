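# Methods

`vesiclekin` quantifies single-vesicle exocytosis from two classical
electrophysiological readouts — carbon-fiber amperometry and whole-cell
membrane capacitance — and relates the kinetics of the fusion pore to two
structural properties of the v-SNARE transmembrane domain (TMD): its
content of β-branched residues (valine/isoleucine) and its conformational
flexibility measured on Cα trajectories. This note describes the models,
the estimators, the synthetic-data generator the test suite runs against,
and the numerical choices that were genuinely open.

## Amperometric spike and prespike-foot analysis

### Signal model and filtering

Amperometric currents are treated as uniformly sampled traces (default
25 kHz), low-pass filtered at 2 kHz before analysis. The filter is a
zero-phase Gaussian smoother specified by its −3 dB cutoff
(σ_t = √(ln 2)/(2π f_c)). A Gaussian kernel was chosen over a causal
Bessel/Butterworth emulation because its symmetric impulse response adds
no phase lag: rise times, half widths and derivative timing are measured
on the filtered trace and any systematic delay would bias them. The
passband is flat to <1% a decade below cutoff and attenuates >99% two
octaves above it.

### Baseline

Baseline level and noise are estimated on an event-free window as the
median and a MAD-based sd of linearly detrended samples. The robust pair
tolerates slow electrode drift and the occasional stray event inside the
window. When no window is supplied, the quietest 200 ms stretch of the
trace (smallest 1–99 percentile spread) is used.

### Event detection and selection

Candidate events are maximal regions exceeding baseline by the detection
amplitude (4 pA, or 3 baseline sd if larger), grown outward to the
re-crossing of baseline + 1 sd, and required to stay above threshold for
at least 0.3 ms. Windows containing several resolved spikes are split at
the minimum between peaks; a peak counts as separate only when its
prominence reaches the detection amplitude *and* the valley between peaks
drops below 25% of the lower peak. The prominence/valley rule is the one
genuinely open design choice in detection: a plain threshold-gap split
misclassifies the prespike foot (or a noise dip on a flank) as a second
event, while the chosen rule keeps feet attached to their spikes and
still separates clearly resolved overlapping events. Detected events are
kept when the baseline-subtracted peak exceeds 4 pA and the trapezoidal
charge lies in 10–5000 fC (1 pA·ms = 1 fC); a stricter 7 pA amplitude cut
selects events for single-spike summaries.

Spike parameters follow the standard definitions: amplitude is the
baseline-subtracted peak; charge the window integral; the 50–90% rise
time and the full width at half maximum are linearly interpolated between
samples. Events whose peak falls on a window edge are flagged unreliable
and excluded from summaries.

### Prespike foot and fusion-pore fluctuation statistics

The foot — the low plateau preceding the spike while transmitter leaks
through the narrow initial fusion pore — is bounded by:

* onset: the last upward crossing of baseline + 4×sd with sustained
  elevation up to the spike rise;
* end (= spike onset): the intersection of the maximal-slope line of the
  spike rising phase with the foot plateau level, the conventional
  back-extrapolation construction. The plateau level is the median of the
  stretch between onset and the beginning of the contiguous steep-slope
  run (>20% of the maximal slope) attached to the maximal-slope point;
  scanning that run backwards from the maximal slope, rather than forwards
  from the onset, prevents the foot's own onset step or a flicker limb
  from being mistaken for the spike rise.

Feet shorter than one sample, or with no resolvable plateau, are reported
as absent — a valid outcome, not an error.

Fusion-pore jitter is quantified on the current derivative (units fixed
to pA/ms), additionally filtered at 1.2 kHz: each contiguous excursion
above +6 pA/ms or below −6 pA/ms counts once, and the fluctuation
frequency is (positive + negative counts)/foot duration. The 6 pA/ms
threshold corresponds to roughly 4× the baseline derivative noise;
`check_derivative_threshold` warns when a recording's measured noise
makes that correspondence off by more than a factor of two. The
threshold-independent companion statistic is the rms of the
mean-subtracted filtered derivative over the foot. Both statistics are
evaluated on the foot interior after trimming a 0.5 ms margin at each
end (configurable): the filter spread of the onset step and of the spike
rise otherwise leaks into the foot window and registers as spurious
excursions that have nothing to do with pore flux. Feet shorter than
2 ms are excluded from fluctuation analysis altogether, as is standard.

## Capacitance burst decomposition

Flash-evoked capacitance responses are fit with

    C(t) = A0                                                   t < onset
    C(t) = A0 + A1(1 − e^−(t−onset)/τ1) + A2(1 − e^−(t−onset)/τ2)
              + k(t − onset)                                    t ≥ onset

where A1/τ1 is the rapidly releasable pool (RRP), A2/τ2 the slowly
releasable pool (SRP), and k the sustained rate. The onset is a free
parameter shared by all three components. This parameterization makes
the secretory delay — the time between the flash and the intersection of
the back-extrapolated fast exponential with the pre-flash baseline —
identically `onset − flash_time`, rather than a post-hoc graphical
construction; whether the delay is fit or back-extrapolated graphically
is equivalent under this model.

Fitting is trust-region nonlinear least squares with bounds A1, A2, k ≥ 0,
τ1 ∈ [1 ms, 0.2 s], τ2 ∈ [0.1 s, 10 s] (the chromaffin-cell literature
ranges) and onset within 100 ms after the flash. Double-exponential fits
are multimodal, so eight deterministic starts span the bound box
(τ1 ∈ {10, 50} ms × τ2 ∈ {0.15, 1} s × fast/slow amplitude splits
{30/70, 70/30}% of the observed rise); the lowest-cost solution wins and
components are relabeled afterwards so the fast one is always the RRP.
The fit window defaults to 1 s post-flash plus a 50 ms pre-flash stretch
that identifies A0 and the onset.

Under the default study conditions (A0 = 5000 fF, A1 = 50 fF, τ1 = 20 ms,
A2 = 80 fF, τ2 = 250 ms, k = 20 fF/s, delay 3 ms, 2 kHz sampling,
2 fF Gaussian noise) noiseless traces invert to ≤1e−4 relative error on
all seven parameters, and the 100-trace noisy study recovers amplitudes
to ~1% and time constants to ~2% median error, comfortably inside the
10%/15% targets the recovery tests assert.

The sucrose-pool routine integrates the baseline-subtracted current over
the hypertonic-stimulus window (pA·s = pC) and corrects the total charge
by subtracting the steady-state refilling current — the mean over the
final 1 s of the stimulus (configurable) — times the window duration.

## TMD β-branched composition

A TMD record carries the sequence, 1-based inclusive TMD boundaries, and
optionally explicit half assignments. The default split gives the
N-terminal half the extra residue when the TMD length is odd (first
⌈L/2⌉ residues) — an arbitrary but fixed convention. Valine and
isoleucine are counted per half and the percentage rounds to the nearest
integer with ties away from zero.

The packaged fixture holds the five exocytotic v-SNARE isoforms with
their published half assignments (syb1 `MMIMLGAIC`, cellubrevin
`MWAIGISVL`, syb2 `MMIILGVIC`, VAMP7 `LTIIIIIVSIV`, VAMP8 `MIVIICVIV`).
Two published values are internally inconsistent with their own counts
(7/9 printed as 77%, where exact rounding gives 78), so the fixture tests
assert counts everywhere but percentages only where rounding is
unambiguous (22/33/44). VAMP7's halves (an 11/15 split that does not
follow the midpoint rule, with boundary superscripts that disagree with
the printed residue count) are stored verbatim and flagged `inferred`.

## Helix flexibility

The ideal α-helix reference uses the textbook geometry: rise 1.5 Å and
twist 100° per residue (3.6 residues/turn), Cα radius 2.3 Å, giving the
canonical ~3.8 Å consecutive-Cα spacing. Superposition is the Kabsch
algorithm (SVD of the cross-covariance with determinant-sign correction,
so no reflection is ever introduced); collinear selections are rejected.
The test suite checks it against an independently implemented
quaternion-method (Horn) oracle to 1e−9.

Windowed RMSF discards an initial equilibration stretch, splits the rest
into non-overlapping windows (frames per window = ⌊window_ns/frame_dt⌋,
partial trailing windows dropped), and within each window iteratively
superposes frames onto the window-average structure until the average
moves <1e−6 nm. The reference is the converged window average — not
frame 0 — matching the convention of measuring fluctuations about the
mean structure. RMSF_i = √(mean over frames of |r_i − r̄_i|²), reported
in nm (coordinates are stored in Å; figures in this field quote nm). The
fit selection for superposition defaults to all atoms and can be
restricted to a residue range, since either convention is found in
practice.

RMSD-to-ideal-helix builds an ideal helix of the region's length,
superposes it onto the selected Cα coordinates, and reports the residual
RMSD in nm — zero for a perfect helix, growing with any departure from
helicity.

Note a small-sample property of superposition-based RMSF: fitting 6
rigid-body degrees of freedom against 3N coordinates absorbs roughly
√(1 − 6/(3N)) of isotropic noise, so a 20-residue peptide recovers only
~95% of the injected jitter while 40 residues recover ~97.5%. Flexibility
fixtures therefore use ≥30 residues when checking the σ√3 closed form.

## Synthetic-data generator

The generator produces the three raw-data types with exact ground truth.

* **Amperometric events.** Each event is a foot plateau (amplitude ~6 pA,
  a few ms) followed by a spike. The spike kernel is a difference of
  exponentials A(e^−t/τd − e^−t/τr) normalized to the stated peak
  (defaults τr = 0.1 ms, τd = 1–2 ms, peak 20–30 pA, matching typical
  chromaffin-granule events); a rectangular kernel variant gives exact
  analytic charges for tests. Foot flicker is k symmetric sawtooth
  triangles of limb slope ±20 pA/ms (half-width capped at 0.4 ms) evenly
  spaced in the central 80% of the foot, so each oscillation contributes
  exactly one positive and one negative suprathreshold derivative
  excursion and the fluctuation-count ground truth is exact by
  construction. Baseline noise is white Gaussian (default 2 pA sd,
  SNR 10 against the default 20 pA spike); the acquisition low-pass is
  applied by the analysis side, not baked into the trace, so the
  detector's 2 kHz filter models the recording chain. The real noise
  spectrum of an amperometric setup is not white, and real spikes vary in
  shape; passing recovery tests therefore demonstrate estimator
  correctness under the stated model, not robustness to every recording
  artifact.
* **Capacitance responses** sample the exact burst model plus white
  Gaussian noise (default 2 fF at 2 kHz).
* **Helix trajectories** add per-residue, per-axis Gaussian jitter (sd in
  nm) to the ideal helix and then apply an arbitrary rigid rotation and
  translation per frame. Ground truth: post-superposition mean RMSF → σ√3.
  The jitter is isotropic and uncorrelated between residues and frames,
  unlike real MD where fluctuations are correlated along the chain and in
  time — so the generator validates the RMSF estimator, not any force
  field. The published per-construct flexibility values (polyL 0.0374 nm
  < wildtype 0.0472 nm < polyV 0.0644 nm) require the original
  force-field simulations; the package demonstrates the *ordering* on
  jitter levels 0.012/0.020/0.028 nm chosen to bracket those magnitudes.

Every generator call takes one integer seed; identical seeds reproduce
traces bit-for-bit.

## Group statistics

Event parameters are summarized as the mean ± SEM across cells of the
per-cell median, with cells required to contribute strictly more than 20
events (the legend rule read literally: 21 qualifies, 20 does not). SEM
for a single qualifying cell is reported as undefined (NaN), not 0.
ECDFs use the i/n convention with ties sharing the fraction of their last
occurrence. Regression of kinetic parameters on β-branched content is
ordinary least squares (delegated to `scipy.stats.linregress`; a flat
response returns slope 0, r² 0 rather than NaN). Hypothesis tests (ANOVA,
Mann–Whitney, Tukey–Kramer) are deliberately not re-implemented; call
scipy/statsmodels directly.

The weighted Mander's coefficient thresholds the reference channel at
6× the background sd and reports the fraction of the measured channel's
intensity on above-threshold reference pixels. Whether the measured
channel is itself thresholded before the denominator sum is ambiguous in
common practice; both conventions are exposed (`threshold_a`, default
thresholds both channels).

## Problem sizes and degenerate inputs

The simulation studies bundled in tests and in `scripts/acceptance.py`
use 200 events on a 120 s trace for detection, 100 noisy traces for
capacitance recovery, and 300–400-frame trajectories of 30–40 residues
for flexibility — sizes at which every estimate's sampling error is well
inside the asserted tolerances. Degenerate inputs are defined errors:
empty baseline windows, unfiltered traces passed to detection, inverted
or overlapping integration windows, τ1 ≥ τ2, collinear superposition
selections, empty ECDF inputs and zero-variance regressors all raise
with a message naming the violation.

## Known limitations

* The foot-boundary construction (4 sd onset, maximal-slope
  back-extrapolation) is a documented stand-in for the various published
  conventions; absolute foot durations carry a systematic component of
  about one filter rise time.
* Overlap handling is local-minimum splitting only; heavily overlapping
  spike trains (inter-event intervals of a few ms) need deconvolution
  that is out of scope.
* The 7 pA cut for fluctuation summaries is applied to the main-spike
  amplitude (switchable), since the alternative reading (prespike
  amplitude) cannot be excluded from the source material.
* Endocytosis, flash artifacts and Ca²⁺-indicator calibration are not
  modelled in the capacitance path.
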