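# Methods

## The detection model

`rwakit` quantifies REM sleep without atonia from a single chin-EMG
derivation.  The detector is deterministic signal processing, not a fitted
model: every parameter is a published factor of the method or a documented
implementation choice, and identical input always gives identical output.

**Pre-filtering.**  The raw EMG is band-passed 10–100 Hz with a 4th-order
zero-phase Butterworth filter plus a 50-Hz notch (Q = 30) before envelope
extraction, following standard chin-EMG practice.  The upper edge is
clamped to 0.9 × Nyquist at low sampling rates.

**Canonical sampling rate.**  Signals are resampled (polyphase,
band-limited) to 256 Hz on load.  The envelope window is specified in
*samples* (51), so fixing the rate fixes its physical span at ≈ 0.199 s, a
physiologically sensible envelope scale for chin EMG; the resampling can be
disabled per call.

**Amplitude curve (AC).**  AC(t) is the peak-to-peak range (max − min) of
the filtered EMG in the centred 51-sample window, computed exactly with
running max/min filters.  Windows are truncated at the signal edges rather
than padded; this affects < 0.1 s per edge.  The envelope operator is
config-free and robust to DC offsets; an RMS variant could be swapped in
via the same `AmplitudeCurve` container.

**Baseline.**  The baseline must track the atonia floor through the night
(drifts, therapy wear-off) while *not* tracking the activity it is meant to
detect.  A plain centred percentile fails the second requirement: inside a
long tonic segment the percentile climbs to tone level, the threshold
(4 × baseline) can then never be exceeded, and sustained activity — the
hallmark of severe RWA — becomes invisible.  The default estimator is
therefore causal and exclusion-aware:

* the AC is processed in 0.25-s blocks;
* samples at or below `madt_factor ×` the current baseline are admitted to
  a trailing 30-s buffer of "quiet" signal;
* the baseline is the 5th percentile of that buffer, floored at 0.5 µV,
  held constant within each block;
* the update is applied only when the buffer holds at least 10 % of a
  window's worth of quiet samples (`baseline_min_quiet_frac`), because
  with fewer the percentile would be estimated from the sporadic dips
  *inside* activity and ratchet upward.

The floor prevents zero thresholds on idealised noiseless signals; the
threshold itself is a ratio, so detection is equivariant under amplitude
scaling whenever the floor is not engaged.  The centred plain-percentile
estimator is retained as `baseline_mode="percentile"` for comparison.
Window length (30 s), percentile (5), floor (0.5 µV), hop (0.25 s) and the
quiet fraction are all exposed in `DetectionConfig`.

**Events, mini-epochs, score.**  Candidate events are maximal runs with
AC > 4 × baseline; runs separated by gaps strictly below the 0.5-s
inter-event interval are merged *first*, and merged events shorter than
0.3 s are dropped *second* — so two 0.2-s bursts 0.3 s apart survive as one
0.7-s event (the IEI defines event unity; the published factors do not fix
the order).  No artifact- or arousal-based exclusions are applied — the
published best-performing configuration.  Each 30-s staging epoch is tiled
by ten 3-s mini-epochs inheriting its stage; occupancy is exact interval
overlap; positivity is strictly "> 50 %", so exactly half coverage does
not count.  The automatic RWA score is the positive fraction of REM
mini-epochs.  All intervals are half-open `[start, end)` seconds.

## Emulated visual scoring

The visual tonic/phasic/any parameters are computed by rule, as an
*emulation* of human scoring, not a reproduction of any scorer: phasic =
a 0.1–5-s burst at > 2 × background within a REM 3-s mini-epoch; tonic =
elevated tone covering > 50 % of a REM 30-s epoch; any = mini-epochs with
either.  Phasic and any are scored on mini-epochs and tonic on 30-s
epochs, following the visual scoring standard.  Two numerical choices
differ deliberately from the automatic detector:

* the envelope is a 51-sample **RMS**, not peak-to-peak — a human comparing
  a burst with the background integrates over it, and an RMS is robust to
  the single extreme samples that would hold a max-based envelope above
  threshold for a whole window and create spurious ≥ 0.1-s "bursts" in pure
  noise;
* the background is the exclusion-aware running **median** RMS (exclusion
  ratio = `amp_ratio`), so sustained tone does not inflate its own
  reference.

Supra-threshold runs shorter than 0.1 s are discarded as noise.  By
construction every phasic-positive mini-epoch is any-positive, so
`any_pct ≥ phasic_pct` always.

## Statistics

AUC is the tie-corrected Mann–Whitney estimator computed from midranks;
its standard error, 95 % CI and the paired two-curve comparison use
DeLong's structural components (no installed package provides the paired
test, so it is implemented here and cross-checked against a stratified
bootstrap in the tests).  The reported cut-point maximises Youden's J with
ties broken toward higher specificity; because visual RWA cut-points are
conventionally reported at full specificity, the lowest threshold with
specificity 1.00 and its sensitivity are reported alongside.  ANOVA is the
classic one-way F; post-hoc pairwise tests are pooled-variance t-tests with
Bonferroni multiplication (capped at 1).  Fisher's exact test uses SciPy
for 2×2 tables and complete enumeration of fixed-margin tables for 2×k
(guarded to k ≤ 6, N ≤ 600).  Simple regression is OLS via statsmodels
with R² and the overall F.  Cohort reports pool {iRBD, PD+RBD} against
{HC, PD-without-RBD} as the RBD/non-RBD contrast; the within-pair
Bonferroni post-hoc p-values are logged with a configurable α = 0.05 so a
non-homogeneous pair is flagged rather than silently pooled.  The
Bonferroni family for the correlation screen is all correlations computed
in one invocation.

## Synthetic data

**Signals.**  The atonia floor is Gaussian noise band-passed 10–100 Hz and
scaled to 2 µV RMS (a realistic quiet-REM chin level).  Bursts and tonic
segments *multiply* the local envelope (half-cosine 50-ms ramps) rather
than adding spikes — closer to surface-EMG physiology, and it keeps a
ratio-based detector in its design regime.  The default hypnogram is one
cycle W 10 min → S1 5 → S2 30 → S3 20 → REM 20; any block layout can be
given.  All randomness flows from one explicit seed; identical spec and
seed give bit-identical signals.

*Occupancy planting.*  With `target_occupancy` set, `round(target ×
n_REM_minis)` mini-epochs are chosen and a 2.0-s burst is centred in each
(occupancy 2/3, decisively above the strict 50 % rule even after the
±0.1-s envelope smear of the 51-sample window).  Bursts are kept strictly
inside mini-epoch boundaries: adjacent planted minis retain a ≈ 0.8-s
atonia gap, which stays above the 0.5-s IEI (no cross-mini merging) and
leaves every 30-s baseline window with well over the required quiet
fraction even at 90 % occupancy.  Full 3-s coverage was rejected because
it removes those gaps and makes any adaptive baseline ill-posed at high
occupancy.

**Cohorts.**  Subject tables are drawn per group from truncated-normal
marginals over each variable's valid range (percentages in [0, 100], the
automatic score in [0, 1], indices ≥ 0).  The underlying location is
solved so the *post-truncation* mean equals the requested mean (the
truncated SD is consequently at most the requested SD — the price of
matching first moments against a hard bound).  Correlation between
variables can be requested through a Gaussian copula; the default is
independence.  Default group sizes, means and SDs reproduce the validation
study's clinical table (11 HC, 24 PD without RBD, 45 iRBD, 46 PD with RBD);
healthy controls carry no imaging values, as in that table.

**What passing synthetic tests does and does not show.**  The generator
contains no ECG crosstalk, snore/respiratory artifact, electrode pops, leg
movement coupling or sweat drift, and its bursts have clean envelopes.
Closure results (atonia → 0, saturation → 1, occupancy recovered within
0.05) therefore validate the *algorithmic chain*, not robustness to real
recording artifacts; the published correlation of the automatic score with
the periodic-leg-movement index suggests real artifact sensitivity that
these tests cannot probe.  Cohort-level results validate the statistics
layer against the published group structure, not the detector itself.

## Problem sizes

Unit and closure tests run on compact nights (5–20 min REM, 100–200 REM
mini-epochs) — large enough that the mini-epoch grid, baseline adaptation
and merging logic are all exercised, small enough to keep the full suite
fast.  The acceptance script uses a 20-min night (200 REM mini-epochs),
5 × 4 occupancy-recovery runs, 50 detector-oracle signals and 30 synthetic
cohorts of 126 subjects.

## Known limitations

* The published description fixes the event factors but not the envelope
  operator, baseline statistic or window length; those are this package's
  documented choices, and results at extreme parameter settings should be
  compared across `baseline_mode`s.
* The EDF writer emits plain EDF (16-bit, 1-s records, zero-padded final
  record); EDF+ annotation *writing* is not supported (reading is).
* Visual-rule thresholds emulate the scoring standard; agreement with an
  individual human scorer is out of scope.
* Stage vocabulary is W/S1–S3/REM; R&K S4 is not accepted (deep-sleep
  staging should be converted to AASM N3/S3 upstream).
* `fisher_exact` enumerates 2×k tables only for small k and N.
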