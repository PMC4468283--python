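# Methods

This note records what `rbhvoice` computes, the choices made where the
procedure was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Signal conditioning

Recordings arrive as RIFF PCM WAV (16-bit integer or float); amplitudes are
mapped to [−1, 1] regardless of bit depth. The speech channel is resampled to
exactly 16 kHz with a polyphase anti-aliased resampler; an EGG channel keeps
its native rate. Times are seconds, half-open intervals `[start, end)`.
Word alignments come from a Praat TextGrid (long or short text form; empty
intervals are dropped, pauses are the gaps between entries) or CTM lines.
Alignment is an input: no speech recognition is performed.

## Voicing and F0

Frames are 16 ms long with a 10 ms shift (256/160 samples at 16 kHz; the
shift is a package choice, exposed in `FramingConfig`). A frame is voiced
when two gates pass:

* the normalized cross-correlation within the F0 search range 50–500 Hz
  (covering pathological adult voices of either sex) peaks at ≥ `v_thresh`
  (default 0.45), computed in a ±20 ms window around the frame centre so the
  lowest admissible F0 still contributes a full period;
* the frame RMS is ≥ `e_thresh` (default 0.1) times the median RMS of
  non-silent frames. Using only non-silent frames for the level reference
  makes the decision invariant to amplitude scaling *and* to padding with
  digital silence.

F0 on voiced frames is the inverse of the chosen correlation lag with
parabolic sub-sample refinement. Because a periodic signal correlates at its
period T and at 2T, 3T, …, and jitter can make a multiple out-correlate T
itself in a short window, the chosen lag is the **shortest local maximum
within a ratio (default 0.87) of the best peak**; exact ties break toward the
longer lag. Each voiced run is then median-smoothed (window 5) and an
octave-jump correction folds frames sitting at 2×/3×/½×/⅓× of their
neighbours' consensus (4 % tolerance) back by exactly that factor. Residual
octave errors on noisy voices are expected and deliberate: they are the
mechanism through which the F0 extremum and onset features carry information
about irregular phonation. Voiced/unvoiced sections are maximal runs of the
frame flags; lengths are frames × shift.

## Word-level features (33)

Pause features measure the silent gap before/after the word, with intervals
whose label is in a configurable filler set (default `äh`, `ähm`, `hm`)
booked separately as filled pauses. Energy features use the frame-RMS contour
in the context; F0 features use the voiced-frame contour in semitones
relative to the recording median F0 (the normalisation is unspecified
upstream; semitones re median is this package's choice). Positions are
normalised to [0, 1] within the context. Contexts are the word itself (`W`)
and the two preceding words plus the pause between them (`WPW`); for the
first two words the WPW features are imputed with the recording mean so the
design matrix stays complete. Remaining normalisations, all package choices:

* `DurNormW = DurAbsW / (nchar · d̄)` with `d̄` the recording's mean duration
  per character — character count proxies the intrinsic word length, since no
  per-word reference durations are available;
* `EnNorm = EnMean / mean frame RMS over non-silent frames`;
* `EnAbs` is the sum of frame RMS values in the context.

A word without voiced frames gets NaN F0 features; NaNs are skipped when
averaging to the recording level, and a feature missing for every word is
dropped from the output vector.

## Window-level features (15)

Words are grouped into consecutive non-overlapping 15-word windows; a final
remainder of ≥ 8 words forms its own window, a shorter one merges into the
previous window. Jitter and shimmer are measured **pitch-synchronously on
the speech waveform**: within each voiced section, cycle peaks are found by
stepping one expected period (seeded by the frame-F0 median of the section)
and searching ±30 % around the prediction, with parabolic refinement of peak
position and height. Weak edge peaks (below half the median amplitude) and
one further cycle at each boundary are discarded against onset/offset
transients; periods deviating more than 20 % from the section median are
excluded. Per section,

    jitter  = mean|T_{i+1} − T_i| / mean(T)
    shimmer = mean|A_{i+1} − A_i| / mean(A)

and the window statistics are the mean and (population) SD over sections,
reported in percent. Section counts and lengths are clipped to the window's
time span; ratios with an empty denominator (no unvoiced material) are
missing-coded. `StandDevF0` is the sample SD of semitone F0 over voiced
frames in the window.

## Electroglottographic measures

Closure instants are positive peaks of the differentiated EGG above an
adaptive threshold (0.3 × a rolling 95th-percentile envelope of the positive
dEGG, floored at a tenth of the global maximum so silence yields nothing),
at least 1/500 s apart, refined to sub-sample precision. Consecutive
instants bound full cycles; cycles implying Fx outside 50–500 Hz are
discarded, and only *contiguous* surviving cycle pairs enter the
cycle-to-cycle statistics, so unvoiced gaps cannot fake irregularity. The
contact quotient Qx normalises each cycle to [0, 1] and measures the time
above a 30 % level (a common EGG convention; config-exposed) with linearly
interpolated threshold crossings. The summaries are

    CFx = 100 · mean|Fx_{i+1} − Fx_i| / mean(Fx)    (percent)
    CQx = mean|Qx_{i+1} − Qx_i|                     (percentage points)

The hardware vendor's exact CFx/CQx definitions are proprietary; this
mean-absolute period-to-period formulation matches their verbal description
("period-to-period variations") and is what the parameter-recovery tests
validate. Whether the vendor statistic is instead a distribution-width
measure cannot be determined from public sources.

## Agreement statistics

Krippendorff's α uses the coincidence-matrix formulation: every item with
m ≥ 2 ratings contributes its ordered rating pairs with weight 1/(m−1), so
missing ratings need no imputation. The default difference metric is
interval on the numeric 0–3 scale (ratings are averaged numerically
elsewhere, so treating them as interval is consistent); the ordinal metric is
available by flag. Pearson r and Spearman ρ (mid-ranked ties) carry
two-sided p-values from the t approximation for n ≥ 10 and from the exact
pairing-permutation distribution below that. Rater-versus-rest correlates
each rater with the item-wise mean of the others, skipping zero-variance
raters with a counted warning. The human reference for model evaluation is
the per-item mean over available raters.

## Feature selection and regression

Features are standardized to zero mean and unit variance before selection
and regression; published preset weights are interpreted in this
standardized space. CFS runs in k-fold cross-validation (default 10; folds
are contiguous blocks of a seeded shuffle): within each fold's training part
a best-first search maximizes

    M_S = k · mean|r_cf| / sqrt(k + k(k−1) · mean|r_ff|)

expanding the best open subset by single-feature additions and stopping
after 5 non-improving expansions. Features are ranked by cross-fold
selection frequency (ties: mean merit of the selecting folds, then name);
the final model uses features selected in at least half the folds. Constant
columns are dropped with a warning.

The ε-SVR dual is solved by sequential minimal optimization in the
2n-variable form with maximal-violating-pair working-set selection and
analytic two-variable updates, until the KKT violation falls below `tol`
(default 1e−3; the oracle-equivalence tests tighten it to 1e−8, where the
optimum matches an SLSQP quadratic-programming solution to ≲1e−8). Defaults
C = 1, ε = 0.001, linear kernel; the procedure gives no grounds for other
values, and a nested hyperparameter search is out of scope. The preset
weight sets were published without intercepts, so preset predictions are
relative scores: valid for correlation-based evaluation, not for absolute
0–3 scoring.

## Synthetic data

The generators are pure functions of their specs (seed included). Voiced
words are glottal-style impulse trains with per-period multiplicative
Gaussian perturbations of period (jitter) and amplitude (shimmer), filtered
by a fixed two-formant resonator (500/1500 Hz, bandwidths 80/120 Hz), with
an optional white-noise floor at a given SNR re the voiced RMS. The EGG
generator emits smoothed rectangular contact pulses with per-cycle period
and Qx perturbations. Gaussian perturbations make the recovery targets
analytic: a perturbation sd *s* yields an expected mean-absolute-difference
statistic of 2s/√π ≈ 1.128 s. Rating panels are clamped rounded true scores
plus Gaussian rater noise.

What the generators do **not** emulate: articulation and coarticulation,
formant movement, aspiration noise tied to breathiness, additive hum or room
acoustics, non-Gaussian or correlated cycle perturbations (e.g. diplophonia,
subharmonic regimes), or EGG baseline drift and electrode artefacts. Passing
parameter-recovery tests therefore shows the estimators are correct on
signals that match their assumptions — not that the features are clinically
valid; the latter rests on the published study.

Problem sizes used by the test suite and acceptance script: 17-word
recordings (one global window), 2.5 s EGG signals (~250 cycles), a
30-recording / 19-rater synthetic study for the end-to-end determinism
check, and 200-row feature tables for model recovery. These sizes keep each
statistic's sampling noise well inside its tolerance band.

## Numerical and degenerate-input conventions

Missing values are NaN throughout and excluded pairwise. Statistics over
fewer than two observations raise an "undefined value" error rather than
returning 0. Empty alignments, overlapping intervals, ratings outside
{0..3} and duplicate (item, rater) pairs are validation errors. A flat EGG
cycle is skipped; a recording whose EGG yields no usable cycles logs a
warning and omits CFx/CQx. Reports serialize with sorted keys and fixed
float formatting, so identical inputs, config and seed reproduce reports
byte-identically.

## Known limitations

* **CFS can drop a weak true predictor at small n.** The merit's √k penalty
  means that when a feature's sample correlation dips (n ≲ 60), the optimal
  subset may genuinely exclude it — best-first and exhaustive search agree.
  This mirrors the behaviour of the original selection procedure and is why
  the model-recovery checks use larger tables.
* **Octave errors persist on noisy voices** (by design, see above); F0-mean
  style features are biased downward on heavily perturbed signals.
* **Shift invariance is exact only up to boundary frames**: padding creates
  one partial frame that can move the median-based references by ~0.1 %.
* `DurNorm`'s character-count proxy ignores true phone durations; it is a
  stand-in for intrinsic word-length normalisation.
* Jitter/shimmer values from running speech are algorithm-specific and not
  directly comparable across tools; the definitions above are the ones the
  tests validate.
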