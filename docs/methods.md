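# Methods

This note documents the models and procedures physioscore implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions — in enough detail that every
number the pipeline produces can be traced to a decision stated here.

## Design model

Each trial crosses feedback **Probability** (Certain / Uncertain) with
feedback **Valence** (Positive / Negative). Because participants always
present their performance positively, Certain-Negative feedback defines
**Deception**, Certain-Positive defines **Truth**, and both Uncertain cells
define **Uncertainty** irrespective of valence. Each trial contains three
question events (questions 1–2 are controls, question 3 is experimental);
every question is epoched into an 11-s window: a 1-s baseline followed by a
10-s analysis window whose start is "time 0". Epochs are half-open sample
windows `[onset − 1 s, onset + 10 s)` on a 0-based grid with onsets snapped
to the nearest sample, so an epoch always holds exactly
`round(11 · fs)` samples.

Only trials the participant self-rated "among the best" enter the
statistics: negatively rated trials cannot carry the self-enhancing
behavior the design targets. The retention filter is idempotent and
order-preserving.

## Electrodermal pipeline

1. **Whole-recording band-pass**, 0.005–1.0 Hz. Realized as two
   second-order Butterworth stages (high-pass, low-pass) applied
   zero-phase (`sosfiltfilt`), so the effective magnitude response is the
   squared design response and trough/peak latencies are not delayed. Only
   the cutoffs are prescribed by the scoring convention; family and order
   are our choice — second-order Butterworth is the standard gentle choice
   for slowly varying electrodermal signals.
2. **Per-epoch conditioning**, in order: linear detrend over the full 11 s;
   subtraction of the baseline-second mean; restriction to the 10-s window;
   subtraction of the window minimum (the pre-smoothing minimum is exactly
   0); moving-average smoothing.
3. **Smoothing window: 0.1 s** (`EdaConfig.smooth_window_s`, centered,
   forced odd, edge-truncated). The scoring convention names a "smoothing
   factor" of 0.1 without defining the operator; its stated purpose is
   only to suppress spurious local extrema before detection. We verified
   numerically that a 1-s window (0.1 × the analysis window, a plausible
   alternative reading) destroys the trough/peak geometry it is supposed
   to protect: the smeared trough of an SCR with onset latency ≤ 1.6 s
   drifts in front of the 1-s validity bound (the response is then falsely
   rejected), and recovered amplitudes lose 4–9%. A 0.1-s window removes
   sub-SCR-scale ripple while keeping noise-free closed-loop amplitude
   error near 2% (median ≈ 1.3% in the acceptance run); it is the package
   default and fully exposed.
4. **Detection**: strict three-point local extrema of the smoothed signal.
   Each maximum is paired with the nearest preceding minimum; the first
   pair (in peak order) with trough time in the closed interval [1, 3] s
   from time 0 and peak lag in the closed interval [1, 3] s after the
   trough is scored as `TTP = peak − trough`. "Lower than 0.01 µS" is a
   strict exclusion: TTP = 0.01 is retained, 0.009 excluded
   (`below_threshold`); no qualifying pair is `no_response`. If the signal
   rises from sample 0 with no interior minimum, no pair forms.

All stages except extrema selection are linear, and selection is
scale-invariant, so scaling an epoch by c > 0 scales TTP by exactly c.

## Facial-EMG pipeline

1. **Filtering**: 4th-order Butterworth high-pass at 15 Hz plus
   second-order IIR notches (Q = 30) at 50 Hz and harmonics below Nyquist
   (50/100/150/200 Hz at fs = 500 Hz), all zero-phase.
2. **Envelope**: magnitude of the analytic (Hilbert) signal of the
   filtered trace — the envelope of the rectified waveform, computed
   without rectifying first — followed by a 100-ms centered moving
   average. For a stationary tone of amplitude A this envelope equals A;
   rectifying *before* the Hilbert transform would bias it to ≈ 0.7 A
   (the rectified tone's 2A/π DC plus harmonics), which is why the
   operator acts on the signed signal.
3. **Threshold**: 45% of the mean envelope. The scope of that mean is a
   genuine degree of freedom; `EmgConfig.threshold_scope` selects the full
   11-s epoch (default) or the 10-s scoring window.
4. **Duration**: seconds the envelope spends strictly above threshold
   within the 10-s window. Strict comparison makes the all-zero case
   unambiguous (0 s). Duration is monotone non-increasing in the threshold
   and invariant under rescaling the epoch (the threshold scales with it).

**Occupancy limit of the relative threshold.** Because the threshold is a
fraction of the *epoch's own* mean envelope, it can only sit above a
stationary background's envelope when the burst lifts that mean enough.
For a burst of duration d at envelope contrast r over an 11-s epoch the
mean is ē ≈ ē_bg (1 + (r−1) d/11), so the threshold 0.45 ē clears the
background level only when **(r−1) d ≳ 13.4 s**. Consequences the test
suite documents honestly: (a) at a 5:1 burst-to-background contrast,
bursts shorter than ≈ 3.4 s are inseparable from background (the duration
saturates toward the full window) — the corresponding closed-loop
acceptance test is expected to fail and is kept as a faithful record of
the method's limit; (b) an epoch with *no* burst over a stationary floor
scores near the full 10 s, since 0.45 × mean falls below the floor's own
envelope. At the generator's default, realistic facial-EMG contrast
(2 µV RMS resting floor vs 0.15 mV bursts, ≈ 75:1), every burst length in
[0.5, 8] s is recovered within ≈ 0.1 s. Users applying this scorer to
low-contrast data should prefer an absolute or baseline-derived threshold.

## Trial-level inference

- **Winsorization** (per measure, pooled across retained trials):
  values above the 95th percentile are collapsed to it, values below the
  1st percentile to it — deliberately asymmetric. The percentile
  convention is exposed (`method`); the default linearly interpolates
  order statistics (MATLAB's `prctile` convention). Under interpolating
  conventions re-winsorizing can still move the caps slightly (the capped
  tails shift the sample percentiles); order-statistic conventions such as
  `"lower"` are exactly idempotent.
- **Ratings**: linear mixed model `value ~ condition + (1 | subject)`
  fitted by REML (statsmodels `MixedLM`).
- **TTP and reflected fEMG durations**: Gamma GLMM with log link and
  subject random intercept, maximized by adaptive Gauss–Hermite
  quadrature (15 nodes; 1 node = Laplace) over the scalar random effect:
  per-subject conditional modes by Newton (the conditional log-density is
  strictly concave), L-BFGS-B over fixed effects, log shape and log σ_b,
  standard errors from the numerical Hessian. The fit matches R's
  `glmmTMB` to ~5 decimals on coefficients (cross-checked in the suite).
  fEMG durations are first reflected, x → 10 − x, so that *longer*
  activity maps to *smaller* positive values; durations of exactly 10 s
  map to 0, violate the Gamma support, and are flagged and excluded (the
  count is reported).
- **Tests**: omnibus condition effect as a 2-df Wald F; pairwise
  Deception–Truth, Uncertainty–Truth, Uncertainty–Deception contrasts as
  single-df Wald F-tests (numerically t²) on linear combinations of the
  coefficients, with Truth as the reference level. Denominator degrees of
  freedom are residual (n − p); mixed-model df conventions differ across
  implementations (Satterthwaite/Kenward–Roger would give smaller df), so
  small-sample p-values are mildly liberal — the type-I simulation at
  16 × 8 measured 0.051–0.060 at α = 0.05. The FDR family is the three
  pairwise contrasts within one measure (Benjamini–Hochberg step-up).
- **Partial η²** is reported as F·df1/(F·df1 + df2). This is the classical
  ANOVA-style approximation; for mixed models it can differ substantially
  from variance-component definitions, so treat it as a rough magnitude.
- **Uncertainty-valence control**: before pooling the two Uncertain cells,
  the same model machinery tests Uncertain-Positive vs Uncertain-Negative;
  pooling into a single Uncertainty level is endorsed only when that test
  is non-significant. The pipeline reports the control result alongside
  the pooled analysis.

## Synthetic-study generator

The generator emits what the analysis assumes, with ground truth recorded
per trial:

- **EDA**: tonic level (5 µS) + drift (0.05 µS/min) + slow sinusoidal
  wander (0.1 µS, 90-s period) + measurement noise (3 nS), plus at most
  one SCR per question (response probability 0.85): a bi-exponential
  kernel `exp(−t/τ_d) − exp(−t/τ_r)` normalized to unit peak
  (τ_r = 0.75 s, τ_d = 3 s; analytic peak time
  τ_dτ_r/(τ_d−τ_r)·ln(τ_d/τ_r) ≈ 1.39 s), amplitude Gamma-distributed
  (CV 0.4) around condition means 0.50/0.40/0.30 µS
  (Deception/Uncertainty/Truth), latency N(1.8, 0.4²) s. Control
  questions get condition-independent 0.35-µS responses.
- **fEMG**: stationary 20–120 Hz Gaussian floor (2 µV RMS) plus one
  amplitude-modulated burst per question (0.15 mV, 20-ms cosine ramps);
  burst durations Gamma-distributed around condition means (corrugator
  3.5/3.0/2.5 s, zygomaticus flat 2.8 s — the null channel), clipped to
  [0.5, 9] s and placed uniformly inside the scoring window.
- **Ratings**: Truth mean 70 plus condition deltas −10.516 (Deception)
  and −4.491 (Uncertainty) — the reported behavioral effect sizes, used
  here as generative defaults, not claims — plus a N(0, 10²) subject
  offset and N(0, 15²) residual, clipped to [0, 100].
- **Design**: 32 subjects × 20 trials × 3 questions at 500 Hz; the four
  feedback types are assigned uniformly at random per trial (the original
  allocation ratio is not reported, so Uncertainty receives about half
  the trials); P(self-rating = "best") = 0.8 so the retention filter has
  work to do. Questions are spaced 15 s with a 5-s inter-trial gap, so
  epochs never overlap; pacing is a convention, not a reconstruction.
  Everything derives from one seed via spawned per-subject streams
  (byte-identical outputs for equal seeds, no global state).

What the generator does **not** emulate — and therefore what passing
closed-loop tests do not establish about real recordings: multiple or
superposed SCRs per epoch, non-stationary tonic storms, motion and
electrode artifacts, EMG cross-talk between channels or into the EDA
lead, heteroscedastic rating scales, and any dependence of physiology on
the rating (signals and ratings are conditionally independent given
condition). The verification shows the chain is *correct*, not that the
scoring conventions are *optimal* for messy data.

## Verification at a glance

`scripts/acceptance.py --seed 1` recomputes (typical values): noise-free
TTP closed loop median error ≈ 1.3% over 200 trials; detection-rule suite
18/18; fEMG closed loop worst error ≈ 0.09 s at default contrast (and the
documented failure at 5:1); filter responses 0.9999 @ 0.1 Hz and 0.0016 @
5 Hz (EDA), 3e-29 @ 50 Hz, 1.5e-4 @ 5 Hz, 0.995 @ 30 Hz (EMG);
winsorize/BH oracle agreement 2600/2600; LME type-I rate 0.051 (1000 × 16
subjects × 8 trials); 95% CI coverage ≥ 0.94 for both models' effects at
32 × 20 (200 replicates each); and a full 32-subject synthetic study
recovering its generating effects through the complete pipeline. Problem
sizes were chosen so the whole script completes in a few minutes on one
core.

## Known limitations

- Residual-df Wald inference is mildly anti-conservative at very small
  n (see calibration above); no Satterthwaite correction is implemented.
- Only the first qualifying trough-peak pair is scored; multi-response
  epochs are summarized by their earliest valid response.
- The Gamma GLMM assumes a single scalar random intercept; random slopes
  are out of scope.
- The relative fEMG threshold's occupancy confound (above) is a property
  of the scoring convention itself; the implementation reproduces it
  faithfully rather than repairing it.
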