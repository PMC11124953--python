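# Methods

## Estimation model

Windowed gait speed is modelled as a multiple linear regression with an
intercept and at most ten linear terms over z-normalized features,
ŷ = β₀ + Σ βⱼ fⱼ. The cap keeps models comparable across device
combinations and keeps coefficients interpretable; z-normalization (per
training fold, population SD) makes the βⱼ directly comparable across
features. Regressors are added greedily, one at a time, by minimizing the
Gaussian-likelihood BIC

    BIC = n·ln(RSS/n) + k·ln(n),   k = intercept + regressors,

with constant terms omitted (they cancel in comparisons). Selection is
forward-only and is *forced to the cap*: it continues to exactly
min(10, pool size) terms even when a step worsens the BIC, so every
combination model has the same arity whenever the pool allows. Ties are
broken by lexicographic feature name; candidates whose addition makes the
normal equations numerically singular (near-zero Cholesky pivot relative to
the Gram diagonal) are skipped. The final model is refit by OLS
(statsmodels) to obtain coefficient SEs, t-statistics and p-values. The
stepwise search itself runs on precomputed Gram matrices, so one fold costs
one XᵀX product plus tiny per-candidate solves.

Predictions are not clipped; negative estimates, should they occur, are
reported as-is.

## Preprocessing

* Filters: 4th-order Butterworth, applied forward–backward (`sosfiltfilt`),
  low-pass 10 Hz and band-pass 0.1–10 Hz. The filter family and order are a
  design choice — standard in gait analysis; zero phase keeps filtered
  windows aligned with the reference trace. Effective magnitude response is
  the squared single-pass response.
* Orientation angles are unwrapped (period 360°) before filtering; filtering
  wrapped angles creates spurious transients at ±180° crossings.
* Windows: length L ∈ {2.5, 5, 10, 20} s, hop fixed at 1 s for every length
  (one feature vector per second; 80 % overlap at the default L = 5). An
  alternative reading — 80 % overlap at every length — exists; the 1 s hop
  was adopted because the emission-rate statement is unconditional.
  Incomplete tail windows are discarded. Turn segments are not excluded.
* Target: y = mean reference speed over the window (config-switchable to the
  midpoint sample).
* The trial-level "true" 6MWD is computed from the same windowed reference
  means (mean of window targets × 360 s); with ~356 windows per trial the
  difference from integrating the full trace is negligible.

## Feature bank

Nine statistics per component (x, y, z, modulus) and one SMA per sensor, per
filter mode: 74 per sensor. Conventions where the definitions are open:

* STD uses the population denominator N (consistent with the z-normalization
  SD).
* CV = STD/|MEAN|, defined as 0 when |MEAN| < 1e-12 — band-passed signals
  have near-zero means and the raw ratio explodes.
* MCR: sign changes of (x − mean), samples exactly at the mean inheriting
  the sign of the previous nonzero deviation (deterministic counts on
  quantized data), divided by window duration.
* PF: argmax of a single rectangular-window FFT magnitude spectrum, DC bin
  excluded, ties to the lowest frequency. Windows are short (125–1000
  samples), so Welch averaging would cost too much resolution.
* Shannon entropy: 16 equal-width bins spanning the window's own [min, max]
  (config `entropy.bins`), log base 2; constant windows are 0 bits. This
  estimator is scale- and offset-invariant and bounded by 4 bits.
* The modulus of orientation channels (norm of unwrapped azimuth/pitch/roll)
  has limited physical meaning but is computed for uniformity.
* Pressure channels p1–p3 and orientation angles are labelled positionally
  as components x/y/z in feature names.

Both shoes are featurised (left `dev_3`, right `dev_4`, flag
`shoes.both=true` by default), giving a working pool of 740 columns; the
*combinatorial* per-inventory counts (148/148/222, 518 pooled) follow the
single-shoe sensor inventory and are what `count_features` reports.

## Synthetic cohort

The generator emulates the study conditions the pipeline targets: 20
subjects, three ~6 min trials each (self-selected slow/medium/fast paces)
on a 10 m back-and-forth path, 50 Hz sampling. Defaults:

* Pace speeds drawn uniformly per subject: slow 0.7–1.0, medium 1.1–1.4,
  fast 1.5–1.9 m/s (disjoint ranges enforce the ordering).
* Cadence f_step = c₀ + c₁·v with c₀, c₁ ~ U(0.85, 0.95) steps/s — places
  step frequency at 1.5–2.6 Hz, inside the 0.1–10 Hz passband.
* Vertical accelerometer: gravity + two harmonics of f_step, fundamental
  amplitude 0.35·amp_scale·v·g with amp_scale ~ U(0.8, 1.2) per subject;
  white Gaussian noise, SD ~ U(0.1, 0.3) m/s². Gyroscopes: zero-mean
  oscillations at f_step, amplitude 0.6·amp_scale·v, noise SD
  U(0.02, 0.08) rad/s. Orientation: slowly varying angles plus a
  speed-proportional ripple at f_step. Pressure: rectified, phase-shifted
  squared-sine pulse trains at f_step, antiphase between feet.
* Turns: a 1–2 s multiplicative speed dip of 20–40 % (smooth half-sine
  profile) every ~10 m of integrated distance — the source of within-trial
  speed variance.
* Determinism: every stochastic quantity derives from explicit
  `numpy.random.Generator` seeds; identical seeds give bit-identical
  cohorts.

What the generator does **not** emulate: limb kinematics, stride-phase
structure beyond a fixed harmonic/pulse shape, sensor bias drift, device
placement variability, or pathological gait. Its speed-to-feature mapping is
cleaner than reality: the planted oscillation amplitudes and frequencies are
nearly deterministic functions of speed. Passing the end-to-end bound (LOSO
RMSE < 0.3 m/s, R² > 0.5) therefore demonstrates that the pipeline recovers
the information the signals carry — not that real-device accuracies are
reproduced. Two knock-on effects worth knowing:

* Absolute synthetic errors (~0.03–0.09 m/s) are *smaller* than realistic
  real-data errors.
* Longer analysis windows do not improve LOSO RMSE here: the residual error
  is subject-systematic (per-subject amplitude scale that the training folds
  cannot see), so it does not average down with window length the way
  window-level measurement noise would on real data. The window sweep
  therefore shows a flat-to-slightly-rising RMSE with window size on
  synthetic cohorts.

## Evaluation conventions

* Bland–Altman differences are (estimate − reference); limits of agreement
  use the sample SD (n − 1).
* R² is the squared Pearson correlation of pooled held-out (y, ŷ) pairs —
  the correlation-plot reading; 1 − SSE/SST is available via
  `r2_method="residual"`.
* RMSE is reported both pooled over all held-out windows and as
  mean ± SD across the per-subject folds.
* ε_r is stored signed, (true − est)/true·100; summaries report the mean ±
  SD of |ε_r| across trials, with the signed mean kept alongside.

## Feature-importance funnel

Stage 1 keeps features selected with p < 0.001 (uncorrected, by design) in
at least one fitted model. Stage 2, per combination, keeps features selected
in ≥ ⌈n_folds/2⌉ folds — the threshold is derived from the actual fold
count, never hard-coded. Stage 3, per device, keeps features appearing in
strictly more than half of that device's evaluated combinations (3 of 4 in
the full design). The strict reading was chosen because "more than half" is
the operative phrase; a relaxed ≥ half rule (2 of 4) is available as
`combo_rule="half"` since the two readings genuinely diverge. Survivor
summaries (mean ± SD of β and t over passing occurrences) use the population
SD, so a single occurrence reports SD = 0.

## Problem sizes

The reference synthetic benchmark is 20 subjects × 3 trials × 360 s with
5 s windows (21 360 windows × 740 features); a full LOSO evaluation of the
all-devices combination takes well under a minute on one core, and the test
suite exercises smaller cohorts (2–4 subjects, 40–90 s trials) for the
per-module contracts.

## Known limitations

* Forward-only stepwise (no deletion steps); beyond the first step the
  greedy path can diverge from best-subset selection.
* The significance screen is intentionally uncorrected for multiplicity.
* The CSV loader handles the package dialect only; vendor formats (e.g.
  motion-capture exports) must be converted externally.
* Real-data accuracy claims are outside what the synthetic cohort can
  establish (see above).
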