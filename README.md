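# gaitspeed

Estimation of gait speed (GS) and six-minute-walk distance (6MWD) from any
combination of three wearable devices — a smartphone, a smartwatch and a pair
of sensor-instrumented shoes — with a fully synthetic walking cohort so the
whole pipeline can be developed and tested without hardware.

Gait speed is a simple, sensitive vital sign: its decline tracks disease
severity in COPD, heart failure and neurodegenerative conditions. Wearables
can measure it continuously in daily life, but patients do not always wear
every device. This package trains one estimator per non-empty device subset
(7 combinations), so an estimate is available from whatever the person
happens to be wearing, and quantifies how accuracy changes with the subset.

## Method

Raw 50 Hz channels (accelerometer, gyroscope, orientation, insole pressure)
are filtered twice — low-pass at 10 Hz (keeping gravity/orientation content)
and band-pass 0.1–10 Hz — with a zero-phase 4th-order Butterworth, then cut
into sliding windows (default 5 s, hop 1 s, i.e. 80 % overlap). Each window
yields, per sensor and per filtered view, nine statistics (mean, SD,
coefficient of variation, RMS, range, max, mean-crossing rate, peak
frequency, Shannon entropy) on x, y, z and the modulus, plus one signal
magnitude area: 74 features per sensor — 148 for the phone, 148 for the
watch, 222 for the shoes' inventory, 518 pooled.

For each device combination a linear model

&nbsp;&nbsp;&nbsp;&nbsp;ŷ = β₀ + β₁ f₁ + … + β₁₀ f₁₀

is fitted on z-normalized features, the 10 regressors chosen by forward
stepwise selection under the Gaussian BIC, n·ln(RSS/n) + k·ln(n), always
continuing to the 10-term cap. Evaluation is leave-one-subject-out (LOSO):
normalization and selection are re-run inside every fold. Agreement is
reported as RMSE, Bland–Altman bias and limits of agreement (±1.96 SD of
differences), and R² (squared Pearson correlation). Walk distance is
6MWD = mean(ŷ)·360 s per trial with signed relative error
ε_r = (6MWD − 6MWD̂)/6MWD·100. A three-stage funnel (p < 0.001 screen →
selected in ≥ half the folds → present in > half of a device's combinations)
identifies the most important features.

## Worked example

Simulate a 6-subject cohort, run the full workflow and print headline
metrics:

```
$ gaitspeed run-all --seed 42 --subjects 6 --out demo_run
phone        pooled RMSE 0.083 m/s  R2 0.933  |eps_r| 5.8%
watch        pooled RMSE 0.092 m/s  R2 0.920  |eps_r| 6.7%
shoes        pooled RMSE 0.035 m/s  R2 0.988  |eps_r| 2.5%
phone+watch  pooled RMSE 0.092 m/s  R2 0.920  |eps_r| 6.6%
phone+shoes  pooled RMSE 0.036 m/s  R2 0.987  |eps_r| 2.5%
watch+shoes  pooled RMSE 0.035 m/s  R2 0.987  |eps_r| 2.5%
all          pooled RMSE 0.035 m/s  R2 0.988  |eps_r| 2.5%
```

Each line is one device combination evaluated leave-one-subject-out: the
pooled windowed-speed RMSE in m/s, the squared correlation between reference
and estimated speed, and the mean absolute relative error of the per-trial
walk distance. `demo_run/` then contains the feature table, per-fold model
JSONs, the agreement and walk-error tables, the stepwise selection ledger
and the surviving-feature importance report (`importance.csv`).

The same stages are available individually (`simulate`, `extract`, `train`,
`evaluate`, `sweep`, `importance`) and as library functions; recordings are
plain CSV, one file per device plus a reference speed trace, so real
exports in the same dialect drop into the identical pipeline path.

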