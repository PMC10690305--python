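# Methods

This document states the statistical model, the estimators, the synthetic
cohort generator, and the numerical conventions implemented in `backtraj`.
Everything here is what the code does; no empirical claim is made beyond
what the test suite and `scripts/acceptance.py` actually compute.

## 1. Problem setup

Each patient `i` has a latent time `T*_i` of a deterioration outcome,
a death time `D_i`, a discharge time `C_i`, and an administrative horizon
`H = 192 h` after onset. The observed follow-up is
`X_i = min(T*_i, D_i, C_i, H)` with status

- `1` — the outcome occurred first (a "case"),
- `2` — death occurred before the outcome (competing event),
- `0` — censored (discharge, horizon, or, for radiographic outcomes,
  a decompressive hemicraniectomy that preceded the radiographic crossing).

Three outcomes are adjudicated from the measurement and procedure tables:

| Outcome | Definition |
|---|---|
| `mls5` | first time midline shift (MLS) reaches **≥ 5 mm** (inclusive) |
| `pgs4` | first time pineal gland shift (PGS) exceeds **> 4 mm** (strict) |
| `dhc`  | decompressive hemicraniectomy (from the procedures table) |

Ties at identical timestamps resolve in the order event > death >
DHC-censoring > discharge. For `mls5`/`pgs4`, a DHC before the first
radiographic crossing censors the patient at the DHC time
(`censor_reason = "dhc_precedence"`), because surgery alters the
subsequent radiographic course. MLS is computed as the mean of two
boundary-based measurements when supplied as `mls_a`/`mls_b`.

## 2. Cleaning

A measurement is flagged when **either**

- its pooled cohort Z-score satisfies `|Z| ≥ 3` (inclusive), with mean and
  SD (`ddof = 1`) computed per variable over the full cohort, or
- its relative change from the patient's immediately preceding value of the
  same variable is `≥ 25%` (radiographic variables are exempt from this
  rule, since genuine MLS/PGS progression routinely exceeds 25% between
  scans).

The first value of a series and values following a zero predecessor have
undefined relative change. Policies: `flag_only` (default, keep all rows)
or `drop_flagged`. Flagging is invariant to row order and patient
relabeling.

## 3. Regularization

Each variable has a grid step from its clinical sampling cadence (1 h for
vitals, 2 h temperature, 6 h glucose/sodium, 12 h creatinine and imaging,
24 h WBC). Measurements are binned into half-open windows
`[k·step, (k+1)·step)`; the node sits at the left edge and takes the
in-bin mean (continuous) or the last value in the bin (dichotomous).
Nodes are then interpolated to an hourly grid:

- continuous: piecewise-linear between nodes;
- dichotomous: each hour takes the value of the nearest node, with ties at
  the exact midpoint going to the **later** node.

There is no extrapolation: hours before the first or after the last node
are missing. Per-patient series can be truncated at follow-up end
(`end_h`) before regularizing so that post-outcome data never leak into
backward estimates.

## 4. Aalen–Johansen cumulative incidence

With distinct event times `t_j`, risk sets `n_j`, cause-`k` events `d_kj`
and all-cause events `d_j`:

```
S(t_j) = Π_{l≤j} (1 − d_l / n_l)          (all-cause Kaplan–Meier)
F_k(t_j) = Σ_{l≤j} S(t_{l−1}) d_kl / n_l  (cause-k CIF)
```

so that `Σ_k F_k + S = 1` at every jump. The variance is the Aalen-type
estimator

```
Var F_k(t) = Σ_{j: t_j ≤ t} { (F_k(t) − F_k(t_j))² d_j / (n_j (n_j − d_j))
           + S(t_{j−1})² (n_j − d_kj)/n_j · d_kj/n_j²
           − 2 (F_k(t) − F_k(t_j)) S(t_{j−1}) d_kj / n_j² }
```

computed in O(J) by expanding the squares into cumulative sums.
Confidence intervals use the log(−log) transformation, which keeps bounds
inside [0, 1]. Evaluation between jumps is right-continuous;
`cif_at` flags evaluation times beyond the last jump.

The censoring distribution `Ĝ` is the Kaplan–Meier of the censoring
times, i.e. the same data with the roles of event and censoring reversed.
By default death is pooled with censoring when estimating `Ĝ`
(`death_as_censoring = True`), matching the convention that the backward
trajectories describe *cases* and every non-case exit removes the patient
from future observation. `Ĝ(t−)` is the left limit.

## 5. Backward trajectory estimation

Cases are aligned at their event time. With hourly series `Y_i(h)` and
event hour `r_i = round(X_i)` (round-half-up), the aligned matrix holds
`Y_i(r_i − s)` for lags `s = 0 … 72`. Each case receives the IPCW weight

```
w_i ∝ 1 / Ĝ(X_i −),   non-cases w_i = 0,
```

normalized to sum to one; a case with `Ĝ(X_i−) = 0` is a positivity
violation and raises an error naming the patient. At each lag the weights
of the cases with a defined value are renormalized and the estimator
reports the weighted mean and the weighted quartiles (left-continuous
inverse of the weighted empirical CDF), together with `n_eff`, the number
of contributing cases. Lags with `n_eff < min_n` (default 5) are masked
to missing rather than reported from too few patients. With no censoring
the weights are equal and every statistic reduces exactly to the plain
case-only statistic — this identity is enforced at machine precision by
the acceptance suite.

The rationale: forward averaging from onset mixes patients at wildly
different distances from their deterioration; aligning at the event
recovers the common pre-event signature, and the IPCW weights undo the
over-representation of early events among observed cases under
independent censoring.

## 6. Synthetic cohort generator

Latent times are independent across patients and of each other:

| Quantity | Default law |
|---|---|
| event `T*` | Weibull(shape 0.75, scale 280 h) |
| death `D` | Weibull(shape 1.1, scale 520 h) |
| discharge `C` | lognormal, median 240 h, quartiles 150/380 h |

Sampling times per variable are `t = 0` plus i.i.d. lognormal gaps
parameterized by their median and quartiles
(`σ = ln(q75/q25) / (2 · 0.6745)`), truncated at end of follow-up, plus a
measurement at end of follow-up and at the deterioration time itself
(deterioration triggers assessment, and without it the lag-0 estimand
would be structurally unobservable for sparsely sampled variables).

Each continuous variable follows an event-anchored signature: a
patient-level baseline (normal between patients) plus a linear ramp from
`T* − onset_lag` to `T*` with a fixed net change, plus i.i.d. Gaussian
noise. Defaults: WBC +1.0 ×10⁹/L over 72 h, temperature +0.5 °F over
24 h, sodium +2.0 mmol/L, heart rate −7 bpm; glucose, creatinine, and
blood pressure are flat. Radiographic series ramp to the threshold at
`T*`: MLS latently reaches 5 mm at `T*` and PGS reaches 4 mm at
`1.35·T*`, sampled on the imaging cadence with scan noise, so `pgs4`
events trail `mls5` events. A configurable fraction of in-horizon cases
receives a DHC shortly after `T*`. `inject_artifacts` corrupts a random
subset of rows (30% jumps, or +6 SD for first-in-series values) and
labels them, for measuring cleaning sensitivity.

The generator is the validation harness, not an EHR emulator: times are
continuous hours from onset, measurement cadences are stationary, and
signatures are linear ramps. These simplifications are deliberate — they
give closed-form or brute-force-checkable truth for every estimator.

## 7. Validation studies

- **Signature recovery** (`recovery_study`): an hourly marker with known
  net change Δ over 72 h, exponential event times (scale 120 h), and
  exponential independent censoring (scale 500 h ≈ 30% censored, 140 h ≈
  50%). Per replicate the recovered amplitude is `μ̂(0) − μ̂(72)`; the
  acceptance suite requires the 200-replicate Monte-Carlo mean within 5%
  of Δ at 30% censoring, 15% at 50%, and flat-null (Δ = 0) per-lag
  excursions within 3 Monte-Carlo SEs.
- **CIF consistency/coverage** (`cif_consistency_study`,
  `cif_coverage_study`): independent exponential competing risks with
  closed-form sub-distribution
  `F₁(t) = r₁/(r₁+r₂) · (1 − e^{−(r₁+r₂)t})`; the mean absolute error at
  t = 72 h must shrink over n ∈ {100, 1000, 10000}, and the 95% CI must
  cover the truth at n = 635 within binomial tolerance over 1000
  replicates.

## 8. Numerical conventions and determinism

- Round-half-up (`floor(x + 0.5)`) maps event times to hours.
- Weighted quantiles are the left-continuous inverse CDF; at exact
  cumulative-weight boundaries floating-point rounding may select either
  neighbouring order statistic.
- All randomness flows from `numpy.random.default_rng` seeds carried in
  the configs; derived seeds stay below 2³¹. Identical config + seed
  reproduces byte-identical output tables (enforced end-to-end at
  n = 635 by the acceptance suite).
- Generated values are rounded to 6 decimals and times to 4 before
  writing, so CSV round-trips are exact.

## 9. Limitations

- IPCW assumes censoring independent of the biomarker process given case
  status; the generator satisfies this by construction, real data need
  not.
- The backward mean at large lags is estimated from the cases that
  survived long enough to have data there (and is masked under `min_n`);
  it describes the case population, not a per-patient trajectory.
- The Aalen-type variance is asymptotic; coverage is validated at
  n = 635, not for very small samples.
- Dichotomous regularization and the DHC-precedence rule follow fixed
  conventions (midpoint-to-later, event > death > DHC > discharge ties)
  that real registries may define differently.
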