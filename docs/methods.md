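# Methods

This note records the modeling assumptions, unit conventions, numerical
choices and known limitations behind `evcl`, in the order the pipeline runs.

## 1. One-year service valuation

The functional value method prices four ecosystem services of cultivated
land and sums them. All arithmetic is carried in CNY; 万元 (10⁴ CNY) appears
only in report formatting. The two sum identities — soil subtotal =
V_e + V_n + V_s and grand total = supply + water + (carbon + oxygen) +
soil — hold to the last representable digit: no component is rounded before
aggregation.

**Replication unit conventions.** The bundled county replication follows the
source arithmetic of the published figures literally, and that arithmetic is
not dimensionally uniform. Three conventions, all recorded in the
breakdown's audit trail, reproduce every printed component to the printed
precision:

* erosion mass enters the erosion formula V_e = E/SC/H×P_r and the siltation
  formula V_s = E/SC×24%×0.67 in **kilograms**, against a bulk density of
  SC = 1.22 — a t/m³ magnitude carrying a kg/m³ label;
* erosion mass enters the nutrient formula V_n = ΣE·Aᵢ·Pᵢ in **tons**;
* the land return P_r = output / area(m²) is rounded to **6 decimal places**
  (4.437979 CNY/m² for the bundled constants) before entering V_e. The
  unrounded value misses the published erosion figure by ≈0.21 万元;
  rounding to 3 decimals (4.438) misses it by ≈23 万元. Six decimals is the
  precision that reproduces the figure exactly and cascades to the published
  soil subtotal and grand total (the computed total, 53,055,425,309.2 CNY,
  matches the published 53,055,425,310 within 1 CNY).

A dimensionally consistent mode (`convention="si"`: tons throughout, SC read
as t/m³, P_r unrounded) is provided for new study areas; its erosion and
siltation values are exactly 1000× smaller than the replication values.
Water conservation defaults to the 0.2 m national-standard paddy storage
height; a water-balance mode ((precipitation − evapotranspiration)/1000 m)
exists but requires both climate inputs and a non-negative balance. Prices
are used as given at their stated constant-price bases; a deflator is
deliberately not applied because no index series accompanies the inputs.

## 2. Scale modes and the proxy construction

The canonical internal scale is **percent** (all published regression
constants are percent-scale); fraction-scale input is accepted and
converted, and the conversion is exact and idempotent. The proxy target for
the stage-curve fit is Z_t = x_max_corr − g_t where g is the GDP growth
rate and x_max_corr = headroom × max(g), headroom 1.1 by default — the
correction keeps Z strictly positive at the maximizing year. The bundled
replication rounds the sample maximum to 2 decimals first (1.1 × 28.64 =
31.504, the published corrected maximum); full precision (31.5094) is the
default for new data.

## 3. Stage-curve fitting

With the asymptote a fixed, ln Z = ln b − c·x is estimated by OLS
(statsmodels), giving b = exp(intercept) and c = −slope with their standard
errors. Diagnostics (R², RMSE, MAE, MaxAE, and AIC/BIC in the Gaussian
concentrated form n·ln(RSS/n)+2k / +k·ln n) are reported both on the ln Z
regression scale and on the back-transformed Z scale. Fewer than 3 points,
non-positive Z, or a constant regressor raise immediately. The saturation
level a used for stage coefficients is the **observed sample maximum** of
the proxy target (28.64 for the bundled series), not the headroom-corrected
value; both appear in the audit trail.

On the bundled historical series the OLS slope is *positive* (ln Z rises
with urbanization), i.e. the fitted c is negative and no admissible Gompertz
curve exists for these data under the stated procedure; the pipeline reports
the fit verbatim and falls back to supplied-mode staging (§6). Parameter
recovery is therefore demonstrated on synthetic data: the log-linear fit
recovers (b, c) on noiseless exact-form data to ≤1e−10 relative error, and
within ±3 standard errors under multiplicative log-normal noise
(sd 0.05, n = 200, fixed seed).

The Pearl comparator y = a/(1+b·e^(−c·x)) is fitted by the analogous
linearization ln(a/y − 1) = ln b − c·x; when a is unknown it is profiled
over a grid (default 200 points from 1.001·max(y) to 3·max(y)) minimizing
RSS on the original scale. Model comparison reports per-model diagnostics
plus a Diebold–Mariano test on the loss differential with lag-window 0
(appropriate for one-step errors) and a normal reference distribution; a
zero-variance differential is flagged undefined rather than scored.

## 4. Unit-root diagnostics

**ADF.** Δy_t on intercept (optionally + trend), y_{t−1}, and 0..p lagged
differences; τ is the t-ratio of the y_{t−1} coefficient; critical values
and p-values come from the MacKinnon response-surface tables via
statsmodels. Lag selection offers AIC, BIC, Ng–Perron MAIC
(ln σ̂² + 2(τ_k + k)/T with τ_k = γ̂²·Σy²_{t−1}/σ̂²), or a fixed lag;
candidates are compared on a common sample, then the chosen order is refit
on all usable observations (the statsmodels `adfuller` convention, matched
exactly in a cross-check test). On the bundled GDP series with intercept
and 0 lags: α₁ = 6.346, γ = −0.521, τ = −3.690, rejecting at 1% — the
series is treated as stationary. Test size was checked by simulation:
5.0% nominal, 4% empirical over 200 driftless random walks of length 500.

**Zivot–Andrews.** The ADF regression augmented with a one-time break at an
unknown date: intercept shift DU_t = 1{t>TB}, trend-slope shift
DT_t = (t−TB)·1{t>TB}, or both, always with a linear trend term. Every
candidate TB in the 15%-trimmed interior is estimated; the break is chosen
by regression-AIC minimization (default) or the conventional most-negative-τ
rule — on the bundled urbanization series both rules agree. The grid is
implemented here because statsmodels' `zivot_andrews` neither exposes the
break-dummy coefficients nor offers AIC selection; an independent
brute-force grid reproduces the statistic exactly in the tests. Critical
values are the published asymptotic table per model
(trend-break: −4.93/−4.42/−4.11). On the bundled series the trend-break
model with one augmentation lag gives τ = −4.922 — significant at 5% but
not 1% — with trend-shift coefficient 0.483 and time-trend 0.155; on
low-noise synthetic series with an engineered slope break the selected date
falls within ±1 year of the truth.

## 5. GM(1,1) forecasting

Standard gray plumbing: x¹ = cumsum(x⁰), background z¹(k) =
(x¹(k)+x¹(k−1))/2, least squares of x⁰(k) = b − a·z¹(k), restored
predictions from the continuous closed form with constant one-step ratio
e^(−a). Input must be positive with length ≥ 4. The closed form extends to
k ≤ 0, which implements the bundled protocol of training on 2000–2022 and
validating by *backcasting* the held-out 1990–1999 window — an unusual
direction, kept because it is the stated protocol of the replication;
validation reports MAPE, RMSE, R² and the Durbin–Watson ratio (flagged
undefined on zero residuals, as is MAPE on zero observations). Urbanization
is fitted on the fraction scale.

Two numerical facts matter here. First, the *discrete* gray difference
equation — not the continuous restored form — is what the least-squares
system encodes, so the synthetic gray generator iterates
x⁰(k) = (b − a·x¹(k−1))/(1 + a/2) (one-step ratio (2−a)/(2+a) ≈ e^(−a));
on such data the fit recovers (a, b) to machine precision, which is the
module's primary correctness property. Second, refitting the model's own
continuous-form predictions is a fixed point of the development coefficient
only to O(a³) (and of the control variable to O(a²)): the tests pin the
a-drift below 1e−8 in the small-coefficient regime and document the b-drift
rather than pretending the loop is exactly idempotent. No residual
(Markov/Fourier) correction stages are applied. The published gray-model
coefficients for the county (a = −0.037) are not reproduced by this
protocol (ours gives −0.0446) and are documented as non-replicable; the
published 2025–2050 forecast values do not follow a constant one-step ratio
and are therefore treated, where needed, as supplied inputs.

## 6. Staging and projection

Model mode computes coefficients e^(−b·e^(−c·x)) from the fitted curve with
x in percent; supplied mode validates and passes through an external
coefficient series. Both enforce the open interval (0,1), and model-mode
coefficients are strictly increasing in urbanization. The bundled
replication defaults to supplied mode with the packaged 5-yearly 1980–2050
coefficient table, because every published coefficient is ≈0.8454× the
urbanization rate — a constant ratio that no evaluation of the published
curve divided by its saturation level produces; rather than guess at the
undocumented provenance, the package offers both modes side by side.

Projection: per-ha = round(coefficient × base per-ha) to the nearest
10 CNY, total = round(per-ha × area / 10⁶) to 2 decimals of a million CNY.
Rounding is half-away-from-zero via `decimal` on the shortest-repr string
(binary-float safe); all 15 published projection rows reproduce exactly
under this rule (none of them sits on a half boundary, so half-to-even
would too — the choice is recorded in the run log). The bundled base value
704,250 CNY/ha is itself the nearest-10 rounding of the computed
704,249.79.

## 7. Synthetic data

The generators emulate the *structure* the analysis assumes, at magnitudes
matching the bundled county data: a Gompertz-in-time urban share
(a = 0.6, b = 2.2, c = 0.05 per year spans ≈0.066→0.46 over 44 years),
logit-scale Gaussian noise (sd 0.03) so values stay in (0,1), an optional
one-time logit-slope break; a stationary AR(1) GDP growth series
(mean 0.115, ρ = 0.3, innovation sd 0.055 — roughly the sample moments of
the bundled series); the exact-form gray sequence of §5; and exact-form
proxy pairs z = b·e^(−c·x)·e^ε. One integer seed drives everything through
deterministic per-operation substreams (`default_rng([seed, op_id])`).

What passing on synthetic data does **not** show: real urbanization series
carry policy-driven level shifts, measurement revisions and serial
dependence the generators do not model, and the bundled historical series
itself demonstrates that the proxy construction need not yield an
admissible curve on real data. The closed loops certify the estimators,
not the empirical adequacy of the model for any particular county.

## 8. Problem sizes and determinism

Simulation-backed tests use deliberately small, fixed designs: 200
replicates of length-500 random walks for ADF size, n ∈ {50, 200, 1000}
for recovery-bias checks, 40-year series for break location — enough for
the binomial tolerances asserted, and all seeded, so two runs of the suite
or of the pipeline produce byte-identical numbers. The pipeline writes a
run log naming every convention exercised (mass units, P_r rounding, scale
mode, proxy correction, asymptote rule, break-search rule, train/validate
windows, rounding rules), so a replication differing in any of these is
diagnosable from the artifacts alone.

## 9. Known limitations

* No deflator series ships with the package; monetary inputs are used at
  their stated constant-price bases (the sources themselves disagree on the
  base year), and cross-year monetary comparability is the user's burden.
* The water-balance storage mode is unusable without an evapotranspiration
  input; the bundled constants carry none.
* ZA critical values are asymptotic; at n ≈ 44 the finite-sample thresholds
  are somewhat more negative, so marginal 10% calls should not be leaned on.
* GM(1,1) extrapolates a single exponential; the 30-year horizon of the
  bundled run inherits every caveat of exponential extrapolation, and the
  backcast validation (MAPE ≈ 11% on 1990–1999) measures pre-sample fit,
  not future accuracy.
* The Diebold–Mariano reference distribution is normal; for very short
  comparison windows the small-sample correction of Harvey et al. is not
  applied.
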