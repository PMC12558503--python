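# Methods

## Model

The LKME distribution composes the Kavya–Manoharan (KM) transform
F = e/(e−1)·(1 − e^{−G}) with the exponential baseline evaluated at the
Lomax-type argument: G(x) = 1 − exp(−β z^α), z = (x+λ)/θ.  Writing
t = exp(−β z^α):

- CDF  F(x) = e/(e−1)·[1 − exp(−(1−t))] on x ≥ −λ, 0 below;
- survival S(x) = (e^t − 1)/(e−1);
- density f(x) = αβ/(θ(e−1)) z^{α−1} t e^t;
- quantile x_p = θ·[−(1/β)·ln(1 + ln(1 − ((e−1)/e)p))]^{1/α} − λ.

α > 0 is the dominant shape (α < 1 gives an inverted-J density diverging at
the support edge; α > 1 a unimodal one), β > 0 a rate-like shape, θ > 0 a
scale in data units and λ a location.  The tail is of exponential type
exp(−β z^α), so all raw moments and the MGF on its admissible domain are
finite.

**Identifiability.** β and θ enter only through β/θ^α, because
β((x+λ)/θ)^α = (β/θ^α)(x+λ)^α.  The four-parameter surface therefore has a
flat ridge (β, θ) → (β s^α, θ s).  We keep the four-parameter
parametrization — parameter counts of four are what the information
criteria of the benchmark comparisons assume — and treat (α, λ, β/θ^α) as
the estimable coordinates.  Every fitted objective and every
goodness-of-fit statistic is ridge-invariant (tested to 1e−12); reported β
and θ individually are arbitrary ridge representatives.

**Support boundary.** At x = −λ the CDF is 0 and the survival 1; the
density takes its limit: 0 for α > 1, αβe/(θ(e−1)) for α = 1, +∞ for
α < 1 (returned as `inf`, not an error).  `log_pdf` returns −∞ off the
support so optimizers can reject support violations without exceptions.

**Numerics.** All tail quantities route through `expm1`/`log1p`:
S(x) = expm1(t)/(e−1) is exact as t → 0, and the hazard is evaluated in log
space with the asymptote log S ≈ −β z^α − log(e−1) once expm1 underflows,
so H(x) → (αβ/θ)z^{α−1} for large x without overflow of exp(exp(·)).
Quadrature for moments/entropies is adaptive (`scipy.integrate.quad`,
relative tolerance 1e−9) with the support split at the median and the
extreme tail handled by the semi-infinite integrator.

## Shape and entropy summaries

Galton (Bowley) skewness and Moors kurtosis are computed from the closed
quantile function.  Two variants exist in the literature; the default
"conventional" forms are (Q3 − 2Q2 + Q1)/(Q3 − Q1) and
(E7 − E5 + E3 − E1)/(E6 − E2) on octiles, which are zero for symmetric
quantile sets and ≈1.233 for the normal.  The "as-printed" variants (with
denominator Q3 − Q2 and the alternating octile sign pattern) are provided
for comparability with sources using them; they are not scale-normalized in
the usual way.  Rényi entropy of order u requires u(α−1) > −1 for
integrability near the support edge when α < 1; the u → 1 limit (Shannon)
is a separate function, not auto-dispatched.

Series expansions of the moments (exponential expansion of the outer e^t
factor of the density) are used only as cross-checks in the test suite;
quadrature on the defining integrals is the canonical path because the
binomial-expansion variants of the series are undefined for non-integer α,
and fitted α values are essentially never integers.

## Estimation

Five objectives, shared multi-start harness:

- `mle`: −Σ log f(x_i), minimized;
- `pe`: Σ [x_(i) − Q(i/(n+1))]²;
- `lse`: Σ [F(x_(i)) − i/(n+1)]²;
- `wls`: Σ w_i [F(x_(i)) − i/(n+1)]², w_i = (n+1)²(n+2)/(i(n−i+1));
- `cvm`: 1/(12n) + Σ [F(x_(i)) − (2i−1)/(2n)]².

Gradients are numerical (simplex search); the optimizer is Nelder-Mead per
start with a tighter second pass, best of `n_starts` (default 40)
quasi-random starts drawn from a seeded generator in a data-scaled box
(α ∈ [0.3, 8], β ∈ [0.01, 20], θ ∈ [0.1, 10]·IQR, λ from its lower bound to
the sample median).  Positive parameters are optimized on the log scale.
Everything is deterministic given (data, seed).

**Location bound.** The default `lambda_lower_policy="egap"` allows
λ ∈ (−min(x)+ε, max(x)] with ε = 1e−6·range(x): the model's support rule
x ≥ −λ admits negative locations whenever the support still clears the
data, and on one benchmark dataset (fibre strengths at 20 mm gauge, whose
values are a unit-shifted copy of the tensile-strength data) the maximum of
the likelihood genuinely sits at λ ≈ −0.79.  The ε-gap matters because for
α < 1 the log-likelihood diverges as λ → −min(x) (a support-edge spike, the
classic three-parameter-Weibull pathology); the gap keeps the optimizer off
that degenerate direction.  A "zero" policy (λ ≥ 0) is available.

**Competitor families** (Lomax, KME, KMGE, KMILBE, APTGL) are fitted by
MLE only, each with symbolically derived log-densities.  Two printed-form
ambiguities were resolved on mathematical grounds: the KMILBE baseline is
the inverse length-biased exponential G(x) = (1+θ/x)e^{−θ/x} (the θx
reading is not a CDF), and the APTGL transform is the standard alpha-power
map (α^W − 1)/(α − 1), computed stably as expm1(W ln α)/expm1(ln α) with
the α → 1 limit W.

**Boundary-parked fits.** Lomax-family likelihoods on light-tailed data
increase along the θ, λ → ∞ ridge (the generalized-exponential limit), so
the APTGL "MLE" on all packaged datasets is a box-boundary supremum rather
than an interior optimum.  `FitResult.at_bounds` flags coordinates sitting
on their box constraint; such criteria rows should be read as constrained
optima.

## Goodness of fit

AIC = 2k − 2ℓ, BIC = k ln n − 2ℓ, CAIC = AIC + 2k(k+1)/(n−k−1)
(small-sample corrected AIC), HQIC = 2k ln(ln n) − 2ℓ.  The one-sample
Kolmogorov–Smirnov statistic uses the order-statistic form
D = max_i max(i/n − F_i, F_i − (i−1)/n); its p-value comes from the exact
parameter-free one-sample null (`scipy.stats.kstwo`).  No correction is
applied for the parameters having been estimated from the same data
(no Lilliefors-type adjustment), so p-values are optimistic screening
numbers, not calibrated test levels.  Anderson–Darling
A² = −n − (1/n)Σ(2i−1)[ln F_(i) + ln(1 − F_(n+1−i))], with F clamped to
[1e−15, 1−1e−15] (with a warning) against log(0).

## Monte-Carlo estimator study

`run_study` draws inverse-transform samples from the LKME quantile at the
five canonical parameter sets (I–V) over sample sizes
n ∈ {20, 50, 100, 200, 300, 500} and tabulates, per parameter and method,
the mean estimate, mean absolute deviation from the truth, and MSE —
averaged over replications.  Per-replication seeds derive from
`SeedSequence([seed, set_index, n, rep])`, so any cell reproduces in
isolation and whole studies are byte-deterministic.

Simulation fits are **truth-anchored**: a local Nelder-Mead in raw
parameter space started at the generating parameters, with a 10% initial
simplex step and a 500-iteration cap.  This is deliberate.  Along the
(β, θ) ridge a global multi-start would land at an arbitrary ridge point
each replication, making per-parameter "bias" for β and θ unbounded noise;
a start-anchored local optimum is the only setting in which those columns
are well-defined.  α, λ and β/θ^α do not depend on this choice.  The
iteration cap is part of the estimator definition here, not a shortcut: a
fully converged simplex drifts further along the flat ridge without
changing the fit quality.

Default replication count is 200 in the CLI (the headline benchmark scale
is 1000; the acceptance script uses 1000).  At n = 20 with large parameter
values the optimizer diverges in a fraction of replications, producing MSEs
orders of magnitude above the n ≥ 200 cells; that instability is a real
feature of small-sample fitting of this family, and only its qualitative
pattern (huge at n = 20, small at n ≥ 200) is asserted by the tests —
specific small-n MSE magnitudes are not reproducible quantities.

## What the synthetic generator does and does not emulate

Samples are exact i.i.d. draws from the LKME law via the closed quantile —
no censoring, no covariates, no measurement rounding, no model
misspecification.  Passing simulation tests therefore demonstrates
estimator behaviour *under the model*, not robustness to the ways real
reliability data deviate from it (rounded recording, truncation, batch
effects).  The real-data checks in the comparison suite cover observed
datasets, but all five are complete (uncensored) samples.

## Known limitations

- No censoring/truncation support, no regression covariates, no Bayesian
  machinery; standard errors and confidence intervals for the fitted
  parameters are not provided (the ridge makes per-parameter standard
  errors ill-defined without reparametrization).
- K–S p-values are uncorrected for estimation (see above).
- For α < 1 with the ε-gap location policy, the reported optimum depends
  (weakly) on ε whenever the likelihood's supremum is the support-edge
  spike; such fits should be treated as penalized rather than pure MLE.
- The APTGL and Lomax families frequently have no interior MLE on
  light-tailed data; their rows in comparison tables are constrained
  optima (flagged via `at_bounds`).
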