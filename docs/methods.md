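# Methods

## Model

The extended logistic model (ELM) describes *seasonal totals* — biomass
yield Y (Mg ha⁻¹) and plant N uptake N_u (kg ha⁻¹) at harvest — as logistic
functions of the seasonal applied-N rate N (kg ha⁻¹):

    N_u(N) = A_N / (1 + exp(b_N − cN))
    Y(N)   = A   / (1 + exp(b − cN))

A and A_N are the relative maxima approached at high N; b and b_N are
dimensionless shifting (location) parameters; c (ha kg⁻¹) is a rate
parameter **shared by both curves**. That sharing is the model's central
structural assumption: it makes the biomass–uptake relationship a
one-parameter family. Eliminating N gives the hyperbolic phase relation

    Y = Y_m · N_u / (k_N + N_u),
    Y_m = A / (1 − e^(−Δb)),   k_N = A_N / (e^(Δb) − 1),   Δb = b_N − b,

and the N concentration N_c = N_u/Y runs linearly in N_u with slope 1/Y_m,
from a lower limit N_cl = k_N/Y_m = N_cm·e^(−Δb) at zero uptake to the
maximum N_cm = A_N/A at high N. Units are chosen so the algebra lands in
conventional reporting units: A in Mg ha⁻¹ and A_N in kg ha⁻¹ make
N_cm = A_N/A come out directly in g kg⁻¹.

Within a site, grain and total-plant fractions share b, b_N and c and
differ only in their maxima (constant harvest index A_g/A_t); a site is
therefore described by seven parameters (A_g, A_t, A_Ng, A_Nt, b, b_N, c).
This canonical set is the only stored parameterization; Y_m, k_N, N_cm,
N_cl are always derived from it, which makes inconsistent parameter states
unrepresentable. The phase quantities require Δb > 0 (positive k_N); for
Δb ≤ 0 the logistic and concentration equations still evaluate but Y_m and
k_N are reported absent rather than negative.

Two agronomic summaries follow from the fitted parameters: N_0.5 = b_N/c,
the applied rate at the uptake inflection where N removed per unit applied
peaks, and the yield there, Y(N_0.5) = A/(1 + e^(−Δb)), which sits on the
upper part of the biomass curve whenever Δb > 0. (The closed forms are
reconstructed from the logistic algebra: b_N/c is the half-maximum point of
the uptake curve, and substituting it into the biomass logistic collapses
the exponent to b − b_N.)

## Joint normalized estimation

All series of a trial are fitted simultaneously by minimizing

    Q(θ) = Σ_series Σ_i ( (y_i − ŷ_i(θ)) / s_series )²

where s_series is a fixed per-series scale. Biomass and uptake series
differ by an order of magnitude and by unit; dividing each residual by its
series' observed mean makes every term dimensionless and the objective
additive across sites and invariant to unit changes applied jointly to a
series and its parameters. The scale statistic is configurable (`mean`,
`max`, or `A` = 1.02 × series maximum); `mean` is the default used
throughout.

Three nested sharing structures ("Modes") are estimable for n sites:

- **Mode I** — 7n free parameters, no cross-site constraints;
- **Mode II** — 6n + 1: one global Δb, with b_N ≡ b + Δb per site;
- **Mode III** — 4n + 3: global (Δb, N_cm_grain, N_cm_total), with
  A ≡ A_N/N_cm per site and fraction.

For the canonical three-site design (60 observations) this gives 21/19/15
parameters and 39/41/45 residual degrees of freedom.

### Optimizer

The minimizer is Gauss–Newton on the normal equations with an analytic
Jacobian (the logistic derivatives chain exactly through the Mode II/III
reparameterizations), safeguarded by

- a step-halving line search (up to 40 halvings) accepting only descent,
- a Levenberg ridge λ·diag(JᵀJ) engaged when the normal equations are
  singular or the plain step fails to descend,
- projection of every candidate step onto a parameter box.

Full-Newton iterations (with residual-curvature terms) reach the same
stationary points but are markedly less robust for this normalized
objective, which is why the Gauss–Newton/Levenberg family is used.
Convergence is declared when the projected gradient ∞-norm falls below
`gtol` (default 1e−8) or the relative objective change falls below `tol`
(default 1e−10); the iteration cap is 500. Failure to find any descent
step returns the best iterate with `converged=False`. The fit is fully
deterministic: identical data and options give bit-identical iterate
traces. On the canonical design a fit takes a few milliseconds, so the
simulation studies in the test suite (hundreds of replicate fits) run in
seconds.

### Initialization and bounds

Starting values come from linearizing each logistic:
z = ln(A/y − 1) = b − cN with a provisional A = 1.02·max(y) (the 2%
headroom guarantees the log exists at every observed point; points at or
above the provisional A, or at zero, are excluded with a warning). The 12
individual per-series slopes give 12 estimates of c — their mean is the
starting c and their min/max the raw c box. For each site × fraction the
biomass and uptake lines share the same N sampling, so a single best-fit
shared slope m = (S_xz1 + S_xz2)/(S_xx1 + S_xx2) determines both
intercepts; the six biomass and six uptake intercepts yield per-site
starting values (means) and raw boxes (min/max) for b and b_N.

The raw min–max boxes are *padded* before use: the c box is widened by 50%
on each side, and each shift box by max(half-width, 0.3). This matters
because the raw boxes degenerate to a point whenever the two per-fraction
estimates coincide (which is exact for noiseless data, since b truly is
shared), and because the provisional-A linearization biases the estimates
— the true optimum need not lie inside the raw box. The padding retains
the boxes' role (keeping the normalized iteration, which can diverge more
readily than an unnormalized one, in a plausible region) without excluding
the optimum; both pads are overridable fit options. Amplitudes are bounded
below at a small positive multiple of their start, Δb and N_cm below at
1e−6. A starting value falling outside a user-supplied box is clamped to
the nearer bound and logged.

## Invariance testing

Nested modes are compared with the extra-sum-of-squares F ratio

    F = [(Q_reduced − Q_full)/(df_reduced − df_full)] / (Q_full/df_full)

against the upper 95% point of F(Δdf, df_full) (α configurable). The
denominator is always the *full* model's mean square — the classical
variance-ratio convention — not a pooled estimate. F below the critical
value means the sharing constraint (site-invariant Δb, or Δb and N_cm)
does not degrade the fit detectably. Critical values come from the inverse
regularized incomplete beta function; reported tables round to three
significant figures while JSON output keeps full precision. Per-series
goodness of fit is the Nash–Sutcliffe model efficiency 1 − SSE/SStot, the
nonlinear analogue of R².

Simulation under a true common-Δb null (the test suite runs 500 seeded
replicates at the default noise level) shows the Mode II-vs-I test
rejecting at close to its nominal 5% size, i.e. the F approximation is
adequate for this design despite the model's nonlinearity.

## Synthetic trial generator

`elmfit.simulate` emulates the canonical field design: three sites × two
fractions × two responses at N = 0, 56, 112, 168, 224 kg ha⁻¹, each
reported value the mean of `n_years = 4` year-observations. Each
year-observation is mean·(1 + ε) with ε ~ Normal(0, noise_cv) truncated at
−0.9 (an additive option exists); reported means therefore carry a CV of
about noise_cv/2. The default noise_cv = 0.02 was chosen once as a
realistic few-percent year-to-year variability for replicated trial means;
the published normalized residual magnitudes for this design are of the
order such noise produces. The bundled truth set carries the published
per-site estimates for the three soils; `constrain_truth` projects it onto
an exactly-common Δb (0.660) and/or common N_cm (14.0 and 9.18 g kg⁻¹)
so that null-hypothesis and Mode III recovery scenarios have truths that
satisfy the constraints exactly (the raw printed per-site values differ in
the third decimal, as rounding artifacts do).

What the generator does **not** emulate: block effects of the original
randomized-complete-block layouts (year-to-year noise stands in for all
replication), weather/soil covariates, residual soil N carryover, or any
model misspecification — simulated data follow the ELM exactly. Passing
recovery and calibration tests therefore demonstrates correctness of the
estimator and test under the model, not robustness of the ELM to real
field data.

## Numerical and design notes

- Logistic evaluation uses the numerically stable sigmoid (`expit`), so
  extreme exponents neither overflow nor lose monotonicity; the
  concentration curve is computed as a ratio of sigmoids.
- The parameter algebra round-trips: deriving (Y_m, k_N) and inverting
  back recovers (A, b) to ~1e−15 relative; property tests assert 1e−12.
- Replicate-level input is averaged per N rate before fitting (the model
  is defined for treatment means); duplicate CSV rows are averaged with a
  warning.
- Trial CSVs are written at 17 significant digits and parsed with
  round-trip float precision, so write→read preserves values bit-exactly.
- Degenerate inputs fail loudly: series with non-positive scale statistic,
  fewer than four points, non-increasing N grids, incomplete sites, or
  initialization with fewer than three usable points all raise with a
  message naming the series.

## Known limitations

- Shift parameters of small magnitude are weakly identified by a 5-level
  design: at the default noise level the sampling standard deviation of a
  per-site b is ≈0.015–0.02, so *relative* recovery error for a site whose
  true b is near zero (e.g. −0.105) is large even though the estimator is
  unbiased and efficient. This is an information limit of the design, not
  of the optimizer; see the recovery test for the measured medians.
- No standard errors or confidence intervals are reported for individual
  parameters; inference is limited to the nested-mode ANOVA.
- The ELM is seasonal-total only — no within-season dynamics — and this
  package deliberately excludes multi-nutrient (P, K) coupling and
  plant-population scaling of c or b_N.
- Mode II/III estimates depend on the shared-parameter structure being
  plausible; the ANOVA guards against gross violations but is not a
  goodness-of-fit test of the logistic form itself.
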