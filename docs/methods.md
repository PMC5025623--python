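# Methods

## The model

`cd4recovery` implements a combined model for a longitudinal biomarker
observed both before and after the start of a treatment whose initiation
depends on monitoring the biomarker itself.  The motivating application is
CD4 lymphocyte counts around HAART initiation in HIV seroconverter
cohorts, analysed on the square-root scale; the machinery is agnostic to
the biomarker as long as a (transformed) Gaussian working scale is
appropriate.

**Pre-treatment phase.**  For subject *i* with observation times
**t**_pre (years from seroconversion),

    y_pre = X β + Z b + W_pre + e,
    b ~ N(0, Ψ),  W_pre ~ fBM(κ_pre, H_pre),  e ~ N(0, σ² I),

with X = Z = (1, t) (random intercepts and slopes), and fractional
Brownian motion fBM(κ, H) the zero-mean Gaussian process with
Cov[W_s, W_t] = κ/2 (|s|^2H + |t|^2H − |t−s|^2H).  Marginally
y_pre ~ MVN(Xβ, V_pre) with V_pre = ZΨZ' + Σ_pre + σ²I, a closed form.

**Latent baseline.**  The error-free biomarker value at treatment
initiation t_trt is

    u = β₀ + β₁ t_trt + b₀ + b₁ t_trt + W(t_trt),

jointly normal with y_pre, so its conditional law u | y_pre ~ N(μ′, v′)
follows from the partitioned multivariate normal (Schur complement).
Subjects with no pre-treatment data use the unconditional law
N(x_trt'β, v₂₂).  The truncation u⁺ = max(0, u) is applied *inside* the
post-treatment mean and link functions only: u keeps its normal law on
all of ℝ and all probability mass below zero acts as a baseline of
exactly zero.  This keeps the integrand smooth except for one kink at
u = 0.

**Post-treatment phase.**  Given u⁺, the mean is the asymptotic
regression curve

    g(t, u⁺) = φ₁ + (u⁺ − φ₁) exp(−exp(φ₂) t),

rising from u⁺ at t = 0 towards the long-term maximum φ₁ at rate
exp(φ₂); the half-life of the transition is log 2 / exp(φ₂).  φ₁ and φ₂
are deterministic link functions of u⁺ (constant, linear, or a natural
cubic spline on a truncated-power basis with knots at 15.5, 17.5, 19.5
and 22 on the square-root scale), optionally stratified by the time from
seroconversion to treatment with cutpoints 0.5 and 1 year (closed upper
endpoints).  φ₁ additionally carries a subject-specific deviation
τ ~ N(0, P).  Because g is linear in τ — g with asymptote φ₁+τ equals g
with φ₁ plus τ·c(t), c(t) = 1 − exp(−exp(φ₂)t) — τ is marginalised
analytically as the rank-one update P·cc', giving the closed form

    y_post | u ~ MVN( g(t_post, u⁺),  P cc' + Σ_post + σ² I ),

with Σ_post a new fBM (κ_post, H_post) started at zero at treatment
initiation, and σ² shared between the phases.

**Marginal likelihood.**  Per subject,

    f(y_pre, y_post) = f_pre(y_pre) ∫ f_post(y_post | u) f_u(u | y_pre) du,

a one-dimensional integral evaluated by adaptive Gauss–Hermite
quadrature (15 points by default): the log-integrand is recentred at its
mode and rescaled by the curvature there.  The mode search is a coarse
grid scan (±4 prior sd) followed by a safeguarded Newton iteration on
numerical derivatives; with a single node the rule collapses to the
Laplace approximation.  No special node placement is made at the u = 0
kink: it has measure zero and in realistic configurations μ′ sits many
standard deviations above zero.  Cohort log-likelihoods are sums over
independent subjects.

**Heavy tails.**  Between-patient differences in variability are modelled
by scaling each phase's process covariance with a latent gamma variable:
W_pre | w₁ ~ MVN(0, Σ_pre/w₁), w₁ ~ Gamma(v₁/2, v₁/2) (marginally a
multivariate-t phase with v₁ df), and likewise w₂ for the post phase.
The pair (w₁, w₂) follows Moran's bivariate gamma: (a, b) standard
bivariate normal with correlation ρ_Moran and wᵢ the gamma quantile of
Φ(·).  The subject likelihood becomes a triple integral over (u, a, b).
It is evaluated by a Laplace approximation over (a, b) on the
standard-normal scale — where the Laplace approximation is most accurate
— with the inner u-integral handled by the same adaptive Gauss–Hermite
rule as in the Gaussian model.  (A strict joint three-latent Laplace is
available as the one-node quadrature configuration; it carries the
u-direction Laplace error of up to a few times 10⁻² per subject, whereas
the nested scheme recovers the Gaussian limit v → ∞ exactly up to
quadrature error.)  The Φ∘gamma-quantile composition is clipped at
|z| ≤ 8; the clipped tail mass is below 10⁻¹⁵.

## Estimation

Maximum likelihood on transformed scales: log for variances, fBM scales
and degrees of freedom; logistic for Hurst indices; a generalised
logistic (scaled tanh) for correlations; identity for means and link
coefficients.  The optimiser is L-BFGS-B with finite-difference
gradients (central differences, step 1e-6, by default; a forward scheme
is available for large simulation studies) and generous box bounds
(±25 on log/logit scales) that prevent overflow in weakly identified
directions without restricting the parameter space statistically.  The
objective is deliberately stateless — latent-mode searches restart from
scratch each evaluation — because warm starts make the objective
history-dependent and corrupt finite-difference gradients.  Staged
initialisation (pre-model alone by ML; link coefficients from a crude
regression of each subject's last post-treatment value on its plug-in
baseline; variance components from residual moments) is used when no
starting values are given.  An abnormal line-search exit with a
near-zero projected gradient is accepted as converged, after one restart
with a coarser gradient step.

Wald intervals come from the observed information — a finite-difference
Hessian of the transformed-scale log-likelihood at the MLE (central,
step 1e-4, by default; a one-sided scheme with step 1e-3 for the large
replicate studies) — with endpoints mapped through the inverse
transforms, hence asymmetric on the natural scale for variance and
correlation parameters.  When the information matrix is numerically
indefinite the pseudo-inverse is used and flagged.  Nested Gaussian
models are compared by the generalised likelihood-ratio test against a
plain χ² reference (no boundary corrections, a known caveat for
variance parameters on the boundary); non-nested models by BIC with the
penalty computed from the **total** observation count (pre plus post),
not the subject count.  Laplace-based (heavy-tailed) log-likelihoods are
not comparable to quadrature-based ones by LRT or BIC.

Per-subject latent summaries: û is the mode of the (unnormalised)
posterior f(y_pre, y_post, u) at the MLEs with a curvature-based
standard deviation — for subjects with no post-treatment data this is
exactly (μ′, √v′) — and in heavy-tailed fits ŵ₁, ŵ₂ are the inner
Laplace optima mapped through the gamma quantile transform.

Prediction bands for a hypothetical subject with known true baseline use
the pointwise normal quantiles of g ± z·√(P c(t)² + κ_post t^2H + σ²)
on the analysis scale, then square (the analysis scale is the square
root of the raw measurement) and clip at zero.

## The synthetic cohort generator

The generator draws from the model's exact stochastic structure and
emulates the shape of a seroconverter cohort:

* time from seroconversion to treatment: log-normal, median 1.3 y,
  log-sd 1.14 (interquartile range ≈ 0.6–2.8 y), or a threshold rule
  (below) — clipped to [0.05, 8] y;
* visits: an entry measurement 0.02 y after seroconversion, then
  gamma-distributed gaps (shape 2) with mean 0.30 y pre- and 0.25 y
  post-treatment; post-treatment follow-up log-normal with median 1.5 y
  (log-sd 0.8, capped at 8 y).  These constants were tuned once to give
  median 5 pre- and 6 post-treatment observations per subject;
* a 39/852 fraction of subjects with no recorded pre-treatment values;
* subjects without at least one post-treatment observation are redrawn
  (the inclusion criterion of the motivating cohort);
* the pre-phase process is drawn jointly at the visit times *and* t_trt
  by Cholesky factorisation of the joint kernel matrix, so the latent
  baseline is exactly consistent with the observed path;
* under the optional threshold rule, visits accrue sequentially (the
  process extended by conditional simulation) until the *observed* value
  crosses sqrt(350); treatment starts after a short uniform delay
  (2–6 weeks).  This reproduces the downward bias of the last observed
  value relative to the true baseline that motivates the latent-variable
  construction;
* latent truth (b, u, τ, w₁, w₂ and the process paths) is always emitted
  alongside the observations, so simulation tests never re-derive
  latents from seeds.

Default generating values are fitted-model magnitudes for this model
family on square-root CD4 data (e.g. β₀ ≈ 22.3, β₁ ≈ −1.3, σ ≈ 1.9,
H_pre ≈ 0.3).  What the generator does **not** emulate: informative
dropout and death, outcome-dependent visit frequency (offered nowhere a
functional form; timing is independent by default, consistent with the
missing-at-random analysis assumption), assay floors/ceilings, and
calendar-time effects.  Passing simulation tests therefore validate the
estimation machinery under the model's own assumptions, not robustness
to their violation.

## Numerical choices and problem sizes

* Quadrature: 15 nodes, adaptive recentring on; mode search tolerance
  1e-6 of the prior scale; node count convergence (15 vs 41 nodes,
  difference < 1e-6) holds for subjects with pre-treatment data.  For
  subjects with *no* pre-treatment data the baseline prior is diffuse
  (v′ ≈ 15 on the default scale) and the u-posterior can be visibly
  non-Gaussian: the 15-point rule is then accurate to about 1e-3 in
  log-likelihood and more nodes are needed for tighter work.  This is a
  documented limitation, immaterial at the default 4.6% no-pre fraction.
* Heavy-tail Laplace: damped Newton over (a, b) with a 9-point stencil;
  the finite-difference step (0.02 standardised) is chosen large enough
  that the inner quadrature's numerical noise (~1e-10) does not corrupt
  second differences.
* Cholesky factorisations add escalating diagonal jitter
  (1e-12 → 1e-8) before failing, for near-duplicate visit times.
* The Gaussian likelihood has two implementations — a batched, padded
  numpy path (reference) and a numba-compiled per-subject kernel (same
  algorithm; agreement asserted at 1e-6) — selected automatically.
* Simulation studies in the test suite run scaled down so the whole
  suite completes on a single CPU: Wald coverage uses 12 cohorts × 100
  subjects with the per-parameter pass threshold (≥ 9/12) recomputed
  from the same binomial error rate as a full-sized 50-cohort study;
  the likelihood-ratio null calibration uses 200 replicates of
  30-subject cohorts; moment checks use 50,000 draws.  Larger runs are a
  matter of looping the same public functions.

## Design decisions taken where the design was open

* Knots and stratum cutpoints are fixed configuration, not recomputed
  from data centiles, keeping model comparison well defined on synthetic
  data.
* An additive covariate hook on the links (extra linear predictor in
  patient characteristics) is exposed structurally but ships without
  fitted defaults or validation targets.
* The documented non-convergent extensions (random effect on φ₂,
  independent effect of the pre-treatment slope) raise an explicit
  "unsupported" error instead of silently fitting.
* φ₂'s link uses u⁺ (not u), indistinguishable from the alternative
  whenever u > 0, for consistency with φ₁.
* In the heavy-tailed model the pre-phase scaling w₁ also divides the
  process contributions to v₁₂ and v₂₂ in the baseline law, including
  for subjects with no pre-treatment data (whose likelihood still
  integrates over both scaling variables).
* Time is in years and the package operates on the analysis scale
  throughout; square-root transformation of raw counts is an I/O option.
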