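# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `dynalign`. Units: time constants in the recording
pipeline are milliseconds (sampling period `Ts = 125` ms); ring-model
membrane constants are milliseconds with a simulation step of 1 ms; the
two-neuron illustration networks use arbitrary time units.

## Optimal discrimination of noisy input streams (`dynalign.signal`)

Inputs under stimulus `s` are i.i.d. per time step,
`u(s, t) ~ N(g(s), Σ_η)` with stimulus-independent noise. For a projection
`w`, the signal is `Δμ = wᵀ(g₂ − g₁)`, the noise `σ = √(wᵀ Σ_η w)`, and
`SNR = |Δμ|/σ`. The SNR-maximizing direction is `w = Σ_η⁻¹(g₂ − g₁)`;
summing the projection over `T` steps multiplies the SNR by `√T`.
Assumptions: Gaussian, temporally white, stimulus-independent noise. With
temporally correlated or stimulus-dependent noise the optimal decoder is
different (generally nonlinear); those cases are out of scope here.
Near-singular `Σ_η` (condition number above 1e12) is refused rather than
pseudo-inverted: discriminant components in the null space are undefined.

## Linear-network theory (`dynalign.linnet`)

For stable `dr/dt = A r + u(s, t)`, activation patterns are the *left*
eigenvectors of `A` (unit norm, sign fixed so the largest-magnitude entry
is positive), with `τ = −1/Re(λ)`. Key results implemented:

- stationary mean `r∞ = −A⁻¹ g` and covariance from the Lyapunov equation
  `AΣ + ΣAᵀ + Σ_η = 0` (via the Bartels–Stewart solver);
- stationary SNR along an isolated real mode,
  `SNR_out(m) = SNR_in(m) √(2τ)`, and its exact Ornstein–Uhlenbeck time
  course `SNR(t) = SNR_in(m) √(2τ (1 − e^{−t/τ}) / (1 + e^{−t/τ}))`
  (so `SNR(τ)/SNR(∞) ≈ 0.680`). The printed form of this expression is
  typographically ambiguous; this placement of the radical is the one that
  is exact for an OU process and recovers the `√(2τ)` limit;
- linear Fisher information of the stationary response
  `I = Δrᵀ Σ⁻¹ Δr`, `Δr = −A⁻¹Δg`, normalized by
  `Δgᵀ Σ_η⁻¹ Δg · 2τ₁` — the best achievable by any normal network with
  the same time constants, so normal networks reach 1 exactly when the
  slowest mode is aligned with the input discriminant, and functionally
  feedforward chains can exceed 1;
- information-limiting correlations
  `ρ_ILC = Δrᵀ Σ Δr / (ΔrᵀΔr · tr Σ)` and Henrici's normalized departure
  from normality `H = √(‖A‖_F² − Σ|λ|²)/‖A‖_F`.

Oscillatory (complex-pair) modes are retained in full-network computations
but excluded from per-mode SNR reports, where the real-mode formula does
not apply.

**Euler–Maruyama noise scaling.** The simulator draws per-step noise with
covariance `Σ_η·dt` (equivalently `√dt · N(0, Σ_η)` increments), the
scaling under which the discrete stationary covariance converges to the
Lyapunov solution as `dt → 0`; at finite step the covariance carries an
`O(dt)` relative bias (`≈ dt/2τ` per mode). A literal per-step draw from
`N(0, Σ_η)` multiplied by `dt` would make the stationary covariance itself
shrink linearly in `dt` and cannot reproduce the `√(2τ)` law, so it is not
used. Default `dt = 0.01` for the two-neuron illustrations.

## Synthetic recordings (`dynalign.synth`)

The generator emulates the geometry of chronic two-photon recordings in a
go/no-go task: 17 frames per trial at 125 ms spanning −1..1 s around
stimulus onset; conditions vertical (go), angled (no-go), gray; cell-type
labels in proportions ≈ 85/8/4/3% PYR/PV/SOM/VIP; per-trial running speed
(nonnegative AR(1), mean 10, AR coefficient 0.8) and lick rasters
(log-normal first-lick times, median 1.24 s on go trials and 0.87 s on
false alarms, lick probabilities 0.85/0.35/0.05 per condition).

Activity follows the same autoregressive form the analysis fits:
`r_t = (A + I) r_{t−1} + u_t(s) + ξ v_t + e_t`, `e ~ N(0, σ²I)`. The first
frame, which the recursion does not define, is drawn from the circuit's
pre-stimulus stationary distribution under the gray (baseline) input;
fitting starts at frame 2. The interaction matrix is built from an
explicit eigenmode specification: continuous-time modes are assembled as
`A_cont = M⁻¹ Λ M` from chosen left-eigenvector patterns and time
constants, then discretized exactly as `A = exp(A_cont · Ts) − I`.

Each circuit carries **three slow modes** near 850 ms (±75 ms jitter) over
a bed of fast background modes at 100–300 ms. Design rationale:

- real recordings show a population of slowly decaying modes per animal,
  and the learning effect is a population-level shift, not a single
  mode's; a single planted slow mode also makes the trial-shuffle null
  pathological (the mixture fit's one slow eigenvector locks onto either
  session's pattern, producing a bimodal null);
- the gap between 300 ms and the slow cluster keeps the slow eigenvalues
  spectrally isolated, so they remain identifiable (un-isolated slow
  modes merge into complex pairs under estimation noise and their
  alignment estimates attenuate).

With isotropic residuals the input discriminant is the planted direction
`d`, and a mode at angle `α` to `d` has normalized input SNR `cos α`.
Because any pattern basis must cover the direction `d`, one additional
"relay" mode (along the residual of `d` after projecting out the slow
patterns, so the basis stays near-orthogonal) carries most of the
discriminant input; its time constant sits in the scenario's spectral gap
(450 ms; 575 ms for the slowing scenario), clear of both the planted
modes and the 650–1050 ms window band of the conditional-average
analysis, where its large alignment would otherwise contaminate window
means.

Scenarios (defaults): *realignment* rotates the slow modes from
`cos α = 0.08` to `0.30` at fixed time constants; *slowing* lengthens
aligned modes (fixed `cos α = 0.18`) from ~400 ms to ~900 ms; *null*
copies the circuit. The realignment endpoint deliberately lies above the
0.25 upper edge of the conditional-average analysis range while the
slowing alignment sits inside it: realigned modes leave the domain of
the τ-conditioned-on-SNR curve (the hypothesized picture of modes moving
to high SNR) rather than registering there as a spurious influx of slow
time constants. Stimulus input is a step at onset with a shared
component plus `±δ/2 · d` (per-frame discriminant SNR δ/σ = 1). Eight
replicate "mice" are generated by default since the mode statistics are
pooled across replicates.

What the generator does **not** emulate: calcium-indicator convolution
(activity is treated as ΔF/F directly), ΔF/F preprocessing and
normalization, slow drifts across a session, non-Gaussian residuals, and
stimulus-dependent noise. Passing tests therefore demonstrate correctness
of the estimators under the model's own assumptions, not robustness to
those real-data features; `fit_mvar(standardize=True)` exposes the
per-neuron z-scoring toggle because the preprocessing applied to the
experimental data is not fully specified.

## MVAR analysis (`dynalign.mvar`)

The fit is per-neuron ordinary least squares of the frame increment
`r_t − r_{t−1}` on the previous frame, condition×time indicators (the
stimulus-locked input, free per condition and frame 2..17), running speed,
and optionally a lick indicator, over all trials of all three conditions.
Regressing the increment makes the activity-block coefficient the
deviation matrix `A` itself and leaves degenerate inputs (e.g. all-zero
activity or an empty lick column) with the minimum-norm solution `A = 0`
rather than an arbitrary one. The normal-equation path is used when the
Gram matrix is well conditioned, with an SVD fallback. Residual means
vanish exactly per (condition, time) cell because the indicators are in
the design. `Σ_e` pools residual outer products over vertical/angled
trials and the nine post-stimulus frames; the gray condition contributes
to the fit but not to discriminants or `Σ_e`, and all information and
covariance statistics use the 0–1 s window. Constrained pre/post refits
tie the named block (`A`, `u`, or both) and always tie the running
coefficients, matching the main model (tying both blocks then reduces
exactly to a pooled fit). Ill-conditioned covariances are
ridge-regularized with `ε = 1e-6 × mean diagonal` and a warning.

Impulse time constants follow
`τ = (Ts/2)(Σ_t q_t)² / (Σ_t q_t²)` for `q_t = w·(A+I)ᵗp` (the printed
formula's numerator/denominator distinction is lost to typesetting; this
reading returns `(Ts/2)(1+λ)/(1−λ)` for geometric decay and the continuous
`τ` in the slow-mode limit, which fixes it uniquely). The recursion stops
when `|q_t|` falls below 1e-10 of its initial value or at 1e4 steps; a
divergent projection raises, an identically zero one returns NaN with a
warning.

Mode statistics keep real eigenvalues with `λ + 1 > 0`
(`τ = −Ts/log(λ+1)`); conditional averages use moving boxes (width 100 ms,
centers 100–1400 ms; width 0.025, centers 0.025–0.25), with time constants
truncated at 2000 ms so an eigenvalue estimated at the stability edge
cannot dominate a window mean. The density map applies a 2-D Gaussian
filter (`σ_τ = 100` ms, `σ_SNR = 0.025`) on a configurable grid.

**Shuffle nulls.** Trials are pooled across sessions per condition and
resampled without replacement into pseudo-sessions of the original sizes;
the model is refit and the statistic recomputed (1000 shuffles in the
original analysis; tests use fewer). Pointwise 95% bands are reported
without family-wise correction, as in the source analysis. The *headline*
scenario test additionally aggregates each change curve over its
hypothesis region — 700–1000 ms for the ΔSNR_norm curve (the band where
learning effects concentrate), normalized SNR 0.125–0.25 for the Δτ
curve — and compares the aggregate against the null using the
`ceil(0.975(B+1))`-th order statistic, the standard exact Monte-Carlo test
convention. Aggregating before thresholding calibrates the test for the
region width (a pointwise scan would need a multiplicity correction), and
the order-statistic threshold is exact under exchangeability at any
number of shuffles, where an interpolated percentile is anti-conservative.

Behavioral statistics define hits and false alarms by the first post-onset
lick in the raster (the trial window ends at 1 s, so late licks fall
outside it), use a two-bin sliding window for the rate curves, and compute
per-trial discriminant autocorrelations over the nine post-stimulus frames
(lag-0 normalized, AUC over lags −8..8, so white noise gives ≈ 1/17).
Preferred-stimulus analyses include a cell only when a rank-sum test
separates its vertical/angled trial responses at p < 0.05 in both sessions
with a stable preference — the guard against regression to the mean — and
report mean, variance, SEM and the standard error of the variance
(`var · √(2/(n−1))`).

## E-I ring model (`dynalign.ring`)

Two rings (`N_E = 1000`, `N_I = 200`; angles `2πi/N`) with Wilson–Cowan
dynamics `T ṙ = −r + φ(W r + g + η)`, `φ(x) = [x]₊^γ`, `γ = 2`,
`τ_E = 10` ms, `τ_I = 5` ms. Input tuning and all weight kernels are von
Mises, `exp(κ cos Δθ)/I₀(κ)`-normalized so the ring average is
independent of `κ`. Baseline parameters: `κ_E = 0.5`, `κ_I = 0`,
`g₀_E = 0.5`, `g₀_I = 0` (the modeled input is the tuned component;
inhibitory cells receive only recurrent drive), `W₀_EE = 0.019`,
`W₀_II = −1.1·W₀_EE`, `W₀_EI = −0.04`, `W₀_IE = 0.04`, `κ_EE = 2`,
`κ_II = 0`, `κ_IE = 0.1`, `κ_EI = 0.4`, and input-noise variances
`σ_E² = 2Σg_E/N_E`, `σ_I² = σ_E²/2`. The non-uniform variant adds a
separable von Mises E→I subnetwork (`κ_sub = 4.2`, `W₀_sub = 0.004`)
centered on the trained orientation `θ_sub = π`, rescaled to preserve the
block mean. A narrow-bump alternative preset (`κ_E = 2`, `κ_EE = 3`,
`κ_sub = 32`, …) is shipped as `alternative_preset()`. Stimuli are
snapped to the shared E/I lattice (multiples of `2π/gcd(N_E, N_I)`);
off-lattice stimuli warn that rotational symmetry is broken.

**Fixed points.** Newton's method with the analytic Jacobian
`J = Φ′W − T⁻¹`, `Φ′ = T⁻¹ diag(γ φ(Wr+g)^{1−1/γ})`, terminated at
`‖ṙ‖ < 1e-15` (converged) or 100 Newton iterations (reported, not
raised). Pure Newton from `r = 0` stalls at the threshold kink, so each
Newton attempt is preceded by a block of forward-Euler relaxation
(`dt = min(τ)/5`) that carries the state into the attracting basin;
Newton supplies the terminal accuracy forward simulation alone cannot.
Sweeps warm-start from the previous fixed point. At baseline the network
is in the marginal regime (a weak bump persists under mean-matched
untuned input — `marginal_regime_check` is a diagnostic, not a
constraint).

**Linearization and information.** Per-mode input SNRs project the
analytic input-tuning derivative `g′(θ_s)` onto the left eigenvectors of
`J̃ = WΦ′ − T⁻¹` (similar to `J`; with silent cells both are block
triangular with identical spectra), with diagonal input-noise covariance,
normalized by `√(g′ᵀ Σ_η⁻¹ g′)`. Stationary covariances solve
`JΣ + ΣJᵀ + Φ′Σ_ηΦ′ = 0`; two-stimulus information is
`Δrᵀ [(Σ₁+Σ₂)/2]⁻¹ Δr`. The stationary covariance is numerically
singular (condition ~1e16: very low-gain cells), so the information
quadratic form uses an eigenvalue-cutoff pseudo-inverse (`rcond = 1e-12`)
and discriminant loadings use the ridge `ε = 0.01 × mean rate`. The
nonlinear stochastic simulation (Euler, `dt = 1` ms, per-step input noise
`N(0, σ²/dt)` inside the nonlinearity, matching the `Φ′Σ_ηΦ′` diffusion
of the linearization) projects onto the ε-regularized discriminant: the
raw inverse loads near-zero-variance cells whose nonlinear fluctuations
swamp the projection.

**Integration ordering.** With stimuli at `θ_sub ± 20°` (snapped to the
lattice), the non-uniform network's SNR(t) exceeds the baseline's at every
time — accelerated integration — while the sharpened network
(`κ_EE = 2.0` vs. baseline `1.8`) is the slowest to approach its own
plateau (largest fractional rise time) yet plateaus higher. Because the
sharpened plateau is ~1.5× baseline, its baseline-normalized curve crosses
above baseline within ~15 steps, so a literal three-way ordering of the
normalized curves holds only very early; the package's tests assert the
two robust statements above, which are the substantive claims.

## Test problem sizes

Monte-Carlo checks are sized so the sampling error supports their
tolerances: the `√(2τ)` law uses 300–400 trial-batched trajectories with
stationary statistics averaged over late snapshots; Lyapunov-consistency
checks use 3e5-step trajectories (8 parallel chains for the ring), since
a mode of time constant `τ` contributes only `T/τ` effective samples per
trajectory of length `T`. The scenario-discrimination pipeline runs 8
replicates × 500 trials/condition at 60 neurons with 60 shuffles, and
null-calibration runs use a reduced 30-neuron, 3-replicate configuration.
Parameter recovery is checked on 40-neuron circuits (8 replicates x 500
trials/condition, pooled off-diagonal correlation r > 0.95); at a fixed
trial count recovery degrades with population size (r ~ 0.91 at 100
neurons), since the per-weight signal scales down with the network while
the per-weight estimation error does not. Known limitations:
estimator behavior under model mismatch (calcium dynamics, non-Gaussian
noise) is untested by construction; the mode-alignment statistics assume
enough trials that eigenvector estimation noise is small (alignment
estimates attenuate visibly below ~200 trials/condition); and the
shuffle-null pipeline's power depends on population size, because random
background modes have alignments of order `1/√N` that crowd the
normalized-SNR analysis range for small populations.
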