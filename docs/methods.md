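# Methods

## Model

Both signal models describe a voxel as two exchanging water pools: an
intra-neurite pool (fraction f, one-dimensional diffusion at D_i along the
neurite axis — "sticks") and an extra-neurite pool (fraction 1−f,
isotropic Gaussian diffusion at D_e). Exchange is first-order with rate
matrix

    R = [[−k_ie, k_ei], [k_ie, −k_ei]],   k_ie = (1−f)/t_ex,  k_ei = f/t_ex,

which satisfies detailed balance f·k_ie = (1−f)·k_ei and mass conservation
(columns sum to zero). t_ex = 1/(k_ie + k_ei) is the *total* exchange
time, not the intra-neurite residence time t_i = t_ex/(1−f); comparisons
with implementations using the residence-time convention must rescale.

Per gradient direction g and neurite orientation n only the cosine
u = g·n enters. The narrow-pulse variant (NEXI) evaluates the two-pool
Kärger propagator over the effective diffusion time t_d = Δ − δ/3 with
b = q²t_d; the finite-pulse variant (SMEX) integrates
dM/dt = (R − k(t)²·diag(D_i u², D_e))·M through the rectangular-PGSE
wave-number profile (linear ramps 0→q_max over [0, δ] and back over
[Δ, Δ+δ], constant q_max in between, q_max = sqrt(b/(Δ−δ/3)) so the
nominal b is reproduced exactly). The powder average is ∫₀¹ K(u) du.

Model assumptions worth keeping in mind: Gaussian diffusion within each
pool (no soma/restriction compartment, no structural disorder
corrections), orientation-independent exchange, a single σ per voxel, and
instantaneous gradient ramps.

## Numerics

* **2×2 matrix exponentials.** Every propagator is the closed-form
  exponential of a 2×2 matrix, exp(B) = e^m[cosh(d)I + sinh(d)/d (B−mI)]
  with m = tr(B)/2, d² = ((B₁₁−B₂₂)/2)² + B₁₂B₂₁ ≥ 0 here. Verified
  against `scipy.linalg.expm` to 1e-10. The d → 0 limit switches to the
  series below |d| = 1e-8.
* **Orientation quadrature.** Gauss–Legendre with 32 nodes on [0, 1];
  doubling the nodes changes clinical-protocol signals by ~1e-15 (the
  integrand is entire), so 32 is converged with margin.
* **SMEX ramp integration.** Default is a fourth-order commutator-free
  Magnus scheme (two exponentials per substep evaluated at the Gauss
  points of each substep, 10 substeps per ramp). Measured against a dense
  adaptive ODE solve at rtol 1e-12 over the clinical protocol the maximum
  error is ≈5e-8, and the error falls as h⁴. Because each step is an
  exact matrix exponential, the scheme is unconditionally stable and free
  of solver-noise artifacts in parameter maps, and it vectorizes over
  parameter sets, shells and orientation nodes — roughly 50× faster than
  the adaptive solver, which matters for voxelwise fitting.
  `method="ivp"` (adaptive Runge–Kutta on the ramps, rtol 1e-8/atol 1e-10
  by default, analytic plateau propagator) and `method="dense"` (one
  adaptive solve of [0, Δ+δ]) are retained as cross-checks; "ivp" vs
  "dense" agree to ~2e-10 at matched tight tolerances.
* **Derivatives.** The analytic paths (NEXI, SMEX/Magnus) are
  compositions of exp/sinh/cosh/sqrt, so ∂S/∂p is computed by
  complex-step differentiation (step 1e-200) — exact to machine precision
  and verified against central differences at 1e-4 relative. One batched
  evaluation yields the signal and all four derivatives together; this
  gradient also feeds the optimizer.
* **Rician mean.** E[S] = σ√(π/2)e^{−x/2}[(1+x)I₀(x/2)+xI₁(x/2)],
  x = ν²/2σ², via exponentially scaled Bessel functions; above SNR 30 the
  asymptote sqrt(ν²+σ²) + σ⁴/4ν³ is used (agreement with the exact form
  ~4e-9 at the switch; σ = 0 returns ν exactly). The analytic derivative
  dE/dν = √(π/2)(ν/2σ)e^{−z}[I₀(z)+I₁(z)], z = ν²/4σ², backs the fit
  gradient.

## Estimation

Only b > 0 shells enter the objective (after per-Δ b0 normalization the
b = 0 points are identically 1); n = 16 points for the built-in protocol.
The objective is Σ(data − E[S(p)])² with the Rice-mean transform applied
to the prediction, using one σ per voxel shared across shells. σ is the
per-magnitude-image scale: the Rician bias of an arithmetic mean of
magnitudes equals the mean of per-image biases, so the same σ applies to
the powder-averaged prediction (direction averaging reduces the spread,
not the bias).

Initialization is an exhaustive grid search (8 points per axis, t_ex
log-spaced, 4096 candidates) restricted to D_i > D_e; the restriction is
deliberately *not* enforced during the subsequent bounded L-BFGS-B
refinement (ftol = gtol = 1e-14) — it is a soft constraint that selects
the physically expected basin. Grid signals depend only on
(model, protocol, bounds, grid), so they are computed once and shared
across voxels. If the optimizer fails or worsens the objective, the best
point seen is returned with `converged=False`. Estimates within
1e-9·(hi−lo) of a bound are flagged per parameter.

AICc uses the Gaussian least-squares form n·ln(rss/n) + 2k +
2k(k+1)/(n−k−1) with k = 4 (σ is fixed externally and not counted); for
n = 16 and RMSE ≈ 0.04 this lands near −90, the scale on which ROI-level
model comparison operates.

Voxelwise fitting (`fit_volume`) powder-averages and normalizes each
masked voxel, rescales the σ map by the voxel's mean b0 intensity (unless
told the map is already in normalized units), and fits voxels
independently — results are identical for any worker count and voxel
order. Unfittable voxels (zero b0, non-finite inputs) yield NaN maps.

## Synthetic studies

The generator draws ground truth from flat ranges spanning plausible
cortical values — t_ex ∈ [1, 40] ms, D_i ∈ [2.5, 3.5], D_e ∈ [0.5, 1.5]
µm²/ms, f ∈ [0.2, 0.7] — simulates signals (finite-pulse model by
default, the physically faithful choice for wide pulses), adds
independent Rician noise per direction (20 repetitions per b > 0 shell,
one per b = 0), averages directions arithmetically, and divides by the
noisy per-Δ b0 — replicating the real pipeline including its
normalization noise (`b0_noise=False` disables the last step for
calibration checks). The default σ = 0.02 in b0-normalized units (SNR 50
per image at b = 0) is a plausible clinical figure chosen once; the
studies report per-parameter bias and RMSE after discarding fits that end
on a bound.

What these simulations emulate: the acquisition geometry, the
direction-count statistics, the Rician floor, the normalization noise.
What they do not: spatially correlated noise, partial-volume mixing with
WM/CSF, residual artifacts after preprocessing, orientation-coherent
tissue (the generator is a powder by construction), or ground-truth
correlations between parameters as found in tissue. Passing recovery
tests therefore demonstrate estimator correctness under the model's own
assumptions, not accuracy in vivo.

Two pulse-width arms are studied: δ = 16.5 ms (the acquisition value) and
δ = 4 ms (near-narrow pulses), with b and Δ held fixed. In the noiseless
limit the pulse-width mismatch has a clean signature: a t_ex-only
narrow-pulse fit of finite-pulse signals underestimates t_ex, and the
full 4-parameter fit overestimates D_i and underestimates f. At σ = 0.02,
however, estimator noise dominates: t_ex (weakly identified beyond the
sampled t_d window of ≈60 ms) scatters heavily, and because the flat D_i
range shares its upper edge with the fit bound (3.5 µm²/ms), bound
clipping plus the at-bound discard rule drags the D_i bias negative for
both models. Study-level sign claims should therefore be read jointly
with the noiseless diagnostics.

## Analysis choices

* The "mode with 95% interval" summary of ROI distributions uses a
  Gaussian KDE with Silverman bandwidth on a 512-point grid; the interval
  is the outer envelope of the smallest density-superlevel set holding
  the requested mass (a highest-density interval) — chosen over
  equal-tailed intervals to match the "integrate around the mode" intent.
* The exchange-signature slope test is plain OLS of signal on Δ with a
  two-sided p; one-sided claims are evaluated as slope < 0 with p/2.
* Repeatability pools ROI means across subjects for the intra-session
  correlation (session 1 vs 2) and across all subject pairs at session 1
  for the inter-subject correlation; ROI means use unweighted voxel
  means (median behind a `robust` flag).
* ROI parcellations are consumed as integer label images + lookup
  tables; no surface processing is performed.

## Known limitations

* t_ex above the sampled diffusion-time window (≳60 ms for this
  protocol) is intrinsically poorly determined; its RMSE grows with the
  true value and its noisy-estimate distribution is heavily skewed.
* The narrow-pulse/finite-pulse *forward* difference at δ = 16.5 ms is
  ≈2e-3 in normalized signal at cortical parameters — comparable to the
  powder-average noise at SNR 50 — so estimator-level comparisons at that
  noise level mostly reflect noise handling rather than pulse physics.
* SMEX fitting costs ~5-10× NEXI per voxel even with the vectorized
  propagators.
* The CLI covers the standard NIfTI workflow; exotic acquisition layouts
  (per-shell δ differences within one Δ) are rejected by design.
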