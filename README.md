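# gmexi

Two-compartment exchange modelling of gray-matter diffusion MRI for
clinical-scanner protocols: forward simulation, Rician-floor-corrected
fitting, synthetic noise-propagation studies and ROI-level statistics.

## The problem

In cortical gray matter the diffusion-weighted MRI signal at moderate b
and varying diffusion time carries a distinctive *exchange signature*:
at fixed b the powder-averaged signal decreases as the diffusion time
grows, because water exchanges between neurites and the extra-neurite
space on a time scale t_ex of tens of milliseconds. Modelling this
signature yields microstructural parameters — the exchange time t_ex
(a proxy for membrane permeability, empirically related to myelination),
the intra-neurite diffusivity D_i, the extra-neurite diffusivity D_e and
the intra-neurite signal fraction f.

Clinical scanners need long gradient pulses (δ ≈ 16.5 ms) to reach high b
with their limited gradient strength, which strains the narrow-pulse
assumption behind the classical Kärger treatment. This package implements
both model variants so that their agreement and biases can be studied:

* **NEXI** (narrow-pulse Kärger): along one direction with orientation
  cosine u = g·n,

      K(q, t_d; p, u) = 1ᵀ · exp[(R − q² D(u)) t_d] · (f, 1−f)ᵀ,
      D(u) = diag(D_i u², D_e),
      R = [[−k_ie, k_ei], [k_ie, −k_ei]],  k_ie = (1−f)/t_ex, k_ei = f/t_ex,

  with the pulse-width correction t_d = Δ − δ/3 and b = q² t_d. The
  powder average is S̄ = ∫₀¹ K(u) du (Gauss–Legendre quadrature).
* **SMEX** (finite pulses): the generalized two-pool rate equation
  dM/dt = (R − k(t)² D(u)) M is integrated through the actual rectangular
  PGSE wave-number profile k(t) (linear ramps of width δ around a constant
  plateau), with the exact matrix-exponential propagator on [δ, Δ] and a
  fourth-order commutator-free Magnus scheme (or an adaptive ODE solver)
  on the ramps.

Fitting incorporates the Rician noise floor directly into the model: the
prediction is passed through the exact Rice mean
E[S] = σ√(π/2)·L_{1/2}(−S²/2σ²) before the residual is formed. Estimation
is a D_i > D_e-constrained grid search followed by bounded L-BFGS-B
(tolerance 1e-14, bounds t_ex ∈ [1, 150] ms, diffusivities ∈ [0.1, 3.5]
µm²/ms, f ∈ [0.1, 0.9]), with goodness of fit summarized by AICc.

The built-in clinical protocol has b = {1, 2} ms/µm² at Δ = {28.3, 36.0} ms,
b = {1, 2, 3.2, 4.44} at Δ = 45 ms and b = {1, 2, 3.2, 5} at
Δ = {55, 65} ms, δ = 16.5 ms, 20 directions per shell and one b = 0 per Δ
— 325 volumes in total.

## Who this is for

Researchers modelling gray-matter microstructure from multi-shell,
multi-diffusion-time PGSE data on clinical systems, and anyone studying
how pulse width, noise floor and estimator choices propagate into
exchange-parameter estimates.

## Worked example

```python
import numpy as np
from gmexi import default_clinical_protocol, nexi_signal, smex_signal, TissueParams
from gmexi.fitting import fit_curve

proto = default_clinical_protocol()
p = TissueParams(t_ex=20.0, D_i=3.0, D_e=1.0, f=0.4)
S_nexi = nexi_signal(p, proto)
S_smex = smex_signal(p, proto)
sel = proto.Delta == 45.0
print("b at Delta=45:", proto.b[sel])
print("NEXI:", np.round(S_nexi[sel], 4))
print("SMEX:", np.round(S_smex[sel], 4))
res = fit_curve(S_smex, 0.0, "nexi", proto)
print("NEXI fit of SMEX curve:", res.params)
```

prints

```
b at Delta=45: [0.   1.   2.   3.2  4.44]
NEXI: [1.     0.4085 0.1998 0.1047 0.0661]
SMEX: [1.     0.408  0.1989 0.1035 0.0647]
NEXI fit of SMEX curve: TissueParams(t_ex=23.712557588424588, D_i=3.235007862659304, D_e=0.9649623685012487, f=0.3734273197094706)
```

The two forward models agree to ~1e-3 at this pulse width; fitting the
finite-pulse signal with the narrow-pulse model absorbs the mismatch into
the parameters (here D_i drifts up and f down from their true values) —
quantifying exactly this is the purpose of the synthetic study below.

## Command line

```bash
gmexi simulate --n 500 --model smex --delta 16.5 --sigma 0.02 --seed 1 --out sim/
gmexi fit --model nexi --dwi dwi.nii.gz --table acq.tsv \
          --mask mask.nii.gz --sigma sigma.nii.gz --out maps/
gmexi recover --n 500 --scenarios 16.5,4 --seed 1 --out study/
gmexi summarize --maps maps/ --labels dkt.nii.gz --lut dkt.tsv --out tables/
gmexi repeatability --tables ses1.tsv ses2.tsv --out report.json
```

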