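"""Rician magnitude-noise model: expectation (noise floor) and sampling.

A magnitude MR image with underlying noise-free signal ν and complex
Gaussian noise of scale σ per channel follows a Rice distribution with mean

    E[S] = σ·sqrt(π/2)·L_{1/2}(−ν²/(2σ²))
         = σ·sqrt(π/2)·e^{−x/2}·[(1+x)·I₀(x/2) + x·I₁(x/2)],  x = ν²/(2σ²),

evaluated here with exponentially scaled Bessel functions for stability.
At ν = 0 this reduces to the noise floor σ·sqrt(π/2); at high SNR it
approaches sqrt(ν² + σ²).  The floor transform is applied to model
predictions before residual computation so that the noise bias is part of
the fitted model rather than a data correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ive

__all__ = ["NoiseModel", "rician_mean", "rician_mean_derivative", "apply_floor", "sample_rician"]

#: above this SNR the high-order asymptotic sqrt(ν²+σ²) is exact to ~1e-9
_ASYMPTOTIC_SNR = 30.0

_SQRT_PI_2 = np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class NoiseModel:
    """Rician scale in b0-normalized signal units.

    ``sigma`` is the per-magnitude-image scale; the Rician bias of an
    average of magnitude images equals the average of per-image biases, so
    the same σ applies to powder-averaged predictions.
    ``n_dirs_averaged`` is the number of magnitude images averaged per
    shell, which controls the Gaussian spread (not the bias) of the
    powder-average in simulations.
    """

    sigma: float
    n_dirs_averaged: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_dirs_averaged < 1:
            raise ValueError("n_dirs_averaged must be >= 1")


def rician_mean(nu, sigma):
    """Expected magnitude E[|ν + ε₁ + i·ε₂|] for Gaussian ε of s.d. σ.

    Monotone increasing in ν, bounded below by max(ν, σ·sqrt(π/2)).
    Vectorized over ν; σ is a scalar or broadcastable array.
    """
    nu_in = np.asarray(nu, dtype=float)
    sig_in = np.asarray(sigma, dtype=float)
    if np.any(sig_in < 0):
        raise ValueError("sigma must be >= 0")
    if np.any(nu_in < 0):
        raise ValueError("nu must be >= 0")
    out_shape = np.broadcast_shapes(nu_in.shape, sig_in.shape)
    nu_b, sig_b = (np.ascontiguousarray(a) for a in
                   np.broadcast_arrays(np.atleast_1d(nu_in), np.atleast_1d(sig_in)))
    out = np.empty_like(nu_b, dtype=float)

    zero_sig = sig_b == 0
    out[zero_sig] = nu_b[zero_sig]

    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(zero_sig, np.inf, nu_b / np.where(zero_sig, 1.0, sig_b))
    asym = (~zero_sig) & (snr > _ASYMPTOTIC_SNR)
    # sqrt(nu²+σ²) matches E to O((σ/ν)⁴); the σ⁴/(4ν³) term extends this
    # to O((σ/ν)⁶), making the branch switch seamless at SNR 30
    out[asym] = (
        np.sqrt(nu_b[asym] ** 2 + sig_b[asym] ** 2)
        + sig_b[asym] ** 4 / (4.0 * nu_b[asym] ** 3)
    )

    core = (~zero_sig) & (~asym)
    if np.any(core):
        x = nu_b[core] ** 2 / (2.0 * sig_b[core] ** 2)
        z = x / 2.0
        # e^{-z} I_n(z) via scaled Bessel functions: stable for all z >= 0
        i0 = ive(0, z)
        i1 = ive(1, z)
        out[core] = sig_b[core] * _SQRT_PI_2 * ((1.0 + x) * i0 + x * i1)
    out = out.reshape(out_shape) if out_shape else out
    return float(out[0]) if out_shape == () else out.reshape(out_shape)


def rician_mean_derivative(nu, sigma):
    """d rician_mean / dν, used for analytic objective gradients.

    Closed form: sqrt(π/2)·(ν/(2σ))·e^{−z}·[I₀(z) + I₁(z)] with
    z = ν²/(4σ²).  Tends to 1 as σ → 0 and to ν/sqrt(ν²+σ²) at high SNR.
    """
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    nu_b, sig_b = np.broadcast_arrays(nu, np.atleast_1d(sigma))
    out = np.empty_like(nu_b, dtype=float)
    zero_sig = sig_b == 0
    out[zero_sig] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(zero_sig, np.inf, nu_b / np.where(zero_sig, 1.0, sig_b))
    asym = (~zero_sig) & (snr > _ASYMPTOTIC_SNR)
    out[asym] = nu_b[asym] / np.sqrt(
        nu_b[asym] ** 2 + sig_b[asym] ** 2
    ) - 3.0 * sig_b[asym] ** 4 / (4.0 * nu_b[asym] ** 4)
    core = (~zero_sig) & (~asym)
    if np.any(core):
        z = nu_b[core] ** 2 / (4.0 * sig_b[core] ** 2)
        out[core] = _SQRT_PI_2 * (nu_b[core] / (2.0 * sig_b[core])) * (ive(0, z) + ive(1, z))
    return out


def apply_floor(curve, noise: NoiseModel | float):
    """Rician-floor transform of a (normalized) model prediction.

    Elementwise ``rician_mean(value, σ)``; every output is ≥ the input and
    ≥ the floor σ·sqrt(π/2).  With σ = 0 the curve is returned unchanged.
    """
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    curve = np.asarray(curve, dtype=float)
    if sigma == 0:
        return curve.copy()
    return rician_mean(curve, sigma)


def sample_rician(nu, sigma, n=1, seed=None, rng=None):
    """Draw Rician magnitudes |ν + ε₁ + i·ε₂|.

    Parameters
    ----------
    nu : scalar or array
        Noise-free magnitude(s).
    sigma : float
        Gaussian scale per quadrature channel.
    n : int
        Number of draws per element of ``nu`` (leading axis of the output).
    seed : int, optional
        Seed for a fresh generator; ignored when ``rng`` is given.
    rng : numpy.random.Generator, optional
        Existing generator (for reproducible composite pipelines).
    """
    if rng is None:
        if seed is None:
            raise ValueError("either seed or rng must be provided (reproducibility contract)")
        rng = np.random.default_rng(seed)
    nu = np.asarray(nu, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    shape = (n,) + nu.shape
    if sigma == 0:
        return np.broadcast_to(nu, shape).copy()
    e1 = rng.normal(0.0, sigma, size=shape)
    e2 = rng.normal(0.0, sigma, size=shape)
    return np.hypot(nu + e1, e2)
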