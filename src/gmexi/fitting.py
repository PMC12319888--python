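"""Voxelwise estimation of exchange-model parameters.

The estimator mirrors standard practice for gray-matter exchange imaging:

1. an exhaustive grid search over the parameter box (log-spaced exchange
   times, linear diffusivity and fraction axes) restricted to
   ``D_i > D_e`` picks the starting point;
2. bounded nonlinear least squares (L-BFGS-B, tolerance 1e-14) refines it.
   ``D_i > D_e`` is *not* enforced during the refinement — it is only a
   soft constraint that guides initialization;
3. the model prediction is passed through the Rician-mean transform before
   the residual is computed, so the noise floor is part of the model
   rather than a data correction;
4. goodness of fit is summarized by the corrected Akaike information
   criterion in its Gaussian least-squares form with k = 4 parameters.

Only b > 0 shells enter the objective: after per-diffusion-time b0
normalization the b = 0 points are identically 1 and carry no information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import minimize

from .forward import TissueParams, model_signal, signal_and_jacobian
from .noise import NoiseModel, rician_mean, rician_mean_derivative
from .protocol import AcquisitionProtocol

__all__ = ["FitBounds", "FitResult", "grid_search", "fit_curve", "aicc", "fit_volume"]

_BOUND_TOL = 1e-9
_DEFAULT_GRID = (8, 8, 8, 8)


class ConfigurationError(ValueError):
    """Raised when bounds / grid settings admit no feasible candidate."""


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the optimization, (lo, hi) per parameter."""

    t_ex: tuple[float, float] = (1.0, 150.0)
    D_i: tuple[float, float] = (0.1, 3.5)
    D_e: tuple[float, float] = (0.1, 3.5)
    f: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        for name in ("t_ex", "D_i", "D_e", "f"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi, got ({lo}, {hi})")

    def as_list(self) -> list[tuple[float, float]]:
        return [self.t_ex, self.D_i, self.D_e, self.f]

    def as_tuple(self) -> tuple:
        return (self.t_ex, self.D_i, self.D_e, self.f)


@dataclass
class FitResult:
    """Outcome of one curve fit."""

    params: TissueParams
    rss: float
    n_points: int
    aicc: float
    at_bound: np.ndarray
    converged: bool
    init: TissueParams

    @property
    def any_at_bound(self) -> bool:
        return bool(np.any(self.at_bound))


def aicc(rss: float, n_points: int, k: int = 4) -> float:
    """Corrected Akaike information criterion, Gaussian least-squares form.

    ``n·ln(rss/n) + 2k + 2k(k+1)/(n − k − 1)``.  The noise scale is fixed
    externally and not counted in k.
    """
    if n_points <= k + 1:
        raise ValueError(f"AICc needs n_points > k+1, got n={n_points}, k={k}")
    if not rss > 0:
        raise ValueError(f"AICc needs rss > 0, got {rss}")
    n = n_points
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _grid_axes(bounds: FitBounds, grid_sizes) -> list[np.ndarray]:
    n_tex, n_di, n_de, n_f = grid_sizes
    return [
        np.geomspace(bounds.t_ex[0], bounds.t_ex[1], n_tex),
        np.linspace(bounds.D_i[0], bounds.D_i[1], n_di),
        np.linspace(bounds.D_e[0], bounds.D_e[1], n_de),
        np.linspace(bounds.f[0], bounds.f[1], n_f),
    ]


_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
_SUBPROTO_CACHE: dict[tuple, AcquisitionProtocol] = {}


def _dwi_subprotocol(protocol: AcquisitionProtocol) -> AcquisitionProtocol:
    """b > 0 shells only: the objective never evaluates the constant b0 points."""
    key = protocol.fingerprint()
    sp = _SUBPROTO_CACHE.get(key)
    if sp is None:
        shells = tuple(s for s in protocol.shells if s.b > 0)
        sp = AcquisitionProtocol(shells, name=f"{protocol.name}-dwi")
        _SUBPROTO_CACHE[key] = sp
    return sp


def _grid_signals(
    model: str, protocol: AcquisitionProtocol, bounds: FitBounds, grid_sizes, **forward_kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate parameter sets (n_cand, 4) and their b>0 signals (n_cand, n_b).

    Cached per (model, protocol, bounds, grid, forward settings): the grid
    is data-independent, so thousands of voxels share one evaluation.
    """
    key = (
        model,
        protocol.fingerprint(),
        bounds.as_tuple(),
        tuple(grid_sizes),
        tuple(sorted(forward_kwargs.items())),
    )
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    axes = _grid_axes(bounds, grid_sizes)
    P = np.array(np.meshgrid(*axes, indexing="ij")).reshape(4, -1).T
    P = P[P[:, 1] > P[:, 2]]  # soft constraint D_i > D_e at initialization
    if P.shape[0] == 0:
        raise ConfigurationError("no grid candidate satisfies D_i > D_e under these bounds")
    S = model_signal(model, P, protocol, **forward_kwargs)[:, protocol.dwi_mask]
    _GRID_CACHE[key] = (P, S)
    return P, S


def grid_search(
    curve,
    noise: NoiseModel | float,
    model: str,
    protocol: AcquisitionProtocol,
    bounds: FitBounds | None = None,
    grid_sizes=_DEFAULT_GRID,
    **forward_kwargs,
) -> TissueParams:
    """Best grid candidate by floor-corrected residual sum of squares.

    The t_ex axis is log-spaced, the others linear; only candidates with
    ``D_i > D_e`` are considered.
    """
    bounds = bounds or FitBounds()
    curve = np.asarray(curve, dtype=float)
    dwi = protocol.dwi_mask
    if dwi.sum() < 5:
        raise ValueError("need at least 5 b > 0 data points")
    data = curve[dwi] if curve.shape[-1] == len(protocol) else curve
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    P, S = _grid_signals(model, protocol, bounds, grid_sizes, **forward_kwargs)
    pred = rician_mean(S, sigma) if sigma > 0 else S
    rss = np.sum((data[None, :] - pred) ** 2, axis=1)
    return TissueParams.from_array(P[int(np.argmin(rss))])


def fit_curve(
    curve,
    noise: NoiseModel | float,
    model: str,
    protocol: AcquisitionProtocol,
    bounds: FitBounds | None = None,
    grid_sizes=_DEFAULT_GRID,
    x0: TissueParams | None = None,
    **forward_kwargs,
) -> FitResult:
    """Rician-floor-corrected bounded NLS fit of one powder-averaged curve.

    Parameters
    ----------
    curve : array
        Signal values, either per protocol shell (b = 0 entries ignored) or
        already restricted to b > 0 shells.
    noise : NoiseModel or float
        Rician σ in normalized units; 0 disables the floor transform.
    model : {"nexi", "smex"}
    x0 : TissueParams, optional
        Starting point; defaults to the grid-search winner.
    """
    bounds = bounds or FitBounds()
    curve = np.asarray(curve, dtype=float)
    dwi = protocol.dwi_mask
    data = curve[dwi] if curve.shape[-1] == len(protocol) else curve
    n_points = int(dwi.sum())
    if n_points < 5:
        raise ValueError("need at least 5 b > 0 data points")
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)

    init = x0 or grid_search(
        data, sigma, model, protocol, bounds, grid_sizes, **forward_kwargs
    )
    lo = np.array([b[0] for b in bounds.as_list()])
    hi = np.array([b[1] for b in bounds.as_list()])

    subproto = _dwi_subprotocol(protocol)

    def objective(p):
        S, J = signal_and_jacobian(model, p, subproto, **forward_kwargs)
        if sigma > 0:
            pred = rician_mean(S, sigma)
            dpred = rician_mean_derivative(S, sigma)[:, None] * J
        else:
            pred, dpred = S, J
        r = data - pred
        return float(np.dot(r, r)), -2.0 * (r[None, :] @ dpred)[0]

    rss0 = objective(init.as_array())[0]
    res = minimize(
        objective,
        init.as_array(),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds.as_list(),
        options={"ftol": 1e-14, "gtol": 1e-14, "maxiter": 1000},
    )
    x = np.clip(res.x, lo, hi)
    rss = float(res.fun)
    converged = bool(res.success)
    if not np.isfinite(rss) or rss > rss0:
        # optimizer failure: fall back to the best point actually seen
        x, rss, converged = init.as_array(), rss0, False
    at_bound = (np.abs(x - lo) < _BOUND_TOL * (hi - lo)) | (
        np.abs(x - hi) < _BOUND_TOL * (hi - lo)
    )
    crit = aicc(rss, n_points) if rss > 0 else -np.inf
    return FitResult(
        params=TissueParams.from_array(x),
        rss=rss,
        n_points=n_points,
        aicc=crit,
        at_bound=at_bound,
        converged=converged,
        init=init,
    )


def _as_array(img, ndim: int, what: str):
    """Accept a nibabel spatial image or a bare ndarray."""
    if hasattr(img, "get_fdata"):
        data, affine = np.asarray(img.get_fdata()), img.affine
    else:
        data, affine = np.asarray(img, dtype=float), None
    if data.ndim != ndim:
        raise ValueError(f"{what} must be {ndim}-D, got {data.ndim}-D")
    return data, affine


def fit_volume(
    dwi,
    protocol: AcquisitionProtocol,
    mask,
    sigma_map,
    model: str = "nexi",
    bounds: FitBounds | None = None,
    n_workers: int = 1,
    sigma_is_normalized: bool = False,
    grid_sizes=_DEFAULT_GRID,
    **forward_kwargs,
) -> dict[str, np.ndarray]:
    """Fit every masked voxel of a 4D DWI volume; return 3D parameter maps.

    The 4D data are powder-averaged per shell and normalized by the mean
    b = 0 of each diffusion time before fitting.  Unless
    ``sigma_is_normalized``, the σ map is divided by the voxel's mean b = 0
    intensity to express it in the same normalized units as the curves.

    Returns a dict of maps ``{"tex", "di", "de", "f", "rss", "aicc",
    "nb_bounds", "converged"}``; voxels outside the mask (or unfittable,
    e.g. all-zero) are NaN.  Voxel order and worker count never affect the
    result.
    """
    from .analysis import powder_average

    dwi_data, dwi_aff = _as_array(dwi, 4, "dwi")
    mask_data, mask_aff = _as_array(mask, 3, "mask")
    sig_data, sig_aff = _as_array(sigma_map, 3, "sigma_map")
    if dwi_data.shape[:3] != mask_data.shape or dwi_data.shape[:3] != sig_data.shape:
        raise ValueError("dwi, mask and sigma_map grids disagree in shape")
    for aff in (mask_aff, sig_aff):
        if dwi_aff is not None and aff is not None and not np.allclose(dwi_aff, aff, atol=1e-5):
            raise ValueError("dwi, mask and sigma_map affines disagree")

    table = protocol.volume_table()
    curves, coords, b0_mean = powder_average(dwi_data, table, mask_data > 0)
    sigmas = sig_data[coords[:, 0], coords[:, 1], coords[:, 2]]
    if not sigma_is_normalized:
        with np.errstate(divide="ignore", invalid="ignore"):
            sigmas = np.where(b0_mean > 0, sigmas / np.where(b0_mean > 0, b0_mean, 1.0), np.nan)

    bounds = bounds or FitBounds()
    # build the shared grid once, before any worker forks
    _grid_signals(model, protocol, bounds, grid_sizes, **forward_kwargs)

    def one(i):
        c, s = curves[i], sigmas[i]
        if not np.all(np.isfinite(c)) or not np.isfinite(s):
            return None
        return fit_curve(c, float(s), model, protocol, bounds, grid_sizes, **forward_kwargs)

    idx = range(curves.shape[0])
    if n_workers == 1:
        results = [one(i) for i in idx]
    else:
        results = Parallel(n_jobs=n_workers)(delayed(one)(i) for i in idx)

    shape = dwi_data.shape[:3]
    maps = {
        k: np.full(shape, np.nan)
        for k in ("tex", "di", "de", "f", "rss", "aicc", "nb_bounds", "converged")
    }
    for (x, y, z), r in zip(coords, results):
        if r is None:
            continue
        maps["tex"][x, y, z] = r.params.t_ex
        maps["di"][x, y, z] = r.params.D_i
        maps["de"][x, y, z] = r.params.D_e
        maps["f"][x, y, z] = r.params.f
        maps["rss"][x, y, z] = r.rss
        maps["aicc"][x, y, z] = r.aicc
        maps["nb_bounds"][x, y, z] = int(r.at_bound.sum())
        maps["converged"][x, y, z] = float(r.converged)
    return maps
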