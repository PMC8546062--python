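"""Lineshape model, spectrum synthesis, and bounded quasi-Newton fitting.

An estimated spectrum is a kernel-density-style sum of unit-height
Gaussian-Lorentzian peaks, one per chemical shift:

    f(x) = sum_i k((x - mu_i) / sigma_i ; lambda_i)
    k(z; lam) = (1 - lam) * exp(-(4 ln 2) z^2) + lam / (1 + 4 z^2)

Both kernel components equal 1 at z = 0 and 1/2 at z = +-1/2, so sigma_i
is exactly the full width at half maximum of peak i in ppm and lam_i in
[0, 1] mixes Gaussian (0) and Lorentzian (1) character.

Fitting maximizes the objective

    J(mu, sigma, lam) = cossim(y, yhat)
                        - || y/||y||_1 - yhat/||yhat||_1 ||^2
                        - sum_i (mu_i - anchor_i)^2
                        - sum_i sigma_i^2
                        - sum_i max(mu_i - mu_{i+1} + eps, 0)^2

over (mu, sigma, lam) with L-BFGS-B under box constraints
sigma_i >= sigma_floor and lam_i in [0, 1].  The first two terms reward
spectral agreement (cosine similarity and squared Euclidean distance
between the L1-normalized spectra); the third keeps peak centers near
their aligned anchors; the fourth prefers narrow peaks; the last is a
squared hinge that charges for centers that are not ascending by at
least the margin eps, encouraging nearby peaks to split.  All five terms
enter with unit weight; the anchor and width terms are in ppm^2 against
the unitless similarity terms, which in practice pins mu tightly to the
anchors and drives sigma well below its initial value h.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from nmrsearch.spectra import Spectrum

__all__ = [
    "FOUR_LN2",
    "EstimationError",
    "LineshapeParams",
    "EstimatedSpectrum",
    "OptimizeConfig",
    "OptimizeResult",
    "kernel",
    "synthesize_spectrum",
    "cosine_similarity",
    "objective",
    "objective_gradient",
    "optimize",
]

FOUR_LN2 = 4.0 * np.log(2.0)


class EstimationError(ValueError):
    """Invalid lineshape parameters or degenerate spectra."""


@dataclasses.dataclass(frozen=True)
class LineshapeParams:
    """Per-peak lineshape parameters (mu, sigma, lam), all length m.

    mu : peak centers, ppm.  sigma : FWHM per peak, ppm, > 0.
    lam : Gaussian-Lorentzian mixing in [0, 1].
    """

    mu: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        for name, v in (("mu", mu), ("sigma", sigma), ("lam", lam)):
            object.__setattr__(self, name, v)
        if not (mu.size == sigma.size == lam.size):
            raise EstimationError("mu, sigma, lam must share one length")
        if mu.size == 0:
            raise EstimationError("at least one peak required")
        if np.any(sigma <= 0):
            raise EstimationError("sigma must be positive")
        if np.any(lam < 0) or np.any(lam > 1):
            raise EstimationError("lam must lie in [0, 1]")

    @property
    def m(self) -> int:
        return int(self.mu.size)


@dataclasses.dataclass(frozen=True)
class EstimatedSpectrum:
    """Synthesized intensities on the query grid plus their parameters."""

    intensities: np.ndarray
    params: LineshapeParams


@dataclasses.dataclass(frozen=True)
class OptimizeConfig:
    """Settings for the lineshape fit.

    h : initial sigma (FWHM) in ppm.  epsilon : ordering margin in ppm.
    sigma_floor : lower box bound on sigma.  gradient : "analytic" uses
    closed-form derivatives of J; "fd" lets the optimizer take 2-point
    finite differences.  w_* : optional term weights, all 1 by default.
    """

    h: float = 1.0
    epsilon: float = 0.01
    max_iter: int = 500
    grad_tol: float = 1e-8
    sigma_floor: float = 1e-3
    gradient: str = "analytic"
    w_shape: float = 1.0
    w_anchor: float = 1.0
    w_width: float = 1.0
    w_order: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.epsilon <= 0 or self.sigma_floor <= 0:
            raise ValueError("h, epsilon and sigma_floor must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.gradient not in ("analytic", "fd"):
            raise ValueError("gradient must be 'analytic' or 'fd'")


@dataclasses.dataclass(frozen=True)
class OptimizeResult:
    """Outcome of the bounded fit."""

    delta_star: np.ndarray
    params: LineshapeParams
    estimate: EstimatedSpectrum
    j_init: float
    j_final: float
    converged: bool
    n_iter: int
    message: str = ""


def kernel(z, lam):
    """Gaussian-Lorentzian sum kernel k(z; lam), unit height, unit FWHM."""
    z = np.asarray(z, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0) or np.any(lam_arr > 1):
        raise EstimationError("lam must lie in [0, 1]")
    z2 = z * z
    return (1.0 - lam_arr) * np.exp(-FOUR_LN2 * z2) + lam_arr / (1.0 + 4.0 * z2)


def synthesize_spectrum(grid: np.ndarray, params: LineshapeParams) -> EstimatedSpectrum:
    """Evaluate the peak sum f on a frequency grid.

    Coincident peaks stack additively; the sum is deliberately left
    unnormalized, matching the unit-height kernel model.
    """
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - params.mu[None, :]) / params.sigma[None, :]
    y = kernel(z, params.lam[None, :]).sum(axis=1)
    return EstimatedSpectrum(intensities=y, params=params)


def cosine_similarity(y: np.ndarray, yhat: np.ndarray) -> float:
    """cossim(y, yhat) = y.yhat / (||y|| ||yhat||), in [0, 1] for nonnegative input."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise EstimationError("vectors must share a length")
    ny = np.linalg.norm(y)
    nyh = np.linalg.norm(yhat)
    if ny == 0 or nyh == 0:
        raise EstimationError("cosine similarity undefined for an all-zero vector")
    return float(y @ yhat / (ny * nyh))


def _j_and_grad(
    mu: np.ndarray,
    sigma: np.ndarray,
    lam: np.ndarray,
    grid: np.ndarray,
    y: np.ndarray,
    anchors: np.ndarray,
    cfg: OptimizeConfig,
    want_grad: bool,
) -> tuple[float, np.ndarray | None]:
    z = (grid[:, None] - mu[None, :]) / sigma[None, :]
    z2 = z * z
    gauss = np.exp(-FOUR_LN2 * z2)
    lor = 1.0 / (1.0 + 4.0 * z2)
    k = (1.0 - lam) * gauss + lam * lor
    yhat = k.sum(axis=1)

    ny = np.linalg.norm(y)
    nyh = np.linalg.norm(yhat)
    if ny == 0:
        raise EstimationError("query intensities are all zero")
    if nyh == 0 or not np.isfinite(nyh):
        raise EstimationError("estimated spectrum is degenerate (all zero)")
    cos = float(y @ yhat / (ny * nyh))

    s_y = float(np.sum(y))
    s_h = float(np.sum(yhat))
    p = y / s_y
    q = yhat / s_h
    d = q - p
    shape = float(d @ d)

    anchor_res = mu - anchors
    anchor = float(anchor_res @ anchor_res)
    width = float(sigma @ sigma)
    hinge = np.maximum(mu[:-1] - mu[1:] + cfg.epsilon, 0.0)
    order = float(hinge @ hinge)

    j = (
        cos
        - cfg.w_shape * shape
        - cfg.w_anchor * anchor
        - cfg.w_width * width
        - cfg.w_order * order
    )
    if not want_grad:
        return j, None

    # dJ/dyhat from the two spectral terms
    g_cos = (y / ny - cos * yhat / nyh) / nyh
    g_shape = (2.0 / s_h) * (d - float(d @ q))
    g_yhat = g_cos - cfg.w_shape * g_shape

    dk_dz = (1.0 - lam) * (-2.0 * FOUR_LN2) * z * gauss + lam * (-8.0) * z * lor * lor
    g_mu = -(g_yhat @ dk_dz) / sigma - cfg.w_anchor * 2.0 * anchor_res
    g_sigma = -(g_yhat @ (dk_dz * z)) / sigma - cfg.w_width * 2.0 * sigma
    g_lam = g_yhat @ (lor - gauss)
    if mu.size > 1:
        g_mu[:-1] -= cfg.w_order * 2.0 * hinge
        g_mu[1:] += cfg.w_order * 2.0 * hinge
    return j, np.concatenate([g_mu, g_sigma, g_lam])


def objective(
    params: LineshapeParams,
    query: Spectrum,
    anchors: np.ndarray,
    cfg: OptimizeConfig | None = None,
) -> float:
    """The fitting objective J, evaluated exactly as defined above."""
    cfg = cfg if cfg is not None else OptimizeConfig()
    anchors = np.atleast_1d(np.asarray(anchors, dtype=float))
    if anchors.size != params.m:
        raise EstimationError("anchors must match the number of peaks")
    j, _ = _j_and_grad(
        params.mu, params.sigma, params.lam,
        query.frequencies, query.intensities, anchors, cfg, want_grad=False,
    )
    return j


def objective_gradient(
    params: LineshapeParams,
    query: Spectrum,
    anchors: np.ndarray,
    cfg: OptimizeConfig | None = None,
) -> np.ndarray:
    """Analytic gradient of J with respect to (mu, sigma, lam), concatenated."""
    cfg = cfg if cfg is not None else OptimizeConfig()
    anchors = np.atleast_1d(np.asarray(anchors, dtype=float))
    if anchors.size != params.m:
        raise EstimationError("anchors must match the number of peaks")
    _, g = _j_and_grad(
        params.mu, params.sigma, params.lam,
        query.frequencies, query.intensities, anchors, cfg, want_grad=True,
    )
    assert g is not None
    return g


def optimize(
    anchors: np.ndarray,
    query: Spectrum,
    cfg: OptimizeConfig | None = None,
) -> OptimizeResult:
    """Fit peak centers, widths, and mixing to the query spectrum.

    Initialization follows the method's prescription: mu at the aligned
    shifts (`anchors`), sigma at h, lam at 0.5.  L-BFGS-B maximizes J
    under sigma_i >= sigma_floor and lam_i in [0, 1]; mu is unbounded.

    Returns the best iterate even when the iteration cap is hit
    (``converged`` is then False); the final J never falls below the
    initial one.  ``delta_star`` is the optimized mu in positional order,
    not re-sorted.
    """
    cfg = cfg if cfg is not None else OptimizeConfig()
    anchors = np.atleast_1d(np.asarray(anchors, dtype=float))
    m = anchors.size
    if m == 0:
        raise EstimationError("anchors must be nonempty")
    grid = query.frequencies
    y = query.intensities

    x0 = np.concatenate([anchors, np.full(m, cfg.h), np.full(m, 0.5)])
    bounds = (
        [(None, None)] * m
        + [(cfg.sigma_floor, None)] * m
        + [(0.0, 1.0)] * m
    )
    analytic = cfg.gradient == "analytic"

    def fun(x):
        mu, sigma, lam = x[:m], x[m : 2 * m], x[2 * m :]
        try:
            j, g = _j_and_grad(mu, sigma, lam, grid, y, anchors, cfg, want_grad=analytic)
        except EstimationError:
            # ultra-narrow pure-Gaussian iterates can underflow yhat to zero
            # off the grid; report a terrible value so the line search backtracks
            j, g = -1e12, np.zeros(3 * m)
        if analytic:
            return -j, -g
        return -j

    j_init, _ = _j_and_grad(
        x0[:m], x0[m : 2 * m], x0[2 * m :], grid, y, anchors, cfg, want_grad=False
    )
    res = minimize(
        fun,
        x0,
        jac=analytic,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.max_iter, "ftol": 1e-12, "gtol": cfg.grad_tol},
    )
    x_best, j_final = res.x, float(-res.fun)
    if j_final < j_init:  # never return an iterate worse than the initialization
        x_best, j_final = x0, float(j_init)
    params = LineshapeParams(
        mu=x_best[:m], sigma=x_best[m : 2 * m], lam=x_best[2 * m :]
    )
    estimate = synthesize_spectrum(grid, params)
    return OptimizeResult(
        delta_star=params.mu,
        params=params,
        estimate=estimate,
        j_init=float(j_init),
        j_final=j_final,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
    )
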