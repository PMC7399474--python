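"""Per-pixel recovery of (mu_a, mu_s') from calibrated Rd(fx).

A Nelder-Mead simplex search minimises the squared misfit between the
measured Rd values and interpolated lookups in the tabulated forward
model.  Pixels are fitted independently; identical Rd vectors are fitted
once and shared, which makes homogeneous or quantised images cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .forward_model import OpticalProperties, ReflectanceTable

__all__ = ["InversionConfig", "PropertyMap", "objective", "fit_pixel", "fit_image"]

_PENALTY = 1e6


@dataclass(frozen=True)
class InversionConfig:
    initial_guess: tuple = (0.1, 1.5)       # (mu_a, mu_s'), centre of the
                                            # physiological range
    bounds_mu_a: tuple = (0.005, 0.5)       # 1/mm
    bounds_mu_s_prime: tuple = (0.3, 5.0)   # 1/mm
    fatol: float = 1e-10                    # objective tolerance
    xatol: float = 1e-6                     # parameter tolerance, 1/mm
    max_iter: int = 500
    g: float = 0.8
    n: float = 1.4

    def __post_init__(self) -> None:
        mua0, musp0 = self.initial_guess
        if not (self.bounds_mu_a[0] <= mua0 <= self.bounds_mu_a[1]):
            raise ValueError("initial mu_a outside bounds")
        if not (self.bounds_mu_s_prime[0] <= musp0 <= self.bounds_mu_s_prime[1]):
            raise ValueError("initial mu_s_prime outside bounds")


@dataclass
class PropertyMap:
    """Per-pixel optical property estimates for one spectral band."""

    mu_a_map: np.ndarray
    mu_s_prime_map: np.ndarray
    residuals: np.ndarray
    converged: np.ndarray  # bool per pixel
    band: str = ""

    @property
    def fov_mean(self) -> tuple[float, float]:
        """Field-of-view mean (mu_a, mu_s') over converged pixels."""
        ok = self.converged
        if not np.any(ok):
            return (float("nan"), float("nan"))
        return (
            float(self.mu_a_map[ok].mean()),
            float(self.mu_s_prime_map[ok].mean()),
        )


class _TableEvaluator:
    """Fast bilinear (log mu_a, log mu_s') evaluation at fixed fx planes.

    Scalar-Python hot path: the simplex search calls this tens of
    thousands of times per image, where numpy's small-array overhead
    dominates.
    """

    def __init__(self, table: ReflectanceTable, fx_list: Sequence[float]):
        self.ks = [table.fx_index(f) for f in fx_list]
        self.nfx = len(self.ks)
        self.log_a = [float(v) for v in np.log(table.mu_a_grid)]
        self.log_s = [float(v) for v in np.log(table.mu_s_prime_grid)]
        planes = table.rd[:, :, self.ks]  # (Na, Ns, nfx)
        self.planes = [
            [tuple(float(v) for v in planes[i, j]) for j in range(planes.shape[1])]
            for i in range(planes.shape[0])
        ]
        self.a_lo = float(table.mu_a_grid[0])
        self.a_hi = float(table.mu_a_grid[-1])
        self.s_lo = float(table.mu_s_prime_grid[0])
        self.s_hi = float(table.mu_s_prime_grid[-1])

    def __call__(self, mu_a: float, mu_s_prime: float):
        if not (self.a_lo <= mu_a <= self.a_hi):
            return None
        if not (self.s_lo <= mu_s_prime <= self.s_hi):
            return None
        from bisect import bisect_right
        from math import log

        la = log(mu_a)
        ls = log(mu_s_prime)
        ia = min(max(bisect_right(self.log_a, la) - 1, 0), len(self.log_a) - 2)
        js = min(max(bisect_right(self.log_s, ls) - 1, 0), len(self.log_s) - 2)
        ta = (la - self.log_a[ia]) / (self.log_a[ia + 1] - self.log_a[ia])
        ts = (ls - self.log_s[js]) / (self.log_s[js + 1] - self.log_s[js])
        p00 = self.planes[ia][js]
        p01 = self.planes[ia][js + 1]
        p10 = self.planes[ia + 1][js]
        p11 = self.planes[ia + 1][js + 1]
        return [
            (p00[k] * (1 - ts) + p01[k] * ts) * (1 - ta)
            + (p10[k] * (1 - ts) + p11[k] * ts) * ta
            for k in range(self.nfx)
        ]


_EV_CACHE: dict = {}


def _cached_evaluator(table: ReflectanceTable, fx_list) -> _TableEvaluator:
    key = (id(table), tuple(fx_list))
    ev = _EV_CACHE.get(key)
    if ev is None:
        ev = _TableEvaluator(table, fx_list)
        if len(_EV_CACHE) > 64:
            _EV_CACHE.clear()
        _EV_CACHE[key] = ev
    return ev


def objective(
    params,
    rd_measured: Sequence[float],
    fx_list: Sequence[float],
    table: ReflectanceTable,
) -> float:
    """Sum of squared Rd residuals over the selected spatial frequencies.

    ``params`` is an (mu_a, mu_s') pair or OpticalProperties.  Out-of-table
    parameters incur a large finite penalty growing with the violation, so
    the simplex is steered back inside rather than crashing.
    """
    if isinstance(params, OpticalProperties):
        mu_a, musp = params.mu_a, params.mu_s_prime
    else:
        mu_a, musp = float(params[0]), float(params[1])
    rd_measured = np.asarray(rd_measured, dtype=np.float64)
    ev = _cached_evaluator(table, fx_list)
    model = ev(mu_a, musp)
    if model is None:
        dist = _bounds_violation(mu_a, musp, ev)
        return _PENALTY * (1.0 + dist)
    return float(np.sum((rd_measured - np.asarray(model)) ** 2))


def _bounds_violation(mu_a, musp, ev) -> float:
    d = 0.0
    d += max(ev.a_lo - mu_a, 0.0, mu_a - ev.a_hi) ** 2
    d += max(ev.s_lo - musp, 0.0, musp - ev.s_hi) ** 2
    return d


def _fit_one(
    rd: np.ndarray,
    ev: _TableEvaluator,
    config: InversionConfig,
    x0: np.ndarray,
) -> tuple[float, float, float, bool]:
    a_lo = max(config.bounds_mu_a[0], ev.a_lo)
    a_hi = min(config.bounds_mu_a[1], ev.a_hi)
    s_lo = max(config.bounds_mu_s_prime[0], ev.s_lo)
    s_hi = min(config.bounds_mu_s_prime[1], ev.s_hi)

    rd_t = tuple(float(v) for v in rd)

    def fun(p):
        mu_a = float(p[0])
        musp = float(p[1])
        if not (a_lo <= mu_a <= a_hi and s_lo <= musp <= s_hi):
            d = (
                max(a_lo - mu_a, 0.0, mu_a - a_hi) ** 2
                + max(s_lo - musp, 0.0, musp - s_hi) ** 2
            )
            return _PENALTY * (1.0 + d)
        model = ev(mu_a, musp)
        return sum((m - v) ** 2 for m, v in zip(rd_t, model))

    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "fatol": config.fatol,
            "xatol": config.xatol,
            "maxiter": config.max_iter,
        },
    )
    mu_a, musp = res.x
    inside = a_lo <= mu_a <= a_hi and s_lo <= musp <= s_hi
    return float(mu_a), float(musp), float(res.fun), bool(res.success and inside)


def fit_pixel(
    rd_measured: Sequence[float],
    fx_list: Sequence[float],
    table: ReflectanceTable,
    config: InversionConfig | None = None,
) -> tuple[OpticalProperties, float, bool]:
    """Nelder-Mead fit of one Rd(fx) vector.

    Returns (properties, residual, converged).  All-zero or non-finite
    measurements are flagged non-converged instead of raising.
    """
    if config is None:
        config = InversionConfig()
    rd = np.asarray(rd_measured, dtype=np.float64)
    fx_list = list(fx_list)
    if len(fx_list) < 2:
        raise ValueError("at least two spatial frequencies are required")
    if len(rd) != len(fx_list):
        raise ValueError("rd_measured and fx_list length mismatch")
    ev = _cached_evaluator(table, fx_list)
    fallback = OpticalProperties(
        config.initial_guess[0], config.initial_guess[1], g=config.g, n=config.n
    )
    if not np.all(np.isfinite(rd)) or np.all(rd <= 0):
        return fallback, float("nan"), False
    mu_a, musp, fun, ok = _fit_one(rd, ev, config, np.asarray(config.initial_guess))
    mu_a = float(np.clip(mu_a, ev.a_lo, ev.a_hi))
    musp = float(np.clip(musp, ev.s_lo, ev.s_hi))
    props = OpticalProperties(mu_a, musp, g=config.g, n=config.n)
    return props, fun, ok


def fit_image(
    rd_stack: np.ndarray,
    fx_list: Sequence[float],
    table: ReflectanceTable,
    config: InversionConfig | None = None,
    band: str = "",
) -> PropertyMap:
    """Independent per-pixel fits of an Rd stack, shape (n_fx, H, W).

    Pixels are order-independent; identical Rd vectors (common after 8-bit
    quantisation) are fitted once and the result shared.
    """
    if config is None:
        config = InversionConfig()
    rd_stack = np.asarray(rd_stack, dtype=np.float64)
    fx_list = list(fx_list)
    if rd_stack.ndim != 3:
        raise ValueError("rd_stack must have shape (n_fx, H, W)")
    if rd_stack.shape[0] != len(fx_list):
        raise ValueError(
            f"rd_stack has {rd_stack.shape[0]} fx planes but fx_list has "
            f"{len(fx_list)}"
        )
    nfx, h, w = rd_stack.shape
    flat = rd_stack.reshape(nfx, -1)
    uniq, inverse = np.unique(flat, axis=1, return_inverse=True)
    ev = _cached_evaluator(table, fx_list)

    n_uniq = uniq.shape[1]
    mu_a_u = np.empty(n_uniq)
    musp_u = np.empty(n_uniq)
    res_u = np.empty(n_uniq)
    ok_u = np.empty(n_uniq, dtype=bool)
    x0 = np.asarray(config.initial_guess, dtype=np.float64)
    # warm start: per-pixel solutions cluster around the FOV-mean fit
    mean_rd = flat.mean(axis=1)
    if np.all(np.isfinite(mean_rd)) and np.any(mean_rd > 0):
        wa, ws, _, wok = _fit_one(mean_rd, ev, config, x0)
        if wok:
            x0 = np.array([wa, ws])
    for i in range(n_uniq):
        rd = uniq[:, i]
        if not np.all(np.isfinite(rd)) or np.all(rd <= 0):
            mu_a_u[i], musp_u[i] = config.initial_guess
            res_u[i] = np.nan
            ok_u[i] = False
            continue
        mu_a, musp, fun, ok = _fit_one(rd, ev, config, x0)
        mu_a_u[i] = np.clip(mu_a, ev.a_lo, ev.a_hi)
        musp_u[i] = np.clip(musp, ev.s_lo, ev.s_hi)
        res_u[i] = fun
        ok_u[i] = ok

    return PropertyMap(
        mu_a_map=mu_a_u[inverse].reshape(h, w),
        mu_s_prime_map=musp_u[inverse].reshape(h, w),
        residuals=res_u[inverse].reshape(h, w),
        converged=ok_u[inverse].reshape(h, w),
        band=band,
    )
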