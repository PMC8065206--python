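"""Nonlinear quantile regression for the dose-response family.

Fits the tau-th conditional quantile by minimizing the check loss

    sum_i rho_tau(y_i - f(x_i; theta)),   rho_tau(r) = r * (tau - 1[r < 0]),

over the model parameters.  The kink at r = 0 makes the exact loss
non-smooth, so optimization proceeds on a Huberized surrogate whose kink
is rounded over a width ``h`` (quadratic on |r| <= h, matching value and
slope at +-h), annealed through h = 1e-1..1e-4 times the residual scale,
followed by a final Nelder-Mead polish on the exact loss.  Standard errors
come from a case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import ModelSpec
from .robust import RobustOptions, fit_robust, mad_scale


def check_loss(residuals, tau: float):
    """Exact check (pinball) loss, summed."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def smoothed_check_loss(residuals, tau: float, h: float):
    """C1 surrogate: quadratic |r| <= h, linear outside, matching at +-h."""
    r = np.asarray(residuals, dtype=float)
    quad = r**2 / (4 * h) + (tau - 0.5) * r + h / 4
    lin = r * (tau - (r < 0))
    return float(np.sum(np.where(np.abs(r) <= h, quad, lin)))


def _smoothed_grad(r, tau, h):
    inner = r / (2 * h) + (tau - 0.5)
    outer = tau - (r < 0)
    return np.where(np.abs(r) <= h, inner, outer)


@dataclass
class QuantileFitResult:
    model: str
    tau: float
    parameter_names: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray | None
    p_values: np.ndarray | None
    loss: float
    converged: bool
    n: int
    n_bootstrap: int = 0
    seed: int | None = None

    @property
    def params(self) -> dict:
        return dict(zip(self.parameter_names, map(float, self.estimates)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "tau": self.tau,
                "estimate": self.estimates,
                "se": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def fit_quantile(
    spec: ModelSpec,
    samples: pd.DataFrame,
    tau: float,
    start: np.ndarray | None = None,
    anneal=(1e-1, 1e-2, 1e-3, 1e-4),
) -> QuantileFitResult:
    """Point fit of the tau-th conditional quantile.

    The robust mean fit provides the starting point unless ``start`` is
    given.  Deterministic: no randomness enters the point fit.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    y = samples["response"].to_numpy(float)
    dose = samples["dose_gy"].to_numpy(float)
    cat = samples["let_category"].to_numpy(object)
    n = y.size
    if n <= spec.k + 1:
        raise ValueError(f"need n > k+1 samples, got {n}")
    X = spec.design_matrix(dose, cat)

    if start is None:
        theta = fit_robust(spec, samples, RobustOptions()).estimates.copy()
    else:
        theta = spec.coerce_params(start)

    resid0 = y - X @ theta
    scale = mad_scale(resid0)
    if scale <= 0:
        scale = max(float(np.mean(np.abs(resid0))), 1e-8)

    converged = True
    for frac in anneal:
        h = frac * scale

        def fun(th, h=h):
            r = y - X @ th
            return smoothed_check_loss(r, tau, h)

        def grad(th, h=h):
            r = y - X @ th
            return -X.T @ _smoothed_grad(r, tau, h)

        res = optimize.minimize(fun, theta, jac=grad, method="L-BFGS-B")
        theta = res.x
        converged = converged and bool(res.success)

    # final polish on the exact kinked loss
    res = optimize.minimize(
        lambda th: check_loss(y - X @ th, tau),
        theta,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000},
    )
    if check_loss(y - X @ res.x, tau) <= check_loss(y - X @ theta, tau):
        theta = res.x
    return QuantileFitResult(
        model=spec.name,
        tau=tau,
        parameter_names=spec.parameter_names,
        estimates=theta,
        standard_errors=None,
        p_values=None,
        loss=check_loss(y - X @ theta, tau),
        converged=converged,
        n=n,
    )


def bootstrap_se(
    spec: ModelSpec,
    samples: pd.DataFrame,
    tau: float,
    n_bootstrap: int = 500,
    seed: int = 0,
    point_fit: QuantileFitResult | None = None,
) -> QuantileFitResult:
    """Case-resampling bootstrap standard errors for a quantile fit.

    Each replicate resamples rows with replacement and refits from the
    original point estimate.  SE = SD of the bootstrap estimates; more
    than 20% replicate non-convergence flags the SEs unreliable.
    """
    fit = point_fit or fit_quantile(spec, samples, tau)
    if not fit.converged:
        raise RuntimeError("refusing bootstrap on a non-converged point fit")
    rng = np.random.default_rng(seed)
    n = len(samples)
    boots = []
    n_fail = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        rep = samples.iloc[idx].reset_index(drop=True)
        try:
            bf = fit_quantile(spec, rep, tau, start=fit.estimates)
        except Exception:
            n_fail += 1
            continue
        if not bf.converged:
            n_fail += 1
        boots.append(bf.estimates)
    se = np.std(np.asarray(boots), axis=0, ddof=1)
    if n_fail > 0.2 * n_bootstrap:
        se = np.full_like(se, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.estimates / se, np.sign(fit.estimates) * np.inf)
    pv = 2.0 * stats.norm.sf(np.abs(z))
    return QuantileFitResult(
        model=fit.model,
        tau=tau,
        parameter_names=fit.parameter_names,
        estimates=fit.estimates,
        standard_errors=se,
        p_values=pv,
        loss=fit.loss,
        converged=fit.converged,
        n=fit.n,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def fit_quantiles(
    spec: ModelSpec,
    samples: pd.DataFrame,
    taus=(0.25, 0.5, 0.75),
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit several quantile levels; long-format results table."""
    frames = []
    for i, tau in enumerate(taus):
        fit = fit_quantile(spec, samples, tau)
        if n_bootstrap:
            fit = bootstrap_se(
                spec, samples, tau, n_bootstrap, seed=seed + i, point_fit=fit
            )
        frames.append(fit.to_frame())
    return pd.concat(frames, ignore_index=True)
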