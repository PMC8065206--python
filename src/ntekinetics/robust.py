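"""Robust M-estimation nonlinear regression via IRLS.

The engine minimizes ``sum_i rho((y_i - f(x_i; theta)) / s)`` over the
regression parameters, with ``rho`` a bounded-influence loss (Huber or
Tukey bisquare) and ``s`` a robust residual scale re-estimated each
iteration from the median absolute residual.  Each iteration solves the
weighted nonlinear least-squares subproblem by Gauss-Newton with step
halving; for the dose-response family the model is linear in its
parameters, so each inner step is exact and the outer loop converges in a
handful of weight updates.

Inference is sandwich-type: with ``psi = rho'``, ``u_i = r_i / s`` and
Jacobian rows ``x_i``,

    A = sum_i psi'(u_i) x_i x_i' / s,    Bmat = sum_i psi(u_i)^2 x_i x_i',
    Cov(theta) = A^{-1} Bmat A^{-1},

which reduces to the usual OLS covariance when ``rho`` is squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import DEFAULT_K_NTE_R, ModelSpec

_MAD_CONST = 0.6744897501960817  # Phi^{-1}(0.75): MAD -> sigma for a Gaussian


class RankDeficiencyError(ValueError):
    """Jacobian is rank deficient: some parameters are unidentifiable."""


class NotConvergedError(RuntimeError):
    """Inference requested on a fit that did not converge."""


@dataclass(frozen=True)
class RobustOptions:
    """Knobs of the M-estimator.

    ``loss`` selects the psi family: ``"huber"`` (tuning constant 1.345,
    95% Gaussian efficiency) or ``"bisquare"`` (4.685, redescending), or
    ``"ols"`` to force unit weights and reproduce ordinary nonlinear least
    squares.  The scale estimator is the median absolute residual divided
    by 0.6745, or a fixed user value.
    """

    loss: str = "huber"
    tuning_constant: float | None = None
    scale_estimator: str = "mad"  # "mad" | "fixed"
    fixed_scale: float | None = None
    max_iterations: int = 200
    tolerance: float = 1e-8
    start: dict | None = None
    k_nte_r: float = DEFAULT_K_NTE_R

    def __post_init__(self):
        if self.loss not in ("huber", "bisquare", "ols"):
            raise ValueError("loss must be 'huber', 'bisquare' or 'ols'")
        if self.tuning_constant is not None and self.tuning_constant <= 0:
            raise ValueError("tuning_constant must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def c(self) -> float:
        if self.tuning_constant is not None:
            return self.tuning_constant
        return {"huber": 1.345, "bisquare": 4.685, "ols": np.inf}[self.loss]


def rho(u: np.ndarray, loss: str, c: float) -> np.ndarray:
    """Robust loss evaluated at standardized residuals."""
    u = np.asarray(u, dtype=float)
    if loss == "ols":
        return 0.5 * u**2
    a = np.abs(u)
    if loss == "huber":
        return np.where(a <= c, 0.5 * u**2, c * a - 0.5 * c**2)
    # bisquare
    inside = np.clip(1 - (u / c) ** 2, 0.0, None)
    return (c**2 / 6.0) * (1.0 - inside**3)


def psi(u: np.ndarray, loss: str, c: float) -> np.ndarray:
    """Influence function ``rho'``."""
    u = np.asarray(u, dtype=float)
    if loss == "ols":
        return u
    if loss == "huber":
        return np.clip(u, -c, c)
    inside = np.clip(1 - (u / c) ** 2, 0.0, None)
    return u * inside**2


def psi_deriv(u: np.ndarray, loss: str, c: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if loss == "ols":
        return np.ones_like(u)
    if loss == "huber":
        return (np.abs(u) <= c).astype(float)
    t = np.clip(1 - (u / c) ** 2, 0.0, None)
    return np.where(np.abs(u) < c, t * (t - 4 * u**2 / c**2), 0.0)


def weights_of(u: np.ndarray, loss: str, c: float) -> np.ndarray:
    """IRLS weights ``psi(u)/u`` with ``w(0) = 1``."""
    u = np.asarray(u, dtype=float)
    if loss == "ols":
        return np.ones_like(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(u == 0.0, 1.0, psi(u, loss, c) / u)
    return np.clip(w, 0.0, 1.0)


def mad_scale(residuals: np.ndarray) -> float:
    """Median absolute residual / Phi^{-1}(0.75)."""
    return float(np.median(np.abs(residuals)) / _MAD_CONST)


@dataclass
class FitResult:
    """Point estimates and inference for one model on one dataset."""

    model: str
    parameter_names: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    robust_weights: np.ndarray
    scale: float
    sigma2: float
    log_likelihood: float
    converged: bool
    n: int
    n_iterations: int
    loss_value: float
    options: RobustOptions = field(repr=False, default=None)

    @property
    def params(self) -> dict:
        return dict(zip(self.parameter_names, map(float, self.estimates)))

    @property
    def k(self) -> int:
        """Parameter count for information criteria: regression params + sigma."""
        return len(self.estimates) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "estimate": self.estimates,
                "se": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def default_start(spec: ModelSpec, samples: pd.DataFrame) -> np.ndarray:
    """Deterministic data-driven starting values.

    Baseline starts at the median sham response (overall median when no
    shams are present); the NTE plateau at the median response above the
    saturation dose minus the baseline; all TE slopes at zero.
    """
    y = samples["response"].to_numpy(dtype=float)
    sham = samples["dose_gy"].to_numpy() == 0
    b0 = float(np.median(y[sham])) if sham.any() else float(np.median(y))
    theta = {name: 0.0 for name in spec.parameter_names}
    theta["B"] = b0
    high = samples["dose_gy"].to_numpy() >= 0.05
    knte0 = max(float(np.median(y[high])) - b0, 0.0) if high.any() else 0.0
    for name in spec.parameter_names:
        if name.startswith("kNTE"):
            theta[name] = knte0
    return np.array([theta[n] for n in spec.parameter_names])


def _check_identifiable(spec: ModelSpec, X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        norms = np.linalg.norm(X, axis=0)
        dead = [n for n, v in zip(spec.parameter_names, norms) if v == 0]
        raise RankDeficiencyError(
            f"model {spec.name} is rank deficient on these data; "
            f"parameters without support: {dead or 'collinear columns'}"
        )


def fit_robust(
    spec: ModelSpec,
    samples: pd.DataFrame,
    options: RobustOptions | None = None,
) -> FitResult:
    """Fit one dose-response variant by robust IRLS.

    ``samples`` must carry ``response``, ``dose_gy`` and ``let_category``
    columns (the processed-table schema).  The result records per-sample
    robust weights, the converged scale, and a Gaussian log-likelihood
    evaluated at the robust estimates with ``sigma^2`` equal to the mean
    squared residual — the convention used for information criteria, and
    applied identically to every variant so that AICc differences compare
    like with like.
    """
    options = options or RobustOptions()
    y = samples["response"].to_numpy(dtype=float)
    dose = samples["dose_gy"].to_numpy(dtype=float)
    cat = samples["let_category"].to_numpy(dtype=object)
    n = y.size
    if n <= spec.k + 1:
        raise ValueError(f"need n > k+1 = {spec.k + 1} samples, got {n}")
    X = spec.design_matrix(dose, cat, options.k_nte_r)
    _check_identifiable(spec, X)

    theta = (
        spec.coerce_params(options.start)
        if options.start is not None
        else default_start(spec, samples)
    )
    loss, c = options.loss, options.c

    def scale_of(r):
        if options.scale_estimator == "fixed":
            return float(options.fixed_scale)
        s = mad_scale(r)
        return s if s > 0 else max(float(np.mean(np.abs(r))), 1e-12)

    r = y - X @ theta
    s = scale_of(r)
    total = float(np.sum(rho(r / s, loss, c)))
    converged = False
    it = 0
    for it in range(1, options.max_iterations + 1):
        u = r / s
        w = weights_of(u, loss, c)
        sw = np.sqrt(w)
        # Gauss-Newton step on the weighted subproblem (exact here: the
        # model is linear in theta), with step halving on the robust loss.
        delta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * r, rcond=None)
        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            r_new = y - X @ cand
            total_new = float(np.sum(rho(r_new / s, loss, c)))
            if total_new <= total or not np.isfinite(total):
                break
            step *= 0.5
        else:
            cand, r_new, total_new = theta, r, total
        rel_par = np.max(np.abs(cand - theta)) / max(np.max(np.abs(theta)), 1e-10)
        rel_loss = abs(total_new - total) / max(abs(total), 1e-10)
        theta, r = cand, r_new
        s_new = scale_of(r)
        rel_scale = abs(s_new - s) / max(s, 1e-12)
        s = s_new
        total = float(np.sum(rho(r / s, loss, c)))
        if rel_par < options.tolerance and rel_loss < options.tolerance and (
            options.scale_estimator == "fixed" or rel_scale < 1e-6
        ):
            converged = True
            break

    u = r / s
    w = weights_of(u, loss, c)
    sigma2 = float(np.mean(r**2))
    if sigma2 > 0:
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    else:
        ll = np.inf  # degenerate perfect fit
    if theta[0] < 0:
        warnings.warn(
            f"baseline estimate B = {theta[0]:.4g} is negative", stacklevel=2
        )
    fit = FitResult(
        model=spec.name,
        parameter_names=spec.parameter_names,
        estimates=theta,
        standard_errors=np.full(theta.size, np.nan),
        p_values=np.full(theta.size, np.nan),
        robust_weights=w,
        scale=s,
        sigma2=sigma2,
        log_likelihood=ll,
        converged=converged,
        n=n,
        n_iterations=it,
        loss_value=total,
        options=options,
    )
    if converged:
        se = _wald_se(X, r, s, loss, c)
        fit.standard_errors = se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, theta / se, np.sign(theta) * np.inf)
        fit.p_values = 2.0 * stats.norm.sf(np.abs(z))
    return fit


def _wald_se(X, r, s, loss, c):
    u = r / s
    pw = psi_deriv(u, loss, c)
    A = (X.T * pw) @ X / s
    Bm = (X.T * psi(u, loss, c) ** 2) @ X
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.full(X.shape[1], np.nan)
    cov = Ainv @ Bm @ Ainv
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def wald_inference(fit: FitResult) -> pd.DataFrame:
    """Standard errors and two-sided normal p-values for a converged fit."""
    if not fit.converged:
        raise NotConvergedError(
            "refusing Wald inference on a non-converged fit"
        )
    se = fit.standard_errors
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.estimates / se, np.inf * np.sign(fit.estimates))
    pv = 2.0 * stats.norm.sf(np.abs(z))
    fit.p_values = pv
    return pd.DataFrame(
        {
            "parameter": fit.parameter_names,
            "estimate": fit.estimates,
            "se": se,
            "p_value": pv,
        }
    )
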