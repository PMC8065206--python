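"""Random-intercept nonlinear mixed-effects fit with a dose/LET variance
function, plus residual diagnostics and variance-homogeneity screens.

The random effect enters additively on the baseline ``B``, so the marginal
distribution of each subject's response vector is Gaussian with covariance

    Sigma_j = sigma_b^2 * 11' + diag(v_i),
    v_i = sigma^2 * lambda_cat(i)^2 * exp(2 * delta * D_i),

and the marginal likelihood is available in closed form — no linearization
is needed.  Fixed effects are profiled out exactly by generalized least
squares (the model family is linear in its parameters) inside a direct
search over the variance parameters (sigma, sigma_b, delta, lambdas).
Maximum likelihood is used (not REML) so log-likelihoods are comparable
across fixed-effect structures; REML is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import ModelSpec


class IdentifiabilityWarning(UserWarning):
    pass


@dataclass
class MixedFitResult:
    model: str
    parameter_names: tuple[str, ...]
    fixed_effects: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    random_intercept_sd: float
    random_intercept_sd_ci: tuple[float, float]
    residual_sd: float
    dose_coefficient: float  # delta: variance ∝ exp(2*delta*D)
    let_multipliers: dict  # lambda per category, reference fixed at 1
    log_likelihood: float
    converged: bool
    boundary: bool
    n: int
    n_subjects: int
    method: str = "ML"
    variance_structure: str = "combined"

    @property
    def params(self) -> dict:
        return dict(zip(self.parameter_names, map(float, self.fixed_effects)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "estimate": self.fixed_effects,
                "se": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def _group_codes(subject_ids: np.ndarray) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(pd.Series(subject_ids), sort=False)
    return codes.astype(np.intp), len(uniques)


def marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    sigma_b: float,
    unit_var: np.ndarray,
) -> float:
    """Exact marginal log-likelihood for a shared additive random intercept.

    ``unit_var`` holds the per-observation residual variances v_i; ``gidx``
    maps rows to subjects.  Uses the rank-one Woodbury identity per
    subject: with D = diag(v) inside a subject,
    Sigma^{-1} = D^{-1} - (s_b^2 / (1 + s_b^2 * a)) D^{-1}11'D^{-1} and
    log|Sigma| = sum log v_i + log(1 + s_b^2 * a), a = sum 1/v_i.
    """
    r = y - X @ beta
    s2b = sigma_b**2
    iv = 1.0 / unit_var
    a = np.bincount(gidx, weights=iv, minlength=n_groups)
    m = np.bincount(gidx, weights=r * iv, minlength=n_groups)
    quad = float(np.sum(r**2 * iv))
    corr = float(np.sum(s2b / (1.0 + s2b * a) * m**2))
    logdet = float(np.sum(np.log(unit_var)) + np.sum(np.log1p(s2b * a)))
    return -0.5 * (y.size * np.log(2 * np.pi) + logdet + quad - corr)


def _gls_beta(y, X, gidx, n_groups, sigma_b, unit_var):
    """Profile the fixed effects exactly: GLS with the rank-one covariance."""
    s2b = sigma_b**2
    iv = 1.0 / unit_var
    Xw = X * iv[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    if s2b > 0:
        a = np.bincount(gidx, weights=iv, minlength=n_groups)
        f = s2b / (1.0 + s2b * a)
        U = np.zeros((n_groups, X.shape[1]))
        np.add.at(U, gidx, Xw)
        w = np.bincount(gidx, weights=y * iv, minlength=n_groups)
        XtWX = XtWX - (U * f[:, None]).T @ U
        XtWy = XtWy - U.T @ (f * w)
    beta = np.linalg.solve(XtWX, XtWy)
    return beta, XtWX


def _sigma_b_ci(negll, eta, sigma_b, level: float = 0.95) -> tuple[float, float]:
    """Wald interval for sigma_b on the log scale.

    Uses the full finite-difference Hessian of the profiled negative
    log-likelihood over all variance parameters (the residual scale and
    sigma_b are correlated, so the marginal — not conditional — curvature
    is required for honest coverage).  Degenerate curvature (boundary
    fits) yields a (0, inf) interval.
    """
    d = eta.size
    h = 1e-3
    H = np.empty((d, d))
    f0 = negll(eta)
    for i in range(d):
        for j in range(i, d):
            e = eta.copy()
            if i == j:
                e[i] = eta[i] + h
                fp = negll(e)
                e[i] = eta[i] - h
                fm = negll(e)
                H[i, i] = (fp - 2 * f0 + fm) / h**2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    e = eta.copy()
                    e[i] += si * h
                    e[j] += sj * h
                    vals.append(negll(e))
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h**2
                )
    try:
        cov = np.linalg.inv(H)
        var_log_sb = float(cov[1, 1])
    except np.linalg.LinAlgError:
        var_log_sb = np.nan
    if not np.isfinite(var_log_sb) or var_log_sb <= 0:
        return (0.0, np.inf)
    se_log = np.sqrt(var_log_sb)
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(sigma_b * np.exp(-z * se_log)), float(sigma_b * np.exp(z * se_log)))


def _sigma_b_profile_ci(
    negll, eta, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood interval for sigma_b.

    Inverts the likelihood-ratio test: the bound solves
    ``negll_profiled(log sigma_b) = negll_min + chi2_1(level)/2`` with the
    remaining variance parameters re-optimized at each candidate.  More
    accurate than the Wald interval when the likelihood in sigma_b is
    skewed (small variance components).
    """
    from scipy.optimize import brentq, minimize

    d = eta.size
    others = [i for i in range(d) if i != 1]
    f_min = negll(eta)
    cut = f_min + stats.chi2.ppf(level, 1) / 2

    def prof(lsb, start):
        if d == 1:
            e = np.array([lsb])
            return negll(e), start

        def inner(x):
            e = np.empty(d)
            e[1] = lsb
            e[others] = x
            return negll(e)

        res = minimize(
            inner, start, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
        )
        return res.fun, res.x

    center = eta[1]
    start0 = eta[others]

    def bound(direction):
        step = 0.2
        prev = center
        start = start0
        for _ in range(60):
            cand = prev + direction * step
            val, start = prof(cand, start)
            if val >= cut:
                # root between prev and cand
                lo, hi = sorted((prev, cand))
                st = {"s": start}

                def g(x):
                    v, st["s"] = prof(x, st["s"])
                    return v - cut

                return brentq(g, lo, hi, xtol=1e-4)
            prev = cand
            if direction < 0 and cand < center - 12:
                return -np.inf  # boundary: sigma_b -> 0 not rejected
        return direction * np.inf

    lo = bound(-1.0)
    hi = bound(+1.0)
    return (float(np.exp(lo)), float(np.exp(hi)))


def fit_mixed(
    spec: ModelSpec,
    samples: pd.DataFrame,
    variance_structure: str = "combined",
    method: str = "ML",
    maxiter: int = 4000,
    ci_method: str = "wald",
) -> MixedFitResult:
    """ML fit of the random-intercept model with a variance function.

    ``variance_structure`` selects the residual-variance model:
    ``"combined"`` (per-LET multiplier x exp(2*delta*D)), ``"by-let"``,
    ``"by-dose"`` or ``"const"``.  The reference LET stratum (first seen,
    usually SHAM) has its multiplier fixed at 1.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if variance_structure not in ("combined", "by-let", "by-dose", "const"):
        raise ValueError(f"unknown variance structure {variance_structure!r}")
    y = samples["response"].to_numpy(float)
    dose = samples["dose_gy"].to_numpy(float)
    cat = samples["let_category"].to_numpy(object)
    subj = samples["subject_id"].to_numpy(object)
    gidx, n_groups = _group_codes(subj)
    group_sizes = np.bincount(gidx, minlength=n_groups)
    n = y.size
    if n_groups < 2:
        raise ValueError("need at least 2 subjects")
    if group_sizes.max() < 2 and variance_structure == "const":
        warnings.warn(
            "single observation per subject with homoscedastic variance: "
            "sigma_b and residual SD are jointly unidentifiable",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    X = spec.design_matrix(dose, cat)

    cats_present = list(dict.fromkeys(cat))
    ref = cats_present[0]
    use_let = variance_structure in ("combined", "by-let")
    use_dose = variance_structure in ("combined", "by-dose")
    let_free = [c for c in cats_present if c != ref] if use_let else []
    cat_idx = {c: np.flatnonzero(cat == c) for c in let_free}

    # eta = [log sigma, log sigma_b, delta?, log lambda_c ...]
    def unpack(eta):
        sigma = np.exp(eta[0])
        sigma_b = np.exp(eta[1])
        pos = 2
        delta = 0.0
        if use_dose:
            delta = eta[pos]
            pos += 1
        lam = np.ones(n)
        lam_map = {ref: 1.0}
        for c in let_free:
            lc = np.exp(eta[pos])
            lam_map[c] = lc
            lam[cat_idx[c]] = lc
            pos += 1
        unit_var = sigma**2 * lam**2 * np.exp(2.0 * delta * dose)
        return sigma, sigma_b, delta, lam_map, unit_var

    resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s0 = max(float(np.std(resid0)), 1e-6)
    eta0 = np.concatenate(
        [
            [np.log(s0), np.log(s0 / 2.0)],
            [0.0] if use_dose else [],
            np.zeros(len(let_free)),
        ]
    )

    reml = method == "REML"

    def negll(eta):
        if np.any(np.abs(eta) > 20):
            return 1e12
        sigma, sigma_b, delta, _, unit_var = unpack(eta)
        try:
            beta, XtWX = _gls_beta(y, X, gidx, n_groups, sigma_b, unit_var)
        except np.linalg.LinAlgError:
            return 1e12
        ll = marginal_loglik(y, X, beta, gidx, n_groups, sigma_b, unit_var)
        if reml:
            sign, logdet = np.linalg.slogdet(XtWX)
            ll -= 0.5 * logdet
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        negll,
        eta0,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": maxiter, "maxfev": maxiter},
    )
    eta = res.x
    sigma, sigma_b, delta, lam_map, unit_var = unpack(eta)
    beta, XtWX = _gls_beta(y, X, gidx, n_groups, sigma_b, unit_var)
    ll = marginal_loglik(y, X, beta, gidx, n_groups, sigma_b, unit_var)
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pv = 2.0 * stats.norm.sf(np.abs(z))
    if ci_method == "profile":
        ci = _sigma_b_profile_ci(negll, eta)
    elif ci_method == "wald":
        ci = _sigma_b_ci(negll, eta, sigma_b)
    else:
        ci = (np.nan, np.nan)
    boundary = sigma_b < 1e-4 * max(sigma, 1e-12)
    if boundary:
        warnings.warn(
            f"random-intercept SD at boundary (sigma_b = {sigma_b:.3g})",
            stacklevel=2,
        )
    return MixedFitResult(
        model=spec.name,
        parameter_names=spec.parameter_names,
        fixed_effects=beta,
        standard_errors=se,
        p_values=pv,
        random_intercept_sd=float(sigma_b),
        random_intercept_sd_ci=ci,
        residual_sd=float(sigma),
        dose_coefficient=float(delta),
        let_multipliers=lam_map,
        log_likelihood=float(ll),
        converged=bool(res.success),
        boundary=bool(boundary),
        n=n,
        n_subjects=n_groups,
        method=method,
        variance_structure=variance_structure,
    )


@dataclass
class DiagnosticsReport:
    shapiro_p: float
    skewness: float
    kurtosis: float  # Pearson convention (Gaussian = 3)
    slope_p_dose: float
    slope_p_time: float
    lag1_autocorrelation: float
    per_let_summary: pd.DataFrame = field(repr=False, default=None)
    note: str = ""


def blup_intercepts(
    fit: MixedFitResult, samples: pd.DataFrame, spec: ModelSpec
) -> pd.Series:
    """Best linear unbiased predictions of the per-rat baseline shifts."""
    y = samples["response"].to_numpy(float)
    dose = samples["dose_gy"].to_numpy(float)
    cat = samples["let_category"].to_numpy(object)
    subj = samples["subject_id"].to_numpy(object)
    X = spec.design_matrix(dose, cat)
    r = y - X @ fit.fixed_effects
    lam = np.array([fit.let_multipliers.get(c, 1.0) for c in cat])
    unit_var = fit.residual_sd**2 * lam**2 * np.exp(2 * fit.dose_coefficient * dose)
    s2b = fit.random_intercept_sd**2
    out = {}
    for sid, idx in pd.Series(range(len(subj))).groupby(pd.Series(subj)).indices.items():
        idx = np.asarray(idx)
        a = np.sum(1.0 / unit_var[idx])
        out[sid] = s2b / (1.0 + s2b * a) * np.sum(r[idx] / unit_var[idx])
    return pd.Series(out, name="blup")


def diagnose_residuals(
    fit: MixedFitResult, samples: pd.DataFrame, spec: ModelSpec
) -> DiagnosticsReport:
    """Standardized conditional-residual diagnostics for a converged fit.

    Residuals subtract the BLUP random intercept and are standardized by
    the fitted variance function; the report covers normality
    (Shapiro-Wilk), shape (skewness, Pearson kurtosis), trend tests of
    residual vs dose and vs time, lag-1 autocorrelation in data order, and
    per-LET five-number summaries.
    """
    if not fit.converged:
        raise RuntimeError("diagnostics require a converged fit")
    y = samples["response"].to_numpy(float)
    dose = samples["dose_gy"].to_numpy(float)
    time = samples["time_months"].to_numpy(float)
    cat = samples["let_category"].to_numpy(object)
    subj = samples["subject_id"].to_numpy(object)
    X = spec.design_matrix(dose, cat)
    blup = blup_intercepts(fit, samples, spec)
    b = blup.loc[pd.Index(subj)].to_numpy()
    lam = np.array([fit.let_multipliers.get(c, 1.0) for c in cat])
    sd = fit.residual_sd * lam * np.exp(fit.dose_coefficient * dose)
    e = (y - X @ fit.fixed_effects - b) / sd

    note = ""
    if e.size >= 8:
        shapiro_p = float(stats.shapiro(e).pvalue)
    else:
        shapiro_p, note = np.nan, "n < 8: normality test skipped"
    skew = float(stats.skew(e))
    kurt = float(stats.kurtosis(e, fisher=False))
    slope_p_dose = float(stats.linregress(dose, e).pvalue)
    slope_p_time = float(stats.linregress(time, e).pvalue)
    lag1 = float(np.corrcoef(e[:-1], e[1:])[0, 1]) if e.size > 2 else np.nan
    per_let = (
        pd.DataFrame({"let_category": cat, "residual": e})
        .groupby("let_category")["residual"]
        .describe()[["count", "min", "25%", "50%", "75%", "max"]]
    )
    return DiagnosticsReport(
        shapiro_p=shapiro_p,
        skewness=skew,
        kurtosis=kurt,
        slope_p_dose=slope_p_dose,
        slope_p_time=slope_p_time,
        lag1_autocorrelation=lag1,
        per_let_summary=per_let,
        note=note,
    )


def variance_homogeneity_screen(
    samples: pd.DataFrame,
    factors=("dose_gy", "let_category", "time_months"),
) -> pd.DataFrame:
    """Fligner-Killeen homogeneity-of-variance test per grouping factor.

    Singleton groups carry no variance information and are dropped with a
    notice in the output table.
    """
    rows = []
    y = samples["response"]
    for factor in factors:
        grouped = [g.to_numpy() for _, g in y.groupby(samples[factor])]
        dropped = sum(1 for g in grouped if len(g) < 2)
        kept = [g for g in grouped if len(g) >= 2]
        if len(kept) < 2:
            rows.append((factor, np.nan, dropped, "fewer than 2 usable groups"))
            continue
        stat, p = stats.fligner(*kept)
        rows.append((factor, float(p), dropped, ""))
    return pd.DataFrame(rows, columns=["factor", "p_value", "n_singleton_dropped", "note"])
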