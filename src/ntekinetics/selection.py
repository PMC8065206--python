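"""AICc multimodel comparison, goodness metrics, split-stability analysis.

Model support is quantified by the small-sample-corrected Akaike
criterion, AICc = 2k - 2*logL + 2k(k+1)/(n-k-1), with the Gaussian
log-likelihood convention of :mod:`ntekinetics.robust` (sigma^2 = mean
squared residual, k counts the regression parameters plus sigma).  The
difference from the best model, dAICc, maps to relative support via
exp(-dAICc/2); dAICc > 6 marks poor support (more than 20-fold below the
best model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelSpec, build_model, list_models
from .robust import FitResult, RobustOptions, fit_robust


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n <= k + 1:
        raise ValueError(f"AICc correction diverges for n <= k+1 (n={n}, k={k})")
    aic = 2.0 * k - 2.0 * log_likelihood
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def goodness_metrics(observed, predicted) -> dict:
    """R^2 (about the observed mean), RMSE and MAE."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    resid = y - f
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
    }


@dataclass
class ComparisonTable:
    """Per-model AICc ranking with goodness metrics, sorted by dAICc."""

    table: pd.DataFrame
    fits: dict

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    def within(self, delta: float) -> list[str]:
        t = self.table
        return t.loc[t["delta_aicc"] < delta, "model"].tolist()


def compare_models(
    samples: pd.DataFrame,
    model_names=None,
    options: RobustOptions | None = None,
) -> ComparisonTable:
    """Fit every requested variant and rank by AICc.

    Non-converged fits are retained in the table but flagged and excluded
    from the dAICc reference minimum.
    """
    names = list(model_names) if model_names is not None else list_models()
    rows = []
    fits: dict[str, FitResult] = {}
    for name in names:
        spec = build_model(name)
        fit = fit_robust(spec, samples, options)
        fits[name] = fit
        gm = goodness_metrics(
            samples["response"].to_numpy(),
            spec.predict(
                fit.estimates,
                samples["dose_gy"].to_numpy(),
                samples["let_category"].to_numpy(object),
            ),
        )
        rows.append(
            {
                "model": name,
                "k": fit.k,
                "aicc": aicc(fit.log_likelihood, fit.k, fit.n),
                "converged": fit.converged,
                **gm,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["converged"]
    if not ok.all():
        warnings.warn(
            f"non-converged fits excluded from the dAICc minimum: "
            f"{df.loc[~ok, 'model'].tolist()}",
            stacklevel=2,
        )
    ref = df.loc[ok, "aicc"].min() if ok.any() else df["aicc"].min()
    df["delta_aicc"] = df["aicc"] - ref
    df["support"] = np.exp(-df["delta_aicc"] / 2.0)
    df = df.sort_values("delta_aicc", kind="mergesort").reset_index(drop=True)
    cols = ["model", "k", "aicc", "delta_aicc", "support", "r2", "rmse", "mae", "converged"]
    return ComparisonTable(table=df[cols], fits=fits)


def _strata(samples: pd.DataFrame) -> pd.Series:
    return (
        samples["let_category"].astype(str)
        + ":"
        + samples["dose_gy"].astype(str)
    )


def stratified_split(
    samples: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """50:50 split stratified by LET category x dose group.

    Stratification keeps every design cell represented in both halves, so
    every TE slope stays identifiable in every split.  Odd cells donate
    their leftover row to alternating halves at random.
    """
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, idx in samples.groupby(_strata(samples)).indices.items():
        idx = np.asarray(idx)
        perm = rng.permutation(idx)
        half = len(perm) // 2
        if len(perm) % 2 == 1 and rng.random() < 0.5:
            half += 1
        train_idx.extend(perm[:half])
        test_idx.extend(perm[half:])
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class StabilitySummary:
    """Parameter and metric variability over random 50:50 splits."""

    parameters: pd.DataFrame  # mean/sd/min/max of each training-fit parameter
    metrics: pd.DataFrame  # mean/sd/min/max of r2/rmse/mae per half
    n_splits: int
    seed: int
    n_resampled: int
    per_split: pd.DataFrame


def split_stability(
    samples: pd.DataFrame,
    spec: ModelSpec,
    n_splits: int = 300,
    seed: int = 0,
    options: RobustOptions | None = None,
    stratified: bool = True,
) -> StabilitySummary:
    """Refit on random 50:50 training halves; evaluate both halves.

    For each split the model is fitted to the training half and the
    training-fit parameters are used to score R^2/RMSE/MAE on both the
    training and the held-out testing half.  Unidentifiable splits (only
    possible in unstratified mode) are resampled and counted.
    """
    rng = np.random.default_rng(seed)
    recs = []
    n_resampled = 0
    dose = samples["dose_gy"].to_numpy(float)
    cat = samples["let_category"].to_numpy(object)
    y = samples["response"].to_numpy(float)
    for split in range(n_splits):
        for _attempt in range(100):
            if stratified:
                tr, te = stratified_split(samples, rng)
            else:
                perm = rng.permutation(len(samples))
                tr, te = np.sort(perm[: len(perm) // 2]), np.sort(perm[len(perm) // 2 :])
            try:
                fit = fit_robust(spec, samples.iloc[tr], options)
            except Exception:
                n_resampled += 1
                continue
            break
        else:
            raise RuntimeError("could not form an identifiable split")
        rec = {"split": split}
        rec.update({f"param:{n}": v for n, v in fit.params.items()})
        for label, idx in (("train", tr), ("test", te)):
            pred = spec.predict(fit.estimates, dose[idx], cat[idx])
            for m, v in goodness_metrics(y[idx], pred).items():
                rec[f"{label}_{m}"] = v
        recs.append(rec)
    per_split = pd.DataFrame(recs)

    def summarize(cols):
        sub = per_split[cols]
        return pd.DataFrame(
            {
                "mean": sub.mean(),
                "sd": sub.std(ddof=1),
                "min": sub.min(),
                "max": sub.max(),
            }
        )

    pcols = [c for c in per_split.columns if c.startswith("param:")]
    mcols = [c for c in per_split.columns if c.endswith(("r2", "rmse", "mae"))]
    params = summarize(pcols)
    params.index = [c.removeprefix("param:") for c in pcols]
    return StabilitySummary(
        parameters=params,
        metrics=summarize(mcols),
        n_splits=n_splits,
        seed=seed,
        n_resampled=n_resampled,
        per_split=per_split,
    )
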