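"""Shadow-feature importance screening and tree-ensemble evaluation.

The feature table carries five predictors per behavioral test — dose,
beam energy, time since exposure, LET, and the saturating NTE functional
form ``nte_f = 1 - exp(-1e3 * D)`` — so a nonparametric learner can be
asked whether the NTE shape is informative outside the parametric
regression framework.

The screen follows the shadow-feature (Boruta-style) wrapper: each round
appends a randomly permuted copy of every predictor, fits a random-forest
regressor, and scores each real predictor against the best shadow via
permutation importance; hits accumulate over rounds and a two-sided
binomial rule confirms or rejects each predictor.  The whole procedure is
repeated with independent seeds and predictors are ranked by the median of
per-repeat median importances.  Tree induction itself is delegated to
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, RepeatedKFold, train_test_split

from .models import DEFAULT_K_NTE_R, nte_fraction
from .selection import goodness_metrics

PREDICTORS = ("dose_gy", "energy_mev_n", "time_months", "let_kev_um", "nte_f")


def build_features(samples: pd.DataFrame) -> pd.DataFrame:
    """Five-predictor feature table plus response.

    Sham rows have no beam, so missing energy is encoded as 0 MeV/n; trees
    split on that value harmlessly.
    """
    out = pd.DataFrame(
        {
            "dose_gy": samples["dose_gy"].astype(float),
            "energy_mev_n": samples["energy_mev_n"].fillna(0.0).astype(float),
            "time_months": samples["time_months"].astype(float),
            "let_kev_um": samples["let_kev_um"].astype(float),
            "nte_f": nte_fraction(
                samples["dose_gy"].to_numpy(float), DEFAULT_K_NTE_R
            ),
            "response": samples["response"].astype(float),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class ImportanceRanking:
    """Aggregated shadow-feature screening outcome."""

    table: pd.DataFrame  # per predictor: median_importance, hit_fraction, decision
    n_repeats: int
    seed: int

    @property
    def ranking(self) -> list[str]:
        return self.table["predictor"].tolist()

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]


def oob_permutation_importance(
    rf: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_perm_repeats: int = 1,
) -> np.ndarray:
    """Per-tree out-of-bag permutation importance.

    For each tree, the increase in mean squared error on that tree's OOB
    samples when one feature is permuted, averaged over trees.  Unlike
    whole-forest permutation importance, a feature that shares its signal
    with a correlated companion still earns credit from the trees that
    happened to use it — the behavior expected of the classical RF
    importance that shadow-feature selection was designed around.
    """
    n, p = X.shape
    imp = np.zeros((len(rf.estimators_), p))
    used = np.zeros(len(rf.estimators_), dtype=bool)
    for t, (tree, inbag) in enumerate(zip(rf.estimators_, rf.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size < 5:
            continue
        used[t] = True
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        for j in range(p):
            delta = 0.0
            Xp = Xo.copy()
            for _ in range(n_perm_repeats):
                Xp[:, j] = rng.permutation(Xo[:, j])
                delta += np.mean((tree.predict(Xp) - yo) ** 2) - base
            imp[t, j] = delta / n_perm_repeats
    if not used.any():
        raise RuntimeError("no tree had enough out-of-bag samples")
    return imp[used].mean(axis=0)


def _one_screen(
    Xdf: pd.DataFrame,
    y: np.ndarray,
    rng: np.random.Generator,
    n_trees: int,
    max_rounds: int,
    alpha: float,
    n_perm_repeats: int,
):
    cols = list(Xdf.columns)
    p = len(cols)
    Xreal = Xdf.to_numpy(float)
    importances = np.zeros((max_rounds, p))
    hits = np.zeros(p, dtype=int)
    decided = np.array([""] * p, dtype=object)
    for rnd in range(max_rounds):
        shadow = np.column_stack(
            [rng.permutation(Xreal[:, j]) for j in range(p)]
        )
        Xfull = np.column_stack([Xreal, shadow])
        # sqrt-mtry feature randomness matters: dose and nte_f induce the
        # same sample orderings, and a forest offered every feature at
        # every split would resolve that tie to a single column.
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(Xfull, y)
        pi = oob_permutation_importance(rf, Xfull, y, rng, n_perm_repeats)
        real, sh = pi[:p], pi[p:]
        importances[rnd] = real
        hits += real > sh.max()
        # two-sided binomial decision vs chance p = 0.5 per round
        n_done = rnd + 1
        for j in range(p):
            if decided[j]:
                continue
            test = stats.binomtest(int(hits[j]), n_done, 0.5)
            if test.pvalue < alpha:
                decided[j] = (
                    "confirmed" if hits[j] > n_done / 2 else "rejected"
                )
        if all(decided):
            importances = importances[: rnd + 1]
            break
    decided[decided == ""] = "tentative"
    return (
        np.median(importances, axis=0),
        hits / importances.shape[0],
        decided,
    )


def shadow_feature_rank(
    features: pd.DataFrame,
    n_repeats: int = 100,
    seed: int = 0,
    n_trees: int = 500,
    max_rounds: int = 20,
    alpha: float = 0.01,
    n_perm_repeats: int = 5,
) -> ImportanceRanking:
    """Repeat the shadow-feature screen and aggregate over repeats.

    Predictors are ranked by the median over repeats of the per-repeat
    median permutation importance; ``hit_fraction`` is the mean fraction
    of rounds in which the predictor beat the best shadow, and the
    decision is the majority call across repeats.  A constant predictor is
    auto-rejected.  Reproducible given ``seed``.
    """
    if len(features) < 50:
        raise ValueError("need >= 50 samples for the shadow-feature screen")
    y = features["response"].to_numpy(float)
    cols = [c for c in features.columns if c != "response"]
    const = [c for c in cols if features[c].nunique() <= 1]
    # canonical name order makes the ranking invariant to the caller's
    # column order (all internal randomness then sees identical inputs)
    use = sorted(c for c in cols if c not in const)
    Xdf = features[use]

    med = np.zeros((n_repeats, len(use)))
    hit = np.zeros((n_repeats, len(use)))
    votes = np.zeros((n_repeats, len(use)), dtype=object)
    root = np.random.SeedSequence(seed)
    for rep, ss in enumerate(root.spawn(n_repeats)):
        rng = np.random.default_rng(ss)
        med[rep], hit[rep], votes[rep] = _one_screen(
            Xdf, y, rng, n_trees, max_rounds, alpha, n_perm_repeats
        )

    def majority(v):
        vals, counts = np.unique(v.astype(str), return_counts=True)
        return vals[np.argmax(counts)]

    rows = [
        {
            "predictor": c,
            "median_importance": float(np.median(med[:, j])),
            "hit_fraction": float(np.mean(hit[:, j])),
            "decision": majority(votes[:, j]),
        }
        for j, c in enumerate(use)
    ]
    rows += [
        {
            "predictor": c,
            "median_importance": 0.0,
            "hit_fraction": 0.0,
            "decision": "rejected (constant)",
        }
        for c in const
    ]
    table = (
        pd.DataFrame(rows)
        .sort_values("median_importance", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return ImportanceRanking(table=table, n_repeats=n_repeats, seed=seed)


#: Tuning dimensions: split feature count, leaf size, split rule.
DEFAULT_GRID = {
    "max_features": [1, "sqrt", 1.0],
    "min_samples_leaf": [1, 5, 10],
    "criterion": ["squared_error", "absolute_error"],
}

#: Reduced grid (squared-error splits only) for time-constrained runs.
FAST_GRID = {
    "max_features": [1, "sqrt", 1.0],
    "min_samples_leaf": [1, 5, 10],
}


@dataclass
class EnsemblePerformance:
    summary: pd.DataFrame  # mean/sd/min/max of r2, rmse, mae over outer splits
    best_params: dict
    n_outer_splits: int
    seed: int
    per_split: pd.DataFrame


def evaluate_ensemble(
    features: pd.DataFrame,
    param_grid: dict | None = None,
    cv_folds: int = 3,
    cv_repeats: int = 30,
    n_outer_splits: int = 300,
    n_trees: int = 2000,
    seed: int = 0,
) -> EnsemblePerformance:
    """Tuned random-forest regression over repeated train/test splits.

    Hyperparameters (split feature count, split rule, leaf size) are tuned
    once by cross-validated RMSE on the first training half, then the
    tuned forest is refitted and scored on ``n_outer_splits`` random 50:50
    splits.  Reproducible given ``seed``.
    """
    param_grid = param_grid if param_grid is not None else DEFAULT_GRID
    if not param_grid or not any(len(v) for v in param_grid.values()):
        raise ValueError("degenerate (empty) tuning grid")
    y = features["response"].to_numpy(float)
    X = features[[c for c in features.columns if c != "response"]].to_numpy(float)
    if len(y) < 100:
        raise ValueError("need >= 100 samples to evaluate the ensemble")
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_outer_splits + 2)]

    Xtr, _, ytr, _ = train_test_split(X, y, test_size=0.5, random_state=seeds[0])
    cv = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seeds[1])
    search = GridSearchCV(
        RandomForestRegressor(n_estimators=n_trees, random_state=seeds[1], n_jobs=1),
        param_grid,
        scoring="neg_root_mean_squared_error",
        cv=cv,
        n_jobs=1,
    ).fit(Xtr, ytr)
    best = search.best_params_

    recs = []
    for i in range(n_outer_splits):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.5, random_state=seeds[i + 2]
        )
        rf = RandomForestRegressor(
            n_estimators=n_trees, random_state=seeds[i + 2], n_jobs=1, **best
        ).fit(Xtr, ytr)
        recs.append(goodness_metrics(yte, rf.predict(Xte)))
    per_split = pd.DataFrame(recs)
    summary = pd.DataFrame(
        {
            "mean": per_split.mean(),
            "sd": per_split.std(ddof=1),
            "min": per_split.min(),
            "max": per_split.max(),
        }
    )
    return EnsemblePerformance(
        summary=summary,
        best_params=best,
        n_outer_splits=n_outer_splits,
        seed=seed,
        per_split=per_split,
    )
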