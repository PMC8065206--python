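"""Data model, CSV ingest, response transform, LET binning, predictor screen.

One record is one novel-object-recognition test of one rat: the ion species
and beam energy it was exposed to, the LET and absorbed dose, months since
exposure, and the fraction of exploration time spent at the novel object
(``f_nov``).  Processing adds the modeled response ``-ln(f_nov)`` and a
categorical LET bin (L/M/H/VH, or SHAM for 0 Gy controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import SHAM

#: Required input CSV columns, in canonical order.
INPUT_COLUMNS = (
    "subject_id",
    "ion",
    "energy_mev_n",
    "let_kev_um",
    "dose_gy",
    "time_months",
    "f_nov",
)

#: Columns added by processing.
DERIVED_COLUMNS = ("response", "let_category")


class SchemaError(ValueError):
    """Input table is missing required columns."""


class DomainError(ValueError):
    """A value lies outside its allowed domain."""


class LetBinError(ValueError):
    """Nonzero-dose record whose LET falls outside every bin."""


@dataclass(frozen=True)
class LetBinning:
    """Ordered, non-overlapping LET ranges in keV/um.

    ``ranges`` maps each category label to an ``(lo, hi)`` pair.  With
    ``half_open`` the upper bound is exclusive (used by the permissive
    binning that covers arbitrary simulated LETs); otherwise both bounds
    are inclusive (the exact bins listed for the source study design).
    """

    ranges: tuple[tuple[str, float, float], ...]
    half_open: bool = False

    def __post_init__(self):
        spans = sorted((lo, hi) for _, lo, hi in self.ranges)
        for (_, h1), (l2, _) in zip(spans, spans[1:]):
            if l2 < h1 or (not self.half_open and l2 <= h1):
                raise ValueError("LET ranges overlap")

    def category_of(self, let: float) -> str | None:
        for label, lo, hi in self.ranges:
            if self.half_open:
                if lo <= let < hi:
                    return label
            elif lo <= let <= hi:
                return label
        return None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.ranges)


#: Exact bins: only the LET values present in the emulated study design.
EXACT_BINNING = LetBinning(
    ranges=(
        ("L", 0.22, 0.22),
        ("M", 13.0, 16.0),
        ("H", 41.0, 50.0),
        ("VH", 106.0, 181.0),
    )
)

#: Permissive bins: contiguous intervals so any simulated LET is assignable.
PERMISSIVE_BINNING = LetBinning(
    ranges=(
        ("L", 0.0, 5.0),
        ("M", 5.0, 30.0),
        ("H", 30.0, 80.0),
        ("VH", 80.0, math.inf),
    ),
    half_open=True,
)

BINNINGS = {"exact": EXACT_BINNING, "permissive": PERMISSIVE_BINNING}


def transform_response(f_nov):
    """Response transform ``-ln(f_nov)``.

    ``f_nov`` is the fraction of exploration time at the novel object, in
    (0, 1]; the transform maps it to a non-negative response that grows
    with the severity of the recognition deficit.
    """
    f = np.asarray(f_nov, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0) or np.any(f > 1):
        bad = np.atleast_1d(f)
        idx = np.flatnonzero(~((bad > 0) & (bad <= 1)))
        raise DomainError(
            f"f_nov must lie in (0, 1]; offending values at positions "
            f"{idx.tolist()}: {bad[idx].tolist()}"
        )
    out = -np.log(f)
    return float(out) if np.isscalar(f_nov) else out


def bin_let(let: float, dose: float, binning: LetBinning = EXACT_BINNING) -> str:
    """LET category of a record; SHAM for 0 Gy regardless of LET."""
    if let < 0:
        raise DomainError(f"LET must be >= 0, got {let}")
    if dose == 0:
        return SHAM
    cat = binning.category_of(let)
    if cat is None:
        raise LetBinError(
            f"LET {let} keV/um (dose {dose} Gy) falls outside every bin "
            f"of {binning.ranges}"
        )
    return cat


@dataclass
class IngestResult:
    """Accepted samples plus a per-row rejection log."""

    samples: pd.DataFrame
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.samples)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def process_records(
    df: pd.DataFrame,
    binning: LetBinning = EXACT_BINNING,
    clip_f_nov: bool = False,
    epsilon: float = 1e-3,
) -> IngestResult:
    """Validate raw records and derive response and LET category.

    Every input row is either accepted as a processed sample or reported in
    the rejection log with a reason; the two counts always sum to the input
    row count.  ``f_nov`` values of 0 ("never explored the novel object")
    make the log transform infinite: by default such rows are rejected, or
    clipped up to ``epsilon`` when ``clip_f_nov`` is set.
    """
    missing = [c for c in INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    df = df.loc[:, list(INPUT_COLUMNS)].copy()
    numeric = ["energy_mev_n", "let_kev_um", "dose_gy", "time_months", "f_nov"]
    raw_na = {c: df[c].isna() for c in numeric}
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    rejections: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)

    def reject(mask: pd.Series, reason: str):
        nonlocal keep
        mask = np.asarray(mask, dtype=bool) & keep
        for pos in np.flatnonzero(mask):
            rejections.append((int(df.index[pos]), reason))
        keep &= ~mask

    for c in ("let_kev_um", "dose_gy", "time_months", "f_nov"):
        reject(df[c].isna() & ~raw_na[c], f"unparseable numeric in {c}")
        reject(df[c].isna() & raw_na[c], f"missing value in {c}")
    # energy may be missing only for sham rows
    reject(
        df["energy_mev_n"].isna() & ~raw_na["energy_mev_n"],
        "unparseable numeric in energy_mev_n",
    )
    reject(
        df["energy_mev_n"].isna() & (df["dose_gy"] > 0),
        "missing energy for irradiated record",
    )
    reject(df["dose_gy"] < 0, "negative dose")
    reject(df["let_kev_um"] < 0, "negative LET")
    reject(df["time_months"] < 0, "negative time since exposure")

    if clip_f_nov:
        df["f_nov"] = df["f_nov"].clip(lower=epsilon)
    reject(df["f_nov"] <= 0, "f_nov <= 0 (novel object never explored)")
    reject(df["f_nov"] > 1, "f_nov > 1")

    cats = np.full(len(df), "", dtype=object)
    for pos in np.flatnonzero(keep):
        row = df.iloc[pos]
        try:
            cats[pos] = bin_let(row["let_kev_um"], row["dose_gy"], binning)
        except LetBinError as e:
            rejections.append((int(df.index[pos]), str(e)))
            keep[pos] = False

    out = df.loc[keep].copy()
    out["response"] = transform_response(out["f_nov"].to_numpy())
    out["let_category"] = cats[keep]
    out = out.reset_index(drop=True)
    return IngestResult(samples=out, rejections=sorted(rejections))


def ingest(
    path,
    binning: LetBinning = EXACT_BINNING,
    clip_f_nov: bool = False,
    epsilon: float = 1e-3,
) -> IngestResult:
    """Read the per-test CSV and return processed samples + rejection log.

    The file must carry the header columns ``subject_id, ion, energy_mev_n,
    let_kev_um, dose_gy, time_months, f_nov``; extra columns (e.g. from a
    previously exported processed table) are ignored.
    """
    df = pd.read_csv(path)
    return process_records(df, binning=binning, clip_f_nov=clip_f_nov, epsilon=epsilon)


def export(samples: pd.DataFrame, path) -> None:
    """Write a processed table; round-trips through :func:`ingest`."""
    cols = [c for c in (*INPUT_COLUMNS, *DERIVED_COLUMNS) if c in samples.columns]
    samples.loc[:, cols].to_csv(path, index=False)


def screen_predictors(
    samples: pd.DataFrame, predictors=("dose_gy", "let_kev_um", "time_months")
) -> pd.DataFrame:
    """Spearman rank correlation of each candidate predictor with response.

    Rank correlation is invariant under strictly monotone transforms, so
    this screen is agnostic to the functional form of any dose or LET
    dependence.  A constant predictor has no defined rank correlation and
    is reported with ``rho = NaN`` and a note.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to screen predictors")
    y = samples["response"].to_numpy()
    rows = []
    for p in predictors:
        x = samples[p].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append((p, np.nan, np.nan, "constant predictor; rho undefined"))
            continue
        rho, pval = stats.spearmanr(x, y)
        rows.append((p, float(rho), float(pval), ""))
    return pd.DataFrame(rows, columns=["predictor", "rho", "p_value", "note"])
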