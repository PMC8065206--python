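"""Synthetic novel-object-recognition datasets with known generative truth.

The generator emulates the design of a multi-ion rat irradiation study:
sham controls plus four LET categories (protons at 0.22 keV/um up to Fe
ions near 181 keV/um), doses spanning 0.001-2 Gy, one or two behavioral
tests per rat at different times since exposure, a Gaussian per-rat
baseline shift, and additive Gaussian noise on the log-transformed response
scale with optional gross-outlier contamination.

The latent response of rat ``i`` at dose ``D`` in LET category ``c`` is

    R = B + b_i + kNTE * (1 - exp(-kNTE_r * D)) + TE(D, c) + eps,

with ``b_i ~ N(0, rat_sd)``, ``eps ~ N(0, noise_sd)``, and TE either
``slope_c * D`` or ``slope_c * D^2``.  Draws with negative latent response
are resampled (the response scale is non-negative by construction), and
the observed fraction is ``f_nov = exp(-R)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import data as _data
from .models import DEFAULT_K_NTE_R, ModelSpec, build_model, nte_fraction

#: One ion per LET category, (ion, beam energy MeV/n, LET keV/um).
DEFAULT_IONS = {
    "L": ("H", 1000.0, 0.22),
    "M": ("O", 600.0, 16.0),
    "H": ("Si", 600.0, 44.0),
    "VH": ("Fe", 600.0, 181.0),
}

#: Dose levels (Gy) of the emulated design, including sham.
DEFAULT_DOSES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0)

#: Test times in months since exposure.
DEFAULT_TIMES = (3.0, 9.0)


@dataclass(frozen=True)
class DesignCell:
    """One exposure group: ``n_rats`` rats, each tested at each time."""

    ion: str
    energy: float
    let: float
    dose: float
    n_rats: int
    times: tuple[float, ...] = DEFAULT_TIMES


def default_design(
    n_rats_per_cell: int = 12, n_sham_rats: int = 30
) -> tuple[DesignCell, ...]:
    """Four-category, nine-dose design totalling ~920 tests.

    36 irradiated cells x 12 rats x 2 tests + 30 sham rats x 2 tests
    = 924 samples, matching the scale of the emulated study.
    """
    cells = [DesignCell("sham", 0.0, 0.0, 0.0, n_sham_rats)]
    for cat in ("L", "M", "H", "VH"):
        ion, energy, let = DEFAULT_IONS[cat]
        for dose in DEFAULT_DOSES:
            cells.append(DesignCell(ion, energy, let, dose, n_rats_per_cell))
    return tuple(cells)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative truth plus experimental design.

    Defaults reproduce the fitted dose response of the emulated study: a
    baseline of 0.424 response units, an NTE plateau of 0.166 reached
    below ~0.01 Gy, linear TE slopes of 0.027/Gy shared by the L, M and H
    LET categories and 0.127/Gy for VH, residual noise SD 0.24 (matching
    the observed residual RMSE) and a between-rat baseline SD of 0.073.
    """

    baseline_b: float = 0.424
    k_nte: float = 0.166
    k_nte_r: float = DEFAULT_K_NTE_R
    te_form: str = "linear"
    te_slopes: dict = field(
        default_factory=lambda: {"L": 0.027, "M": 0.027, "H": 0.027, "VH": 0.127}
    )
    noise_sd: float = 0.24
    rat_sd: float = 0.073
    contamination_fraction: float = 0.0
    contamination_shift: float = 1.0
    design: tuple[DesignCell, ...] = field(default_factory=default_design)
    binning: str = "permissive"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.contamination_fraction < 0.5:
            raise ValueError("contamination_fraction must be in [0, 0.5)")
        if self.te_form not in ("linear", "quadratic"):
            raise ValueError("te_form must be 'linear' or 'quadratic'")
        binning = _data.BINNINGS[self.binning]
        for cell in self.design:
            if cell.dose > 0 and binning.category_of(cell.let) is None:
                raise ValueError(
                    f"design LET {cell.let} not assignable under "
                    f"{self.binning} binning"
                )

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def latent_mean(config: SyntheticConfig, dose: float, category: str) -> float:
    """Noise-free population-mean response at (dose, LET category)."""
    r = config.baseline_b + config.k_nte * nte_fraction(dose, config.k_nte_r)
    if category in config.te_slopes:
        d = dose if config.te_form == "linear" else dose**2
        r += config.te_slopes[category] * d
    return r


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one dataset; identical config (incl. seed) gives identical output.

    Returns a raw per-test table with the same schema as the ingest CSV.
    A draw whose latent response falls below zero is censored at the
    boundary (the rat spends all its exploration time at the novel object,
    ``f_nov = 1``); the censoring count is recorded in
    ``DataFrame.attrs['n_censored']``.  Resampling the draw instead would
    shift every boundary-adjacent group mean by the full truncated-tail
    mean (~0.02 response units at the default baseline), breaking the
    generator's mean contracts; censoring perturbs the mean by an order of
    magnitude less and mirrors what the assay itself records.
    """
    rng = np.random.default_rng(config.seed)
    binning = _data.BINNINGS[config.binning]
    rows = []
    n_censored = 0
    rat_counter = 0
    for cell in config.design:
        category = _data.bin_let(cell.let, cell.dose, binning)
        mu = latent_mean(config, cell.dose, category)
        for _ in range(cell.n_rats):
            rat_counter += 1
            rat_id = f"rat{rat_counter:04d}"
            b_i = rng.normal(0.0, config.rat_sd) if config.rat_sd > 0 else 0.0
            for t in cell.times:
                latent = mu + b_i + rng.normal(0.0, config.noise_sd)
                if latent < 0:
                    n_censored += 1
                    latent = 0.0
                if (
                    config.contamination_fraction > 0
                    and rng.random() < config.contamination_fraction
                ):
                    latent += config.contamination_shift
                f_nov = min(float(np.exp(-latent)), 1.0)
                rows.append(
                    (
                        rat_id,
                        cell.ion,
                        cell.energy if cell.dose > 0 else np.nan,
                        cell.let,
                        cell.dose,
                        t,
                        f_nov,
                    )
                )
    df = pd.DataFrame(rows, columns=list(_data.INPUT_COLUMNS))
    df.attrs["n_censored"] = n_censored
    return df


def generate_processed(config: SyntheticConfig) -> pd.DataFrame:
    """Generate and run through the standard processing step."""
    raw = generate(config)
    result = _data.process_records(raw, binning=_data.BINNINGS[config.binning])
    if result.n_rejected:
        raise AssertionError(
            f"synthetic data should never be rejected: {result.rejections[:5]}"
        )
    return result.samples


class UnsupportedConfigError(ValueError):
    """Generative structure has no matching registered model variant."""


def truth_of(config: SyntheticConfig) -> tuple[ModelSpec, dict]:
    """Registered model variant matching the generative truth, with params.

    Categories with zero TE slope are treated as excluded; categories
    sharing one slope value form one slope group.  Raises
    :class:`UnsupportedConfigError` when no registered variant has that
    structure (e.g. a grouping the registry does not enumerate).
    """
    slopes = {c: s for c, s in config.te_slopes.items() if s != 0.0}
    groups: dict[float, list[str]] = {}
    for c in ("L", "M", "H", "VH"):
        if c in slopes:
            groups.setdefault(slopes[c], []).append(c)
    partition = tuple(
        tuple(g) for g in sorted(groups.values(), key=lambda g: ("LMHV".index(g[0][0])))
    )
    has_nte = config.k_nte != 0.0
    form = "none" if not partition else config.te_form
    from .models import MODEL_REGISTRY

    for spec in MODEL_REGISTRY.values():
        if spec.nte_by_let:
            continue
        if (
            spec.has_nte == has_nte
            and spec.te_form == form
            and spec.te_grouping == partition
        ):
            params = {"B": config.baseline_b}
            if has_nte:
                params["kNTE"] = config.k_nte
            for name, group in zip(spec.parameter_names[1 + has_nte :], partition):
                params[name] = slopes[group[0]]
            return spec, params
    raise UnsupportedConfigError(
        f"no registered variant matches NTE={has_nte}, form={form}, "
        f"grouping={partition}"
    )


def config_to_yaml(config: SyntheticConfig, path) -> None:
    import yaml

    d = config.to_dict()
    d["design"] = [asdict(c) if not isinstance(c, dict) else c for c in config.design]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "design" in d and d["design"]:
        d["design"] = tuple(
            DesignCell(**{**c, "times": tuple(c.get("times", DEFAULT_TIMES))})
            for c in d["design"]
        )
    return SyntheticConfig(**d)
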