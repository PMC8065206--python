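"""Dose-response model family combining targeted and non-targeted effects.

The response modeled here is ``R = -ln(F_nov)``, the negative log of the
fraction of exploration time a rat spends at the novel object.  Every model
variant decomposes the dose response into an additive baseline ``B``, an
optional saturating non-targeted-effect (NTE) term, and optional
targeted-effect (TE) terms that are linear or quadratic in dose:

    R(D) = B + kNTE * (1 - exp(-kNTE_r * D)) + sum_g kTE_g * D^q * 1[cat in g]

with ``q = 1`` (linear) or ``q = 2`` (quadratic) and ``g`` ranging over
groups of LET categories that share one TE slope.  The NTE rise constant
``kNTE_r`` is fixed at 1e3 / Gy, which makes the NTE term saturate below
~0.01 Gy while keeping the model a smooth function of dose.

Eighteen named variants are registered; they differ in whether the NTE term
is present (and, for one variant, LET-category specific), whether TE is
linear or quadratic, and how LET categories are grouped or excluded from
the TE term.  Because ``kNTE_r`` is fixed, every variant is linear in its
free parameters; :meth:`ModelSpec.design_matrix` exposes that structure and
doubles as the exact Jacobian for the fitting engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Ordered LET category labels for irradiated samples.
CATEGORIES: tuple[str, ...] = ("L", "M", "H", "VH")

#: Label used for unirradiated (0 Gy) control samples.
SHAM = "SHAM"

#: Fixed NTE "rise" rate constant, 1/Gy.
DEFAULT_K_NTE_R = 1.0e3


def nte_fraction(dose, k_nte_r: float = DEFAULT_K_NTE_R):
    """Saturating NTE dose dependence ``1 - exp(-k_nte_r * D)``.

    Parameters
    ----------
    dose
        Absorbed dose in Gy, scalar or array, >= 0.
    k_nte_r
        Rise rate constant in 1/Gy.

    Returns
    -------
    Fraction of the NTE plateau reached at ``dose``; in ``[0, 1)``,
    strictly increasing in dose.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = -np.expm1(-k_nte_r * d)
    return float(out) if np.isscalar(dose) else out


class UnknownModelError(KeyError):
    """Raised for a model label not in the registry."""


@dataclass(frozen=True)
class ModelSpec:
    """One registered dose-response variant.

    Attributes
    ----------
    name
        Registry label, e.g. ``"NTE_TE_lin_S2"``.
    has_nte
        Whether the saturating NTE term is present.
    nte_by_let
        Whether the NTE plateau is LET-category specific (one variant only).
    te_form
        ``"none"``, ``"linear"`` or ``"quadratic"``.
    te_grouping
        Partition of a subset of :data:`CATEGORIES` into groups sharing one
        TE slope.  Categories absent from every group have their slope
        fixed at zero.
    """

    name: str
    has_nte: bool
    nte_by_let: bool
    te_form: str
    te_grouping: tuple[tuple[str, ...], ...]
    equation: str = field(default="", compare=False)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = ["B"]
        if self.has_nte:
            if self.nte_by_let:
                names += [f"kNTE_{c}" for c in CATEGORIES]
            else:
                names.append("kNTE")
        if self.te_form != "none":
            if self.te_grouping == (CATEGORIES,):
                names.append("kTE")
            else:
                names += ["kTE_" + "".join(g) for g in self.te_grouping]
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of free regression parameters."""
        return len(self.parameter_names)

    def design_matrix(
        self,
        dose: np.ndarray,
        let_category: Sequence[str],
        k_nte_r: float = DEFAULT_K_NTE_R,
    ) -> np.ndarray:
        """Matrix ``X`` with ``predict = X @ params``; also the Jacobian."""
        d = np.asarray(dose, dtype=float)
        cat = np.asarray(let_category, dtype=object)
        cols = [np.ones_like(d)]
        if self.has_nte:
            ntef = nte_fraction(d, k_nte_r)
            if self.nte_by_let:
                for c in CATEGORIES:
                    cols.append(ntef * (cat == c))
            else:
                cols.append(ntef)
        if self.te_form != "none":
            dpow = d if self.te_form == "linear" else d**2
            for g in self.te_grouping:
                cols.append(dpow * np.isin(cat, g))
        return np.column_stack(cols)

    def predict(
        self,
        params,
        dose,
        let_category,
        k_nte_r: float = DEFAULT_K_NTE_R,
    ):
        """Predicted response for ``params`` at (dose, LET category).

        ``params`` may be a mapping keyed by :attr:`parameter_names` or an
        ordered sequence.  SHAM samples necessarily have dose 0 and receive
        the baseline ``B``.
        """
        theta = self.coerce_params(params)
        scalar = np.isscalar(dose)
        d = np.atleast_1d(np.asarray(dose, dtype=float))
        cat = np.atleast_1d(np.asarray(let_category, dtype=object))
        if cat.size == 1 and d.size > 1:
            cat = np.repeat(cat, d.size)
        out = self.design_matrix(d, cat, k_nte_r) @ theta
        return float(out[0]) if scalar else out

    def coerce_params(self, params) -> np.ndarray:
        names = self.parameter_names
        if isinstance(params, Mapping):
            missing = set(names) - set(params)
            extra = set(params) - set(names)
            if missing or extra:
                raise ValueError(
                    f"parameter mismatch for {self.name}: "
                    f"missing {sorted(missing)}, unexpected {sorted(extra)}"
                )
            return np.array([float(params[n]) for n in names])
        theta = np.asarray(params, dtype=float)
        if theta.shape != (len(names),):
            raise ValueError(
                f"{self.name} expects {len(names)} parameters {names}, "
                f"got shape {theta.shape}"
            )
        return theta


def _eq(has_nte, nte_by_let, form, grouping):
    parts = ["B"]
    if has_nte:
        if nte_by_let:
            parts.append("sum_i kNTE_i * (1 - exp[-1e3 * D_i])")
        else:
            parts.append("kNTE * (1 - exp[-1e3 * D])")
    if form != "none":
        p = "D" if form == "linear" else "D^2"
        if grouping == (CATEGORIES,):
            parts.append(f"kTE * {p}")
        else:
            idx = ",".join("".join(g) for g in grouping)
            parts.append(f"sum_(i={idx}) kTE_i * {p}_i")
    return "R = " + " + ".join(parts)


def _make(name, has_nte, nte_by_let, form, grouping):
    grouping = tuple(tuple(g) for g in grouping)
    return ModelSpec(
        name=name,
        has_nte=has_nte,
        nte_by_let=nte_by_let,
        te_form=form,
        te_grouping=grouping,
        equation=_eq(has_nte, nte_by_let, form, grouping),
    )


_PER_CAT = tuple((c,) for c in CATEGORIES)
_ALL = (CATEGORIES,)
_S1 = (("L", "M"), ("H",), ("VH",))
_S2 = (("L", "M", "H"), ("VH",))
_S3 = (("H",), ("VH",))
_S4 = (("VH",),)

MODEL_REGISTRY: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _make("TE_lin", False, False, "linear", _PER_CAT),
        _make("TE_quad", False, False, "quadratic", _PER_CAT),
        _make("NTE", True, True, "none", ()),
        _make("TE_lin_noLET", False, False, "linear", _ALL),
        _make("TE_quad_noLET", False, False, "quadratic", _ALL),
        _make("NTE_noLET", True, False, "none", ()),
        _make("NTE_TE_lin_noLET", True, False, "linear", _ALL),
        _make("NTE_TE_quad_noLET", True, False, "quadratic", _ALL),
        _make("NTE_TE_lin", True, False, "linear", _PER_CAT),
        _make("NTE_TE_lin_S1", True, False, "linear", _S1),
        _make("NTE_TE_lin_S2", True, False, "linear", _S2),
        _make("NTE_TE_lin_S3", True, False, "linear", _S3),
        _make("NTE_TE_lin_S4", True, False, "linear", _S4),
        _make("NTE_TE_quad", True, False, "quadratic", _PER_CAT),
        _make("NTE_TE_quad_S1", True, False, "quadratic", _S1),
        _make("NTE_TE_quad_S2", True, False, "quadratic", _S2),
        _make("NTE_TE_quad_S3", True, False, "quadratic", _S3),
        _make("NTE_TE_quad_S4", True, False, "quadratic", _S4),
    ]
}


def build_model(name: str) -> ModelSpec:
    """Look up a registered variant by label."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {name!r}; valid names: {sorted(MODEL_REGISTRY)}"
        ) from None


def list_models() -> list[str]:
    return list(MODEL_REGISTRY)
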