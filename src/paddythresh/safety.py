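"""Safety-threshold derivation: invert a transfer model at the grain limit.

The safety threshold (ST) for an element in a pH bin is the soil total
concentration at which the fitted transfer model predicts the grain
concentration to equal the food-standard MAC, with every other covariate
held at its regional mean and pH at the bin's representative value (7.0
for the neutral bin, 8.0 for the alkaline bin).

When the soil total appears only through its own log10 term the inversion
is closed-form; when an auxiliary relation ties an available fraction to
the soil total (so the total appears in two terms) a bracketed root finder
on lg(soil total) is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    AVAILABLE_COLUMNS,
    OXIDE_FRACTIONS,
    PH_BINS,
    SOIL_TOTAL_COLUMNS,
    Dataset,
    DomainError,
    PhBin,
    RegulatoryLimits,
    SchemaError,
)
from .regression import TransferModel, linear_predictor


class InversionError(RuntimeError):
    """The root finder could not bracket the grain limit."""


@dataclass(frozen=True)
class CovariateMeans:
    """Regional means used to fix non-target covariates during inversion."""

    som: float
    oxides: dict[str, float]

    def __post_init__(self) -> None:
        if self.som <= 0 or any(v <= 0 for v in self.oxides.values()):
            raise ValueError("covariate means must be positive")

    def as_map(self) -> dict[str, float]:
        return {"SOM": self.som, **self.oxides}


@dataclass(frozen=True)
class AuxiliaryRelation:
    """Linear tie of an available fraction to the soil total (linear scale).

    available = slope · soil_total + intercept, substituted before the
    model's log10 of the available fraction is taken.
    """

    response: str  # e.g. "A_As"
    slope: float
    intercept: float
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def __call__(self, soil_total):
        return self.slope * np.asarray(soil_total, dtype=float) + self.intercept


@dataclass
class ThresholdSet:
    """Derived thresholds for one element in one pH bin, with provenance."""

    element: str
    ph_bin: str
    st: float | None = None
    hc95_inv_bcf: float | None = None
    ht: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.st is not None and self.st <= 0:
            raise ValueError("st must be positive")

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "ph_bin": self.ph_bin,
            "st": self.st,
            "hc95_inv_bcf": self.hc95_inv_bcf,
            "ht": self.ht,
            "provenance": self.provenance,
        }


def means_from_data(dataset: Dataset | pd.DataFrame) -> CovariateMeans:
    """Study-wide covariate means from a paired table."""
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    return CovariateMeans(
        som=float(frame["SOM"].mean()),
        oxides={f: float(frame[f].mean()) for f in OXIDE_FRACTIONS},
    )


def _fixed_covariates(
    model: TransferModel, ph_bin: PhBin, means: CovariateMeans
) -> dict[str, float]:
    cov = {"pH": ph_bin.representative_pH, **means.as_map()}
    soil_col = SOIL_TOTAL_COLUMNS[model.element]
    missing = [
        t.predictor
        for t in model.terms
        if t.predictor not in cov
        and t.predictor != soil_col
        and t.predictor != AVAILABLE_COLUMNS[model.element]
    ]
    if missing:
        raise SchemaError(f"no covariate mean supplied for predictors: {missing}")
    return cov


def _model_lg_prediction(
    model: TransferModel,
    lg_x: float,
    cov: dict[str, float],
    aux: AuxiliaryRelation | None,
):
    x = 10.0 ** lg_x
    data = dict(cov)
    data[SOIL_TOTAL_COLUMNS[model.element]] = x
    avail_col = AVAILABLE_COLUMNS[model.element]
    if avail_col in model.predictors:
        a = float(aux(x))
        if a <= 0:
            raise DomainError(
                f"auxiliary relation gives non-positive {avail_col} at soil total {x:g}"
            )
        data[avail_col] = a
    return float(linear_predictor(model, data))


def invert_for_st(
    model: TransferModel,
    limits: RegulatoryLimits,
    ph_bin: PhBin,
    means: CovariateMeans,
    aux: AuxiliaryRelation | None = None,
    bracket: tuple[float, float] = (-2.0, 4.0),
    method: str = "auto",
) -> float:
    """Soil total (mg·kg⁻¹) at which the model predicts grain = MAC.

    ``method`` is "auto" (closed form when the soil total appears in exactly
    one term, else root finding), "closed_form", or "root_finding". The
    bracket is on lg(soil total); the default (−2, 4) spans 0.01–10,000
    mg·kg⁻¹.
    """
    soil_col = SOIL_TOTAL_COLUMNS[model.element]
    avail_col = AVAILABLE_COLUMNS[model.element]
    if soil_col not in model.predictors:
        raise SchemaError(f"model has no soil-total term {soil_col!r}")
    a_total = model.coefficient(soil_col)
    if a_total == 0:
        raise InversionError("soil-total coefficient is zero; model not invertible")
    needs_aux = avail_col in model.predictors
    if needs_aux and aux is None:
        raise SchemaError(
            f"model references {avail_col!r}; an AuxiliaryRelation is required"
        )
    cov = _fixed_covariates(model, ph_bin, means)
    lg_mac = np.log10(limits.mac)

    if method == "auto":
        method = "root_finding" if needs_aux else "closed_form"
    if method == "closed_form":
        if needs_aux:
            raise ValueError("closed form unavailable: soil total enters two terms")
        # lg(x*) = (lg MAC − intercept − Σ other terms) / a_total
        other = model.intercept + sum(
            t.coefficient
            * (np.log10(cov[t.predictor]) if t.transform == "log10" else cov[t.predictor])
            for t in model.terms
            if t.predictor != soil_col
        )
        lg_st = (lg_mac - other) / a_total
    else:
        lo, hi = bracket
        if needs_aux and aux.slope > 0 and aux.intercept < 0:
            # available fraction positive only above x = -intercept/slope
            lo = max(lo, float(np.log10(-aux.intercept / aux.slope)) + 1e-9)
        f = lambda lg_x: _model_lg_prediction(model, lg_x, cov, aux) - lg_mac
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            grid = np.linspace(lo, hi, 25)
            curve = [(g, f(g)) for g in grid]
            raise InversionError(
                "no sign change in bracket "
                f"[{lo:.3f}, {hi:.3f}]; lg-residual curve: {curve}"
            )
        lg_st = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)

    st = float(10.0 ** lg_st)
    achieved = _model_lg_prediction(model, lg_st, cov, aux if needs_aux else None)
    if abs(achieved - lg_mac) > 1e-10:
        raise InversionError(
            f"round-trip failed: |lg prediction − lg MAC| = {abs(achieved - lg_mac):g}"
        )
    return st


def derive_st_table(
    models: dict[str, TransferModel],
    limits: dict[tuple[str, str], RegulatoryLimits],
    means: CovariateMeans,
    aux: AuxiliaryRelation | None = None,
    bins: tuple[PhBin, ...] = PH_BINS,
) -> list[ThresholdSet]:
    """One ThresholdSet per element × pH bin, deterministic order."""
    out = []
    for element, model in models.items():
        for ph_bin in bins:
            lim = limits[(element, ph_bin.label)]
            st = invert_for_st(model, lim, ph_bin, means, aux=aux)
            out.append(
                ThresholdSet(
                    element=element,
                    ph_bin=ph_bin.label,
                    st=st,
                    provenance={
                        "model_n_fit": model.n_fit,
                        "mac": lim.mac,
                        "representative_pH": ph_bin.representative_pH,
                        "som_mean": means.som,
                    },
                )
            )
    return out
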