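"""Hazard thresholds from a logistic sensitivity distribution over 1/BCF.

The bioconcentration factor BCF = C_rice / C_soil measures how strongly a
site's rice enriches a metal from its soil; its reciprocal 1/BCF is the
soil concentration needed per unit grain concentration. Across sites the
empirical cumulative distribution of 1/BCF follows an S-curve fitted here
with a three-parameter logistic,

    y = a / (1 + (x/x0)^b),        x = 1/BCF, y = cumulative percent,

whose exact algebraic inverse is x = 10^(lg(a/y − 1)/b + lg x0). Because y
rises with x, the fitted shape parameter b is negative (the curve with
b > 0 is decreasing); the inversion algebra is sign-agnostic. The hazard
threshold is HT = MAC × HC95, where HC95 is the fitted 95th-percentile
1/BCF: the soil level at which an estimated 95% of rice exceeds the MAC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .core import (
    RICE_COLUMNS,
    SOIL_TOTAL_COLUMNS,
    Dataset,
    DomainError,
)


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge."""


@dataclass(frozen=True)
class BCFRecord:
    site_id: str
    element: str
    bcf: float
    inv_bcf: float
    cumulative_prob: float  # percent, strictly inside (0, 100)

    def __post_init__(self) -> None:
        if self.bcf <= 0:
            raise ValueError("bcf must be positive")
        if not 0 < self.cumulative_prob < 100:
            raise ValueError("cumulative_prob must be in (0, 100)")


@dataclass
class LogisticSSDFit:
    """Fitted logistic sensitivity-distribution curve over 1/BCF."""

    a: float
    b: float
    x0: float
    residual_sse: float
    n_points: int
    converged: bool = True
    element: str | None = None
    ph_bin: str | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.x0 <= 0:
            raise ValueError("require a > 0 and x0 > 0")

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "x0": self.x0,
            "residual_sse": self.residual_sse, "n_points": self.n_points,
            "converged": self.converged, "element": self.element,
            "ph_bin": self.ph_bin,
        }


def logistic_curve(x, a: float, b: float, x0: float):
    """Cumulative percent at 1/BCF value x (defined for x > 0)."""
    x = np.asarray(x, dtype=float)
    return a / (1.0 + (x / x0) ** b)


def compute_bcf(
    dataset: Dataset | pd.DataFrame,
    element: str,
    plotting_position: str = "hazen",
) -> list[BCFRecord]:
    """Per-site BCF records with empirical cumulative percent over 1/BCF.

    BCF is stored as the dimensionless ratio C_rice/C_soil (reporting it as
    a percent is a display convention); inv_bcf = C_soil/C_rice.
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    soil = frame[SOIL_TOTAL_COLUMNS[element]].to_numpy(dtype=float)
    rice = frame[RICE_COLUMNS[element]].to_numpy(dtype=float)
    sites = frame["site_id"].astype(str).to_numpy()
    bad = np.nonzero(soil <= 0)[0]
    if bad.size:
        raise DomainError(
            f"non-positive soil total for sites: {sites[bad].tolist()}"
        )
    bcf = rice / soil
    inv = soil / rice
    probs = _cumulative_percent(inv, plotting_position)
    return [
        BCFRecord(site_id=s, element=element, bcf=float(b), inv_bcf=float(i),
                  cumulative_prob=float(p))
        for s, b, i, p in zip(sites, bcf, inv, probs)
    ]


def _cumulative_percent(values: np.ndarray, plotting_position: str) -> np.ndarray:
    n = len(values)
    ranks = rankdata(values, method="average")
    if plotting_position == "hazen":
        return 100.0 * (ranks - 0.5) / n
    if plotting_position == "weibull":
        return 100.0 * ranks / (n + 1)
    raise ValueError(f"unknown plotting position {plotting_position!r}")


def empirical_cumulative(
    values, plotting_position: str = "hazen"
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (x, cumulative percent) pairs for 1/BCF values.

    Hazen position: y = 100·(rank − 0.5)/n; Weibull: y = 100·rank/(n + 1).
    Ties share their average rank, so tied x get equal y.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values for an empirical distribution")
    y = _cumulative_percent(values, plotting_position)
    order = np.argsort(values, kind="stable")
    return values[order], y[order]


def fit_logistic_ssd(
    x,
    y,
    fix_a: float | None = None,
    element: str | None = None,
    ph_bin: str | None = None,
) -> LogisticSSDFit:
    """Nonlinear least-squares fit of the logistic S-curve to (x, y) points.

    Initialization: a = 100 (the natural asymptote of a cumulative
    percent), x0 = median(x), b = −2 (rising curve). ``fix_a`` pins the
    asymptote, which stabilises small-sample fits whose plateau is not yet
    visible in the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit the logistic SSD")
    if np.any(x <= 0):
        raise DomainError("all x must be positive")
    x0_init = float(np.median(x))
    try:
        if fix_a is None:
            popt, _ = curve_fit(
                logistic_curve, x, y, p0=(100.0, -2.0, x0_init), maxfev=20000
            )
            a, b, x0 = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                lambda xx, b, x0: logistic_curve(xx, fix_a, b, x0),
                x, y, p0=(-2.0, x0_init), maxfev=20000,
            )
            a, (b, x0) = float(fix_a), (float(popt[0]), float(popt[1]))
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"logistic SSD fit did not converge from p0=(a={fix_a or 100}, b=-2, "
            f"x0={x0_init:g}) on {len(x)} points: {exc}"
        ) from exc
    sse = float(np.sum((logistic_curve(x, a, b, x0) - y) ** 2))
    return LogisticSSDFit(
        a=a, b=b, x0=x0, residual_sse=sse, n_points=len(x),
        converged=True, element=element, ph_bin=ph_bin,
    )


def inverse_ssd(fit: LogisticSSDFit, y: float) -> float:
    """1/BCF at cumulative percent ``y``: the exact inverse of the S-curve.

    x = 10^(lg(a/y − 1)/b + lg x0), valid for 0 < y < a.
    """
    if not 0 < y < fit.a:
        raise DomainError(
            f"cumulative percent must be in (0, {fit.a:g}), got {y:g}"
        )
    return float(10.0 ** (np.log10(fit.a / y - 1.0) / fit.b + np.log10(fit.x0)))


def hazard_threshold(mac: float, inv_bcf: float) -> float:
    """HT (mg·kg⁻¹) = MAC × 1/BCF: two-operand product, no hidden rounding."""
    return mac * inv_bcf


def derive_ht(
    fit: LogisticSSDFit | float,
    mac: float,
    protection: float = 95.0,
) -> tuple[float, float]:
    """(HC at the protection percentile, HT = MAC × HC).

    ``fit`` may be a fitted curve — the percentile is then evaluated on the
    fitted curve via the exact inverse — or a reciprocal-BCF quantile
    obtained elsewhere. A fitted asymptote below the protection level makes
    the percentile unattainable: refit with ``fix_a=100`` or gather more
    data in the upper tail.
    """
    if isinstance(fit, LogisticSSDFit):
        if protection >= fit.a:
            raise DomainError(
                f"protection percentile {protection:g} is unattainable: fitted "
                f"asymptote a = {fit.a:g}; consider fix_a=100"
            )
        hc = inverse_ssd(fit, protection)
    else:
        hc = float(fit)
        if hc <= 0:
            raise DomainError("reciprocal BCF quantile must be positive")
    return hc, hazard_threshold(mac, hc)
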