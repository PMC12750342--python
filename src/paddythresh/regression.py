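"""Soil-to-grain transfer models: screening, collinearity control, OLS fit.

The transfer model is a multiple linear regression on the log10 scale,

    lg(C_rice) = c + b·pH + d·SOM + a·lg(C_soil) + Σ e_k·lg(oxide_k),

with pH and SOM entering untransformed and every concentration entering as
its base-10 logarithm. Predictors are screened by the significance of their
Pearson correlation with lg(C_rice); collinear predictors (VIF > 5) are
resolved by preferring the soil-total form over the available form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    AVAILABLE_COLUMNS,
    CONCENTRATION_COLUMNS,
    OXIDE_FRACTIONS,
    RICE_COLUMNS,
    SOIL_TOTAL_COLUMNS,
    Dataset,
    SchemaError,
)

#: Predictors that enter the design untransformed.
RAW_PREDICTORS = ("pH", "SOM")


def predictor_transform(name: str) -> str:
    return "raw" if name in RAW_PREDICTORS else "log10"


@dataclass(frozen=True)
class Term:
    predictor: str
    coefficient: float
    transform: str  # "log10" or "raw"


@dataclass
class TransferModel:
    """A fitted (or specified) log10 transfer model for one element."""

    element: str
    intercept: float
    terms: tuple[Term, ...]
    n_fit: int | None = None
    r: float | None = None
    r2: float | None = None
    adj_r2: float | None = None
    p_value: float | None = None
    vif_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [t.predictor for t in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("duplicate predictor in model terms")
        if self.r2 is not None and self.adj_r2 is not None:
            if self.adj_r2 > self.r2 + 1e-12 or self.r2 > 1 + 1e-12:
                raise ValueError("require adj_r2 <= r2 <= 1")

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(t.predictor for t in self.terms)

    def coefficient(self, predictor: str) -> float:
        for t in self.terms:
            if t.predictor == predictor:
                return t.coefficient
        raise KeyError(predictor)

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "intercept": self.intercept,
            "terms": [
                {"predictor": t.predictor, "coefficient": t.coefficient,
                 "transform": t.transform}
                for t in self.terms
            ],
            "n_fit": self.n_fit,
            "r": self.r,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "p_value": self.p_value,
            "vif_table": self.vif_table,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferModel":
        return cls(
            element=d["element"],
            intercept=float(d["intercept"]),
            terms=tuple(
                Term(t["predictor"], float(t["coefficient"]), t["transform"])
                for t in d["terms"]
            ),
            n_fit=d.get("n_fit"),
            r=d.get("r"),
            r2=d.get("r2"),
            adj_r2=d.get("adj_r2"),
            p_value=d.get("p_value"),
            vif_table=dict(d.get("vif_table") or {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TransferModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ValidationReport:
    """Hold-out performance of a transfer model on the log10 scale."""

    element: str
    n_validation: int
    r2: float
    rmse: float
    pairs: list[tuple[float, float]]  # (predicted, measured), log10 scale

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def _covariate_values(model: TransferModel, data) -> list[np.ndarray]:
    cols = []
    for t in model.terms:
        if isinstance(data, pd.DataFrame):
            if t.predictor not in data.columns:
                raise SchemaError(f"predictor {t.predictor!r} missing from data")
            v = data[t.predictor].to_numpy(dtype=float)
        else:
            try:
                v = np.asarray(float(data[t.predictor]))
            except KeyError as exc:
                raise SchemaError(f"predictor {t.predictor!r} missing") from exc
        if t.transform == "log10":
            if np.any(v <= 0):
                raise ValueError(f"predictor {t.predictor!r} must be > 0 for log10")
            v = np.log10(v)
        cols.append(t.coefficient * v)
    return cols


def linear_predictor(model: TransferModel, data) -> np.ndarray | float:
    """Evaluate the model on the log10 scale for a frame or covariate map."""
    out = model.intercept + sum(_covariate_values(model, data))
    return out


def predict_rice(model: TransferModel, data) -> np.ndarray | float:
    """Predicted grain concentration, mg·kg⁻¹ (10 ** linear predictor)."""
    lp = linear_predictor(model, data)
    return 10.0 ** lp


def candidate_predictors(element: str, frame: pd.DataFrame) -> list[str]:
    """Default candidate set: pH, SOM, soil total/available, oxide fractions."""
    cands = ["pH", "SOM", SOIL_TOTAL_COLUMNS[element], AVAILABLE_COLUMNS[element],
             *OXIDE_FRACTIONS]
    return [c for c in cands if c in frame.columns and frame[c].notna().all()]


def transformed_design(frame: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Predictor table with log10 applied to concentration columns."""
    out = {}
    for p in predictors:
        v = frame[p].to_numpy(dtype=float)
        if predictor_transform(p) == "log10":
            if np.any(v <= 0):
                raise ValueError(f"predictor {p!r} must be > 0 for log10")
            v = np.log10(v)
        out[p] = v
    return pd.DataFrame(out, index=frame.index)


def screen_predictors(
    dataset: Dataset | pd.DataFrame,
    response: str,
    alpha: float = 0.05,
    candidates: Sequence[str] | None = None,
) -> list[str]:
    """Retain predictors significantly correlated with lg(rice) (p < alpha).

    Correlations are Pearson, computed on the transformed scale (log10 for
    concentrations, raw for pH/SOM). Constant columns are excluded with a
    warning rather than an error.
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    if len(frame) < 10:
        raise ValueError("need at least 10 samples to screen predictors")
    if candidates is None:
        candidates = candidate_predictors(response, frame)
    y = np.log10(frame[RICE_COLUMNS[response]].to_numpy(dtype=float))
    design = transformed_design(frame, candidates)
    kept = []
    for p in candidates:
        x = design[p].to_numpy()
        if np.ptp(x) == 0:
            warnings.warn(f"predictor {p!r} is constant; excluded", stacklevel=2)
            continue
        _, pval = stats.pearsonr(x, y)
        if pval < alpha:
            kept.append(p)
    return kept


def compute_vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1/(1 − R²_j).

    R²_j comes from regressing predictor j on the remaining predictors
    (with intercept). Perfect collinearity is reported as ``inf``.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors for VIF")
    if len(design) <= len(cols):
        raise ValueError("need n > p observations for VIF")
    out = {}
    for j, col in enumerate(cols):
        y = design[col].to_numpy(dtype=float)
        X = sm.add_constant(design.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(y, X).fit().rsquared
        out[col] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def resolve_collinearity(
    design: pd.DataFrame,
    vif_threshold: float = 5.0,
    corr_threshold: float = 0.7,
) -> list[str]:
    """Iteratively drop predictors until all VIFs are at most the threshold.

    At each step, among pairs with |r| above ``corr_threshold`` the most
    correlated pair is found; if one member is an available-form metal
    column it is dropped (totals are kept in preference), otherwise the
    member with the higher VIF goes. With no such pair, the single
    highest-VIF predictor is dropped. Ties break by column order, so the
    procedure is deterministic.
    """
    available_forms = set(AVAILABLE_COLUMNS.values())
    kept = list(design.columns)
    while len(kept) > 1:
        vifs = compute_vif(design[kept])
        worst = max(vifs.values())
        if worst <= vif_threshold:
            break
        corr = design[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if corr.values[i, j] > corr_threshold:
            pair = (kept[i], kept[j])
            in_pair_avail = [p for p in pair if p in available_forms]
            if in_pair_avail:
                drop = in_pair_avail[0]
            else:
                drop = max(pair, key=lambda p: (vifs[p], -kept.index(p)))
        else:
            drop = max(kept, key=lambda p: (vifs[p], -kept.index(p)))
        kept.remove(drop)
    return kept


def fit_transfer_model(
    dataset: Dataset | pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    use_split: bool = True,
) -> TransferModel:
    """Ordinary least squares of lg(rice) on the transformed predictors.

    Uses the modeling split when the dataset carries one (and ``use_split``);
    reports R, R², adjusted R², the overall F-test p-value, and per-predictor
    VIFs. A rank-deficient design raises, naming the dependent columns.
    """
    if isinstance(dataset, Dataset):
        frame = dataset.modeling_frame() if (use_split and dataset.split) else dataset.frame
    else:
        frame = dataset
    p = len(predictors)
    n = len(frame)
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    design = transformed_design(frame, predictors)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        vifs = compute_vif(design) if p >= 2 else {}
        dependent = [k for k, v in vifs.items() if np.isinf(v)] or list(predictors)
        raise ValueError(f"singular design; linearly dependent columns: {dependent}")
    y = np.log10(frame[RICE_COLUMNS[response]].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    vif_table = compute_vif(design) if p >= 2 else {predictors[0]: 1.0}
    terms = tuple(
        Term(pred, float(res.params[k + 1]), predictor_transform(pred))
        for k, pred in enumerate(predictors)
    )
    return TransferModel(
        element=response,
        intercept=float(res.params[0]),
        terms=terms,
        n_fit=n,
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.f_pvalue),
        vif_table=vif_table,
    )


def coefficient_conf_ints(
    dataset: Dataset | pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS coefficient confidence intervals (rows: const then predictors)."""
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    design = transformed_design(frame, predictors)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    y = np.log10(frame[RICE_COLUMNS[response]].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=alpha)
    return pd.DataFrame(ci, index=["const", *predictors], columns=["lower", "upper"])


def relative_importance(
    model: TransferModel, dataset: Dataset | pd.DataFrame
) -> dict[str, float]:
    """Percent importance per predictor, max-scaled to 100.

    This is a surrogate measure: the absolute standardized coefficient
    |b_j|·s_xj / s_y, rescaled so the largest equals 100%. Other software
    reports "normalized importance" by unstated algorithms; rankings are
    comparable, exact percentages are not.
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    design = transformed_design(frame, model.predictors)
    y = np.log10(frame[RICE_COLUMNS[model.element]].to_numpy(dtype=float))
    s_y = np.std(y, ddof=1)
    raw = {
        t.predictor: abs(t.coefficient) * np.std(design[t.predictor], ddof=1) / s_y
        for t in model.terms
    }
    top = max(raw.values())
    if top == 0:
        return {k: 0.0 for k in raw}
    return {k: 100.0 * (v / top) for k, v in raw.items()}


def validate_model(model: TransferModel, dataset: Dataset) -> ValidationReport:
    """Score the model on the validation split (log10 scale R² and RMSE)."""
    frame = dataset.validation_frame()
    if len(frame) == 0:
        raise ValueError("validation split is empty")
    predicted = np.asarray(linear_predictor(model, frame), dtype=float)
    measured = np.log10(frame[RICE_COLUMNS[model.element]].to_numpy(dtype=float))
    resid = measured - predicted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ValidationReport(
        element=model.element,
        n_validation=len(frame),
        r2=r2,
        rmse=rmse,
        pairs=list(zip(predicted.tolist(), measured.tolist())),
    )
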