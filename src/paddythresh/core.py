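"""Domain types and tabular I/O for paired soil–rice survey data.

One :class:`PairedSample` is a single field site: soil pH, organic matter
(SOM), total and (optionally) available Cd/As, six Fe/Mn oxide fractions,
and the Cd/As concentration measured in the milled rice grown on that plot.
All concentrations are mg·kg⁻¹ (SOM is g·kg⁻¹) and are stored on the linear
scale; base-10 log transforms are applied on demand by
:func:`log10_columns` and never persisted.

The canonical on-disk representation is a CSV with one row per site and the
columns listed in :data:`ALL_COLUMNS`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

ELEMENTS = ("Cd", "As")
OXIDE_FRACTIONS = ("C_Fe", "F_Fe", "Am_Fe", "C_Mn", "F_Mn", "Am_Mn")
SOIL_TOTAL_COLUMNS = {"Cd": "S_T_Cd", "As": "S_T_As"}
AVAILABLE_COLUMNS = {"Cd": "A_Cd", "As": "A_As"}
RICE_COLUMNS = {"Cd": "Rice_Cd", "As": "Rice_As"}

#: Columns that must be present in any paired table.
REQUIRED_COLUMNS = (
    "site_id",
    "pH",
    "SOM",
    *SOIL_TOTAL_COLUMNS.values(),
    *OXIDE_FRACTIONS,
    *RICE_COLUMNS.values(),
)
#: Canonical column order for CSV output.
ALL_COLUMNS = (
    "site_id",
    "pH",
    "SOM",
    "S_T_Cd",
    "A_Cd",
    "S_T_As",
    "A_As",
    *OXIDE_FRACTIONS,
    *RICE_COLUMNS.values(),
)
#: Columns holding concentrations (log10-transformable, must be > 0).
CONCENTRATION_COLUMNS = (
    *SOIL_TOTAL_COLUMNS.values(),
    *AVAILABLE_COLUMNS.values(),
    *OXIDE_FRACTIONS,
    *RICE_COLUMNS.values(),
)


class SchemaError(ValueError):
    """A required column is missing or a predictor is unknown."""


class ValidationError(ValueError):
    """One or more rows violate the sample invariants."""


class DomainError(ValueError):
    """A value is outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class PhBin:
    """A pH interval with the representative value used for threshold work.

    The neutral bin is closed on the right (6.5 < pH <= 7.5); the alkaline
    bin is open above 7.5. Samples at or below pH 6.5 fall outside both bins
    and are excluded from threshold workflows with a warning.
    """

    label: str
    lower: float
    upper: float
    representative_pH: float

    def __post_init__(self) -> None:
        if not (self.lower < self.representative_pH <= self.upper):
            raise ValueError("representative_pH must lie inside the bin")

    def contains(self, ph: float) -> bool:
        return self.lower < ph <= self.upper


NEUTRAL_BIN = PhBin("neutral", 6.5, 7.5, 7.0)
ALKALINE_BIN = PhBin("alkaline", 7.5, math.inf, 8.0)
PH_BINS = (NEUTRAL_BIN, ALKALINE_BIN)
PH_BIN_BY_LABEL = {b.label: b for b in PH_BINS}


def assign_ph_bin(ph: float) -> PhBin | None:
    """Return the pH bin containing ``ph``, or None if unsupported (pH <= 6.5)."""
    for b in PH_BINS:
        if b.contains(ph):
            return b
    return None


@dataclass(frozen=True)
class RegulatoryLimits:
    """National limits for one element in one pH bin.

    mac is the food-standard grain limit; rsv/riv are the soil screening and
    intervention values. All mg·kg⁻¹.
    """

    element: str
    ph_bin: str
    mac: float
    rsv: float
    riv: float

    def __post_init__(self) -> None:
        if not (0 < self.mac < self.rsv < self.riv):
            raise ValueError(
                f"require 0 < mac < rsv < riv, got {self.mac}, {self.rsv}, {self.riv}"
            )


@dataclass(frozen=True)
class PairedSample:
    site_id: str
    pH: float
    som: float
    soil_total: Mapping[str, float]
    oxides: Mapping[str, float]
    rice: Mapping[str, float]
    soil_available: Mapping[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "site_id": self.site_id,
            "pH": self.pH,
            "SOM": self.som,
        }
        for el, col in SOIL_TOTAL_COLUMNS.items():
            row[col] = self.soil_total[el]
        for el, col in AVAILABLE_COLUMNS.items():
            if el in self.soil_available:
                row[col] = self.soil_available[el]
        row.update({f: self.oxides[f] for f in OXIDE_FRACTIONS})
        for el, col in RICE_COLUMNS.items():
            row[col] = self.rice[el]
        return row


@dataclass
class Dataset:
    """An ordered collection of paired samples plus an optional modeling split.

    ``frame`` has the canonical columns; ``split`` maps site_id to
    "modeling" or "validation" when :func:`split_dataset` has been applied.
    """

    frame: pd.DataFrame
    split: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.frame["site_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["site_id"].duplicated(), "site_id"]
            raise ValidationError(f"duplicate site_ids: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.frame)

    def samples(self) -> Iterator[PairedSample]:
        for _, row in self.frame.iterrows():
            avail = {
                el: float(row[col])
                for el, col in AVAILABLE_COLUMNS.items()
                if col in row.index and pd.notna(row[col])
            }
            yield PairedSample(
                site_id=str(row["site_id"]),
                pH=float(row["pH"]),
                som=float(row["SOM"]),
                soil_total={el: float(row[c]) for el, c in SOIL_TOTAL_COLUMNS.items()},
                soil_available=avail,
                oxides={f: float(row[f]) for f in OXIDE_FRACTIONS},
                rice={el: float(row[c]) for el, c in RICE_COLUMNS.items()},
            )

    def subset(self, label: str) -> pd.DataFrame:
        if self.split is None:
            raise ValueError("dataset has no split; call split_dataset first")
        ids = {s for s, lab in self.split.items() if lab == label}
        return self.frame[self.frame["site_id"].astype(str).isin(ids)]

    def modeling_frame(self) -> pd.DataFrame:
        return self.subset("modeling")

    def validation_frame(self) -> pd.DataFrame:
        return self.subset("validation")


def _row_problems(row: pd.Series) -> list[str]:
    problems = []
    ph = row["pH"]
    if not (0 < ph < 14):
        problems.append(f"pH={ph!r} outside (0, 14)")
    if not row["SOM"] > 0:
        problems.append(f"SOM={row['SOM']!r} not > 0")
    for col in CONCENTRATION_COLUMNS:
        if col not in row.index:
            continue
        v = row[col]
        if pd.isna(v):
            if col in AVAILABLE_COLUMNS.values() or col in RICE_COLUMNS.values():
                continue  # available fractions and (pre-harvest) rice may be absent
            problems.append(f"{col} is missing")
        elif not v > 0:
            problems.append(f"{col}={v!r} not > 0")
    return problems


def validate_frame(frame: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` with row-level diagnostics on bad rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    diagnostics = []
    for _, row in frame.iterrows():
        problems = _row_problems(row)
        if problems:
            diagnostics.append(f"site {row['site_id']}: " + "; ".join(problems))
    if diagnostics:
        raise ValidationError("invalid rows:\n" + "\n".join(diagnostics))


def read_paired_table(path, column_map: Mapping[str, str] | None = None) -> Dataset:
    """Read a paired soil–rice CSV into a validated :class:`Dataset`.

    ``column_map`` maps file column names to the canonical names in
    :data:`ALL_COLUMNS`, for tables exported under other headers.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    validate_frame(frame)
    keep = [c for c in ALL_COLUMNS if c in frame.columns]
    frame = frame[keep].reset_index(drop=True)
    frame["site_id"] = frame["site_id"].astype(str)
    return Dataset(frame)


def write_paired_table(dataset: Dataset, path) -> None:
    cols = [c for c in ALL_COLUMNS if c in dataset.frame.columns]
    dataset.frame[cols].to_csv(path, index=False)


def log10_columns(
    dataset: Dataset | pd.DataFrame,
    include_pH: bool = False,
    include_som: bool = False,
) -> pd.DataFrame:
    """Return a copy with concentrations/oxides replaced by their log10.

    pH and SOM are left on their raw scale unless explicitly requested;
    the transfer models use them untransformed.
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    out = frame.copy()
    cols = [c for c in CONCENTRATION_COLUMNS if c in out.columns]
    if include_pH:
        cols.append("pH")
    if include_som:
        cols.append("SOM")
    for col in cols:
        vals = out[col].to_numpy(dtype=float)
        bad = vals[np.isfinite(vals)] <= 0
        if bad.any():
            raise DomainError(f"column {col} has non-positive values; cannot log10")
        out[col] = np.log10(vals)
    return out


def split_dataset(dataset: Dataset, n_validation: int, seed: int) -> Dataset:
    """Randomly label samples as modeling/validation, reproducibly for a seed."""
    n = len(dataset)
    if not 0 < n_validation < n:
        raise ValueError(f"n_validation must be in (0, {n}), got {n_validation}")
    rng = np.random.default_rng(seed)
    ids = dataset.frame["site_id"].astype(str).to_numpy()
    validation_ids = set(rng.choice(ids, size=n_validation, replace=False))
    split = {
        sid: ("validation" if sid in validation_ids else "modeling") for sid in ids
    }
    return Dataset(dataset.frame.copy(), split=split)


def load_regulatory_limits(path=None) -> dict[tuple[str, str], RegulatoryLimits]:
    """Load MAC/RSV/RIV constants, keyed by (element, ph_bin label).

    With no ``path``, the bundled national-standard constants are used
    (GB 2762 grain limits; GB 15618 pH-binned screening/intervention values).
    """
    if path is None:
        src = resources.files("paddythresh").joinpath("data/regulatory_limits.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    mac = raw["mac"]
    out = {}
    for rec in raw["limits"]:
        el, bin_label = rec["element"], rec["ph_bin"]
        if bin_label not in PH_BIN_BY_LABEL:
            raise SchemaError(f"unknown ph_bin {bin_label!r}")
        out[(el, bin_label)] = RegulatoryLimits(
            element=el,
            ph_bin=bin_label,
            mac=float(mac[el]),
            rsv=float(rec["rsv"]),
            riv=float(rec["riv"]),
        )
    return out


def reject_unbinned(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop samples whose pH falls outside the supported bins, with a warning."""
    in_bin = frame["pH"].map(lambda p: assign_ph_bin(float(p)) is not None)
    n_out = int((~in_bin).sum())
    if n_out:
        warnings.warn(
            f"{n_out} sample(s) with pH <= 6.5 excluded from threshold workflow",
            stacklevel=2,
        )
    return frame[in_bin]
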