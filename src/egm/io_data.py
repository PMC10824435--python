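"""Reading, unit conversion and assembly of the longitudinal growth dataset.

Two CSV tables feed the analysis: a growth table with one row per plant-sample
event (field, year, days after planting, tuber weight) and a field-descriptor
table with one row per field-year (soil nutrient levels, management
categories, yield, irrigation, planting date).  This module converts raw tuber
weights (g per 3 plants) to an areal density (g m^-2), standardizes the time
axis, joins the two tables and reports every row it could not use.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: numeric soil descriptors searched over by the miner; N..S in kg ha^-1,
#: B..Zn and Si in g ha^-1.
NUMERIC_DESCRIPTORS: tuple[str, ...] = (
    "N_soil",
    "P_soil",
    "K_soil",
    "Ca_soil",
    "Mg_soil",
    "S_soil",
    "B_soil",
    "Fe_soil",
    "Mn_soil",
    "Zn_soil",
    "Si_soil",
)

#: categorical descriptors searched over by the miner.
CATEGORICAL_DESCRIPTORS: tuple[str, ...] = (
    "Dryness",
    "Nutrient_content",
    "Previous_crop",
    "Nematodes",
)

#: annotation columns used for profiling, never for search.
ANNOTATION_COLUMNS: tuple[str, ...] = ("yield_ton_ha", "irrigated", "planting_date")

#: printed row-width constant of the areal conversion (100 / 75 cm rows,
#: kept verbatim at 4 significant digits for bit-compatibility).
ROW_WIDTH_FACTOR = 1.333


class DataError(ValueError):
    """Raised for structurally invalid input tables."""


def tuber_weight_per_m2(raw_weight, planting_distance_cm):
    """Convert a tuber weight of a 3-plant sample to grams per square meter.

    Three plants cover ``planting_distance_cm * 3 / 100`` meters of row; one
    meter of row represents 0.75 m^2 of field (75 cm row spacing), hence the
    factor 1.333 = 100/75.

    Parameters
    ----------
    raw_weight : float or array-like
        Tuber weight of the 3-plant sample, grams. Must be >= 0.
    planting_distance_cm : float or array-like
        In-row distance between plants, centimeters. Must be > 0.

    Returns
    -------
    float or ndarray
        Tuber weight in g m^-2.
    """
    raw = np.asarray(raw_weight, dtype=float)
    dist = np.asarray(planting_distance_cm, dtype=float)
    if np.any(dist <= 0) or np.any(~np.isfinite(dist)):
        raise DataError("planting distance must be positive and finite")
    if np.any(raw < 0):
        raise DataError("raw tuber weight must be non-negative")
    out = raw * ROW_WIDTH_FACTOR / (dist * 3.0 / 100.0)
    if out.ndim == 0:
        return float(out)
    return out


def standardize_times(days: Sequence[float]) -> tuple[np.ndarray, float]:
    """Divide days-after-planting by their pooled sample standard deviation.

    The model is fit on a standardized time axis for numerical stability; the
    returned scale converts curve parameters back to days.

    Returns
    -------
    (standardized_days, time_scale)
        ``time_scale`` is the sample sd (ddof=1) of the pooled day values.
    """
    d = np.asarray(days, dtype=float)
    if d.size < 2 or np.unique(d).size < 2:
        raise DataError("need at least 2 distinct day values to standardize time")
    scale = float(np.std(d, ddof=1))
    if not np.isfinite(scale) or scale <= 0.0:
        raise DataError("degenerate time scale: day values have no spread")
    return d / scale, scale


@dataclasses.dataclass
class Dataset:
    """The joined analysis dataset.

    Attributes
    ----------
    fields : DataFrame
        One row per field-year, indexed by ``unit_id`` (``"{field_id}::{year}"``),
        with ``field_id``, ``year``, the descriptor columns and annotations.
    observations : DataFrame
        Likelihood-ready longitudinal records with columns ``unit_id``,
        ``field_id``, ``year``, ``days_after_planting``, ``t_std``,
        ``weight_g_m2``, ``log_weight``.
    time_scale : float
        Sample sd of days used for ``t_std = days / time_scale``.
    excluded_zeros : DataFrame
        Zero-weight rows (destroyed fields) excluded from the likelihood.
    rejects : DataFrame
        Growth rows whose (field_id, year) has no field record.
    """

    fields: pd.DataFrame
    observations: pd.DataFrame
    time_scale: float
    excluded_zeros: pd.DataFrame = dataclasses.field(
        default_factory=pd.DataFrame
    )
    rejects: pd.DataFrame = dataclasses.field(default_factory=pd.DataFrame)

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.fields.index)

    def validate(self) -> None:
        if self.n_fields == 0:
            raise DataError("dataset has no field records")
        if self.fields.index.has_duplicates:
            raise DataError("duplicate (field_id, year) records")
        missing = set(self.observations["unit_id"]) - set(self.fields.index)
        if missing:
            raise DataError(f"observations reference unknown units: {sorted(missing)[:5]}")
        if self.time_scale <= 0:
            raise DataError("time_scale must be positive")


def _unit_id(field_id, year) -> str:
    return f"{field_id}::{int(year)}"


def attach_unit_ids(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``unit_id`` column built from ``field_id`` and ``year``."""
    out = df.copy()
    out["unit_id"] = [
        _unit_id(f, y) for f, y in zip(out["field_id"], out["year"])
    ]
    return out


def assemble_dataset(growth: pd.DataFrame, fields: pd.DataFrame) -> Dataset:
    """Join in-memory growth and field tables into a likelihood-ready Dataset.

    Rows with weight exactly zero (fields destroyed by extreme weather, after
    which sampling stopped) carry no information under a multiplicative error
    model and are excluded from the likelihood set but reported in
    ``excluded_zeros``.  Growth rows with no matching field record land in
    ``rejects``.  Row counts are conserved:
    ``len(growth) == len(observations) + len(excluded_zeros) + len(rejects)``.
    """
    growth = growth.copy()
    for col in ("field_id", "year", "days_after_planting"):
        if col not in growth.columns:
            raise DataError(f"growth table is missing column {col!r}")
    for col in ("field_id", "year"):
        if col not in fields.columns:
            raise DataError(f"fields table is missing column {col!r}")

    if "weight_g_m2" in growth.columns:
        weight = growth["weight_g_m2"].astype(float)
    elif "weight_g_3plants" in growth.columns:
        if "planting_distance_cm" not in growth.columns:
            raise DataError(
                "raw 3-plant weights require a planting_distance_cm column"
            )
        weight = pd.Series(
            tuber_weight_per_m2(
                growth["weight_g_3plants"].to_numpy(float),
                growth["planting_distance_cm"].to_numpy(float),
            ),
            index=growth.index,
        )
    else:
        raise DataError(
            "growth table needs a weight_g_m2 or weight_g_3plants column"
        )
    if np.any(weight.to_numpy() < 0):
        raise DataError("negative tuber weights")
    growth["weight_g_m2"] = weight

    fields = attach_unit_ids(fields)
    if fields["unit_id"].duplicated().any():
        dup = fields.loc[fields["unit_id"].duplicated(), "unit_id"].tolist()
        raise DataError(f"duplicate field records: {dup[:5]}")
    fields = fields.set_index("unit_id")
    fields["year"] = fields["year"].astype(int)
    if "irrigated" in fields.columns:
        fields["irrigated"] = fields["irrigated"].map(_parse_bool)
    if "planting_date" in fields.columns:
        fields["planting_date"] = pd.to_datetime(fields["planting_date"])

    growth = attach_unit_ids(growth)
    matched = growth["unit_id"].isin(fields.index)
    rejects = growth.loc[~matched].copy()
    growth = growth.loc[matched]

    dup = growth.duplicated(subset=["unit_id", "days_after_planting"])
    if dup.any():
        raise DataError("duplicate (field_id, year, day) growth rows")

    is_zero = growth["weight_g_m2"] == 0.0
    excluded = growth.loc[is_zero].copy()
    obs = growth.loc[~is_zero].copy()
    if np.any(obs["days_after_planting"].to_numpy(float) < 0):
        raise DataError("negative days_after_planting")

    t_std, scale = standardize_times(obs["days_after_planting"].to_numpy(float))
    obs["t_std"] = t_std
    obs["log_weight"] = np.log(obs["weight_g_m2"].to_numpy(float))
    obs["year"] = obs["year"].astype(int)
    keep = [
        "unit_id",
        "field_id",
        "year",
        "days_after_planting",
        "t_std",
        "weight_g_m2",
        "log_weight",
    ]
    ds = Dataset(
        fields=fields,
        observations=obs[keep].reset_index(drop=True),
        time_scale=scale,
        excluded_zeros=excluded.reset_index(drop=True),
        rejects=rejects.reset_index(drop=True),
    )
    ds.validate()
    return ds


def load_dataset(growth_csv, fields_csv) -> Dataset:
    """Read the two CSV tables and assemble the joined dataset.

    CSV dialect: comma-separated, header row, UTF-8, '.' decimal; missing
    values are empty strings or ``NA``.
    """
    growth = pd.read_csv(growth_csv, na_values=["NA"])
    fields = pd.read_csv(fields_csv, na_values=["NA"])
    return assemble_dataset(growth, fields)


def _parse_bool(v):
    if pd.isna(v):
        return v
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise DataError(f"cannot parse boolean value {v!r}")


def validation_report(ds: Dataset) -> dict:
    """Summary counts a `validate` CLI run prints."""
    return {
        "n_fields": ds.n_fields,
        "n_observations": len(ds.observations),
        "n_excluded_zero_weight": len(ds.excluded_zeros),
        "n_rejected_unmatched": len(ds.rejects),
        "time_scale_days": ds.time_scale,
        "years": sorted(ds.fields["year"].unique().tolist()),
    }
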