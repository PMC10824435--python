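"""Seeded generator of farm-like longitudinal growth datasets.

The generator draws data with exactly the statistical structure the model
assumes: per-year fixed-effect logistic curves, three correlated
unit-variance field random effects entering through the scales
(sigma_alpha, sigma_beta, exp(sigma_gamma)), multiplicative lognormal
measurement error, and 5-7 non-equidistant sampling days per field.  Soil
descriptors are drawn lognormally (categoricals from fixed probabilities)
and are independent of growth unless *planted effects* are configured: a
planted effect shifts one random-effect component's mean by delta for every
field satisfying a descriptor condition, creating a known subgroup the
miner should recover.  Ground truth (the drawn random effects) is always
returned next to the data, never hidden.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

from .emm_search import Condition
from .growth_model import ModelParams
from .io_data import Dataset, assemble_dataset


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """Shift ``delta`` on random-effect ``component`` for fields matching ``condition``."""

    condition: Condition
    component: str  # 'a', 'b' or 'c'
    delta: float

    def __post_init__(self):
        if self.component not in ("a", "b", "c"):
            raise ValueError("component must be 'a', 'b' or 'c'")


@dataclasses.dataclass
class SimConfig:
    """Full specification of one synthetic farm dataset.

    ``params`` are the true model parameters **on the raw day scale**; use
    ``params.rescale_time(dataset.time_scale)`` to compare with a model
    fitted on standardized time.  Numeric descriptors are lognormal with
    the given (median, log-sd); categorical descriptors draw from the given
    label probabilities.
    """

    years: tuple[int, ...]
    n_fields_per_year: int
    params: ModelParams
    obs_per_field: tuple[int, int] = (5, 7)
    day_range: tuple[float, float] = (25.0, 135.0)
    numeric_specs: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    categorical_specs: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    planted_effects: tuple[PlantedEffect, ...] = ()
    yield_base: dict[int, float] = dataclasses.field(default_factory=dict)
    yield_slope: float = 8.0
    yield_sd: float = 5.0
    irrigation_p: float = 0.4
    planting_span_days: int = 40
    seed: int = 0

    def validate(self) -> None:
        self.params.validate()
        if self.n_fields_per_year < 1 or not self.years:
            raise ValueError("need at least one year and one field per year")
        lo, hi = self.obs_per_field
        if not (1 <= lo <= hi):
            raise ValueError("invalid obs_per_field range")
        declared = set(self.numeric_specs) | set(self.categorical_specs)
        for pe in self.planted_effects:
            if pe.condition.attribute not in declared:
                raise ValueError(
                    f"planted effect references undeclared descriptor "
                    f"{pe.condition.attribute!r}"
                )


def simulate(config: SimConfig) -> tuple[Dataset, pd.DataFrame]:
    """Draw one dataset; returns (Dataset, truth).

    ``truth`` is a DataFrame indexed by unit_id with the drawn random
    effects ``a``, ``b``, ``c`` (planted shifts included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.params
    R = p.corr_matrix()
    Lr = np.linalg.cholesky(R)
    sc = float(np.exp(p.sigma_gamma))

    field_rows = []
    for year in config.years:
        for i in range(config.n_fields_per_year):
            field_rows.append({"field_id": f"F{year}_{i:03d}", "year": year})
    fields = pd.DataFrame(field_rows)
    F = len(fields)

    for attr, (median, logsd) in config.numeric_specs.items():
        fields[attr] = median * np.exp(rng.normal(0.0, logsd, size=F))
    for attr, probs in config.categorical_specs.items():
        labels = list(probs)
        pvec = np.array([probs[lab] for lab in labels], dtype=float)
        fields[attr] = rng.choice(labels, size=F, p=pvec / pvec.sum())

    re = rng.standard_normal((F, 3)) @ Lr.T
    comp_idx = {"a": 0, "b": 1, "c": 2}
    for pe in config.planted_effects:
        mask = pe.condition.mask(fields)
        re[mask, comp_idx[pe.component]] += pe.delta

    years_arr = fields["year"].to_numpy(int)
    a_f = np.array([p.alpha0[y] for y in years_arr]) + p.sigma_alpha * re[:, 0]
    b_f = np.exp(np.array([p.beta0[y] for y in years_arr]) + p.sigma_beta * re[:, 1])
    c_f = np.array([p.gamma0[y] for y in years_arr]) + sc * re[:, 2]

    growth_rows = []
    d0, d1 = config.day_range
    for i in range(F):
        n_obs = int(rng.integers(config.obs_per_field[0], config.obs_per_field[1] + 1))
        base = np.linspace(d0, d1, n_obs)
        spacing = (d1 - d0) / max(n_obs - 1, 1)
        days = np.sort(base + rng.uniform(-spacing / 3, spacing / 3, size=n_obs))
        days = np.clip(days, 1.0, None)
        eta = b_f[i] * (days - c_f[i])
        mu = a_f[i] - np.logaddexp(0.0, -eta)
        w = np.exp(mu + rng.normal(0.0, p.sigma_resid, size=n_obs))
        for d, y in zip(days, w):
            growth_rows.append(
                {
                    "field_id": fields.loc[i, "field_id"],
                    "year": int(fields.loc[i, "year"]),
                    "days_after_planting": float(d),
                    "weight_g_m2": float(y),
                }
            )
    growth = pd.DataFrame(growth_rows)

    base_yield = np.array(
        [config.yield_base.get(int(y), 50.0) for y in years_arr], dtype=float
    )
    fields["yield_ton_ha"] = (
        base_yield + config.yield_slope * re[:, 0] + rng.normal(0, config.yield_sd, F)
    ).round(1)
    fields["irrigated"] = rng.random(F) < config.irrigation_p
    offsets = rng.integers(0, config.planting_span_days, size=F)
    fields["planting_date"] = [
        datetime.date(int(y), 4, 1) + datetime.timedelta(days=int(o))
        for y, o in zip(years_arr, offsets)
    ]

    ds = assemble_dataset(growth, fields)
    truth = pd.DataFrame(
        re, columns=["a", "b", "c"], index=[f"{f}::{y}" for f, y in zip(fields["field_id"], years_arr)]
    )
    truth = truth.loc[ds.fields.index]
    return ds, truth


#: day-scale steepness around 0.10 d^-1 and midpoints around day 72-80 put
#: half-maximum growth in early-to-mid July for April plantings.
_DEFAULT_PARAMS = dict(
    alpha0={2015: 8.6, 2016: 8.1, 2017: 8.5, 2018: 8.2},
    beta0={2015: -2.25, 2016: -2.35, 2017: -2.30, 2018: -2.40},
    gamma0={2015: 72.0, 2016: 78.0, 2017: 74.0, 2018: 80.0},
    sigma_alpha=0.30,
    sigma_beta=0.25,
    sigma_gamma=float(np.log(6.0)),  # +/- 6 days of midpoint spread per unit c
    rho12=-0.65,
    rho13=0.49,
    rho23=-0.73,
    sigma_resid=0.15,
)

#: numeric descriptor (median, log-sd); N..S kg/ha, B..Zn and Si g/ha.
_DEFAULT_NUMERIC = {
    "N_soil": (120.0, 0.45),
    "P_soil": (8.0, 0.5),
    "K_soil": (200.0, 0.4),
    "Ca_soil": (150.0, 0.8),
    "Mg_soil": (170.0, 0.4),
    "S_soil": (15.0, 0.5),
    "B_soil": (600.0, 0.5),
    "Fe_soil": (380.0, 0.4),
    "Mn_soil": (3000.0, 0.7),
    "Zn_soil": (4000.0, 0.7),
    "Si_soil": (100.0, 0.6),
}

_DEFAULT_CATEGORICAL = {
    "Dryness": {"dry": 0.25, "average": 0.45, "wet": 0.30},
    "Nutrient_content": {"poor": 0.30, "average": 0.50, "rich": 0.20},
    "Previous_crop": {"cereal": 0.35, "maize": 0.25, "sugar_beet": 0.20, "grass": 0.20},
    "Nematodes": {"no": 0.80, "yes": 0.20},
}

#: year-average yields (ton/ha) matching the case-study magnitudes.
_DEFAULT_YIELD = {2015: 63.5, 2016: 40.1, 2017: 54.0, 2018: 38.0}


def default_farm_config(seed: int = 0, n_fields_per_year: int = 90) -> SimConfig:
    """The standard farm-like scenario: 4 years x ~90 fields.

    Year asymptotes exp(8.1)..exp(8.6) ~ 3300-5400 g m^-2, random-effect
    correlations (-0.65, +0.49, -0.73) as estimated in the potato-farm case
    study (steeper curves go with lower maxima and earlier midpoints; higher
    maxima are reached slightly later), residual log-sd 0.15.
    """
    return SimConfig(
        years=(2015, 2016, 2017, 2018),
        n_fields_per_year=n_fields_per_year,
        params=ModelParams(**_DEFAULT_PARAMS),
        numeric_specs=dict(_DEFAULT_NUMERIC),
        categorical_specs={k: dict(v) for k, v in _DEFAULT_CATEGORICAL.items()},
        yield_base=dict(_DEFAULT_YIELD),
        seed=seed,
    )


def planted_recovery_config(
    seed: int = 0,
    n_fields_per_year: int = 90,
    delta: float = 0.8,
    component: str = "a",
) -> SimConfig:
    """Default farm scenario plus one planted subgroup.

    Fields with K_soil > 265 kg/ha (about the upper quarter of the K
    distribution) get a ``delta`` shift on ``component`` — the known answer
    an end-to-end mining run should place in its top subgroups.
    """
    cfg = default_farm_config(seed=seed, n_fields_per_year=n_fields_per_year)
    cfg.planted_effects = (
        PlantedEffect(Condition("K_soil", "numeric_gt", 265.0), component, delta),
    )
    return cfg


def write_csv(ds: Dataset, truth: pd.DataFrame, growth_path, fields_path, truth_path=None):
    """Write a simulated dataset back to the CSV interchange format."""
    obs = ds.observations[
        ["field_id", "year", "days_after_planting", "weight_g_m2"]
    ]
    obs.to_csv(growth_path, index=False)
    fields = ds.fields.reset_index(drop=True)
    fields.to_csv(fields_path, index=False)
    if truth_path is not None:
        truth.rename_axis("unit_id").to_csv(truth_path)
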