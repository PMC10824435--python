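import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from egm.growth_model import ModelParams
from egm.synthetic import SimConfig, simulate

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def one_year_params(**overrides) -> ModelParams:
    """Small single-year model used by likelihood oracles."""
    base = dict(
        alpha0={2015: 8.4},
        beta0={2015: -2.3},
        gamma0={2015: 75.0},
        sigma_alpha=0.3,
        sigma_beta=0.25,
        sigma_gamma=float(np.log(6.0)),
        rho12=-0.5,
        rho13=0.3,
        rho23=-0.6,
        sigma_resid=0.15,
    )
    base.update(overrides)
    return ModelParams(**base)


@pytest.fixture(scope="session")
def toy_two_fields():
    """2-field, 1-year dataset plus its generating parameters (day scale)."""
    cfg = SimConfig(
        years=(2015,),
        n_fields_per_year=2,
        params=one_year_params(),
        obs_per_field=(6, 6),
        seed=42,
    )
    ds, truth = simulate(cfg)
    return ds, cfg.params, truth


@pytest.fixture()
def mining_fixture():
    """12 deterministic field records with 3 descriptors and known targets."""
    fields = pd.DataFrame(
        {
            "field_id": [f"f{i}" for i in range(12)],
            "year": [2015, 2015, 2015, 2016, 2016, 2016] * 2,
            "K_soil": [50, 80, 120, 160, 200, 240, 280, 320, 360, 400, 440, 480],
            "N_soil": [90, 140, 90, 140, 90, 140, 90, 140, 90, 140, 90, 140],
            "Dryness": ["dry", "average", "wet"] * 4,
        }
    )
    fields.index = pd.Index(
        [f"{f}::{y}" for f, y in zip(fields["field_id"], fields["year"])],
        name="unit_id",
    )
    rng = np.random.default_rng(7)
    targets = pd.Series(rng.normal(size=12), index=fields.index)
    # make high K clearly exceptional
    targets[fields["K_soil"] > 240] += 1.5
    return fields, targets
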