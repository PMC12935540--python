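import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_crop_catalog():
    """Small hand-built catalog with clean round-number factors."""
    from rotanutri.diversity import CropProfile

    def crop(name, ftype, f=0.0, a=1.0, r=1.0, gam=None, forage=False):
        return CropProfile(
            crop_name=name,
            functional_type=ftype,
            edible=not forage,
            forage_only=forage,
            f_H2O=f,
            alpha=a,
            f_ref=r,
            gamma=gam or {},
            retail_product="test",
        )

    gam_wheat = {"calorie": 0.0035, "carbohydrate": 0.70, "protein": 0.10, "fat": 0.01}
    gam_pea = {"calorie": 0.0034, "carbohydrate": 0.60, "protein": 0.25, "fat": 0.01}
    gam_oil = {"calorie": 0.0088, "carbohydrate": 0.0, "protein": 0.0, "fat": 1.0}
    gam_beet = {"calorie": 0.0039, "carbohydrate": 1.0, "protein": 0.0, "fat": 0.0}
    return {
        "wheat": crop("wheat", "cereal", f=0.12, a=0.75, gam=gam_wheat),
        "barley": crop("barley", "cereal", f=0.10, a=0.60, gam=gam_wheat),
        "maize": crop("maize", "cereal", f=0.11, a=0.80, gam=gam_wheat),
        "pea": crop("pea", "annual_legume", f=0.11, gam=gam_pea),
        "sugar_beet": crop("sugar_beet", "annual_broadleaf", a=0.14, gam=gam_beet),
        "rape": crop("rape", "annual_broadleaf", a=0.40, gam=gam_oil),
        "ley": crop("ley", "ley", forage=True),
        "fallow": CropProfile(
            crop_name="fallow", functional_type="fallow", edible=False, forage_only=False
        ),
    }


@pytest.fixture(scope="session")
def small_yield_table():
    """Deterministic small synthetic experiment with anomalies injected."""
    from rotanutri.simulate import SimConfig, generate_experiment

    cfg = SimConfig(n_sites=4, years_min=10, years_max=14, seed=42)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def recovery_outputs():
    """One small exactly-specified dataset: generator matches analysis model."""
    from rotanutri.nutrition import build_output_table
    from rotanutri.qc import YieldQC
    from rotanutri.simulate import (
        generate_experiment,
        identity_crop_catalog,
        recovery_sim_config,
    )

    cfg = recovery_sim_config(n_sites=8, years=12, seed=7)
    table = generate_experiment(cfg)
    table = YieldQC(screen_outliers=False).transform(table)
    cat = identity_crop_catalog(set(table["crop"]))
    out = build_output_table(table, crop_catalog=cat, scenario="biofuel")
    return cfg, out[out["nutrient"] == "calorie"].reset_index(drop=True)
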