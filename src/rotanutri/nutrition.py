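"""Convert dry crop yields into human-available calories and macronutrients.

Per-crop conversion follows the food-balance-sheet chain

    M = Y * (1 - f_H2O)**-1 * alpha * f_ref * gamma_n

where ``Y`` is the dry yield (kg ha-1 yr-1), ``f_H2O`` the water fraction of
the retail product, ``alpha`` the crop-to-retail factor, ``f_ref`` the edible
(refuse-corrected) fraction of the retail product and ``gamma_n`` the content
of nutrient ``n`` per kg of retail product.  Calories are tracked in
Gcal ha-1 yr-1 and macronutrients in kg ha-1 yr-1; a ``unit`` tag is carried
through every output table.

Forage crops (ley, ryegrass, forage rape, silage maize, ...) cannot be eaten
directly; their dry matter is converted through an end-use scenario: cow milk
(1.05 l whole milk per kg dry-matter intake), boneless beef (0.047 kg per kg
DM) or biofuel (no output for human nutrition).  The whole-rotation annual
output is the area-weighted sum of the per-crop outputs, each rotation year
weighing ``1 / rotation_length``; fallow years contribute zero.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .diversity import (
    NUTRIENTS,
    CropProfile,
    RotationSpec,
    UnknownCropError,
    default_crop_catalog,
    functional_richness,
)
from .qc import FLAG_EXCLUDED, FLAG_MISSING

UNITS = {
    "calorie": "Gcal ha-1 yr-1",
    "carbohydrate": "kg ha-1 yr-1",
    "protein": "kg ha-1 yr-1",
    "fat": "kg ha-1 yr-1",
}

SCENARIOS = ("milk", "beef", "biofuel")


@dataclass(frozen=True)
class ProductProfile:
    """Conversion factors of an animal product (or biofuel placeholder)."""

    product_name: str
    unit: str
    f_H2O: float
    f_ref: float
    gamma: dict


@dataclass(frozen=True)
class ForageScenario:
    """End use of forage dry matter.

    ``dm_to_product`` is the amount of retail product (kg, or l for milk)
    per kg of dry-matter intake; the nutrient output per kg DM is
    ``dm_to_product * f_ref * gamma_n`` of the product profile.  The biofuel
    scenario yields exactly zero for every nutrient.
    """

    name: str
    dm_to_product: float
    product_profile: ProductProfile | None = None

    def __post_init__(self):
        if self.dm_to_product < 0:
            raise ValueError("dm_to_product must be >= 0")
        if self.name != "biofuel" and self.product_profile is None:
            raise ValueError(f"scenario {self.name!r} needs a product profile")


def _load_animal_products() -> dict:
    ref = importlib.resources.files("rotanutri.data") / "default_animal_products.csv"
    with ref.open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for _, r in df.iterrows():
        out[r["product_name"]] = (
            float(r["dm_to_product"]),
            ProductProfile(
                product_name=str(r["product_name"]),
                unit=str(r["unit"]),
                f_H2O=float(r["f_H2O"]),
                f_ref=float(r["f_ref"]),
                gamma={
                    "calorie": float(r["gamma_calorie"]),
                    "carbohydrate": float(r["gamma_carb"]),
                    "protein": float(r["gamma_protein"]),
                    "fat": float(r["gamma_fat"]),
                },
            ),
        )
    return out


def default_scenario(name: str) -> ForageScenario:
    """Build one of the standard forage scenarios (milk, beef, biofuel).

    Product composition values come from the bundled default catalog of
    representative public-source figures and are replaceable.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    if name == "biofuel":
        return ForageScenario(name="biofuel", dm_to_product=0.0)
    products = _load_animal_products()
    key = "whole_milk" if name == "milk" else "boneless_beef"
    dm_to_product, profile = products[key]
    return ForageScenario(name=name, dm_to_product=dm_to_product, product_profile=profile)


def crop_output(yield_dry, profile: CropProfile, nutrient: str):
    """Nutrient output of a directly-edible crop, per the conversion chain."""
    if nutrient not in NUTRIENTS:
        raise ValueError(f"unknown nutrient {nutrient!r}")
    if profile.forage_only:
        raise ValueError(
            f"crop {profile.crop_name!r} is forage-only; use forage_output with a "
            "scenario instead"
        )
    y = np.asarray(yield_dry, dtype=float)
    m = y / (1.0 - profile.f_H2O) * profile.alpha * profile.f_ref * profile.gamma[nutrient]
    return m if m.ndim else float(m)


def forage_output(yield_dry_dm, scenario: ForageScenario, nutrient: str):
    """Nutrient output of forage dry matter under an end-use scenario.

    Product mass is ``DM * dm_to_product`` (already on the fresh retail
    basis, so no water-fraction correction applies); nutrients follow from
    the product's refuse factor and gamma.  Biofuel returns zero.
    """
    if nutrient not in NUTRIENTS:
        raise ValueError(f"unknown nutrient {nutrient!r}")
    y = np.asarray(yield_dry_dm, dtype=float)
    if scenario.name == "biofuel" or scenario.product_profile is None:
        m = np.zeros_like(y)
    else:
        p = scenario.product_profile
        m = y * scenario.dm_to_product * p.f_ref * p.gamma[nutrient]
    return m if m.ndim else float(m)


def rotation_output(crop_outputs, weights) -> float:
    """Area-weighted whole-rotation output: ``sum_c M_c * F_A_c``.

    ``weights`` must sum to 1 (each rotation year carries 1/length)."""
    m = np.asarray(crop_outputs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if m.shape != w.shape:
        raise ValueError("crop_outputs and weights must have equal length")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"area weights must sum to 1, got {w.sum():.6f}")
    return float(m @ w)


def build_output_table(
    yield_table: pd.DataFrame,
    crop_catalog: dict | None = None,
    rotations: dict | None = None,
    scenario: ForageScenario | str = "milk",
) -> pd.DataFrame:
    """Aggregate a QC'd yield table into whole-rotation annual outputs.

    One output row per site x calendar_year x rotation x group x nutrient for
    the chosen forage scenario.  QC-excluded combinations are dropped before
    aggregation; a non-excluded combination missing one of its rotation's
    crop-years raises, because every crop of a rotation must be present every
    growing season for the aggregation to be meaningful.

    The end use of each row is taken from a ``use`` column ("food" /
    "forage" / "none") when present, falling back to the rotation catalog's
    per-year uses, then to the crop's ``forage_only`` flag.
    """
    if isinstance(scenario, str):
        scenario = default_scenario(scenario)
    if crop_catalog is None:
        crop_catalog = default_crop_catalog()

    t = yield_table.copy()
    if "qc_flag" in t.columns:
        t = t[~t["qc_flag"].isin([FLAG_EXCLUDED, FLAG_MISSING])]
    if "yield_dry" not in t.columns:
        raise ValueError("yield table must carry a yield_dry column (run QC first)")
    if t["yield_dry"].isna().any():
        raise ValueError("yield_dry contains NaN; run QC/gap filling first")

    # rotation length and per-row area weight
    if rotations is not None:
        lengths = {rid: spec.length for rid, spec in rotations.items()}
        t["_length"] = t["rotation_id"].map(lengths)
        if t["_length"].isna().any():
            bad = sorted(t.loc[t["_length"].isna(), "rotation_id"].unique())
            raise UnknownCropError(f"rotations missing from catalog: {bad}")
    elif "rotation_length" in t.columns:
        t["_length"] = t["rotation_length"]
    else:
        raise ValueError(
            "need a rotation catalog or a rotation_length column to weight outputs"
        )

    # end use per row
    if "use" in t.columns:
        use = t["use"].fillna("").astype(str)
    else:
        use = pd.Series("", index=t.index)
    if rotations is not None and "year_index" in t.columns:
        for rid, spec in rotations.items():
            if spec.uses is None:
                continue
            m = t["rotation_id"].eq(rid) & use.eq("")
            use.loc[m] = [spec.uses[int(i)] for i in t.loc[m, "year_index"]]

    unknown = sorted(set(t["crop"]) - set(crop_catalog))
    if unknown:
        rots = sorted(t.loc[t["crop"].isin(unknown), "rotation_id"].unique())
        raise UnknownCropError(
            f"crops {unknown} absent from the crop catalog (rotations {rots})"
        )

    # per-row nutrient outputs M
    y = t["yield_dry"].to_numpy(dtype=float)
    m_cols = {n: np.zeros(len(t)) for n in NUTRIENTS}
    crops = t["crop"].to_numpy()
    use_arr = use.to_numpy()
    for crop in np.unique(crops):
        profile = crop_catalog[crop]
        sel = crops == crop
        if profile.functional_type == "fallow":
            continue  # structural zero
        forage_rows = sel & ((use_arr == "forage") | profile.forage_only)
        food_rows = sel & ~forage_rows
        for n in NUTRIENTS:
            if forage_rows.any():
                m_cols[n][forage_rows] = forage_output(y[forage_rows], scenario, n)
            if food_rows.any():
                if profile.forage_only:
                    raise ValueError(
                        f"crop {crop!r} is forage-only but has food-use rows"
                    )
                m_cols[n][food_rows] = crop_output(y[food_rows], profile, n)

    for n in NUTRIENTS:
        t[f"_M_{n}"] = m_cols[n]
    t["_w"] = 1.0 / t["_length"].to_numpy(dtype=float)

    keys = ["site", "calendar_year", "rotation_id", "group"]
    carry = [c for c in ("time_since_start", "fr_label", "treatment") if c in t.columns]
    grouped = t.groupby(keys, sort=False)
    counts = grouped.size()
    lengths = grouped["_length"].first()
    bad = counts[counts != lengths]
    if len(bad):
        raise ValueError(
            "combinations missing crop-years (all crops of a rotation must be "
            f"present every season): {bad.index.tolist()[:5]}"
        )

    agg = {f"_M_{n}": "sum" for n in NUTRIENTS}
    out = grouped.agg({**{c: "first" for c in carry}, **agg, "_w": "first"})
    rows = []
    for n in NUTRIENTS:
        sub = out.reset_index()[keys + carry].copy()
        sub["nutrient"] = n
        sub["unit"] = UNITS[n]
        sub["scenario"] = scenario.name
        sub["O"] = (out[f"_M_{n}"] * out["_w"]).to_numpy()
        rows.append(sub)
    result = pd.concat(rows, ignore_index=True)

    # FR label: prefer the table's own label, else classify from the catalog
    if "fr_label" not in result.columns:
        if rotations is None:
            raise ValueError("cannot determine FR labels without a rotation catalog")
        labels = {
            rid: functional_richness(spec, crop_catalog).label
            for rid, spec in rotations.items()
            if rid in set(result["rotation_id"])
        }
        result["fr_label"] = result["rotation_id"].map(labels)
    return result


class NutritionConverter(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`build_output_table`.

    Parameters
    ----------
    scenario : str
        Forage end use: "milk", "beef" or "biofuel".
    crop_catalog, rotations : dict or None
        Catalogs; ``None`` falls back to the bundled defaults / table columns.
    """

    def __init__(self, scenario: str = "milk", crop_catalog=None, rotations=None):
        self.scenario = scenario
        self.crop_catalog = crop_catalog
        self.rotations = rotations

    def fit(self, X: pd.DataFrame, y=None):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        out = build_output_table(
            X,
            crop_catalog=self.crop_catalog,
            rotations=self.rotations,
            scenario=self.scenario,
        )
        self.n_outputs_ = len(out)
        return out
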