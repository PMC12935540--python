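"""Crop functional types, rotation functional richness and area fractions.

Crops are binned into four functional types — annual cereal, annual legume,
annual broadleaf (root and oil crops) and ley (biennial/perennial grass and/or
legume plantings for feed) — plus fallow as a structural placeholder.  A
rotation's functional richness (FR) is the number of distinct non-fallow
functional types it contains.  Cereal-based rotations are split into
monocultures (FR "1M": one cereal species repeated) and cereal-only rotations
(FR "1C": two or more cereal species, no other type).

Every rotation year, fallow included, is weighted by ``1 / rotation_length``
when whole-rotation outputs are aggregated: a longer rotation on a fixed land
area devotes a smaller share of that area to each crop in any given year.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

FUNCTIONAL_TYPES = ("cereal", "annual_legume", "annual_broadleaf", "ley", "fallow")

#: Nutrients tracked throughout the package, and the units their outputs carry.
NUTRIENTS = ("calorie", "carbohydrate", "protein", "fat")


class UnknownCropError(KeyError):
    """A crop name is absent from the crop catalog."""


class NoCerealError(ValueError):
    """A rotation contains no cereal year and violates the retention criterion."""


@dataclass(frozen=True)
class CropProfile:
    """Per-crop functional classification and yield-to-nutrient conversion factors.

    Parameters
    ----------
    crop_name : str
        Catalog identifier (species level; cultivars are not distinguished).
    functional_type : str
        One of :data:`FUNCTIONAL_TYPES`.
    edible : bool
        Whether the harvest is directly consumable by humans.
    forage_only : bool
        Whether the crop serves only as animal feed; conversion is then
        handled by a forage end-use scenario and the factors below are unused.
    f_H2O : float
        Water fraction of the retail product, in ``[0, 1)``.
    alpha : float
        Crop-to-retail factor: kg of retail product per kg of harvested yield.
    f_ref : float
        Refuse factor: edible weight per unit mass of retail product, ``[0, 1]``.
    gamma : dict
        Nutrient conversion rates per kg of retail product: Gcal/kg for
        ``"calorie"``, kg/kg for the macronutrients.
    retail_product : str
        Label of the retail product the factors refer to (e.g. flour, oil).
    """

    crop_name: str
    functional_type: str
    edible: bool
    forage_only: bool
    f_H2O: float = 0.0
    alpha: float = 0.0
    f_ref: float = 0.0
    gamma: dict = field(default_factory=dict)
    retail_product: str = ""

    def __post_init__(self):
        if self.functional_type not in FUNCTIONAL_TYPES:
            raise ValueError(
                f"unknown functional type {self.functional_type!r} for crop "
                f"{self.crop_name!r}; expected one of {FUNCTIONAL_TYPES}"
            )
        if self.forage_only or self.functional_type == "fallow":
            return
        if not 0.0 <= self.f_H2O < 1.0:
            raise ValueError(f"{self.crop_name}: f_H2O must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError(f"{self.crop_name}: alpha must be >= 0")
        if not 0.0 <= self.f_ref <= 1.0:
            raise ValueError(f"{self.crop_name}: f_ref must be in [0, 1]")
        if any(v < 0 for v in self.gamma.values()):
            raise ValueError(f"{self.crop_name}: gamma values must be >= 0")


@dataclass(frozen=True)
class RotationSpec:
    """An ordered crop sequence, one entry per rotation year.

    ``uses`` optionally disambiguates the end use of each year ("food",
    "forage" or "none" for fallow); crops such as maize are grown for forage
    in some rotations and for direct human consumption in others.
    """

    rotation_id: str
    crop_sequence: tuple
    uses: tuple | None = None

    def __post_init__(self):
        if len(self.crop_sequence) < 1:
            raise ValueError(f"rotation {self.rotation_id!r}: empty crop sequence")
        if self.uses is not None and len(self.uses) != len(self.crop_sequence):
            raise ValueError(
                f"rotation {self.rotation_id!r}: uses must match sequence length"
            )

    @property
    def length(self) -> int:
        return len(self.crop_sequence)


@dataclass(frozen=True)
class FRLevel:
    """Functional-richness level of a rotation.

    ``label`` is "1M" (cereal monoculture), "1C" (cereal-only rotation with
    >= 2 species) or the number of distinct non-fallow functional types as a
    string ("2", "3", ...).  ``contains_fallow`` flags rotations where fallow
    years were excluded from the type count.
    """

    label: str
    n_types: int
    contains_fallow: bool = False


def classify_functional_type(crop_name: str, catalog: dict) -> str:
    """Look up the functional type of ``crop_name`` in a crop catalog."""
    try:
        return catalog[crop_name].functional_type
    except KeyError:
        raise UnknownCropError(
            f"crop {crop_name!r} not found in the crop catalog "
            f"({len(catalog)} entries); add it to the catalog CSV"
        ) from None


def functional_richness(rotation: RotationSpec, catalog: dict) -> FRLevel:
    """Classify a rotation by the number of functional types it contains.

    Fallow years are excluded from type counting.  A rotation without any
    cereal year raises :class:`NoCerealError`, mirroring the retention rule
    that every analysed rotation include at least one cereal year.
    """
    types = [classify_functional_type(c, catalog) for c in rotation.crop_sequence]
    non_fallow = [(c, t) for c, t in zip(rotation.crop_sequence, types) if t != "fallow"]
    has_fallow = len(non_fallow) < len(types)
    if not any(t == "cereal" for _, t in non_fallow):
        raise NoCerealError(
            f"rotation {rotation.rotation_id!r} has no cereal year; such "
            "rotations are outside the analysis scope"
        )
    distinct_types = sorted({t for _, t in non_fallow})
    n_types = len(distinct_types)
    if distinct_types == ["cereal"]:
        n_species = len({c for c, _ in non_fallow})
        label = "1M" if n_species == 1 else "1C"
    else:
        label = str(n_types)
    return FRLevel(label=label, n_types=n_types, contains_fallow=has_fallow)


def area_fraction(rotation: RotationSpec) -> dict:
    """Area weight of each rotation year: ``1 / length`` for every year.

    Fallow years receive the same weight; they contribute zero output
    downstream.  Weights sum to 1 up to floating point.
    """
    w = 1.0 / rotation.length
    return {i: w for i in range(rotation.length)}


# ---------------------------------------------------------------------------
# catalog I/O


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)


def load_crop_catalog(path_or_buffer) -> dict:
    """Read a crop catalog CSV into a dict of :class:`CropProfile`.

    Expected columns: crop_name, functional_type, edible, forage_only, f_H2O,
    alpha, f_ref, gamma_calorie, gamma_carb, gamma_protein, gamma_fat,
    retail_product.  Factor columns may be empty for forage-only crops and
    fallow.
    """
    df = pd.read_csv(path_or_buffer)
    required = {"crop_name", "functional_type", "edible", "forage_only"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"crop catalog is missing columns: {sorted(missing)}")
    gamma_cols = {
        "calorie": "gamma_calorie",
        "carbohydrate": "gamma_carb",
        "protein": "gamma_protein",
        "fat": "gamma_fat",
    }
    catalog = {}
    for _, row in df.iterrows():
        forage_only = _as_bool(row["forage_only"])
        ftype = str(row["functional_type"])
        has_factors = not (forage_only or ftype == "fallow")

        def num(col, default=0.0):
            v = row.get(col, default)
            return default if pd.isna(v) else float(v)

        gamma = (
            {n: num(col) for n, col in gamma_cols.items()} if has_factors else {}
        )
        profile = CropProfile(
            crop_name=str(row["crop_name"]),
            functional_type=ftype,
            edible=_as_bool(row["edible"]),
            forage_only=forage_only,
            f_H2O=num("f_H2O") if has_factors else 0.0,
            alpha=num("alpha") if has_factors else 0.0,
            f_ref=num("f_ref") if has_factors else 0.0,
            gamma=gamma,
            retail_product=str(row.get("retail_product", "")),
        )
        catalog[profile.crop_name] = profile
    return catalog


def load_rotation_catalog(path_or_buffer) -> dict:
    """Read a rotation catalog CSV (rotation_id, year_index, crop_name[, use])."""
    df = pd.read_csv(path_or_buffer)
    required = {"rotation_id", "year_index", "crop_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rotation catalog is missing columns: {sorted(missing)}")
    rotations = {}
    for rid, sub in df.groupby("rotation_id", sort=False):
        sub = sub.sort_values("year_index")
        idx = sub["year_index"].to_numpy()
        if not (idx == range(len(idx))).all():
            raise ValueError(
                f"rotation {rid!r}: year_index must be 0..length-1 without gaps"
            )
        uses = tuple(sub["use"]) if "use" in sub.columns else None
        rotations[rid] = RotationSpec(
            rotation_id=str(rid), crop_sequence=tuple(sub["crop_name"]), uses=uses
        )
    return rotations


def default_crop_catalog() -> dict:
    """Bundled crop conversion catalog.

    The factor values are representative figures compiled from public
    food-composition sources; they are replaceable defaults, not an
    authoritative reference, and analyses of real experiments should supply
    their own catalog CSV.
    """
    ref = importlib.resources.files("rotanutri.data") / "default_crop_catalog.csv"
    with ref.open() as fh:
        return load_crop_catalog(fh)


def default_rotation_catalog() -> dict:
    """Bundled example rotation catalog spanning FR levels 1M, 1C, 2 and 3."""
    ref = importlib.resources.files("rotanutri.data") / "default_rotations.csv"
    with ref.open() as fh:
        return load_rotation_catalog(fh)
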