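"""Synthetic long-term rotation-experiment yield data with known ground truth.

The generator emulates a network of European long-term experiments: a
configurable number of sites of differing potential productivity, each
running 11-53 consecutive growing seasons with staggered start years,
hosting several rotations whose every crop is present every season,
replicated as treatment x replicate groups.

Yields are generated on the square-root scale, where the downstream analysis
model lives:

    s = sqrt(baseline_crop * fr_effect) + b1*t' + b2*t'^2
        + u_site + u_year + u_group + e,        yield = max(s, 0)^2

with ``t'`` the time since start divided by ``time_scale`` and independent
Gaussian effects for site, calendar year (shared across sites), group
(treatment x replicate, nested in site) and a per-record residual.  The
truncation at zero guarantees non-negative yields.  For single-crop
rotations converted with identity factors, sqrt(whole-rotation output)
follows the analysis model exactly, which is what makes parameter-recovery
testing clean; for multi-crop rotations the mapping of the configured
effects to sqrt-output-scale coefficients is approximate (the square root
of a sum is not the sum of square roots) and :func:`true_params` labels it
as such.

Missing records and unexplained zeros are injected completely at random at
the configured rates (defaults 2.28% and 0.92%) with a provenance flag so
QC tests know the ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from numpy.random import default_rng

from .diversity import CropProfile

#: version of the long-format yield table column schema written by this module
SCHEMA_VERSION = "1"

YIELD_COLUMNS = [
    "site",
    "calendar_year",
    "time_since_start",
    "rotation_id",
    "fr_label",
    "rotation_length",
    "year_index",
    "treatment",
    "replicate",
    "group",
    "crop",
    "use",
    "yield_raw",
    "water_content",
    "note",
    "anomaly",
]


@dataclass(frozen=True)
class SimRotation:
    """A rotation in the simulation: crop sequence with a declared FR label."""

    rotation_id: str
    crop_sequence: tuple
    fr_label: str
    uses: tuple | None = None

    def __post_init__(self):
        if len(self.crop_sequence) < 1:
            raise ValueError(f"rotation {self.rotation_id!r}: empty sequence")
        if self.uses is not None and len(self.uses) != len(self.crop_sequence):
            raise ValueError(f"rotation {self.rotation_id!r}: uses length mismatch")

    @property
    def length(self) -> int:
        return len(self.crop_sequence)


@dataclass
class SimConfig:
    """Ground-truth configuration of a synthetic experiment network.

    Standard deviations are on the sqrt-yield scale; ``fr_effects`` are
    multiplicative yield effects per FR level; ``time_linear`` / ``time_quad``
    are sqrt-scale trend coefficients against scaled time ``t' in [0, 1]``.
    """

    n_sites: int = 16
    years_min: int = 11
    years_max: int = 53
    rotations: list = field(default_factory=lambda: default_sim_rotations())
    n_treatments: int = 1
    n_replicates: int = 3
    site_sd: float = 8.0
    year_sd: float = 3.0
    group_sd: float = 2.0
    residual_sd: float = 5.0
    crop_baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    crop_water: dict = field(default_factory=lambda: dict(DEFAULT_WATER))
    fr_effects: dict = field(
        default_factory=lambda: {"1M": 1.0, "1C": 0.93, "2": 0.96, "3": 1.08}
    )
    time_linear: dict = field(
        default_factory=lambda: {"1M": -4.0, "1C": 2.0, "2": -2.0, "3": 5.0}
    )
    time_quad: dict = field(
        default_factory=lambda: {"1M": 0.0, "1C": 0.0, "2": 0.0, "3": -2.0}
    )
    missing_rate: float = 0.0228
    zero_rate: float = 0.0092
    start_year_min: int = 1970
    start_year_max: int = 2005
    time_scale: float | None = None
    seed: int = 0

    @property
    def groups_per_rotation(self) -> int:
        return self.n_treatments * self.n_replicates

    def effective_time_scale(self) -> float:
        return float(self.time_scale or max(self.years_max - 1, 1))

    def validate(self) -> None:
        errors = []
        if self.n_sites < 1:
            errors.append("n_sites must be >= 1")
        if not 1 <= self.years_min <= self.years_max:
            errors.append("need 1 <= years_min <= years_max")
        if self.n_treatments < 1 or self.n_replicates < 1:
            errors.append("n_treatments and n_replicates must be >= 1")
        for name in ("site_sd", "year_sd", "group_sd", "residual_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("missing_rate", "zero_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        if self.missing_rate + self.zero_rate > 1.0:
            errors.append("missing_rate + zero_rate must not exceed 1")
        if not self.rotations:
            errors.append("at least one rotation is required")
        for rot in self.rotations:
            for crop in rot.crop_sequence:
                if crop != "fallow" and crop not in self.crop_baselines:
                    errors.append(
                        f"rotation {rot.rotation_id!r} references crop {crop!r} "
                        "absent from crop_baselines"
                    )
            if rot.fr_label not in self.fr_effects:
                errors.append(
                    f"rotation {rot.rotation_id!r} FR {rot.fr_label!r} has no "
                    "fr_effects entry"
                )
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))

    # -- (de)serialisation ---------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["rotations"] = [
            {
                "rotation_id": r.rotation_id,
                "crop_sequence": list(r.crop_sequence),
                "fr_label": r.fr_label,
                "uses": list(r.uses) if r.uses else None,
            }
            for r in self.rotations
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["rotations"] = [
            SimRotation(
                rotation_id=r["rotation_id"],
                crop_sequence=tuple(r["crop_sequence"]),
                fr_label=r["fr_label"],
                uses=tuple(r["uses"]) if r.get("uses") else None,
            )
            for r in d.get("rotations", [])
        ]
        return cls(**d)


DEFAULT_BASELINES = {
    "winter_wheat": 6000.0,
    "spring_barley": 4500.0,
    "oat": 4000.0,
    "oilseed_rape": 2800.0,
    "pea": 3000.0,
    "ley": 7000.0,
}

DEFAULT_WATER = {
    "winter_wheat": 0.14,
    "spring_barley": 0.14,
    "oat": 0.14,
}


def default_sim_rotations() -> list:
    """Example rotations spanning FR 1M, 1C, 2 and 3, plus one with fallow."""
    return [
        SimRotation("R1M_wheat", ("winter_wheat",), "1M"),
        SimRotation("R1C_cereals", ("winter_wheat", "spring_barley", "oat"), "1C"),
        SimRotation(
            "R2_oilseed",
            ("winter_wheat", "oilseed_rape", "winter_wheat", "spring_barley"),
            "2",
        ),
        SimRotation(
            "R3_ley",
            ("spring_barley", "ley", "ley", "winter_wheat", "pea"),
            "3",
            uses=("food", "forage", "forage", "food", "food"),
        ),
        SimRotation("R1M_fallow", ("winter_wheat", "fallow"), "1M"),
    ]


@dataclass(frozen=True)
class ParameterSet:
    """Ground-truth parameters in the analysis-model parameterisation.

    ``beta`` maps model coefficient names (intercept, t, t2, fr<L>, fr<L>:t,
    fr<L>:t2) to sqrt-output-scale truths; ``variances`` holds the site,
    group and year variance components and ``residual`` the residual
    variance.  ``exact`` is False when any rotation required the approximate
    multi-crop mapping.
    """

    beta: dict
    variances: dict
    residual: float
    time_scale: float
    exact: bool


def _sqrt_output_poly(config: SimConfig, rot: SimRotation) -> tuple:
    """Quadratic coefficients of noise-free sqrt whole-rotation 'output'
    against scaled time, assuming identity conversion factors (output =
    area-weighted mean yield).  Exact for rotations whose non-fallow crops
    share one baseline; least-squares approximation otherwise."""
    m = config.fr_effects[rot.fr_label]
    b1 = config.time_linear.get(rot.fr_label, 0.0)
    b2 = config.time_quad.get(rot.fr_label, 0.0)
    bases = [
        config.crop_baselines[c] for c in rot.crop_sequence if c != "fallow"
    ]
    L = rot.length
    if len(set(bases)) == 1 and len(bases) == L:
        a0 = np.sqrt(bases[0] * m)
        return (a0, b1, b2), True
    # mixed baselines or fallow years: fit sqrt((1/L) sum s_c^2) on a grid
    grid = np.linspace(0.0, 1.0, 21)
    vals = []
    for t in grid:
        s = np.array([np.sqrt(config.crop_baselines[c] * m) + b1 * t + b2 * t**2
                      for c in rot.crop_sequence if c != "fallow"])
        vals.append(np.sqrt(np.sum(s**2) / L))
    coefs = np.polynomial.polynomial.polyfit(grid, np.array(vals), 2)
    return (coefs[0], coefs[1], coefs[2]), False


def true_params(config: SimConfig) -> ParameterSet:
    """Ground-truth analysis-model parameters implied by a configuration.

    The mapping assumes identity conversion factors (whole-rotation output
    equals the area-weighted yield) and uses, for each FR level, the first
    rotation carrying that label.  See module docstring for when it is
    exact.
    """
    config.validate()
    by_fr = {}
    for rot in config.rotations:
        by_fr.setdefault(rot.fr_label, rot)
    if "1M" not in by_fr:
        raise ValueError("true_params needs a rotation with FR label '1M'")
    exact = True
    polys = {}
    for fr, rot in by_fr.items():
        poly, ok = _sqrt_output_poly(config, rot)
        polys[fr] = poly
        exact = exact and ok
    a0, a1, a2 = polys["1M"]
    beta = {"intercept": a0, "t": a1, "t2": a2}
    order = [f for f in ("1C", "2", "3") if f in polys]
    order += [f for f in sorted(polys) if f not in order + ["1M"]]
    for fr in order:
        c0, c1, c2 = polys[fr]
        beta[f"fr{fr}"] = c0 - a0
        beta[f"fr{fr}:t"] = c1 - a1
        beta[f"fr{fr}:t2"] = c2 - a2
    return ParameterSet(
        beta=beta,
        variances={
            "site": config.site_sd**2,
            "group": config.group_sd**2,
            "year": config.year_sd**2,
        },
        residual=config.residual_sd**2,
        time_scale=config.effective_time_scale(),
        exact=exact,
    )


def generate_experiment(config: SimConfig) -> pd.DataFrame:
    """Generate a long-format synthetic yield table.

    One row per site x calendar_year x rotation x group x crop-in-rotation;
    every crop of every rotation is present every season.  Deterministic for
    a fixed ``config.seed``; yields are never negative.  Missing records and
    unexplained zeros are injected at the configured rates via
    :func:`inject_anomalies`.
    """
    config.validate()
    rng = default_rng(config.seed)
    tscale = config.effective_time_scale()

    sites = [f"S{i:02d}" for i in range(config.n_sites)]
    years_per_site = rng.integers(
        config.years_min, config.years_max + 1, size=config.n_sites
    )
    start_years = rng.integers(
        config.start_year_min, config.start_year_max + 1, size=config.n_sites
    )
    u_site = rng.normal(0.0, config.site_sd, size=config.n_sites)

    all_years = np.arange(
        config.start_year_min, config.start_year_max + config.years_max + 1
    )
    u_year = dict(zip(all_years, rng.normal(0.0, config.year_sd, len(all_years))))

    treatments = [chr(ord("A") + i) for i in range(config.n_treatments)]
    replicates = [str(j + 1) for j in range(config.n_replicates)]
    u_group = rng.normal(
        0.0,
        config.group_sd,
        size=(config.n_sites, config.n_treatments, config.n_replicates),
    )

    frames = []
    for si, site in enumerate(sites):
        n_years = int(years_per_site[si])
        t = np.arange(n_years)
        cal = start_years[si] + t
        ts = t / tscale
        uy = np.array([u_year[c] for c in cal])
        for rot in config.rotations:
            L = rot.length
            seq = np.array(rot.crop_sequence)
            uses = np.array(
                rot.uses
                if rot.uses is not None
                else ["none" if c == "fallow" else "food" for c in seq]
            )
            base = np.array(
                [
                    0.0
                    if c == "fallow"
                    else np.sqrt(
                        config.crop_baselines[c] * config.fr_effects[rot.fr_label]
                    )
                    for c in seq
                ]
            )
            trend = (
                config.time_linear.get(rot.fr_label, 0.0) * ts
                + config.time_quad.get(rot.fr_label, 0.0) * ts**2
            )
            for ti_idx, trt in enumerate(treatments):
                for ri_idx, rep in enumerate(replicates):
                    ug = u_group[si, ti_idx, ri_idx]
                    eps = rng.normal(0.0, config.residual_sd, size=(n_years, L))
                    s = (
                        base[None, :]
                        + trend[:, None]
                        + u_site[si]
                        + uy[:, None]
                        + ug
                        + eps
                    )
                    dry = np.clip(s, 0.0, None) ** 2
                    fallow_mask = seq == "fallow"
                    dry[:, fallow_mask] = 0.0
                    wc = np.array([config.crop_water.get(c, 0.0) for c in seq])
                    raw = dry / (1.0 - wc[None, :])
                    frames.append(
                        pd.DataFrame(
                            {
                                "site": site,
                                "calendar_year": np.repeat(cal, L),
                                "time_since_start": np.repeat(t, L),
                                "rotation_id": rot.rotation_id,
                                "fr_label": rot.fr_label,
                                "rotation_length": L,
                                "year_index": np.tile(np.arange(L), n_years),
                                "treatment": trt,
                                "replicate": rep,
                                "group": trt + rep,
                                "crop": np.tile(seq, n_years),
                                "use": np.tile(uses, n_years),
                                "yield_raw": raw.ravel(),
                                "water_content": np.tile(wc, n_years),
                                "note": np.where(
                                    np.tile(fallow_mask, n_years), "fallow", ""
                                ),
                                "anomaly": "none",
                            }
                        )
                    )
    table = pd.concat(frames, ignore_index=True)[YIELD_COLUMNS]
    if config.missing_rate > 0 or config.zero_rate > 0:
        table = inject_anomalies(
            table,
            missing_rate=config.missing_rate,
            zero_rate=config.zero_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    table.attrs["schema_version"] = SCHEMA_VERSION
    return table


def inject_anomalies(
    table: pd.DataFrame, missing_rate: float, zero_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Randomly blank or zero yields, flagging provenance in ``anomaly``.

    Missingness is completely at random among rows with an observed positive
    yield and no structural annotation (fallow rows are never touched).
    Row count is unchanged; injected zeros are distinguishable from
    structural zeros through the ``anomaly`` column.
    """
    if not 0.0 <= missing_rate <= 1.0 or not 0.0 <= zero_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    if missing_rate + zero_rate > 1.0:
        raise ValueError("missing_rate + zero_rate must not exceed 1")
    table = table.copy()
    if "anomaly" not in table.columns:
        table["anomaly"] = "none"
    note = table.get("note", pd.Series("", index=table.index)).fillna("")
    eligible = (
        table["yield_raw"].notna()
        & (table["yield_raw"] > 0)
        & note.eq("")
        & table["anomaly"].eq("none")
    )
    idx = table.index[eligible]
    rng = default_rng(seed)
    u = rng.random(len(idx))
    miss = idx[u < missing_rate]
    zero = idx[(u >= missing_rate) & (u < missing_rate + zero_rate)]
    table.loc[miss, "yield_raw"] = np.nan
    table.loc[miss, "anomaly"] = "injected_missing"
    table.loc[zero, "yield_raw"] = 0.0
    table.loc[zero, "anomaly"] = "injected_zero"
    return table


def identity_crop_catalog(crop_names) -> dict:
    """Catalog whose factors make nutrient output equal dry yield.

    Used by parameter-recovery tests so the analysis model on sqrt output is
    exactly the generating model for single-crop rotations.
    """
    catalog = {}
    for name in crop_names:
        if name == "fallow":
            catalog[name] = CropProfile(
                crop_name="fallow",
                functional_type="fallow",
                edible=False,
                forage_only=False,
            )
            continue
        catalog[name] = CropProfile(
            crop_name=name,
            functional_type="cereal",
            edible=True,
            forage_only=False,
            f_H2O=0.0,
            alpha=1.0,
            f_ref=1.0,
            gamma={n: 1.0 for n in ("calorie", "carbohydrate", "protein", "fat")},
            retail_product="identity",
        )
    return catalog


def recovery_sim_config(
    n_sites: int = 30,
    years: int = 30,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Configuration used for parameter-recovery studies.

    Four single-crop rotations, one per FR level, with identity conversion
    baselines; equal experiment length at every site so the generating model
    matches the analysis model exactly.
    """
    baselines = {"c_1M": 6000.0, "c_1C": 5200.0, "c_2": 4800.0, "c_3": 5600.0}
    rotations = [
        SimRotation(f"R_{fr}", (f"c_{fr}",), fr) for fr in ("1M", "1C", "2", "3")
    ]
    defaults = dict(
        n_sites=n_sites,
        years_min=years,
        years_max=years,
        rotations=rotations,
        n_treatments=1,
        n_replicates=2,
        site_sd=6.0,
        year_sd=3.0,
        group_sd=2.0,
        residual_sd=5.0,
        crop_baselines=baselines,
        crop_water={},
        fr_effects={"1M": 1.0, "1C": 0.93, "2": 0.96, "3": 1.08},
        time_linear={"1M": -4.0, "1C": 2.0, "2": -2.0, "3": 5.0},
        time_quad={"1M": 1.0, "1C": -1.0, "2": 0.5, "3": -2.0},
        missing_rate=0.0,
        zero_rate=0.0,
        time_scale=float(years - 1),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def write_yield_table(table: pd.DataFrame, path) -> None:
    """Write the long-format yield table CSV (schema v1 column order)."""
    cols = [c for c in YIELD_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)
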