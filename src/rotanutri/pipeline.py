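"""End-to-end orchestration: simulate -> QC -> convert -> fit -> contrast -> report.

A run is driven by a :class:`RunConfig` (YAML-serialisable).  Inputs are a
yield table plus crop and rotation catalogs, or a synthetic-experiment
configuration; the run directory receives every intermediate table, one
fitted-model JSON per nutrient x forage scenario, prediction and contrast
tables, a dietary-balance report and a manifest recording the master seed,
a hash of the configuration and row counts.  Inputs are never mutated in
place.  The leave-one-site-out loop refits the model once per held-out site
and flags contrasts whose sign or significance changes relative to the full
fit, reporting (rather than crashing on) refits that lose an entire FR
level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diet import calorie_shares, compare_recommendation
from .diversity import NUTRIENTS, default_crop_catalog, load_crop_catalog, load_rotation_catalog
from .model import RotationOutputModel, contrast_results_frame
from .nutrition import SCENARIOS, NutritionConverter
from .qc import YieldQC
from .simulate import SimConfig, generate_experiment, write_yield_table

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    yield_table: str | None = None
    crop_catalog: str | None = None
    rotation_catalog: str | None = None
    simulate: SimConfig | None = field(default_factory=SimConfig)
    scenarios: list = field(default_factory=lambda: ["milk"])
    nutrients: list = field(default_factory=lambda: list(NUTRIENTS))
    gap_fill: bool = True
    keep_unexplained_zeros: bool = False
    time_scale: str | float = "max"
    include_random: bool = True
    conf_level: float = 0.90
    prediction_times: list = field(default_factory=lambda: [5.0, 10.0, 20.0])
    mc_draws: int = 100_000
    diet_scenarios: list = field(default_factory=lambda: ["milk"])
    seed: int = 0
    outdir: str = "rotanutri_run"

    def validate(self) -> None:
        for s in list(self.scenarios) + list(self.diet_scenarios):
            if s not in SCENARIOS:
                raise ValueError(f"unknown forage scenario {s!r}")
        unknown = set(self.nutrients) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown nutrients {sorted(unknown)}")
        if self.yield_table is None and self.simulate is None:
            raise ValueError("need either a yield_table path or a simulate config")
        for attr in ("yield_table", "crop_catalog", "rotation_catalog"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr} path does not exist: {p}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"]["rotations"] = [
                {
                    "rotation_id": r.rotation_id,
                    "crop_sequence": list(r.crop_sequence),
                    "fr_label": r.fr_label,
                    "uses": list(r.uses) if r.uses else None,
                }
                for r in self.simulate.rotations
            ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.get("simulate")
        if sim is not None:
            from .simulate import SimRotation

            sim["rotations"] = [
                SimRotation(
                    rotation_id=r["rotation_id"],
                    crop_sequence=tuple(r["crop_sequence"]),
                    fr_label=r["fr_label"],
                    uses=tuple(r["uses"]) if r.get("uses") else None,
                )
                for r in sim.get("rotations", [])
            ]
            d["simulate"] = SimConfig(**sim)
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # where results land does not change what they are
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    crop_catalog = (
        load_crop_catalog(config.crop_catalog)
        if config.crop_catalog
        else default_crop_catalog()
    )
    rotations = (
        load_rotation_catalog(config.rotation_catalog)
        if config.rotation_catalog
        else None
    )
    if config.yield_table:
        table = pd.read_csv(config.yield_table)
    else:
        sim = config.simulate
        sim.seed = config.seed
        table = generate_experiment(sim)
    return table, crop_catalog, rotations


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    With ``dry_run`` the configuration and catalogs are validated and the
    manifest skeleton returned without computing anything.
    """
    config.validate()
    if dry_run:
        _load_inputs(config) if config.yield_table else None
        if config.simulate is not None:
            config.simulate.validate()
        return {"dry_run": True, "config_hash": config.config_hash()}

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "models": [],
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        stage("load")
        table, crop_catalog, rotations = _load_inputs(config)
        write_yield_table(table, out / "yield_table.csv")
        manifest["stages"]["load"] = {"n_rows": int(len(table))}

        stage("qc")
        qc = YieldQC(
            gap_fill=config.gap_fill,
            keep_unexplained_zeros=config.keep_unexplained_zeros,
        )
        qc_table = qc.transform(table)
        qc_table.to_csv(out / "qc_table.csv", index=False)
        qc.report_.to_json(out / "qc_report.json")
        manifest["stages"]["qc"] = qc.report_.to_dict()

        predictions = []
        diet_report = {}
        for scenario in config.scenarios:
            stage(f"convert[{scenario}]")
            conv = NutritionConverter(
                scenario=scenario, crop_catalog=crop_catalog, rotations=rotations
            )
            outputs = conv.transform(qc_table)
            outputs.to_csv(out / f"outputs_{scenario}.csv", index=False)
            manifest["stages"][f"convert_{scenario}"] = {
                "n_rows": int(len(outputs))
            }

            contrasts = []
            fitted = {}
            for nutrient in config.nutrients:
                stage(f"fit[{scenario}/{nutrient}]")
                model = RotationOutputModel(
                    time_scale=config.time_scale,
                    conf_level=config.conf_level,
                    include_random=config.include_random,
                    mc_draws=config.mc_draws,
                    random_state=config.seed,
                ).fit(outputs[outputs["nutrient"] == nutrient])
                model.to_json(out / f"model_{nutrient}_{scenario}.json")
                fitted[nutrient] = model
                manifest["models"].append(
                    {
                        "scenario": scenario,
                        "nutrient": nutrient,
                        "n_obs": model.n_obs_,
                        "converged": model.converged_,
                    }
                )
                levels = [model.baseline_] + model.levels_
                for t in [0.0] + list(config.prediction_times):
                    for fr in levels:
                        cell = model.predict_cells(fr, t)
                        predictions.append(
                            {
                                "scenario": scenario,
                                "nutrient": nutrient,
                                "fr": fr,
                                "time": t,
                                "prediction": cell.prediction,
                                "lower": cell.lower,
                                "upper": cell.upper,
                            }
                        )
                for t in config.prediction_times:
                    cf = contrast_results_frame(model.contrast_fr(t))
                    cf.insert(0, "family", f"fr_at_{t:g}y")
                    cf.insert(0, "nutrient", nutrient)
                    cf.insert(0, "scenario", scenario)
                    contrasts.append(cf)
                for fr in levels:
                    ct = contrast_results_frame(
                        model.contrast_time(fr, times=config.prediction_times)
                    )
                    ct.insert(0, "family", f"time_within_fr{fr}")
                    ct.insert(0, "nutrient", nutrient)
                    ct.insert(0, "scenario", scenario)
                    contrasts.append(ct)
            pd.concat(contrasts, ignore_index=True).to_csv(
                out / f"contrasts_{scenario}.csv", index=False
            )

            if scenario in config.diet_scenarios:
                stage(f"diet[{scenario}]")
                t_ref = max(config.prediction_times)
                per_fr = {}
                some_model = fitted[config.nutrients[0]]
                for fr in [some_model.baseline_] + some_model.levels_:
                    macro = {}
                    for nutrient in ("carbohydrate", "protein", "fat"):
                        if nutrient in fitted:
                            macro[nutrient] = fitted[nutrient].predict_cells(
                                fr, t_ref
                            ).prediction
                    if len(macro) == 3 and sum(macro.values()) > 0:
                        share = calorie_shares(
                            macro["carbohydrate"], macro["protein"], macro["fat"]
                        )
                        per_fr[fr] = {
                            "shares": share.as_dict(),
                            "verdicts": compare_recommendation(share),
                            "time": t_ref,
                        }
                diet_report[scenario] = per_fr

        pd.DataFrame(predictions).to_csv(out / "predictions.csv", index=False)
        with open(out / "diet_report.json", "w") as fh:
            json.dump(diet_report, fh, indent=2)
        manifest["diet_scenarios"] = list(diet_report)
    except Exception as e:
        raise RuntimeError(f"pipeline failed: {e}") from e

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def leave_one_site_out(
    outputs: pd.DataFrame,
    nutrient: str | None = None,
    times=(5.0, 10.0, 20.0),
    alpha: float = SIGNIFICANCE,
    **model_options,
) -> pd.DataFrame:
    """Refit the model once per held-out site; summarise contrast stability.

    Returns one row per held-out site x contrast with the refit estimate and
    adjusted p, and flags for sign changes or significance changes relative
    to the full fit.  A refit losing an entire FR level is reported as
    degenerate for the affected contrasts instead of raising.
    """
    if nutrient is not None:
        outputs = outputs[outputs["nutrient"] == nutrient]
    sites = sorted(outputs["site"].astype(str).unique())
    if len(sites) < 3:
        raise ValueError("leave-one-site-out needs at least 3 sites")

    def all_contrasts(model):
        res = {}
        for t in times:
            for c in model.contrast_fr(t):
                res[c.description] = c
        return res

    full_model = RotationOutputModel(**model_options).fit(outputs)
    full = all_contrasts(full_model)

    rows = []
    for site in sites:
        sub = outputs[outputs["site"].astype(str) != site]
        kept_levels = set(sub["fr_label"].astype(str))
        lost = set(outputs["fr_label"].astype(str)) - kept_levels
        model = RotationOutputModel(**model_options).fit(sub)
        refit = all_contrasts(model)
        for desc, ref in full.items():
            cur = refit.get(desc)
            degenerate = cur is None or any(f"FR{l}@" in desc for l in lost)
            rows.append(
                {
                    "held_out_site": site,
                    "contrast": desc,
                    "degenerate": degenerate,
                    "estimate": None if cur is None else cur.estimate,
                    "p_adj": None if cur is None else cur.p_adj,
                    "sign_change": (
                        False
                        if cur is None
                        else (cur.estimate * ref.estimate < 0)
                    ),
                    "significance_change": (
                        False
                        if cur is None
                        else ((cur.p_adj < alpha) != (ref.p_adj < alpha))
                    ),
                    "full_estimate": ref.estimate,
                    "full_p_adj": ref.p_adj,
                }
            )
    return pd.DataFrame(rows)
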