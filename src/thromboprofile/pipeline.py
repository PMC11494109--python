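"""End-to-end orchestration: simulate a study, profile it, derive barcodes,
score cohort discrimination, and summarise shear and adhesion kinetics.

`run_pipeline` is deterministic under (config, seed): per-stage random streams
are spawned from a single seed sequence, and the run directory receives tidy
CSV tables plus a machine-readable summary.json that embeds a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import barcode as bc
from . import bfp, hydro, stats, synth
from .barcode import DIMENSIONS

__all__ = ["RunConfig", "run_pipeline", "measure_profiles"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full synthetic run."""

    seed: int = 0
    design: synth.StudyDesign = field(default_factory=synth.StudyDesign)
    acquisition: synth.AcquisitionSpec = field(default_factory=synth.AcquisitionSpec)
    inhibitors: tuple[synth.InhibitorSpec, ...] = ()
    geometry: hydro.ChannelGeometry = field(
        default_factory=lambda: hydro.build_geometry(200.0, 50.0, 0.8)
    )
    flow: hydro.FlowCondition = field(default_factory=hydro.FlowCondition)
    bfp_scenario: synth.BfpScenario = field(default_factory=synth.BfpScenario)
    measurement_cv: float = 0.1  # assay noise per profile measurement
    alpha: float = 0.05
    correction: str = "holm-sidak"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "design" in raw:
            d = dict(raw["design"])
            for key in ("baseline_profile", "baseline_cv"):
                if key in d:
                    d[key] = tuple(d[key])
            if "effect_multipliers" in d:
                d["effect_multipliers"] = {
                    k: tuple(v) for k, v in d["effect_multipliers"].items()
                }
            kwargs["design"] = synth.StudyDesign(**d)
        if "acquisition" in raw:
            kwargs["acquisition"] = synth.AcquisitionSpec(**raw["acquisition"])
        if "inhibitors" in raw:
            specs = []
            for item in raw["inhibitors"]:
                item = dict(item)
                if "effect_barcode" in item:
                    item["effect_barcode"] = bc.Barcode.from_string(
                        item["effect_barcode"]
                    )
                specs.append(synth.InhibitorSpec(**item))
            kwargs["inhibitors"] = tuple(specs)
        if "geometry" in raw:
            kwargs["geometry"] = hydro.build_geometry(**raw["geometry"])
        if "flow" in raw:
            kwargs["flow"] = hydro.FlowCondition(**raw["flow"])
        for key in ("measurement_cv", "alpha", "correction"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            if isinstance(o, bc.Barcode):
                return str(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def measure_profiles(
    true_profiles: pd.DataFrame,
    measurement_cv: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Apply multiplicative assay noise to true profiles (one measurement each)."""
    out = true_profiles.copy()
    if measurement_cv > 0:
        sigma = np.sqrt(np.log1p(measurement_cv**2))
        noise = rng.lognormal(
            -0.5 * sigma**2, sigma, size=(len(out), len(DIMENSIONS))
        )
        out.loc[:, list(DIMENSIONS)] = out.loc[:, list(DIMENSIONS)].to_numpy() * noise
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write tables + summary.json to ``out_dir``.

    Stages: study generation -> measured profiles -> factor and drug effect
    barcodes (with the addition rule applied to drug-disease pairs) ->
    reference ranges, personal barcodes, census -> correlation/separation/
    consistency statistics -> stenosis shear table -> BFP kinetics. A failure
    in any stage aborts with an error naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(6)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return deco

    @stage("study")
    def subjects() -> pd.DataFrame:
        df = synth.generate_study(config.design, seed=seeds[0])
        df.to_csv(out / "subjects.csv", index=False)
        return df

    @stage("profiles")
    def profiles() -> pd.DataFrame:
        rng = np.random.default_rng(seeds[1])
        df = measure_profiles(subjects, config.measurement_cv, rng)
        df.to_csv(out / "profiles.csv", index=False)
        return df

    healthy = profiles[profiles["cohort"] == "healthy_young"]
    htn = profiles[profiles["cohort"].str.startswith("htn")]

    @stage("effect_barcodes")
    def effect_barcodes() -> dict:
        result = {}
        code = bc.derive_effect_barcode(
            healthy[list(DIMENSIONS)],
            htn[list(DIMENSIONS)],
            paired=False,
            alpha=config.alpha,
            correction=config.correction,
        )
        result["hypertension"] = str(code)
        rng = np.random.default_rng(seeds[2])
        for spec in config.inhibitors:
            base = htn if len(htn) >= 3 else healthy
            true_vals = base[list(DIMENSIONS)].to_numpy()
            treated = np.array(
                [synth.apply_inhibitor(row, spec, spec.ic50) for row in true_vals]
            )
            sigma = np.sqrt(np.log1p(config.measurement_cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, treated.shape)
            code = bc.derive_effect_barcode(
                true_vals, treated * noise, paired=True,
                alpha=config.alpha, correction=config.correction,
            )
            result[spec.name] = str(code)
            result[f"hypertension+{spec.name}"] = str(
                bc.add_barcodes(
                    bc.Barcode.from_string(result["hypertension"]), code
                )
            )
        return result

    @stage("personal_barcodes")
    def personal() -> dict:
        ranges = bc.build_reference_ranges(healthy[list(DIMENSIONS)])
        codes = [
            bc.personal_barcode(row, ranges)
            for row in profiles[list(DIMENSIONS)].to_numpy()
        ]
        profiles.assign(barcode=[str(c) for c in codes]).to_csv(
            out / "personal_barcodes.csv", index=False
        )
        cen = bc.census(codes)
        cen.abnormal_fractions.to_csv(out / "abnormal_fractions.csv")
        return {
            "n_distinct": cen.n_distinct,
            "most_common": cen.frequencies.index[0],
            "reference_ranges": ranges.to_frame().to_dict(orient="index"),
        }

    @stage("stats")
    def cohort_stats() -> dict:
        corr = stats.correlate(profiles["size"], profiles["eplus"])
        neg = healthy
        pos = profiles[profiles["cohort"] != "healthy_young"]
        sep_size = stats.best_threshold(neg["size"], pos["size"])
        sep_eplus = stats.best_threshold(neg["eplus"], pos["eplus"])
        lab_size = (profiles["size"] > sep_size.threshold).to_numpy()
        lab_eplus = (profiles["eplus"] > sep_eplus.threshold).to_numpy()
        consistency = stats.classification_consistency(lab_size, lab_eplus)
        return {
            "size_vs_eplus": dataclasses.asdict(corr),
            "separation_size": dataclasses.asdict(sep_size),
            "separation_eplus": dataclasses.asdict(sep_eplus),
            "consistency_pct": consistency,
        }

    @stage("hydro")
    def shear() -> dict:
        fieldres = hydro.shear_field(config.geometry, config.flow)
        fieldres.to_frame().to_csv(out / "shear.csv", index=False)
        return {
            "apex_wss_dyn_cm2": fieldres.apex_wall_shear_stress,
            "apex_shear_rate_per_s": fieldres.apex_wall_shear_rate,
            "reynolds_inlet": hydro.reynolds_number(
                config.geometry, config.flow, at="inlet"
            ),
        }

    @stage("bfp")
    def kinetics() -> dict:
        scen = config.bfp_scenario
        outcomes = synth.simulate_adhesion(scen, seed=seeds[3])
        p_a, se = bfp.adhesion_frequency(outcomes)
        res = {"p_a": p_a, "p_a_se": se}
        if 0 < p_a < 1:
            avidity, affinity = bfp.avidity_affinity(p_a, scen.m_r, scen.m_l)
            res.update(
                effective_avidity=avidity,
                effective_affinity=affinity,
                single_bond_probability=bfp.single_bond_probability(p_a),
            )
        lifetimes = synth.simulate_lifetimes(scen, seed=seeds[4])
        lifetimes.to_csv(out / "lifetimes.csv", index=False)
        curve = bfp.bin_lifetimes(lifetimes)
        call = bfp.classify_force_dependence(curve)
        res["bond_phenotype"] = call.phenotype.value
        if call.peak_force is not None:
            res["peak_force_pN"] = call.peak_force
            res["peak_lifetime_s"] = call.peak_lifetime
        return res

    summary.update(
        n_subjects=int(len(subjects)),
        effect_barcodes=effect_barcodes,
        personal_barcodes=personal,
        statistics=cohort_stats,
        hydrodynamics=shear,
        bfp=kinetics,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
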