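"""End-to-end middle-out workflow.

Stages: (1) synthesize/load observed studies, (2) calibrate mouse SpecPStc,
(3) cross-species evaluation (prediction-performance table), (4) derive
species observed clearances from printed dose/AUC summaries, (5) project
human clearance by the three methods, (6) simulate human exposure (MTM
6-h-infusion verification and the 13 ug/kg bolus comparison of both
compounds), (7) assemble the exposure-comparison table (plasma/liver AUCs,
liver partition, ratios vs MTM), (8) parameter sensitivity analysis.

The module-level helpers are the public API; :func:`run_workflow` wires
them together from a single config mapping and writes per-stage CSVs.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import fit_spec_pstc
from .clearance import (
    ClearanceRecord,
    additional_clearance_human,
    allometric_fit,
    allometric_predict,
    renal_filtration_cl,
    single_species_scale,
)
from .compounds import CompoundParams, load_compound
from .engine import Regimen, SimulationResult, build_model
from .evaluation import evaluate_profile
from .kp import predict_kp
from .nca import auc_loglinear, observed_clearance
from .physiology import SpeciesPhysiology, get_physiology
from .sensitivity import SCAN_PARAMETERS, default_scan_values, psa, rank_parameters
from .synth import DEFAULT_SAMPLING_H, make_study

log = logging.getLogger("mithrapbpk")

PRECLINICAL_SPECIES = ("mouse", "rat", "monkey")

#: Human first-in-human comparison regimen: 13 ug/kg single IV bolus.
HUMAN_BOLUS = Regimen.bolus(13.0, unit="ug/kg")

#: Human MTM clinical regimen: 13 ug/kg as a 6-h IV infusion daily for 7 days.
HUMAN_INFUSION_X7 = Regimen.infusion(13.0, unit="ug/kg", duration_h=6.0,
                                     n_doses=7, interval_h=24.0)

METHOD_LABELS = {
    "additional": "Additional clearance",
    "allometric": "Allometric scaling",
    "single_species": "Single species scaling",
}


def load_studies() -> pd.DataFrame:
    """Bundled observed-study summary table (dose, route, observed AUC)."""
    raw = yaml.safe_load(
        resources.files("mithrapbpk").joinpath("data/studies.yaml").read_text()
    )
    return pd.DataFrame(raw["studies"])


def regimen_for_study(row: Mapping) -> Regimen:
    raw_n = row.get("n_doses")
    n_doses = 1 if raw_n is None or pd.isna(raw_n) else int(raw_n)
    raw_iv = row.get("interval_h")
    interval = 24.0 if raw_iv is None or pd.isna(raw_iv) else float(raw_iv)
    if row["route"] == "bolus":
        return Regimen.bolus(row["dose"], unit=row["dose_unit"], n_doses=n_doses,
                             interval_h=interval)
    return Regimen.infusion(row["dose"], unit=row["dose_unit"],
                            duration_h=float(row["infusion_h"]),
                            n_doses=n_doses, interval_h=interval)


def derive_clearances(
    compound: CompoundParams,
    studies: pd.DataFrame | None = None,
    physiologies: Mapping[str, SpeciesPhysiology] | None = None,
) -> pd.DataFrame:
    """Observed clearances and their renal/additional split per species.

    CL_obs = dose / AUC_obs from the reference study arm of each
    preclinical species (the higher monkey dose level). Returns one row per
    species with per-kg and absolute clearance plus the Method-1
    decomposition against fup * GFR.
    """
    studies = load_studies() if studies is None else studies
    physiologies = physiologies or {s: get_physiology(s) for s in PRECLINICAL_SPECIES}
    rows = []
    sel = studies[(studies["compound"] == compound.name) & studies["reference"]]
    for species in PRECLINICAL_SPECIES:
        arm = sel[sel["species"] == species]
        if arm.empty:
            continue
        arm = arm.iloc[0]
        phys = physiologies[species]
        cl_kg = observed_clearance(arm["dose"], arm["auc_obs"], dose_unit=arm["dose_unit"])
        cl_abs = cl_kg * phys.body_weight
        record = ClearanceRecord.from_observed(
            species, cl_abs, compound.fup_for(species), phys.gfr
        )
        rows.append(
            {
                "species": species,
                "dose": arm["dose"],
                "dose_unit": arm["dose_unit"],
                "auc_obs": arm["auc_obs"],
                "cl_obs_ml_h_kg": cl_kg,
                "cl_obs_ml_h": cl_abs,
                "cl_renal_ml_h": record.cl_renal,
                "cl_add_ml_h": record.cl_add,
                "pct_cl_add": record.pct_cl_add,
                "body_weight_kg": phys.body_weight,
            }
        )
    return pd.DataFrame(rows)


def predict_human_clearance(
    compound: CompoundParams,
    clearances: pd.DataFrame | None = None,
    human: SpeciesPhysiology | None = None,
    methods: Sequence[str] = ("additional", "allometric", "single_species"),
) -> dict[str, float]:
    """Human plasma clearance (mL/h) by each requested method."""
    human = human or get_physiology("human")
    cls = derive_clearances(compound) if clearances is None else clearances
    out: dict[str, float] = {}
    if "additional" in methods:
        records = [
            ClearanceRecord(
                species=r["species"], cl_obs=r["cl_obs_ml_h"], cl_renal=r["cl_renal_ml_h"],
                cl_add=r["cl_add_ml_h"], pct_cl_add=r["pct_cl_add"],
            )
            for r in cls.to_dict("records")
        ]
        out["additional"] = additional_clearance_human(
            records, compound.fup_for("human"), human.gfr
        )
    if "allometric" in methods:
        fit = allometric_fit(list(zip(cls["body_weight_kg"], cls["cl_obs_ml_h"])))
        out["allometric"] = allometric_predict(fit, human.body_weight)
    if "single_species" in methods:
        monkey = cls[cls["species"] == "monkey"]
        if monkey.empty:
            log.warning("%s: no monkey clearance; single-species scaling skipped",
                        compound.name)
        else:
            out["single_species"] = single_species_scale(
                float(monkey["cl_obs_ml_h"].iloc[0]),
                float(monkey["body_weight_kg"].iloc[0]),
                human.body_weight,
            )
    return out


def simulate_human(
    compound: CompoundParams,
    cl_input: float,
    regimen: Regimen = HUMAN_BOLUS,
    duration: float = 24.0,
    output_interval: float = 0.5,
    human: SpeciesPhysiology | None = None,
) -> SimulationResult:
    human = human or get_physiology("human")
    kp = predict_kp(compound, human, "human")
    model = build_model(compound, human, "human", cl_input, kp)
    return model.simulate(regimen, duration, output_interval=output_interval)


def human_exposure_table(
    mtm: CompoundParams | None = None,
    mtmsa: CompoundParams | None = None,
    duration: float = 24.0,
    output_interval: float = 0.5,
) -> pd.DataFrame:
    """Exposure-comparison table for the 13 ug/kg human bolus projections.

    One row for the MTM comparator (additional-clearance method — the
    preferred human clearance prediction for MTM) and one per clearance
    method for MTMSA-Trp, each with plasma and liver AUC(0-24h), liver
    partition (AUC_liver / AUC_plasma) and ratios versus the MTM row.
    """
    mtm = mtm or load_compound("MTM")
    mtmsa = mtmsa or load_compound("MTMSA-Trp")
    human = get_physiology("human")

    def exposures(compound: CompoundParams, cl: float) -> tuple[float, float]:
        result = simulate_human(compound, cl, HUMAN_BOLUS, duration, output_interval,
                                human=human)
        auc_plasma = auc_loglinear(result.plasma_profile(), t_end=duration)
        auc_liver = auc_loglinear(result.tissue_profile("liver"), t_end=duration)
        return auc_plasma, auc_liver

    cl_mtm = predict_human_clearance(mtm, methods=("additional",))["additional"]
    mtm_plasma, mtm_liver = exposures(mtm, cl_mtm)
    rows = [
        {
            "compound": mtm.name,
            "method": METHOD_LABELS["additional"],
            "cl_human_ml_h": cl_mtm,
            "auc_plasma": mtm_plasma,
            "auc_liver": mtm_liver,
            "liver_partition": mtm_liver / mtm_plasma,
            "plasma_ratio_vs_mtm": 1.0,
            "liver_ratio_vs_mtm": 1.0,
        }
    ]
    cls_mtmsa = predict_human_clearance(mtmsa)
    for method in ("additional", "allometric", "single_species"):
        if method not in cls_mtmsa:
            continue
        plasma, liver = exposures(mtmsa, cls_mtmsa[method])
        rows.append(
            {
                "compound": mtmsa.name,
                "method": METHOD_LABELS[method],
                "cl_human_ml_h": cls_mtmsa[method],
                "auc_plasma": plasma,
                "auc_liver": liver,
                "liver_partition": liver / plasma,
                "plasma_ratio_vs_mtm": plasma / mtm_plasma,
                "liver_ratio_vs_mtm": liver / mtm_liver,
            }
        )
    return pd.DataFrame(rows)


def human_mtm_infusion_auc24(output_interval: float = 0.5) -> float:
    """Predicted human MTM plasma AUC over the 24 h after the first dose of
    the clinical regimen (13 ug/kg 6-h infusion daily x7), Method-1 clearance."""
    mtm = load_compound("MTM")
    cl = predict_human_clearance(mtm, methods=("additional",))["additional"]
    result = simulate_human(mtm, cl, HUMAN_INFUSION_X7, duration=24.0,
                            output_interval=output_interval)
    return auc_loglinear(result.plasma_profile(), t_end=24.0)


# -- orchestration --------------------------------------------------------


def default_config() -> dict:
    return {
        "seed": 1,
        "outdir": "workflow_out",
        "compounds": ["MTM", "MTMSA-Trp"],
        "noise_cv": 0.15,
        "sampling_times_h": list(DEFAULT_SAMPLING_H),
        "psa_parameters": list(SCAN_PARAMETERS),
        "calibration_bounds": [1e-6, 1.0],
    }


def run_workflow(config: Mapping | str | Path | None = None) -> dict:
    """Execute the full middle-out workflow; returns the per-stage results.

    ``config`` is a mapping (or path to a YAML file) with the keys of
    :func:`default_config`. CSV outputs are written under ``outdir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**default_config(), **(config or {})}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    studies = load_studies()
    compounds = {name: load_compound(name) for name in cfg["compounds"]}
    physiologies = {s: get_physiology(s) for s in PRECLINICAL_SPECIES + ("human",)}
    results: dict = {"config": cfg, "version": __version__}
    log.info("workflow start: seed=%s outdir=%s", seed, outdir)

    # (1) synthetic observed studies, one per printed study arm
    fixtures = {}
    for _, arm in studies.iterrows():
        compound = compounds.get(arm["compound"])
        if compound is None:
            continue
        key = (arm["compound"], arm["species"], float(arm["dose"]))
        times = (
            tuple(float(t) for t in cfg["sampling_times_h"])
            if arm["species"] != "human"
            else (0.5, 1, 2, 4, 6, 8, 12, 24)
        )
        profile, cl_used = make_study(
            compound,
            arm["species"],
            regimen_for_study(arm),
            sampling_times=times,
            noise_cv=float(cfg["noise_cv"]),
            seed=int(rng.integers(2 ** 31)),
            target_auc=float(arm["auc_obs"]),
            physiology=physiologies[arm["species"]],
        )
        fixtures[key] = {"profile": profile, "cl_used": cl_used, "arm": arm}
        profile.to_csv(outdir / f"observed_{arm['compound']}_{arm['species']}_{arm['dose']:g}.csv")
    results["fixtures"] = fixtures

    # (2) mouse SpecPStc calibration per compound
    calibration = {}
    for name, compound in compounds.items():
        arm = studies[(studies["compound"] == name) & (studies["species"] == "mouse")].iloc[0]
        key = (name, "mouse", float(arm["dose"]))
        cl_nca = observed_clearance(arm["dose"], auc_loglinear(fixtures[key]["profile"]),
                                    dose_unit=arm["dose_unit"])
        report = fit_spec_pstc(
            fixtures[key]["profile"], compound, physiologies["mouse"],
            regimen_for_study(arm), cl_nca * physiologies["mouse"].body_weight,
            bounds=tuple(cfg["calibration_bounds"]),
        )
        calibration[name] = report
        log.info("calibrated SpecPStc %s: %.4g (input %.4g)", name,
                 report.spec_pstc, compound.spec_pstc)
    results["calibration"] = calibration
    pd.DataFrame(
        [
            {"compound": name, "spec_pstc_fit": rep.spec_pstc,
             "spec_pstc_input": compounds[name].spec_pstc,
             "objective": rep.objective, "at_bound": rep.at_bound}
            for name, rep in calibration.items()
        ]
    ).to_csv(outdir / "calibration.csv", index=False)

    # (3)+(4) cross-species evaluation and observed clearances
    eval_rows = []
    for key, fx in fixtures.items():
        name, species, dose = key
        arm = fx["arm"]
        compound = compounds[name]
        phys = physiologies[species]
        cl_pred_input = observed_clearance(arm["dose"], arm["auc_obs"],
                                           dose_unit=arm["dose_unit"]) * phys.body_weight
        kp = predict_kp(compound, phys, species)
        model = build_model(compound, phys, species, cl_pred_input, kp)
        obs = fx["profile"]
        pred = model.simulate(regimen_for_study(arm), duration=float(obs.times[-1]),
                              times=obs.times).plasma_profile()
        report = evaluate_profile(pred, obs, auc_window=24.0)
        eval_rows.append(
            {"compound": name, "species": species, "dose": dose,
             "auc_obs": report.auc_obs, "auc_pred": report.auc_pred,
             "auc_ratio": report.auc_ratio, "afe": report.afe,
             "rmse": report.rmse, "pass_2fold": report.pass_2fold}
        )
    evaluation_table = pd.DataFrame(eval_rows)
    evaluation_table.to_csv(outdir / "prediction_performance.csv", index=False)
    results["evaluation"] = evaluation_table

    clearance_tables = {name: derive_clearances(c, studies) for name, c in compounds.items()}
    pd.concat(
        [t.assign(compound=name) for name, t in clearance_tables.items()]
    ).to_csv(outdir / "observed_clearances.csv", index=False)
    results["clearances"] = clearance_tables

    # (5) human clearance projections
    human_cl = {name: predict_human_clearance(c, clearance_tables[name])
                for name, c in compounds.items()}
    pd.DataFrame(human_cl).to_csv(outdir / "human_clearance.csv")
    results["human_clearance"] = human_cl

    # (6)+(7) human simulations and the exposure-comparison table
    if "MTM" in compounds:
        results["human_mtm_infusion_auc24"] = human_mtm_infusion_auc24()
    if {"MTM", "MTMSA-Trp"} <= set(compounds):
        table3 = human_exposure_table(compounds["MTM"], compounds["MTMSA-Trp"])
        table3.to_csv(outdir / "human_exposure_comparison.csv", index=False)
        results["exposure_table"] = table3

    # (8) PSA on the human MTMSA-Trp model (allometric clearance scenario)
    if "MTMSA-Trp" in compounds:
        mtmsa = compounds["MTMSA-Trp"]
        cl_allo = human_cl["MTMSA-Trp"]["allometric"]
        scans = {}
        for parameter in cfg["psa_parameters"]:
            values = default_scan_values(mtmsa, parameter)
            scans[parameter] = psa(
                mtmsa, parameter, values, HUMAN_BOLUS, physiologies["human"],
                cl_allo, clearance_method="allometric",
            )
            pd.DataFrame(
                [{"parameter": parameter, "value": p.value, "auc_0_24": p.auc}
                 for p in scans[parameter]]
            ).to_csv(outdir / f"psa_{parameter}.csv", index=False)
        ranking = rank_parameters(scans)
        pd.DataFrame(ranking, columns=["parameter", "auc_range_ratio"]).to_csv(
            outdir / "psa_ranking.csv", index=False
        )
        results["psa"] = scans
        results["psa_ranking"] = ranking

    with open(outdir / "run_info.json", "w") as fh:
        json.dump({"seed": seed, "version": __version__,
                   "compounds": list(compounds)}, fh, indent=2)
    log.info("workflow complete")
    return results
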