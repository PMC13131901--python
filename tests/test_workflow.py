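import numpy as np
import pandas as pd
import pytest

from mithrapbpk.workflow import (
    default_config,
    derive_clearances,
    human_exposure_table,
    predict_human_clearance,
    run_workflow,
)


@pytest.fixture(scope="module")
def results(tmp_path_factory):
    cfg = default_config()
    cfg.update(seed=7, outdir=str(tmp_path_factory.mktemp("wf")))
    return run_workflow(cfg)


def test_observed_clearance_table(mtm):
    table = derive_clearances(mtm)
    assert list(table["species"]) == ["mouse", "rat", "monkey"]
    # monkey row uses the higher (reference) dose level
    assert table.set_index("species").loc["monkey", "dose"] == 13.18
    assert (table["pct_cl_add"] > 0).all()
    assert (table["pct_cl_add"] < 100).all()


def test_three_human_clearance_methods(mtmsa):
    cl = predict_human_clearance(mtmsa)
    assert set(cl) == {"additional", "allometric", "single_species"}
    assert all(v > 0 for v in cl.values())
    # the analog's additional-clearance projection is far below the
    # allometric one (extreme protein binding caps renal filtration)
    assert cl["additional"] < cl["allometric"]


def test_exposure_table_structure():
    table = human_exposure_table()
    assert len(table) == 4  # 1 MTM row + 3 MTMSA-Trp rows
    assert list(table["compound"]).count("MTM") == 1
    mtm_row = table[table["compound"] == "MTM"].iloc[0]
    assert mtm_row["plasma_ratio_vs_mtm"] == 1.0
    assert (table["liver_partition"] > 0).all()
    # every clearance method projects higher analog plasma exposure than MTM
    analog = table[table["compound"] == "MTMSA-Trp"]
    assert (analog["plasma_ratio_vs_mtm"] > 1.0).all()


def test_workflow_outputs_exist(results):
    outdir = results["config"]["outdir"]
    import pathlib

    names = {p.name for p in pathlib.Path(outdir).iterdir()}
    for expected in (
        "calibration.csv", "prediction_performance.csv", "observed_clearances.csv",
        "human_clearance.csv", "human_exposure_comparison.csv", "psa_ranking.csv",
        "run_info.json",
    ):
        assert expected in names
    assert len(results["fixtures"]) == 9  # one per printed study arm


def test_workflow_calibration_recovers_inputs(results):
    """Mouse-calibrated SpecPStc stays near the bundled optimum for both
    compounds despite 15% observation noise."""
    for name, ref in (("MTM", 2.95e-2), ("MTMSA-Trp", 1.23e-4)):
        fitted = results["calibration"][name].spec_pstc
        assert 0.2 * ref < fitted < 5 * ref


def test_workflow_psa_ranking(results):
    assert results["psa_ranking"][0][0] == "bpr"


def test_workflow_deterministic(tmp_path):
    cfg = default_config()
    out1, out2 = tmp_path / "a", tmp_path / "b"
    cfg.update(seed=3, outdir=str(out1), psa_parameters=["bpr"])
    run_workflow(dict(cfg))
    cfg["outdir"] = str(out2)
    run_workflow(dict(cfg))
    for name in ("human_exposure_comparison.csv", "prediction_performance.csv",
                 "psa_bpr.csv"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_evaluation_table_mostly_within_twofold(results):
    """Cross-species predictions built from printed dose/AUC inputs agree
    with the synthetic observed studies within the 2-fold band."""
    table = results["evaluation"]
    assert len(table) == 9
    assert table["pass_2fold"].mean() >= 0.7
    assert np.isfinite(table[["afe", "rmse"]].to_numpy()).all()
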