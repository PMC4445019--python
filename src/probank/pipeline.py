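"""End-to-end item-bank development pipeline.

Runs the full engineering sequence from one configuration:

    simulate (or load) -> dimensionality screen -> GRM calibration ->
    S-X2 item fit -> DIF screen -> (recalibrate if items removed) ->
    optional Stocking-Lord linking -> short-form selection ->
    CAT simulation -> reliability report

Every stage logs its inputs/outputs and item counts (tested, removed,
retained) into a machine-readable summary, and all randomness flows from a
single seed, so re-running with an identical configuration reproduces the
run bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import bankio
from .bankio import ResponseMatrix
from .calibrate import CalibrationConfig, fit_grm, s_x2_item_fit
from .cat import CatConfig, SimulatedResponder, administer, simulate_cat_study
from .dif import DifConfig, dif_screen_all
from .dimensionality import ScreenConfig, prune_pool
from .grm import to_t_metric
from .linking import stocking_lord, transform_bank
from .reliability import cronbach_alpha, test_retest
from .shortform import ShortFormConfig, select_short_form
from .simulate import SimulationDesign, make_bank, simulate_responses

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "probank_run",
    "simulate": {"n_persons": 877, "n_items": 30, "n_categories": 5},
    "data": None,               # {"responses": path, "covariates": path}
    "screen": {},               # ScreenConfig overrides
    "calibration": {},          # CalibrationConfig overrides
    "dif": {"remove_flagged": False},
    "linking": None,            # {"reference_bank": path}
    "short_form": {},           # ShortFormConfig overrides
    "cat": {"n_simulees": 250},  # CatConfig overrides + n_simulees
    "retest": {"n_persons": 245},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _get_data(cfg: dict, seed: int) -> ResponseMatrix:
    if cfg.get("data"):
        return bankio.read_responses(cfg["data"]["responses"],
                                     cfg["data"].get("covariates"))
    sim = cfg["simulate"]
    bank = make_bank(n_items=sim["n_items"], n_categories=sim["n_categories"],
                     seed=seed)
    design = SimulationDesign(bank=bank, n_persons=sim["n_persons"], seed=seed)
    return simulate_responses(design)


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute the pipeline; returns the run directory.

    ``config`` may be a dict or a path to a YAML file.  A stage failure
    raises after writing the artifacts produced so far.
    """
    cfg = load_config(config) if not isinstance(config, dict) else {
        **json.loads(json.dumps(DEFAULT_CONFIG)), **config}
    for key in ("screen", "calibration", "dif", "short_form", "cat", "retest",
                "simulate"):
        if key in cfg and isinstance(DEFAULT_CONFIG.get(key), dict):
            merged = dict(DEFAULT_CONFIG[key])
            merged.update(cfg.get(key) or {})
            cfg[key] = merged
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "stages": {}}

    def record(stage: str, **kw) -> None:
        summary["stages"][stage] = kw
        log.info("stage %s: %s", stage, kw)

    # 1. data
    data = _get_data(cfg, seed)
    bankio.write_responses(data, out / "responses.tsv", out / "covariates.tsv")
    record("data", n_persons=data.n_persons, n_items=len(data.item_ids))

    # 2. dimensionality screen
    screen_cfg = ScreenConfig(**{k: v for k, v in cfg["screen"].items()})
    report = prune_pool(data, screen_cfg)
    (out / "screen_report.txt").write_text(report.summary() + "\n")
    record("screen", tested=len(data.item_ids), removed=len(report.removals),
           retained=len(report.retained),
           lid_removals=sum(1 for r in report.removals if r.reason == "lid"),
           fit_acceptable=report.fit_acceptable)
    screened = data.subset_items(report.retained)

    # 3. calibration + item fit
    cal_cfg = CalibrationConfig(**{k: v for k, v in cfg["calibration"].items()})
    result = fit_grm(screened, cal_cfg)
    bankio.write_bank(result.bank, out / "calibrated_bank.tsv")
    fit_table = s_x2_item_fit(result, screened, cal_cfg)
    fit_table.to_csv(out / "item_fit.tsv", sep="\t")
    record("calibration", n_items=len(result.bank),
           converged=result.convergence.converged,
           cycles=result.convergence.cycles,
           log_likelihood=result.log_likelihood,
           misfit_p_lt_05=int((fit_table["p"] < 0.05).sum()))

    # 4. DIF screen (on responses recoded to the calibrated categories)
    screened = result.recode(screened)
    dif_kwargs = {k: v for k, v in cfg["dif"].items() if k != "remove_flagged"}
    dif_cfg = DifConfig(**dif_kwargs)
    dif_table = dif_screen_all(screened, result.bank, config=dif_cfg)
    dif_table.to_csv(out / "dif_report.tsv", sep="\t")
    flagged = sorted(set(dif_table.reset_index().loc[
        dif_table.reset_index()["flag"], "item_id"]))
    record("dif", tested=len(result.bank), flagged=len(flagged),
           flagged_items=flagged)

    bank = result.bank
    if cfg["dif"].get("remove_flagged") and flagged:
        retained = [i for i in bank.item_ids if i not in flagged]
        screened = screened.subset_items(retained)
        result = fit_grm(screened, cal_cfg)
        screened = result.recode(screened)
        bank = result.bank
        bankio.write_bank(bank, out / "calibrated_bank.tsv")
        record("recalibration", n_items=len(bank),
               converged=result.convergence.converged)

    # 5. optional linking onto a reference metric
    if cfg.get("linking"):
        ref_bank = bankio.read_bank(cfg["linking"]["reference_bank"])
        constants = stocking_lord(bank, ref_bank)
        bank = transform_bank(bank, constants, metric_name=ref_bank.metric_name)
        bankio.write_bank(bank, out / "linked_bank.tsv")
        record("linking", A=constants.A, B=constants.B,
               n_anchors=len(constants.anchor_ids))

    # 6. short form
    sf_cfg = ShortFormConfig(**{k: v for k, v in cfg["short_form"].items()})
    sf_items, audit = select_short_form(bank, sf_cfg)
    audit.to_csv(out / "short_form_audit.tsv", sep="\t")
    record("short_form", size=len(sf_items), items=sf_items)

    # 7. CAT simulation (CAT vs SF correlation study)
    cat_overrides = {k: v for k, v in cfg["cat"].items() if k != "n_simulees"}
    cat_cfg = CatConfig(**cat_overrides)
    table, cat_summary = simulate_cat_study(
        bank, sf_items, n_simulees=int(cfg["cat"]["n_simulees"]),
        seed=seed + 1, config=cat_cfg)
    table.to_csv(out / "cat_study.tsv", sep="\t", index=False)
    record("cat_simulation", **cat_summary)

    # 8. reliability: alpha on the retained pool + simulated CAT test-retest
    alpha, item_total = cronbach_alpha(screened.subset_items(list(bank.item_ids)))
    item_total.to_csv(out / "item_total.tsv", sep="\t")
    rng = np.random.default_rng(seed + 2)
    n_retest = int(cfg["retest"]["n_persons"])
    thetas = rng.normal(size=n_retest)
    t1 = np.empty(n_retest)
    t2 = np.empty(n_retest)
    for i, th in enumerate(thetas):
        s1 = administer(SimulatedResponder(th, seed=int(rng.integers(2**31))),
                        bank, cat_cfg)
        s2 = administer(SimulatedResponder(th, seed=int(rng.integers(2**31))),
                        bank, cat_cfg)
        t1[i], t2[i] = to_t_metric(s1.final.theta), to_t_metric(s2.final.theta)
    retest = test_retest(t1, t2)
    record("reliability", cronbach_alpha=float(alpha),
           retest_pearson_r=retest.pearson_r, retest_icc=retest.icc,
           retest_icc_ci=list(retest.icc_ci), n_retest=n_retest)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return out
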