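"""End-to-end orchestration: simulate -> predictors -> spectral -> stats
-> model comparison, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, io, simulate, spectral, stats
from .design import DesignConfig

log = logging.getLogger("idatheta")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    design: DesignConfig = field(default_factory=DesignConfig)
    truth: simulate.GroundTruth = field(default_factory=simulate.GroundTruth)
    band: tuple[float, float] = (4.0, 5.0)
    channels: tuple[str, ...] = ("Fz", "FCz", "Cz")
    min_trials: int = 8
    outdir: Path = Path("idatheta_run")
    seed: int = 0
    write_epochs: bool = False
    glm_channel: str = "Fz"

    def __post_init__(self) -> None:
        if not (3.0 <= self.band[0] < self.band[1] <= 30.0):
            raise ValueError("theta band must lie within 3-30 Hz")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        design = DesignConfig(**raw.pop("design", {}))
        truth = simulate.GroundTruth(**raw.pop("truth", {}))
        cfg = cls(design=design, truth=truth, **{
            k: tuple(v) if k in ("band", "channels") else v
            for k, v in raw.items()})
        return cfg


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and persist all artifacts; return the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    t0 = time.perf_counter()

    truth = dataclasses.replace(config.truth, seed=config.seed)

    # --- simulate -------------------------------------------------------
    tic = time.perf_counter()
    cohort = simulate.simulate_cohort(truth, config.design, make_epochs=True,
                                      seed=config.seed)
    predictors = cohort.predictor_frame()
    predictors.to_csv(out / "predictors.csv", index=False)
    cohort.behavior.to_csv(out / "behavior.csv", index=False)
    simulate.ground_truth_json(truth, out / "ground_truth.json")
    manifest["files"]["predictors"] = "predictors.csv"
    manifest["files"]["behavior"] = "behavior.csv"
    manifest["files"]["ground_truth"] = "ground_truth.json"
    if config.write_epochs:
        epochs_dir = out / "epochs"
        epochs_dir.mkdir(exist_ok=True)
        for subj in cohort.subjects:
            for cond, ep in subj.epochs.items():
                io.write_epochs(ep, epochs_dir / f"{subj.subject_id}_{cond}.csv")
        manifest["files"]["epochs_dir"] = "epochs"
    manifest["stages"]["simulate"] = {"seconds": time.perf_counter() - tic,
                                      "n_subjects": truth.n_subjects}
    log.info("simulate: %d subjects", truth.n_subjects)

    # --- spectral -------------------------------------------------------
    tic = time.perf_counter()
    theta_rows = []
    for subj in cohort.subjects:
        for cond, epochs in subj.epochs.items():
            clean = spectral.preprocess(epochs)
            psd = spectral.compute_psd(clean)
            tab = spectral.extract_theta(psd, band=config.band,
                                         channels=config.channels,
                                         trial_info=epochs.trial_info)
            tab["subject"] = subj.subject_id
            tab["condition"] = cond
            looked = subj.sequences[cond].looked
            tab["trial"] = tab["trial_overall"]
            tab["looked"] = looked[tab["trial"].to_numpy() - 1]
            theta_rows.append(tab)
    theta_trials = pd.concat(theta_rows, ignore_index=True)
    retained, report = spectral.apply_inclusion_rules(
        theta_trials, min_trials=config.min_trials)
    theta_subject = spectral.subject_condition_means(retained)
    theta_trials.to_csv(out / "theta_trials.csv", index=False)
    retained.to_csv(out / "theta_retained.csv", index=False)
    theta_subject.to_csv(out / "theta_subject.csv", index=False)
    io.write_json(report, out / "exclusions.json")
    manifest["files"].update({
        "theta_trials": "theta_trials.csv", "theta_retained": "theta_retained.csv",
        "theta_subject": "theta_subject.csv", "exclusions": "exclusions.json"})
    manifest["stages"]["spectral"] = {"seconds": time.perf_counter() - tic,
                                      "n_trials": int(len(theta_trials) /
                                                      len(config.channels))}
    log.info("spectral: %d retained subjects", report["n_subjects_retained"])

    # --- group statistics ----------------------------------------------
    tic = time.perf_counter()
    followups = stats.bonferroni_followups(theta_subject,
                                           channels=config.channels)
    stats_out = {
        "alpha_corrected": followups["alpha_corrected"],
        "significant_channels": followups["significant_channels"],
        "anovas": {ch: dataclasses.asdict(r)
                   for ch, r in followups["anovas"].items()},
        "pairwise": followups["pairwise"].to_dict(orient="records"),
        "note": followups["note"],
    }
    # behavior coupling: subject theta (variable condition, GLM channel)
    sub = theta_subject[(theta_subject["condition"] == "variable")
                        & (theta_subject["channel"] == config.glm_channel)]
    beh = cohort.behavior.merge(sub, on="subject", how="inner")
    pcors = {}
    measures = ["success_targets_only", "first_touch_novel",
                "success_all_objects"]
    for m in measures:
        controls = beh[[o for o in measures if o != m]]
        try:
            res = stats.partial_correlation(beh["theta_power"], beh[m],
                                            controls)
            pcors[m] = dataclasses.asdict(res)
        except ValueError as exc:
            pcors[m] = {"error": str(exc)}
    stats_out["partial_correlations"] = pcors
    io.write_json(stats_out, out / "group_stats.json")
    manifest["files"]["group_stats"] = "group_stats.json"
    manifest["stages"]["stats"] = {"seconds": time.perf_counter() - tic}

    # --- model comparison ----------------------------------------------
    tic = time.perf_counter()
    trials = retained.loc[retained["channel"] == config.glm_channel,
                          ["subject", "condition", "trial", "theta_power"]
                          ].merge(
        predictors, left_on=["subject", "condition", "trial"],
        right_on=["subject", "condition", "trial_overall"], how="inner")
    trials = trials[trials["included"]].copy()
    trials["theta_norm"] = glm.normalize_theta(trials)
    table, fits = glm.compare_models(trials, response="theta_norm")
    table.to_csv(out / "model_comparison.csv", index=False)
    coef = {name: {"params": f.params.to_dict(), "bse": f.bse.to_dict(),
                   "sigma_log": f.sigma_log, "aic": f.aic, "loglik": f.llf,
                   "nobs": f.nobs}
            for name, f in fits.items()}
    io.write_json(coef, out / "coefficients.json")
    manifest["files"]["model_comparison"] = "model_comparison.csv"
    manifest["files"]["coefficients"] = "coefficients.json"
    manifest["stages"]["compare"] = {"seconds": time.perf_counter() - tic,
                                     "best_model": table["model"].iloc[0]}

    manifest["total_seconds"] = time.perf_counter() - t0
    io.write_json(manifest, out / "manifest.json")
    missing = [f for f in manifest["files"].values() if not (out / f).exists()]
    if missing:
        raise RuntimeError(f"manifest references missing files: {missing}")
    return manifest
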