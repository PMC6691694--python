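"""End-to-end study replica: generate, split, extract, select, fit, evaluate.

``run_pipeline`` executes the five-stage radiomics workflow on a synthetic
cohort: (1) cohort generation, (2) seeded 4:3 training/validation split,
(3) 970-feature extraction, (4) per-modality LR-RFE selection on the
training cohort only, (5) Cox Rad-scores, the combined radiomic + clinical
model, a clinical-only comparison model, median-threshold stratification,
C-index / log-rank / calibration evaluation, and (optionally) nomogram
rendering.  All randomness derives from one master seed; validation rows
never reach standardization, ranking, subset choice or model fitting.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from radnomics.cohort import CohortParams, PhantomParams, SurvivalParams, generate_cohort
from radnomics.features import extract_cohort
from radnomics.selection import make_binary_label, rfe_rank, select_best_subset
from radnomics.survival import (
    PUBLISHED_MODEL,
    CoxPH,
    PublishedModel,
    backward_eliminate,
    baseline_table,
    calibration_curve,
    combined_rad_score,
    concordance_index,
    km_logrank,
    split_cohort,
    stratify_by_median,
)
from radnomics.nomogram import build_nomogram, render_calibration, render_km, render_nomogram

logger = logging.getLogger("radnomics")

__all__ = ["RunConfig", "run_pipeline", "score_patient"]

CLINICAL_COVARIATES = ["gender", "age", "hgb", "n_stage"]
ALL_CLINICAL = ["age", "gender", "t_stage", "n_stage", "hgb", "platelets"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Defaults reproduce the study-shaped design: 140 patients split 4:3 into
    80 training / 60 validation, 970 features, 32 gray-level bins, per-
    modality RFE with AUC subset choice capped at 30 candidate sizes,
    combined model over {Rad-score1, Rad-score2, gender, age, HGB, N stage}
    (forced entry), horizons at 24 and 36 months.
    """

    seed: int = 0
    n_patients: int = 140
    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing: tuple[float, float, float] = (0.9, 0.9, 5.0)
    tumor_radius_range: tuple[float, float] = (6.0, 11.0)
    noise_sd: float = 6.0
    beta_heterogeneity: float = 2.0
    beta_n_stage: float = 0.2
    split_ratio: tuple[int, int] = (4, 3)
    n_bins: int = 32
    max_subset_size: int = 30
    cv_splits: int = 5
    combined_covariates: list = field(default_factory=lambda: list(CLINICAL_COVARIATES))
    forced_entry: bool = True
    horizons: tuple[float, float] = (24.0, 36.0)
    calibration_groups: int = 4
    calibration_boot: int = 200
    output_dir: str | None = None
    render: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("grid_shape", "voxel_spacing", "tumor_radius_range", "split_ratio", "horizons"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            phantom=PhantomParams(
                n_patients=self.n_patients,
                grid_shape=tuple(self.grid_shape),
                voxel_spacing=tuple(self.voxel_spacing),
                tumor_radius_range=tuple(self.tumor_radius_range),
                noise_sd=self.noise_sd,
                rng_seed=self.seed,
            ),
            survival=SurvivalParams(
                true_betas={"heterogeneity": self.beta_heterogeneity, "n_stage": self.beta_n_stage}
            ),
        )


def _fit_modality_radscore(features, selected, outcomes_train):
    data = features[selected].copy()
    data["time"] = outcomes_train["time"].to_numpy()
    data["event"] = outcomes_train["event"].to_numpy()
    # selected radiomic features are correlated; a light ridge keeps the
    # partial-likelihood maximization well-conditioned
    return CoxPH(data, covariates=selected).fit(penalizer=0.1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full study replica; return the report dict (also written to disk
    when ``config.output_dir`` is set)."""
    t_start = _time.time()
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()}}
    stage_times: dict[str, float] = {}

    def _stage(name):
        stage_times[name] = _time.time()
        logger.info("stage %s", name)

    # ---- 1. cohort -------------------------------------------------------
    _stage("generate")
    cohort = generate_cohort(config.cohort_params())
    clinical = cohort.clinical.set_index("patient_id")
    outcomes = cohort.outcomes.set_index("patient_id")

    # ---- 2. split --------------------------------------------------------
    _stage("split")
    ids = np.array(cohort.patient_ids)
    train_ids, valid_ids = split_cohort(ids, seed=config.seed, ratio=tuple(config.split_ratio))
    report["cohort"] = {
        "n_patients": int(len(ids)),
        "n_training": int(len(train_ids)),
        "n_validation": int(len(valid_ids)),
        "event_fraction": float(outcomes["event"].mean()),
    }
    report["baseline_comparison_p"] = (
        baseline_table(clinical.loc[train_ids], clinical.loc[valid_ids])["p"].to_dict()
    )

    # ---- 3. features -----------------------------------------------------
    _stage("extract")
    features = extract_cohort(cohort.patients, patient_ids=list(ids), n_bins=config.n_bins)
    report["features"] = {
        "n_total": int(features.shape[1]),
        "n_per_modality": {m: int(sum(c.startswith(m + "_") for c in features.columns))
                           for m in ("CET1-w", "T2-w")},
    }

    feats_train, feats_valid = features.loc[train_ids], features.loc[valid_ids]
    out_train, out_valid = outcomes.loc[train_ids], outcomes.loc[valid_ids]
    labels_train = make_binary_label(out_train.reset_index())

    # ---- 4. per-modality selection (training cohort only) ---------------
    _stage("select")
    selections = {}
    radscores_train, radscores_valid = {}, {}
    modality_models = {}
    for tag, modality in (("radscore1", "CET1-w"), ("radscore2", "T2-w")):
        cols = [c for c in features.columns if c.startswith(modality + "_")]
        ranking = rfe_rank(feats_train[cols], labels_train.to_numpy())
        sel = select_best_subset(
            ranking, feats_train[cols], labels_train.to_numpy(),
            max_subset_size=config.max_subset_size, n_splits=config.cv_splits,
            random_state=config.seed,
        )
        # Cox fit on the training-standardized selected features (the same
        # standardization statistics are applied to the validation cohort)
        std_train = ranking.standardize(feats_train[cols])
        std_valid = ranking.standardize(feats_valid[cols])
        res = _fit_modality_radscore(std_train, sel.selected_features, out_train)
        selections[modality] = {
            "n_selected": sel.n_selected,
            "selected_features": sel.selected_features,
            "achieved_cv_auc": sel.achieved_auc,
        }
        modality_models[tag] = res
        radscores_train[tag] = res.linear_predictor(std_train)
        radscores_valid[tag] = res.linear_predictor(std_valid)
    report["selection"] = selections

    # ---- 5. combined and clinical-only Cox models -----------------------
    _stage("fit")

    def _combined_table(clin, rs, out):
        tab = clin[config.combined_covariates].copy()
        tab["radscore1"] = rs["radscore1"]
        tab["radscore2"] = rs["radscore2"]
        tab["time"] = out["time"].to_numpy()
        tab["event"] = out["event"].to_numpy()
        return tab

    comb_cols = ["radscore1", "radscore2"] + config.combined_covariates
    train_tab = _combined_table(clinical.loc[train_ids], radscores_train, out_train)
    valid_tab = _combined_table(clinical.loc[valid_ids], radscores_valid, out_valid)
    if config.forced_entry:
        combined = CoxPH(train_tab, covariates=comb_cols).fit()
    else:
        combined = backward_eliminate(train_tab, comb_cols)
    report["combined_model"] = {
        "coefficients": combined.params_.to_dict(),
        "p_values": combined.p_values_.to_dict(),
    }

    clin_train = clinical.loc[train_ids, ALL_CLINICAL].copy()
    clin_train[["time", "event"]] = out_train[["time", "event"]].to_numpy()
    clinical_model = backward_eliminate(clin_train, ALL_CLINICAL)
    report["clinical_model"] = {"coefficients": clinical_model.params_.to_dict()}

    # ---- evaluation ------------------------------------------------------
    _stage("evaluate")
    cols = list(combined.params_.index)
    c_train, _ = concordance_index(
        combined.linear_predictor(train_tab[cols]), train_tab["time"], train_tab["event"])
    c_valid, _ = concordance_index(
        combined.linear_predictor(valid_tab[cols]), valid_tab["time"], valid_tab["event"])
    ccols = list(clinical_model.params_.index)
    clin_valid = clinical.loc[valid_ids, ALL_CLINICAL]
    c_clin_train, _ = concordance_index(
        clinical_model.linear_predictor(clin_train[ccols]), out_train["time"], out_train["event"])
    c_clin_valid, _ = concordance_index(
        clinical_model.linear_predictor(clin_valid[ccols]), out_valid["time"], out_valid["event"])
    report["c_index"] = {
        "combined_training": c_train,
        "combined_validation": c_valid,
        "clinical_training": c_clin_train,
        "clinical_validation": c_clin_valid,
    }

    scores_train = combined.linear_predictor(train_tab[cols])
    scores_all = combined.linear_predictor(
        pd.concat([train_tab, valid_tab])[cols])
    strat = stratify_by_median(scores_train, scores_all)
    all_out = pd.concat([out_train, out_valid])
    lr = km_logrank(all_out["time"], all_out["event"], strat["group"])
    report["stratification"] = {
        "threshold": strat["threshold"],
        "n_low": int((strat["group"] == "low").sum()),
        "n_high": int((strat["group"] == "high").sum()),
        "logrank_chi2": lr["chi2"],
        "logrank_p": lr["p"],
    }

    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(77,)))
    calib = {}
    for h in config.horizons:
        tab = calibration_curve(
            combined, train_tab[cols], train_tab["time"], train_tab["event"], h,
            n_groups=config.calibration_groups, n_boot=config.calibration_boot, rng=rng,
        )
        calib[h] = tab
        report.setdefault("calibration", {})[f"{h:g}m"] = {
            "max_abs_error": float((tab["predicted"] - tab["observed"]).abs().max()),
            "table": tab.to_dict(orient="records"),
        }

    # ---- artifacts -------------------------------------------------------
    report["runtime_s"] = float(_time.time() - t_start)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        features.to_csv(outdir / "features.csv")
        cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
        cohort.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        for h, tab in calib.items():
            tab.to_csv(outdir / f"calibration_{h:g}m.csv", index=False)
        for g, curve in lr["curves"].items():
            curve.to_csv(outdir / f"km_{g}.csv", index=False)
        if config.render:
            ranges = {c: (float(train_tab[c].min()), float(train_tab[c].max())) for c in cols}
            spec = build_nomogram(combined, ranges, horizons=config.horizons)
            spec.to_json(outdir / "nomogram.json")
            render_nomogram(spec, outdir / "nomogram.svg")
            render_calibration(calib, outdir / "calibration.svg")
            render_km(all_out["time"], all_out["event"], strat["group"], outdir / "km.svg")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def score_patient(covariates: dict, model: PublishedModel = PUBLISHED_MODEL) -> dict:
    """Combined Rad-score and risk group for one patient.

    With the published model the printed coefficients are applied verbatim
    and the risk group uses the printed threshold: score >= 5.50 is
    high-risk.  Missing covariates are named explicitly.
    """
    score = model.score(covariates)
    return {"score": score, "risk_group": model.risk_group(score), "threshold": model.threshold}
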