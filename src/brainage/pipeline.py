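"""End-to-end orchestration: simulate → harmonize → train → predict → stats.

This is the programmatic core behind the command-line interface: each stage
is a function taking and returning plain tables/dataclasses, so the stages
are individually testable and the CLI stays thin.

Protocol notes (mirroring the analysis this package implements):

* harmonization is fit per modality on the union of training and analysis
  tables with age as the preserved covariate (a leakage-safe
  fit-on-train-only variant is available via ``combat_fit_on_train``);
* unimodal GP age models are trained on the training set only, with the
  noise σ tuned once per model; the stacked model is trained on out-of-fold
  first-level predictions;
* BAG inference runs on the analysis set: uncorrected predictions are used
  for performance metrics, while every statistical test controls for age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agemodel, bagstats
from .harmonize import apply_combat, fit_combat
from .synthetic_cohort import Cohort, CohortSpec, generate_cohort_full
from .tables import FeatureTable, performance_from_predictions

MODEL_TAGS = ("FC", "S", "S+FC")


@dataclass
class PipelineResult:
    cohort: Cohort
    fc_harmonized: FeatureTable
    s_harmonized: FeatureTable
    stacked: agemodel.StackedModel
    train_performance: dict                  # tag -> ModelPerformance (train CV)
    analysis_performance: dict               # tag -> ModelPerformance (uncorrected)
    predictions: pd.DataFrame                # id, model_tag, age, pred_age
    bags: pd.DataFrame                       # + bag, residual_bag
    bag_models: dict = field(default_factory=dict)       # tag -> (effects, n)
    group_shifts: dict = field(default_factory=dict)     # tag -> {group: EffectEstimate}
    contrasts: dict = field(default_factory=dict)        # tag -> GroupContrastResult
    associations: dict = field(default_factory=dict)     # (tag, outcome) -> dict
    null: agemodel.ShuffledFcNull | None = None


def harmonize_cohort(cohort: Cohort, fit_on_train_only: bool = False):
    """ComBat both modalities, preserving age as a linear covariate."""
    frame = cohort.frame
    ages = frame["age"].rename("age")
    if fit_on_train_only:
        train_ids = frame.index[frame["role"] == "train"]
        out = []
        for table in (cohort.fc, cohort.struct):
            model = fit_combat(table.subset(train_ids), ages.loc[train_ids])
            out.append(apply_combat(model, table, ages))
        return tuple(out)
    fc_model = fit_combat(cohort.fc, ages)
    s_model = fit_combat(cohort.struct, ages)
    return apply_combat(fc_model, cohort.fc, ages), apply_combat(s_model, cohort.struct, ages)


def train_models(fc_h: FeatureTable, s_h: FeatureTable, frame: pd.DataFrame,
                 seed: int, folds: int = 10, sigma_strategy: str = "grid",
                 sigma_budget: int = agemodel.SIGMA_SEARCH_BUDGET):
    """Fit FC, structural and stacked models on the training participants."""
    train_ids = frame.index[frame["role"] == "train"]
    ages = frame.loc[train_ids, "age"].to_numpy()
    stacked = agemodel.fit_stacked(fc_h.subset(train_ids), s_h.subset(train_ids),
                                   ages, seed=seed, folds=folds,
                                   sigma_strategy=sigma_strategy,
                                   sigma_budget=sigma_budget)
    return stacked


def predict_analysis(stacked: agemodel.StackedModel, fc_h: FeatureTable,
                     s_h: FeatureTable, frame: pd.DataFrame) -> pd.DataFrame:
    """Apply the trained models to the analysis set; long predictions table."""
    ids = frame.index[frame["role"] == "analysis"]
    ages = frame.loc[ids, "age"].to_numpy()
    fc_x, s_x = fc_h.subset(ids), s_h.subset(ids)
    preds = {
        "FC": stacked.fc_model.predict(fc_x),
        "S": stacked.s_model.predict(s_x),
        "S+FC": stacked.predict(fc_x, s_x),
    }
    rows = []
    for tag in MODEL_TAGS:
        rows.append(pd.DataFrame({"id": ids, "model_tag": tag, "age": ages,
                                  "pred_age": preds[tag]}))
    return pd.concat(rows, ignore_index=True)


def run_stats(predictions: pd.DataFrame, frame: pd.DataFrame,
              outcomes: tuple[str, ...] = ()) -> tuple[pd.DataFrame, dict, dict, dict]:
    """BAG, Table-2-style regressions, group contrasts and associations."""
    bags = bagstats.compute_bag(predictions)
    analysis = frame[frame["role"] == "analysis"]
    bag_models, contrasts, associations, group_shifts = {}, {}, {}, {}
    for tag in MODEL_TAGS:
        bag_models[tag] = bagstats.fit_bag_model(bags, analysis, tag)
        group_shifts[tag] = bagstats.fit_group_shift_model(bags, analysis, tag)
        sub = bags[bags["model_tag"] == tag].merge(
            analysis.reset_index()[["id", "group"]], on="id")
        contrasts[tag] = bagstats.group_contrasts(sub["residual_bag"], sub["group"])
        for outcome in outcomes:
            try:
                associations[(tag, outcome)] = bagstats.biomarker_association(
                    bags, analysis, outcome, tag)
            except ValueError:
                continue   # outcome unavailable at this cohort size
    return bags, bag_models, group_shifts, contrasts, associations


def run_pipeline(spec: CohortSpec, seed: int | None = None, *, folds: int = 10,
                 sigma_strategy: str = "grid",
                 sigma_budget: int = agemodel.SIGMA_SEARCH_BUDGET,
                 combat_fit_on_train: bool = False,
                 outcomes: tuple[str, ...] = (),
                 n_resamples: int = 0) -> PipelineResult:
    """Full simulate→harmonize→train→predict→stats run on one seed."""
    if seed is not None:
        spec = CohortSpec(**{**spec.__dict__, "seed": seed})
    cohort = generate_cohort_full(spec)
    frame = cohort.frame
    fc_h, s_h = harmonize_cohort(cohort, combat_fit_on_train)
    stacked = train_models(fc_h, s_h, frame, spec.seed, folds,
                           sigma_strategy, sigma_budget)
    predictions = predict_analysis(stacked, fc_h, s_h, frame)

    analysis_perf = {}
    for tag in MODEL_TAGS:
        sub = predictions[predictions["model_tag"] == tag]
        analysis_perf[tag] = performance_from_predictions(
            sub["age"], sub["pred_age"], context="analysis-set")

    bags, bag_models, group_shifts, contrasts, associations = run_stats(
        predictions, frame, outcomes)

    null = None
    if n_resamples:
        train_ids = frame.index[frame["role"] == "train"]
        null = agemodel.shuffled_fc_null(
            s_h.subset(train_ids), fc_h.subset(train_ids),
            frame.loc[train_ids, "age"].to_numpy(),
            n_resamples=n_resamples, seed=spec.seed, folds=folds,
            force=True, stacked=stacked)

    return PipelineResult(
        cohort=cohort, fc_harmonized=fc_h, s_harmonized=s_h, stacked=stacked,
        train_performance=stacked.performance, analysis_performance=analysis_perf,
        predictions=predictions, bags=bags, bag_models=bag_models,
        group_shifts=group_shifts, contrasts=contrasts,
        associations=associations, null=null)


# --------------------------------------------------------------------------
# report helpers

def demographics_report(frame: pd.DataFrame) -> pd.DataFrame:
    """Welch t (age, education) and Yates χ² (sex) vs the CN/A− analysis set."""
    analysis = frame[frame["role"] == "analysis"]
    ref = analysis[analysis["group"] == "CN_Aneg"]
    rows = []
    for g in ("CN_Apos", "CI"):
        grp = analysis[analysis["group"] == g]
        if grp.empty:
            continue
        for var in ("age", "education"):
            t, df, p = bagstats.welch_t_from_summary(
                grp[var].mean(), grp[var].std(ddof=1), len(grp),
                ref[var].mean(), ref[var].std(ddof=1), len(ref))
            rows.append({"group": g, "measure": var, "stat": "welch_t",
                         "value": t, "df": df, "p": p})
        table = [[int((grp["sex"] == "female").sum()), int((grp["sex"] == "male").sum())],
                 [int((ref["sex"] == "female").sum()), int((ref["sex"] == "male").sum())]]
        chi2, df, p = bagstats.chi2_yates(table)
        rows.append({"group": g, "measure": "sex", "stat": "chi2_yates",
                     "value": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)


def bag_models_to_frame(bag_models: dict) -> pd.DataFrame:
    """Flatten per-tag effect lists into a Table-2-layout frame."""
    rows = []
    for tag, (effects, n) in bag_models.items():
        for e in effects:
            rows.append({"model_tag": tag, "term": e.term, "estimate": e.beta,
                         "se": e.se, "t": e.stat, "p": e.p,
                         "partial_eta_sq": e.partial_eta_sq,
                         "df_resid": e.df_den, "n": n})
    return pd.DataFrame(rows)
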