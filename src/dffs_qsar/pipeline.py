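"""End-to-end two-stage screening workflow.

Order of stages: ingest -> drop uninformative descriptors -> 8:2 split ->
min-max normalization (fit on train) -> dual-filter selection of the
activity subset -> stage-1 activity regression (budgeted tuning, 5-fold CV)
-> activity gate on predicted pIC50 -> dual-filter selection of the ADMET
subset on gated training compounds -> per-endpoint stacking classifiers ->
interpretation (phi association matrix, Shapley attributions) -> report.

Gate predictions for training compounds are out-of-fold by default, so no
compound is gated by a model that saw its own label; test compounds are
gated by the final model, which never saw them. Every artifact is written
under the run directory and the report JSON is byte-reproducible under a
fixed seed (no timestamps inside).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold, cross_val_predict

from . import data_io
from ._seeds import child_seed
from .activity import (
    PredictionSet,
    RegressorSpec,
    evaluate_regression,
    fit_regressor,
    relative_error_histogram,
    tune_hyperparameters,
    _make_model,
)
from .admet import (
    DEFAULT_STACKS,
    GateResult,
    StackingConfig,
    evaluate_classification,
    fit_stacking,
    gate_by_activity,
)
from .data_io import ADMET_PROPERTIES, DescriptorMatrix
from .interpret import compute_attributions, global_importance, phi_association_matrix
from .selection import select_features
from .synthetic import SyntheticConfig, generate_dataset


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One config drives the whole run; every field has a working default."""

    descriptors_path: str | None = None
    activity_path: str | None = None
    admet_path: str | None = None
    synthetic: SyntheticConfig | None = None  # used when paths are absent
    k_activity: int = 20
    k_admet: int = 40
    gate_threshold: float = 6.0
    gate_inclusive: bool = True
    gate_prediction_source: str = "out_of_fold"
    stage1_family: str = "hist_boosted_trees"
    tune_budget: int = 10
    tune_folds: int = 5
    tune_metric: str = "mse"
    stacking_menus: dict | None = None
    drop_mode: str = "zero_constant"
    normalize_on: str = "train"
    split_ratio: float = 0.8
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SyntheticConfig(**synth)
        return cfg

    def resolved(self) -> dict:
        out = asdict(self)
        if self.synthetic is not None:
            synth = asdict(self.synthetic)
            synth["latent_correlation"] = np.asarray(
                synth["latent_correlation"]
            ).tolist()
            out["synthetic"] = synth
        return out


@dataclass
class PipelineResult:
    """Report dict plus the fitted components needed for screening."""

    report: dict
    normalization: data_io.NormalizationStats
    activity_features: list[str]
    admet_features: list[str] | None
    stage1_model: object
    stacking_models: dict
    out_dir: Path


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig, data=None) -> PipelineResult:
    """Execute all stages and write every artifact under ``cfg.out_dir``.

    ``data`` may supply in-memory ``(descriptors, activity, admet)`` tables,
    bypassing both file ingestion and the synthetic generator.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    report: dict = {"seed": cfg.seed, "stages": {}}
    collected_warnings: list[str] = []
    stage = "configure"

    def _fail(exc: Exception):
        failed_marker.write_text(f"{stage}: {exc}\n")
        _write_json(out / "report.json", report)
        raise PipelineError(stage, exc) from exc

    try:
        _write_json(out / "resolved_config.json", cfg.resolved())

        # ------------------------------------------------------------ ingest
        stage = "ingest"
        if data is not None:
            descriptors, activity, admet = data
        elif cfg.descriptors_path:
            descriptors = data_io.read_descriptor_table(cfg.descriptors_path)
            activity = data_io.read_label_table(cfg.activity_path, "activity")
            admet = data_io.read_label_table(cfg.admet_path, "admet")
        else:
            synth_cfg = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
            descriptors, activity, admet, _truth = generate_dataset(synth_cfg)
        report["stages"]["ingest"] = {
            "n_compounds": descriptors.n_compounds,
            "n_descriptors": descriptors.n_descriptors,
        }

        # -------------------------------------------------------- preprocess
        stage = "preprocess"
        filtered, removed = data_io.drop_uninformative_descriptors(
            descriptors, mode=cfg.drop_mode
        )
        split = data_io.split_train_test(
            filtered.compound_ids,
            ratio=cfg.split_ratio,
            seed=child_seed(cfg.seed, "split"),
        )
        train = filtered.subset_compounds(split.train_ids)
        test = filtered.subset_compounds(split.test_ids)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if cfg.normalize_on == "train":
                stats = data_io.fit_minmax(train, fitted_on="train")
            elif cfg.normalize_on == "all":
                stats = data_io.fit_minmax(filtered, fitted_on="all")
            else:
                raise ValueError(f"normalize_on must be train|all, got {cfg.normalize_on!r}")
            train_n = data_io.apply_minmax(train, stats)
            test_n = data_io.apply_minmax(test, stats)
        collected_warnings += [str(w.message) for w in caught]
        y_train = activity.aligned_to(split.train_ids)
        y_test = activity.aligned_to(split.test_ids)
        report["stages"]["preprocess"] = {
            "removed_descriptors": len(removed),
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
        }
        data_io.write_run_manifest(
            out / "preprocess_manifest.json",
            seed=cfg.seed,
            removed_descriptors=removed,
            n_train=len(split.train_ids),
            n_test=len(split.test_ids),
        )

        # ------------------------------------------- stage 1 feature subset
        stage = "select_activity"
        sel_act = select_features(
            train_n,
            y_train,
            k=cfg.k_activity,
            seed=child_seed(cfg.seed, "dffs-activity"),
        )
        from .selection import write_selection_report

        write_selection_report(sel_act, out / "activity_selection")
        report["stages"]["select_activity"] = {"selected": sel_act.selected_names}

        # ------------------------------------------------ stage 1 regression
        stage = "stage1_regression"
        Xtr = train_n.subset_descriptors(sel_act.selected_names)
        Xte = test_n.subset_descriptors(sel_act.selected_names)
        tune = tune_hyperparameters(
            cfg.stage1_family,
            Xtr,
            y_train,
            budget=cfg.tune_budget,
            folds=cfg.tune_folds,
            metric=cfg.tune_metric,
            seed=child_seed(cfg.seed, "tune-stage1"),
        )
        spec = RegressorSpec(
            cfg.stage1_family, tune["params"], seed=child_seed(cfg.seed, "stage1-fit")
        )
        model = fit_regressor(spec, Xtr, y_train)
        pred_test = model.predict(Xte.values)
        pset = PredictionSet(list(split.test_ids), y_test, pred_test)
        metrics = evaluate_regression(pset)
        hist = relative_error_histogram(pset)
        _write_json(
            out / "stage1_metrics.json",
            {**metrics.as_dict(), "family": cfg.stage1_family,
             "tuned_cv_score": tune["cv_score"],
             "default_cv_score": tune["default_cv_score"]},
        )
        hist.to_dataframe().to_csv(out / "stage1_error_histogram.csv", index=False)
        report["stages"]["stage1_regression"] = {
            "family": cfg.stage1_family,
            "metrics": metrics.as_dict(),
            "tuned_cv_score": tune["cv_score"],
        }

        # --------------------------------------------------------------- gate
        stage = "gate"
        if cfg.gate_prediction_source == "out_of_fold":
            oof_model = _make_model(
                RegressorSpec(cfg.stage1_family, tune["params"],
                              seed=child_seed(cfg.seed, "stage1-oof"))
            )
            oof_train = cross_val_predict(
                oof_model,
                Xtr.values,
                y_train,
                cv=KFold(5, shuffle=True, random_state=child_seed(cfg.seed, "oof-cv")),
                n_jobs=1,
            )
            gate_preds = dict(zip(split.train_ids, oof_train))
            gate_preds.update(zip(split.test_ids, pred_test))
        elif cfg.gate_prediction_source == "refit":
            gate_preds = dict(zip(split.train_ids, model.predict(Xtr.values)))
            gate_preds.update(zip(split.test_ids, pred_test))
        elif cfg.gate_prediction_source == "true_labels":
            gate_preds = dict(zip(split.train_ids, y_train))
            gate_preds.update(zip(split.test_ids, y_test))
        else:
            raise ValueError(
                f"unknown gate_prediction_source {cfg.gate_prediction_source!r}"
            )
        gate = gate_by_activity(
            gate_preds,
            threshold=cfg.gate_threshold,
            inclusive=cfg.gate_inclusive,
            prediction_source=cfg.gate_prediction_source,
        )
        _write_json(
            out / "gate_result.json",
            {
                "threshold": gate.threshold,
                "inclusive": gate.inclusive,
                "prediction_source": gate.prediction_source,
                "n_retained": gate.n_retained,
                "n_rejected": gate.n_rejected,
            },
        )
        report["stages"]["gate"] = {
            "threshold": gate.threshold,
            "inclusive": gate.inclusive,
            "n_retained": gate.n_retained,
            "n_rejected": gate.n_rejected,
        }

        # --------------------------------------------------- stage 2 stacking
        stage = "select_admet"
        retained = set(gate.retained_ids)
        gated_train_ids = [c for c in split.train_ids if c in retained]
        gated_test_ids = [c for c in split.test_ids if c in retained]
        stage2_skipped = None
        if len(gated_train_ids) < 50:
            stage2_skipped = (
                f"gate retained {len(gated_train_ids)} training compounds; "
                "stage 2 requires at least 50"
            )
        sel_admet = None
        stacking_models: dict[str, object] = {}
        if stage2_skipped is None:
            admet_train = admet.aligned_to(gated_train_ids)
            gtrain_n = train_n.subset_compounds(gated_train_ids)
            targets = {
                prop: admet_train.column(prop) for prop in ADMET_PROPERTIES
            }
            constant = [p for p, t in targets.items() if np.ptp(t) == 0]
            if constant:
                stage2_skipped = (
                    f"gated training labels constant for {constant}; "
                    "stacking undefined"
                )
        if stage2_skipped is None:
            sel_admet = select_features(
                gtrain_n,
                targets,
                k=cfg.k_admet,
                seed=child_seed(cfg.seed, "dffs-admet"),
            )
            write_selection_report(sel_admet, out / "admet_selection")
            report["stages"]["select_admet"] = {
                "selected": sel_admet.selected_names
            }

            stage = "stage2_stacking"
            admet_test = admet.aligned_to(gated_test_ids)
            gtest_n = test_n.subset_compounds(gated_test_ids)
            Xtr2 = gtrain_n.subset_descriptors(sel_admet.selected_names)
            Xte2 = gtest_n.subset_descriptors(sel_admet.selected_names)
            menus = cfg.stacking_menus or {
                p: list(DEFAULT_STACKS[p]) for p in ADMET_PROPERTIES
            }
            stage2_metrics = {}
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                for prop in ADMET_PROPERTIES:
                    scfg = StackingConfig(
                        property=prop,
                        base_learners=tuple(menus[prop]),
                        seed=child_seed(cfg.seed, f"stack:{prop}"),
                    )
                    smodel = fit_stacking(scfg, Xtr2, targets[prop])
                    stacking_models[prop] = smodel
                    proba = smodel.predict_proba(Xte2)
                    m, counts = evaluate_classification(
                        admet_test.column(prop), (proba >= 0.5).astype(int), proba
                    )
                    stage2_metrics[prop] = {
                        **m.as_dict(),
                        "confusion": asdict(counts),
                        "base_learners": list(scfg.base_learners),
                    }
            collected_warnings += [str(w.message) for w in caught]
            _write_json(out / "stage2_metrics.json", stage2_metrics)
            report["stages"]["stage2_stacking"] = {
                p: {k: v for k, v in d.items() if k != "confusion"}
                for p, d in stage2_metrics.items()
            }
        else:
            report["stages"]["stage2_stacking"] = {"skipped": stage2_skipped}

        # ------------------------------------------------------ interpretation
        stage = "interpretation"
        if stage2_skipped is None:
            gated_all = gated_train_ids + gated_test_ids
            phi = phi_association_matrix(admet.aligned_to(gated_all))
        else:
            phi = phi_association_matrix(admet)
        phi.phi.to_csv(out / "phi_matrix.csv")
        phi.p_values.to_csv(out / "phi_pvalues.csv")
        attr = compute_attributions(model, Xte)
        ranking, export = global_importance(attr, Xte)
        attr.to_dataframe().to_csv(out / "attributions.csv", index=False)
        ranking.to_dataframe().to_csv(out / "global_importance.csv", index=False)
        export.to_csv(out / "attribution_export.csv", index=False)
        report["stages"]["interpretation"] = {
            "top_descriptors": ranking.descriptor_names[:5],
            "top_mean_abs_attribution": [
                float(v) for v in ranking.mean_abs_attribution[:5]
            ],
            "phi_undefined": phi.undefined,
        }

        stage = "report"
        report["warnings"] = sorted(set(collected_warnings))
        report["stage2_skipped"] = stage2_skipped
        _write_json(out / "report.json", report)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - every stage funnels here
        _fail(exc)

    return PipelineResult(
        report=report,
        normalization=stats,
        activity_features=sel_act.selected_names,
        admet_features=None if sel_admet is None else sel_admet.selected_names,
        stage1_model=model,
        stacking_models=stacking_models,
        out_dir=out,
    )


def screen_candidates(
    result: PipelineResult, unlabeled: DescriptorMatrix
) -> tuple[pd.DataFrame, dict]:
    """Score unlabeled compounds with the fitted two-stage artifacts.

    Unlabeled descriptors are normalized with the training-set stats (never
    refit). Every compound gets a predicted pIC50, the gate verdict and the
    five endpoint probabilities; compounds failing the gate keep their
    probabilities but are flagged ``screened=False``. Rows are sorted by
    predicted pIC50 descending; band counts (>7, 6-7, <6) are returned.
    """
    needed = set(result.activity_features) | set(result.admet_features or [])
    missing = [d for d in needed if d not in unlabeled.descriptor_names]
    if missing:
        raise KeyError(f"unlabeled table lacks descriptor(s): {sorted(missing)[:5]}")
    stats_names = set(result.normalization.descriptor_names)
    usable = [d for d in unlabeled.descriptor_names if d in stats_names]
    norm = data_io.apply_minmax(
        unlabeled.subset_descriptors(usable), result.normalization
    )
    Xa = norm.subset_descriptors(result.activity_features)
    pic50 = result.stage1_model.predict(Xa.values)
    gate_info = result.report["stages"]["gate"]
    thr, inclusive = gate_info["threshold"], gate_info["inclusive"]
    df = pd.DataFrame({"Name": unlabeled.compound_ids, "pred_pIC50": pic50})
    df["screened"] = (
        df["pred_pIC50"] >= thr if inclusive else df["pred_pIC50"] > thr
    )
    if result.stacking_models:
        Xs = norm.subset_descriptors(result.admet_features)
        for prop, model in result.stacking_models.items():
            df[f"P({prop}=1)"] = model.predict_proba(Xs)
    df = df.sort_values("pred_pIC50", ascending=False).reset_index(drop=True)
    bands = {
        "above_7": int(np.sum(pic50 > 7.0)),
        "between_6_and_7": int(np.sum((pic50 >= 6.0) & (pic50 <= 7.0))),
        "below_6": int(np.sum(pic50 < 6.0)),
    }
    return df, bands
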