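"""Full-study orchestration: generate/load -> pretreatment x classifier
grid -> RF deep tuning (ensemble size, node subset size, wavenumber
region, importance cutoff) -> final refit -> band report -> external
prediction.  Every run writes its tables, the trained model, a structured
log and a manifest with checksums, and reruns bit-identically under the
same seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import default_band_table, discriminating_report
from .core import SpectraError, SpectrumSet, read_csv, resample, write_csv
from .evaluation import (comparison_grid, default_regions,
                         evaluate_predictions, region_experiment,
                         vip_experiment)
from .models import (DEFAULT_SEED, RFConfig, SVMConfig, PLSDAConfig,
                     TrainedModel, fit_rf, predict, rf_importance,
                     select_by_vip, tune_mtry, tune_ntree)
from .preprocess import PRESETS, preset_recipe
from .sampling import kennard_stone
from .synth import FIXTURES, make_fixture

__all__ = ["StudyConfig", "StudyResult", "run_study", "predict_external",
           "save_model_bundle", "load_model_bundle"]

log = logging.getLogger("ftirclass")


@dataclass
class StudyConfig:
    """Configuration of a full discrimination study."""

    input: str = "easy"                    # CSV path or fixture name
    recipes: tuple[str, ...] = tuple(PRESETS)
    models: tuple[str, ...] = ("rf", "plsda", "svm")
    fraction: float = 0.8
    rf: RFConfig = field(default_factory=RFConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    plsda: PLSDAConfig = field(default_factory=PLSDAConfig)
    vip_cutoffs: tuple[float, ...] = (0.05, 0.01, 0.015, 0.020)
    positive_class: str = "A"
    seed: int = DEFAULT_SEED
    outdir: str = "study_run"

    def validate(self) -> None:
        for r in self.recipes:
            if r not in PRESETS:
                raise SpectraError(f"unknown recipe {r!r}; known: {sorted(PRESETS)}")
        for m in self.models:
            if m not in ("rf", "svm", "plsda"):
                raise SpectraError(f"unknown model kind {m!r}")
        if not 0 < self.fraction <= 1:
            raise SpectraError("fraction must be in (0, 1]")
        if not (isinstance(self.input, str)
                and (self.input in FIXTURES or Path(self.input).suffix == ".csv")):
            raise SpectraError(
                f"input must be a fixture name {FIXTURES} or a .csv path")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, klass in (("rf", RFConfig), ("svm", SVMConfig),
                           ("plsda", PLSDAConfig)):
            if key in d and isinstance(d[key], dict):
                sub = {k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in d[key].items()}
                d[key] = klass(**sub)
        for key in ("recipes", "models", "vip_cutoffs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class StudyResult:
    run_dir: Path
    tables: dict[str, pd.DataFrame]
    best_recipe: str
    best_model: str
    final_model: TrainedModel
    final_metrics: dict
    manifest: dict


def _load_input(cfg: StudyConfig) -> SpectrumSet:
    if cfg.input in FIXTURES:
        train, _ = make_fixture(cfg.input, seed=cfg.seed)
        return train
    return read_csv(cfg.input)


def _setup_log(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "study.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _write_table(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(cfg: StudyConfig) -> StudyResult:
    """Execute the full study workflow; see the module docstring.

    Step order: (1) load or generate the labeled spectra; (2) pretreatment
    x classifier comparison grid; (3) choose the best (recipe, model) by
    validation accuracy (tie -> higher MCC); (4) RF deep tuning on the best
    recipe: ``n_tree`` grid -> ``m_try`` grid -> wavenumber-region
    experiment -> importance-cutoff experiment -> final refit on the
    selected variables; (5) final validation metrics, band report, model
    bundle, manifest.
    """
    cfg.validate()
    run_dir = Path(cfg.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(run_dir)
    checksums: dict[str, str] = {}
    try:
        log.info("study start input=%s seed=%d", cfg.input, cfg.seed)
        s = _load_input(cfg)
        tables: dict[str, pd.DataFrame] = {}

        # (2) pretreatment x classifier grid
        grid = comparison_grid(s, cfg.recipes, cfg.models,
                               fraction=cfg.fraction, seed=cfg.seed,
                               positive_class=cfg.positive_class)
        tables["comparison_grid"] = grid
        log.info("comparison grid: %d rows", len(grid))

        # (3) best (recipe, model) by validation ACC, tie -> MCC
        val = grid[grid["set"] == "validation"].copy()
        if val.empty:
            raise SpectraError("comparison grid produced no validation rows")
        val = val.sort_values(["ACC", "MCC", "recipe", "model"],
                              ascending=[False, False, True, True],
                              kind="stable")
        best_recipe = str(val.iloc[0]["recipe"])
        best_model = str(val.iloc[0]["model"])
        log.info("best cell: recipe=%s model=%s ACC=%.4f",
                 best_recipe, best_model, val.iloc[0]["ACC"])

        # RF deep tuning uses the best recipe *for the RF model*
        rf_val = val[val["model"] == "rf"]
        rf_recipe_name = str(rf_val.iloc[0]["recipe"]) if len(rf_val) else best_recipe
        recipe = preset_recipe(rf_recipe_name)

        t_all = recipe.fit(s).transform(s)
        split = kennard_stone(t_all, fraction=cfg.fraction, stratified=True)
        s_cal, s_val = s.take(split.calibration_idx), s.take(split.validation_idx)
        frozen = recipe.fit(s_cal)
        Xcal = frozen.transform(s_cal).values
        Xval = frozen.transform(s_val).values
        ycal = s_cal.label_array().astype(str)
        yval = s_val.label_array().astype(str)

        # (4a) n_tree grid
        best_ntree, ntree_table = tune_ntree(Xcal, ycal, cfg.rf,
                                             positive_class=cfg.positive_class)
        tables["ntree"] = ntree_table
        log.info("best n_tree=%d", best_ntree)

        # (4b) m_try grid
        best_mtry, mtry_table = tune_mtry(Xcal, ycal, best_ntree,
                                          grid=cfg.rf.m_try_grid,
                                          seed=cfg.rf.seed,
                                          positive_class=cfg.positive_class)
        tables["mtry"] = mtry_table
        log.info("best m_try=%d", best_mtry)

        # (4c) region experiment
        tables["regions"] = region_experiment(
            s, recipe, n_tree=best_ntree, m_try=best_mtry,
            regions=default_regions(), fraction=cfg.fraction,
            seed=cfg.rf.seed, positive_class=cfg.positive_class)

        # (4d) VIP cutoff experiment
        tuned = fit_rf(Xcal, ycal, n_tree=best_ntree, m_try=best_mtry,
                       seed=cfg.rf.seed, positive_class=cfg.positive_class)
        importance = rf_importance(tuned, Xcal, ycal)
        vip_table = vip_experiment(Xcal, ycal, Xval, yval, importance,
                                   n_tree=best_ntree, m_try=best_mtry,
                                   cutoffs=cfg.vip_cutoffs, seed=cfg.rf.seed,
                                   positive_class=cfg.positive_class)
        tables["vip"] = vip_table
        vbest = vip_table.sort_values(["ACC", "MCC", "vip_cutoff"],
                                      ascending=[False, False, True],
                                      kind="stable").iloc[0]
        best_cutoff = float(vbest["vip_cutoff"])
        log.info("best VIP cutoff=%g (%d variables)", best_cutoff,
                 int(vbest["n_selected"]))

        # (4e) final refit on selected variables
        keep = select_by_vip(importance, best_cutoff)
        final = fit_rf(Xcal[:, keep], ycal, n_tree=best_ntree,
                       m_try=min(best_mtry, keep.size), seed=cfg.rf.seed,
                       positive_class=cfg.positive_class,
                       metadata={"recipe": rf_recipe_name,
                                 "vip_cutoff": best_cutoff,
                                 "split_hash": _split_hash(split),
                                 "seed": cfg.rf.seed})
        # repackage so predict() accepts full-width preprocessed spectra
        final.selected_variable_idx = keep
        final.n_features_in = Xcal.shape[1]
        final.importance = importance
        final.importance_raw = tuned.importance_raw

        # (5) final validation metrics
        vp, vs = predict(final, Xval)
        em = evaluate_predictions(yval, vp.astype(str), vs, cfg.positive_class)
        final_metrics = {"SENS": em.sens, "SPEC": em.spec, "ACC": em.acc,
                         "MCC": em.mcc,
                         "AUC": None if em.auc is None else em.auc}
        tables["final_validation"] = pd.DataFrame([{
            "recipe": rf_recipe_name, "n_tree": best_ntree,
            "m_try": best_mtry, "vip_cutoff": best_cutoff,
            "n_selected": int(keep.size), **{k: (np.nan if v is None else v)
                                             for k, v in final_metrics.items()}}])
        log.info("final validation ACC=%.4f MCC=%.4f", em.acc, em.mcc)

        # band report on the raw training spectra (absorbance view)
        from .core import to_absorbance

        tables["bands"] = discriminating_report(to_absorbance(s),
                                                default_band_table())

        # ---- outputs ----
        for name, df in tables.items():
            checksums[f"{name}.csv"] = _write_table(df, run_dir / f"{name}.csv")
        split.to_frame(s.sample_ids).to_csv(run_dir / "split.csv", index=False)
        checksums["split.csv"] = hashlib.sha256(
            (run_dir / "split.csv").read_bytes()).hexdigest()
        model_dir = run_dir / "model"
        save_model_bundle(final, frozen, s.wavenumbers, model_dir)
        checksums["model_metadata"] = hashlib.sha256(
            (model_dir / "metadata.json").read_bytes()).hexdigest()

        manifest = {
            "package_version": __version__,
            "python": sys.version.split()[0],
            "seed": cfg.seed,
            "config": _jsonable(cfg.to_dict()),
            "config_hash": cfg.config_hash(),
            "best_recipe": best_recipe,
            "best_model": best_model,
            "rf_recipe": rf_recipe_name,
            "best_n_tree": int(best_ntree),
            "best_m_try": int(best_mtry),
            "best_vip_cutoff": best_cutoff,
            "n_selected_variables": int(keep.size),
            "final_validation": final_metrics,
            "checksums": checksums,
        }
        (run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        log.info("study complete -> %s", run_dir)
        return StudyResult(run_dir=run_dir, tables=tables,
                           best_recipe=best_recipe, best_model=best_model,
                           final_model=final, final_metrics=final_metrics,
                           manifest=manifest)
    finally:
        log.removeHandler(handler)
        handler.close()


def _split_hash(split) -> str:
    payload = json.dumps([split.calibration_idx.tolist(),
                          split.validation_idx.tolist()])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model bundle = trained model + frozen recipe + training grid
# ---------------------------------------------------------------------------

def save_model_bundle(model: TrainedModel, frozen_recipe, grid: np.ndarray,
                      path) -> None:
    path = Path(path)
    model.save(path)
    joblib.dump(frozen_recipe, path / "recipe.joblib")
    np.savetxt(path / "grid.csv", np.asarray(grid, dtype=float),
               fmt="%.10g", header="wavenumber", comments="")


def load_model_bundle(path):
    path = Path(path)
    model = TrainedModel.load(path)
    frozen = joblib.load(path / "recipe.joblib")
    grid = np.loadtxt(path / "grid.csv", skiprows=1)
    return model, frozen, grid


def predict_external(model_dir, spectra, positive_class: str | None = None
                     ) -> tuple[pd.DataFrame, dict | None]:
    """Score external spectra with a saved model bundle.

    ``spectra`` is a CSV path or a SpectrumSet.  The frozen pretreatment
    (with its calibration-set statistics) is applied, the model predicts,
    and — when the external set carries labels — the four evaluation
    parameters plus AUC are computed.  External grids are linearly
    interpolated onto the training grid when they differ (within the
    training range only); a mismatch beyond interpolation raises.
    """
    model, frozen, grid = load_model_bundle(model_dir)
    s = read_csv(spectra) if not isinstance(spectra, SpectrumSet) else spectra
    interpolated = False
    if s.wavenumbers.shape != grid.shape or not np.allclose(s.wavenumbers, grid):
        s = resample(s, grid)
        interpolated = True
    X = frozen.transform(s).values
    labels, scores = predict(model, X)
    report = pd.DataFrame({
        "sample_id": s.sample_ids,
        "predicted": labels.astype(str),
        "score": scores,
    })
    if interpolated:
        report.attrs["interpolated"] = True
    metrics_block = None
    if s.labels is not None:
        pos = positive_class or model.positive_class
        em = evaluate_predictions(s.label_array().astype(str),
                                  labels.astype(str), scores, pos)
        metrics_block = {"SENS": em.sens, "SPEC": em.spec, "ACC": em.acc,
                         "MCC": em.mcc,
                         "AUC": None if em.auc is None else em.auc}
        report["label"] = s.labels
    return report, metrics_block
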