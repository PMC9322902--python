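"""Classification evaluation and the study's comparison experiments.

Confusion-matrix metrics for a two-class problem:

    SENS = TP / (TP + FN)
    SPEC = TN / (TN + FP)
    ACC  = (TP + TN) / (TP + TN + FP + FN)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus a rank-based (Mann-Whitney, midrank tie-corrected) AUC.  Any metric
with a zero denominator is reported as 0 and flagged rather than raised, so
grid experiments never abort on a degenerate cell.

The experiment drivers reproduce the study's comparisons on any labeled
SpectrumSet: the pretreatment x classifier grid, the wavenumber-region
experiment, and the importance-cutoff (VIP) variable-selection experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import RegionSet, SpectraError, SpectrumSet, subset_region
from .sampling import SplitResult, kennard_stone, stratified_kfold

__all__ = [
    "ConfusionCounts", "EvalMetrics", "confusion", "metrics", "roc_auc",
    "evaluate_predictions", "comparison_grid", "region_experiment",
    "vip_experiment", "default_regions",
]

METRIC_COLS = ["SENS", "SPEC", "ACC", "MCC", "AUC"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    positive_class: str

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise SpectraError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvalMetrics:
    sens: float
    spec: float
    acc: float
    mcc: float
    auc: float | None = None
    degenerate: tuple[str, ...] = ()   # metrics zeroed by a 0 denominator


def confusion(y_true, y_pred, positive_class: str) -> ConfusionCounts:
    """Standard 2x2 tabulation; labels outside the truth alphabet raise."""
    t = np.asarray(y_true, dtype=str)
    p = np.asarray(y_pred, dtype=str)
    if t.shape != p.shape:
        raise SpectraError("y_true and y_pred must have equal length")
    alphabet = set(t.tolist()) | {positive_class}
    if len(alphabet) > 2:
        raise SpectraError(f"expected a 2-class alphabet, got {sorted(alphabet)}")
    unseen = set(p.tolist()) - alphabet
    if unseen:
        raise SpectraError(f"predicted labels outside the alphabet: {sorted(unseen)}")
    pos_t = t == positive_class
    pos_p = p == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


def metrics(c: ConfusionCounts, auc: float | None = None) -> EvalMetrics:
    """Sensitivity, specificity, accuracy and the Matthews correlation
    coefficient from a 2x2 table; zero-denominator metrics become 0 with a
    flag in ``degenerate``."""
    if c.total == 0:
        raise SpectraError("empty confusion table")
    degenerate = []

    def _ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sens = _ratio(c.TP, c.TP + c.FN, "sens")
    spec = _ratio(c.TN, c.TN + c.FP, "spec")
    acc = (c.TP + c.TN) / c.total
    den2 = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if den2 == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(den2))
    return EvalMetrics(sens=float(sens), spec=float(spec), acc=float(acc),
                       mcc=float(mcc), auc=auc, degenerate=tuple(degenerate))


def roc_auc(scores, y_true, positive_class: str) -> float | None:
    """Rank-based AUC (Mann-Whitney with midrank tie correction).

    Equivalent to the trapezoidal area under the ROC curve.  Returns
    ``None`` when ``y_true`` contains a single class.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise SpectraError("scores must be finite")
    t = np.asarray(y_true, dtype=str)
    pos = t == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_predictions(y_true, y_pred, scores, positive_class: str) -> EvalMetrics:
    """Convenience: confusion + metrics + AUC in one call."""
    c = confusion(y_true, y_pred, positive_class)
    auc = roc_auc(scores, y_true, positive_class)
    return metrics(c, auc=auc)


def _metrics_dict(em: EvalMetrics) -> dict:
    return {"SENS": em.sens, "SPEC": em.spec, "ACC": em.acc, "MCC": em.mcc,
            "AUC": np.nan if em.auc is None else em.auc}


# ---------------------------------------------------------------------------
# model fitting helpers shared by the experiment drivers
# ---------------------------------------------------------------------------

def _fit_model(kind: str, X, y, seed, positive_class,
               rf_params=None, svm_cfg=None, plsda_cfg=None):
    from . import models  # deferred: models imports this module's metrics

    if kind == "rf":
        rf_params = rf_params or {}
        return models.fit_rf(X, y,
                             n_tree=rf_params.get("n_tree", 300),
                             m_try=rf_params.get("m_try", "sqrt"),
                             seed=seed, positive_class=positive_class)
    if kind == "svm":
        return models.fit_svm_rbf(X, y, cfg=svm_cfg, seed=seed,
                                  positive_class=positive_class)
    if kind == "plsda":
        from .models import PLSDAConfig, plsda_outlier_removal

        cfg = plsda_cfg or PLSDAConfig()
        keep = plsda_outlier_removal(X, cfg)
        return models.fit_plsda(np.asarray(X)[keep], np.asarray(y)[keep],
                                cfg=cfg, seed=seed,
                                positive_class=positive_class)
    raise SpectraError(f"unknown model kind {kind!r}")


def _cv_predictions(kind: str, X, y, seed, positive_class, fitted,
                    rf_params=None, svm_cfg=None, plsda_cfg=None):
    """5-fold CV predictions on the calibration set with the already-tuned
    hyperparameters (refit per fold, parameters frozen)."""
    from . import models

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    folds = stratified_kfold(y, k=5, seed=seed)
    pred = np.empty(y.size, dtype=object)
    score = np.empty(y.size, dtype=float)
    for f, te in enumerate(folds):
        tr = np.setdiff1d(np.arange(y.size), te)
        if kind == "rf":
            m = models.fit_rf(X[tr], y[tr],
                              n_tree=fitted.tuned_params["n_tree"],
                              m_try=fitted.tuned_params["m_try"],
                              seed=seed + f, positive_class=positive_class)
        elif kind == "svm":
            m = models.fit_svm_rbf(
                X[tr], y[tr],
                cfg=models.SVMConfig(gamma=fitted.tuned_params["gamma"],
                                     cost=fitted.tuned_params["C"]),
                seed=seed + f, positive_class=positive_class)
        else:
            m = models.fit_plsda(
                X[tr], y[tr],
                cfg=models.PLSDAConfig(
                    n_components=fitted.tuned_params["n_components"]),
                seed=seed + f, positive_class=positive_class)
        pl, sc = models.predict(m, X[te])
        pred[te] = pl
        score[te] = sc
    return pred.astype(str), score


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def comparison_grid(s: SpectrumSet, recipes, model_kinds,
                    fraction: float = 0.8, seed: int = 20220720,
                    positive_class: str = "A",
                    split: SplitResult | None = None,
                    return_details: bool = False):
    """Pretreatment x classifier grid.

    For every (recipe, model) pair: preprocess -> Kennard-Stone split (on
    the preprocessed spectra; or a supplied split) -> refit the recipe on
    the calibration rows only -> tune/fit -> report calibration metrics
    (5-fold CV predictions) and validation metrics.  Emits a long-format
    table (recipe, model, set, SENS, SPEC, ACC, MCC, AUC); a failing cell
    is recorded as an error row and the grid continues.
    """
    from .preprocess import PreprocessRecipe, preset_recipe

    if not recipes or not model_kinds:
        raise SpectraError("need at least one recipe and one model kind")
    rows = []
    details = {}
    for rec in recipes:
        recipe = preset_recipe(rec) if isinstance(rec, str) else rec
        rname = recipe.name or "custom"
        try:
            t_all = recipe.fit(s).transform(s)
            sp = split or kennard_stone(t_all, fraction=fraction, stratified=True)
            s_cal = s.take(sp.calibration_idx)
            s_val = s.take(sp.validation_idx)
            frozen = recipe.fit(s_cal)
            Xcal = frozen.transform(s_cal).values
            Xval = frozen.transform(s_val).values
            ycal = s_cal.label_array().astype(str)
            yval = s_val.label_array().astype(str)
        except Exception as exc:
            for kind in model_kinds:
                rows.append({"recipe": rname, "model": kind, "set": "error",
                             "error": str(exc)})
            continue
        for kind in model_kinds:
            try:
                from . import models

                fitted = _fit_model(kind, Xcal, ycal, seed, positive_class)
                cv_pred, cv_score = _cv_predictions(
                    kind, Xcal, ycal, seed, positive_class, fitted)
                em_cal = evaluate_predictions(ycal, cv_pred, cv_score,
                                              positive_class)
                vp, vs = models.predict(fitted, Xval)
                em_val = evaluate_predictions(yval, vp.astype(str), vs,
                                              positive_class)
                rows.append({"recipe": rname, "model": kind,
                             "set": "calibration", **_metrics_dict(em_cal)})
                rows.append({"recipe": rname, "model": kind,
                             "set": "validation", **_metrics_dict(em_val)})
                details[(rname, kind)] = {"model": fitted, "split": sp,
                                          "frozen_recipe": frozen}
            except Exception as exc:
                rows.append({"recipe": rname, "model": kind, "set": "error",
                             "error": str(exc)})
    report = pd.DataFrame(rows)
    if return_details:
        return report, details
    return report


def default_regions() -> dict[str, RegionSet]:
    """The four wavenumber-region variants of the region experiment."""
    return {
        "4000-600": RegionSet([(600.0, 4000.0)], mode="keep"),
        "4000-600 minus water/CO2": RegionSet(
            [(3500.0, 4000.0), (2208.0, 2442.0)], mode="exclude"),
        "2000-600": RegionSet([(600.0, 2000.0)], mode="keep"),
        "4000-2000": RegionSet([(2000.0, 4000.0)], mode="keep"),
    }


def region_experiment(s: SpectrumSet, recipe, n_tree: int = 300,
                      m_try: int | str = "sqrt", regions=None,
                      fraction: float = 0.8, seed: int = 20220720,
                      positive_class: str = "A") -> pd.DataFrame:
    """Fit the tuned RF on wavenumber-region subsets of the spectra.

    Each region is cut from the raw spectra before preprocessing, then the
    usual preprocess/split/fit path runs; one validation-metrics row per
    region (plus the surviving variable count).
    """
    from . import models
    from .preprocess import preset_recipe

    regions = regions if regions is not None else default_regions()
    if not regions:
        raise SpectraError("regions must be nonempty")
    recipe = preset_recipe(recipe) if isinstance(recipe, str) else recipe
    rows = []
    for name, region in regions.items():
        try:
            s_r = subset_region(s, region)
        except SpectraError as exc:
            rows.append({"region": name, "error": str(exc)})
            continue
        t_all = recipe.fit(s_r).transform(s_r)
        sp = kennard_stone(t_all, fraction=fraction, stratified=True)
        s_cal, s_val = s_r.take(sp.calibration_idx), s_r.take(sp.validation_idx)
        frozen = recipe.fit(s_cal)
        Xcal, Xval = frozen.transform(s_cal).values, frozen.transform(s_val).values
        ycal = s_cal.label_array().astype(str)
        yval = s_val.label_array().astype(str)
        mt = m_try if m_try == "sqrt" else min(int(m_try), Xcal.shape[1])
        fitted = models.fit_rf(Xcal, ycal, n_tree=n_tree, m_try=mt, seed=seed,
                               positive_class=positive_class)
        vp, vs = models.predict(fitted, Xval)
        em = evaluate_predictions(yval, vp.astype(str), vs, positive_class)
        rows.append({"region": name, "n_variables": Xcal.shape[1],
                     **_metrics_dict(em)})
    return pd.DataFrame(rows)


def vip_experiment(Xcal, ycal, Xval, yval, importance, n_tree: int = 300,
                   m_try: int | str = "sqrt", cutoffs=(0.05, 0.01, 0.015, 0.020),
                   seed: int = 20220720,
                   positive_class: str = "A") -> pd.DataFrame:
    """Refit the RF on importance-selected variables at each cutoff.

    One row per cutoff with the surviving-variable count and validation
    metrics.  ``importance`` is on the rescaled (max = 1) scale.
    """
    from . import models

    if not len(cutoffs):
        raise SpectraError("cutoffs must be nonempty")
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    rows = []
    for cut in cutoffs:
        keep = models.select_by_vip(importance, cut)
        mt = m_try if m_try == "sqrt" else min(int(m_try), keep.size)
        fitted = models.fit_rf(Xcal[:, keep], np.asarray(ycal, dtype=str),
                               n_tree=n_tree, m_try=mt, seed=seed,
                               positive_class=positive_class)
        vp, vs = models.predict(fitted, Xval[:, keep])
        em = evaluate_predictions(np.asarray(yval, dtype=str), vp.astype(str),
                                  vs, positive_class)
        rows.append({"vip_cutoff": float(cut), "n_selected": int(keep.size),
                     **_metrics_dict(em)})
    return pd.DataFrame(rows)
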