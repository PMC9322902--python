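"""Pattern-recognition models and their tuning workflow.

Three classifiers, as used for two-class spectral discrimination:

* Random forest — a bagged CART ensemble with per-node random variable
  subsets.  The bagging/out-of-bag (OOB) bookkeeping is implemented here so
  the workflow can expose per-sample OOB predictions, OOB-error-based
  tuning of ``n_tree`` and ``m_try``, and OOB permutation variable
  importance with cutoff-based variable (VIP) selection.
* SVM with an RBF kernel, soft margin, one-versus-one strategy; C and
  gamma selected by 5-fold cross-validated accuracy over log grids.
* PLS-DA — PLS1 regression on a {0, 1} class code (0.5 decision
  threshold), preceded by PCA + Mahalanobis-distance outlier removal;
  the number of latent components selected by 5-fold CV.

All stochastic steps take explicit seeds; the default seed is 20220720.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import SpectraError
from .evaluation import confusion, metrics, roc_auc

__all__ = [
    "RFConfig", "SVMConfig", "PLSDAConfig", "TrainedModel",
    "fit_rf", "tune_ntree", "tune_mtry", "rf_importance", "select_by_vip",
    "fit_svm_rbf", "plsda_outlier_removal", "fit_plsda", "predict",
]

DEFAULT_SEED = 20220720

_METRIC_COLS = ["SENS", "SPEC", "ACC", "MCC", "AUC"]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class RFConfig:
    n_tree_grid: tuple[int, ...] = (100, 200, 300, 500, 800, 1000)
    m_try: int | str = "sqrt"           # "sqrt" -> floor(sqrt(p))
    m_try_grid: tuple[int, ...] | None = None
    vip_cutoff_grid: tuple[float, ...] = (0.05, 0.01, 0.015, 0.020)
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not self.n_tree_grid or not self.vip_cutoff_grid:
            raise SpectraError("RF grids must be nonempty")


@dataclass
class SVMConfig:
    gamma: float | str = "grid"
    cost: float | str = "grid"
    multiclass_strategy: str = "OVO"

    def __post_init__(self):
        for v, name in ((self.gamma, "gamma"), (self.cost, "cost")):
            if not (v == "grid" or (isinstance(v, (int, float)) and v > 0)):
                raise SpectraError(f"SVM {name} must be positive or 'grid'")


#: CV grids for the RBF-SVM hyperparameter search (log2 spacing).
SVM_C_GRID = tuple(2.0 ** k for k in range(-3, 8))
SVM_GAMMA_GRID = tuple(2.0 ** k for k in range(-10, 3))


@dataclass
class PLSDAConfig:
    n_components: int | str = "cv"
    decision_threshold: float = 0.5
    outlier_pca_variance: float = 0.95
    outlier_chi2_quantile: float = 0.975
    max_components: int = 10

    def __post_init__(self):
        if not 0 < self.decision_threshold < 1:
            raise SpectraError("decision_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# trained-model bundle
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Fitted classifier with tuned parameters and variable selection.

    ``selected_variable_idx`` indexes into the training variable space and
    is applied internally by :func:`predict`; ``fitted_state`` is the
    opaque fitted estimator (operating on the selected variables only).
    """

    kind: str                       # "rf" | "svm" | "plsda"
    tuned_params: dict
    selected_variable_idx: np.ndarray
    fitted_state: object
    classes_: list[str]
    positive_class: str
    n_features_in: int
    importance: np.ndarray | None = None       # rescaled, max = 1
    importance_raw: np.ndarray | None = None   # mean OOB accuracy drop
    training_metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Serialize to a directory: JSON metadata + joblib fitted state."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind,
            "tuned_params": _jsonable(self.tuned_params),
            "selected_variable_idx": self.selected_variable_idx.tolist(),
            "classes": self.classes_,
            "positive_class": self.positive_class,
            "n_features_in": int(self.n_features_in),
            "importance": None if self.importance is None else self.importance.tolist(),
            "importance_raw": None if self.importance_raw is None
                              else self.importance_raw.tolist(),
            "training_metadata": _jsonable(self.training_metadata),
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        joblib.dump(self.fitted_state, path / "state.joblib")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        return cls(
            kind=meta["kind"],
            tuned_params=meta["tuned_params"],
            selected_variable_idx=np.asarray(meta["selected_variable_idx"], dtype=int),
            fitted_state=joblib.load(path / "state.joblib"),
            classes_=meta["classes"],
            positive_class=meta["positive_class"],
            n_features_in=meta["n_features_in"],
            importance=None if meta["importance"] is None
                       else np.asarray(meta["importance"]),
            importance_raw=None if meta["importance_raw"] is None
                           else np.asarray(meta["importance_raw"]),
            training_metadata=meta["training_metadata"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _check_two_classes(y) -> list[str]:
    classes = sorted(set(np.asarray(y, dtype=str).tolist()))
    if len(classes) < 2:
        raise SpectraError("training labels contain a single class")
    if len(classes) > 2:
        raise SpectraError(f"binary workflow, got classes {classes}")
    return classes


def _resolve_positive(classes: list[str], positive_class: str | None) -> str:
    if positive_class is None:
        return "A" if "A" in classes else classes[0]
    if positive_class not in classes:
        raise SpectraError(f"positive class {positive_class!r} not in {classes}")
    return positive_class


def _resolve_mtry(m_try, p: int) -> int:
    if m_try == "sqrt":
        return max(1, int(np.floor(np.sqrt(p))))
    m = int(m_try)
    if not 1 <= m <= p:
        raise SpectraError(f"m_try={m} outside [1, {p}]")
    return m


# ---------------------------------------------------------------------------
# random forest (bagged CART with explicit OOB bookkeeping)
# ---------------------------------------------------------------------------

class _Forest:
    """Bagged CART ensemble with retained bootstrap/OOB masks."""

    def __init__(self, n_tree: int, m_try: int, seed: int):
        self.n_tree = int(n_tree)
        self.m_try = int(m_try)
        self.seed = int(seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=str)
        self.classes_ = sorted(set(y.tolist()))
        y_idx = np.searchsorted(np.asarray(self.classes_), y)
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_masks_: list[np.ndarray] = []
        oob_votes = np.zeros((n, len(self.classes_)))
        for _ in range(self.n_tree):
            boot = rng.integers(0, n, n)
            tree = DecisionTreeClassifier(
                max_features=self.m_try,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y_idx[boot])
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            if oob.any():
                pred = tree.predict(X[oob]).astype(int)
                oob_votes[np.where(oob)[0], pred] += 1.0
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        self._y_idx = y_idx
        self.oob_vote_counts_ = oob_votes
        return self

    # -- prediction -------------------------------------------------------
    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.trees_:
            pred = tree.predict(X).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1.0
        return votes / self.n_tree

    def oob_decision(self) -> tuple[np.ndarray, np.ndarray]:
        """(vote fractions, covered mask) over the training samples."""
        counts = self.oob_vote_counts_.sum(axis=1)
        covered = counts > 0
        frac = np.zeros_like(self.oob_vote_counts_)
        frac[covered] = self.oob_vote_counts_[covered] / counts[covered, None]
        return frac, covered

    def oob_error(self) -> float:
        frac, covered = self.oob_decision()
        if not covered.any():
            return float("nan")
        pred = frac[covered].argmax(axis=1)
        return float(np.mean(pred != self._y_idx[covered]))


def fit_rf(Xcal, ycal, n_tree: int = 300, m_try: int | str = "sqrt",
           seed: int = DEFAULT_SEED, positive_class: str | None = None,
           metadata: dict | None = None) -> TrainedModel:
    """Fit a random forest; majority-vote prediction with per-class vote
    fractions as scores; OOB predictions retained on the fitted state."""
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=str)
    classes = _check_two_classes(y)
    pos = _resolve_positive(classes, positive_class)
    m = _resolve_mtry(m_try, X.shape[1])
    forest = _Forest(n_tree, m, seed).fit(X, y)
    return TrainedModel(
        kind="rf",
        tuned_params={"n_tree": int(n_tree), "m_try": m, "seed": int(seed)},
        selected_variable_idx=np.arange(X.shape[1]),
        fitted_state=forest,
        classes_=classes,
        positive_class=pos,
        n_features_in=X.shape[1],
        training_metadata=metadata or {},
    )


def _oob_metric_row(forest: _Forest, y: np.ndarray, positive_class: str) -> dict:
    frac, covered = forest.oob_decision()
    classes = np.asarray(forest.classes_)
    pred = classes[frac[covered].argmax(axis=1)]
    truth = y[covered]
    c = confusion(truth, pred, positive_class)
    em = metrics(c)
    pos_col = forest.classes_.index(positive_class)
    auc = roc_auc(frac[covered, pos_col], truth, positive_class)
    return {"SENS": em.sens, "SPEC": em.spec, "ACC": em.acc, "MCC": em.mcc,
            "AUC": np.nan if auc is None else auc,
            "oob_error": forest.oob_error()}


def tune_ntree(Xcal, ycal, cfg: RFConfig | None = None,
               positive_class: str | None = None
               ) -> tuple[int, pd.DataFrame]:
    """Select the ensemble size with the lowest OOB misclassification error.

    One forest per grid value at ``m_try = floor(sqrt(p))``; ties broken
    toward the smaller ``n_tree``.  Returns the winner plus the full
    per-value OOB metric table.
    """
    cfg = cfg or RFConfig()
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=str)
    classes = _check_two_classes(y)
    pos = _resolve_positive(classes, positive_class)
    m = _resolve_mtry(cfg.m_try, X.shape[1])
    rows = []
    best = None
    for nt in cfg.n_tree_grid:
        forest = _Forest(nt, m, cfg.seed).fit(X, y)
        row = {"n_tree": int(nt), **_oob_metric_row(forest, y, pos)}
        rows.append(row)
        if best is None or row["oob_error"] < best[1]:
            best = (int(nt), row["oob_error"])
    return best[0], pd.DataFrame(rows)


def default_mtry_grid(p: int) -> tuple[int, ...]:
    """Eight values in steps of 2 centered on floor(sqrt(p)), clipped to
    [1, p]."""
    c = max(1, int(np.floor(np.sqrt(p))))
    vals = [c + d for d in range(-6, 10, 2)]
    vals = sorted({min(p, max(1, v)) for v in vals})
    return tuple(vals)


def tune_mtry(Xcal, ycal, n_tree: int, grid=None, seed: int = DEFAULT_SEED,
              positive_class: str | None = None
              ) -> tuple[int, pd.DataFrame]:
    """Select ``m_try`` at fixed ``n_tree`` by lowest OOB error.

    Ties break toward higher resubstitution (calibration) accuracy, then
    the smaller ``m_try``.
    """
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=str)
    classes = _check_two_classes(y)
    pos = _resolve_positive(classes, positive_class)
    p = X.shape[1]
    grid = tuple(grid) if grid is not None else default_mtry_grid(p)
    for g in grid:
        if not 1 <= int(g) <= p:
            raise SpectraError(f"m_try grid value {g} outside [1, {p}]")
    rows = []
    best = None  # (m, oob_error, -cal_acc)
    for m in grid:
        forest = _Forest(n_tree, int(m), seed).fit(X, y)
        cal_pred = np.asarray(forest.classes_)[
            forest.vote_fractions(X).argmax(axis=1)]
        cal_acc = float(np.mean(cal_pred == y))
        row = {"m_try": int(m), **_oob_metric_row(forest, y, pos),
               "cal_acc": cal_acc}
        rows.append(row)
        key = (row["oob_error"], -cal_acc, int(m))
        if best is None or key < best:
            best = key
    return best[2], pd.DataFrame(rows)


def rf_importance(model: TrainedModel, Xcal, ycal,
                  chunk: int = 64) -> np.ndarray:
    """OOB permutation accuracy importance, rescaled so the maximum is 1.

    For each tree, OOB accuracy is recomputed with each variable's OOB
    column permuted (one permutation per tree); the importance of a
    variable is its mean accuracy drop across trees.  The raw (unscaled)
    scores are stored on ``model.importance_raw``.
    """
    if model.kind != "rf":
        raise SpectraError("importance is defined for RF models only")
    forest: _Forest = model.fitted_state
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=str)
    y_idx = np.searchsorted(np.asarray(forest.classes_), y)
    n, p = X.shape
    rng = np.random.default_rng(forest.seed + 1000003)
    drops = np.zeros(p)
    used = 0
    for tree, oob in zip(forest.trees_, forest.oob_masks_):
        o = np.where(oob)[0]
        if o.size == 0:
            continue
        used += 1
        Xo = X[o]
        yo = y_idx[o]
        perm = rng.permutation(o.size)
        base_acc = float(np.mean(tree.predict(Xo).astype(int) == yo))
        # only variables the tree splits on can change its predictions;
        # permuting any other column leaves the accuracy drop exactly 0
        split_vars = np.unique(tree.tree_.feature)
        split_vars = split_vars[split_vars >= 0]
        for start in range(0, split_vars.size, chunk):
            cols = split_vars[start:start + chunk]
            rep = np.tile(Xo, (cols.size, 1))
            for k, j in enumerate(cols):
                rep[k * o.size:(k + 1) * o.size, j] = Xo[perm, j]
            pred = tree.predict(rep).astype(int)
            acc = (pred == np.tile(yo, cols.size)).reshape(
                cols.size, o.size).mean(axis=1)
            drops[cols] += base_acc - acc
    if used == 0:
        raise SpectraError("no tree has OOB samples; cannot compute importance")
    raw = drops / used
    top = raw.max()
    scaled = raw / top if top > 0 else np.zeros_like(raw)
    model.importance = scaled
    model.importance_raw = raw
    return scaled


def select_by_vip(importance: np.ndarray, cutoff: float) -> np.ndarray:
    """Indices of variables whose rescaled importance is >= ``cutoff``.

    If fewer than two survive, the top two by score are kept (warning).
    """
    imp = np.asarray(importance, dtype=float)
    if not 0 <= cutoff <= 1:
        raise SpectraError("cutoff must be in [0, 1] on the rescaled scale")
    keep = np.where(imp >= cutoff)[0]
    if keep.size < 2:
        warnings.warn(
            f"VIP cutoff {cutoff} keeps {keep.size} variables; padding to "
            "the top 2 by importance")
        keep = np.argsort(-imp, kind="stable")[:2]
        keep = np.sort(keep)
    return keep


# ---------------------------------------------------------------------------
# SVM (RBF)
# ---------------------------------------------------------------------------

def fit_svm_rbf(Xcal, ycal, cfg: SVMConfig | None = None,
                seed: int = DEFAULT_SEED, positive_class: str | None = None,
                metadata: dict | None = None) -> TrainedModel:
    """Soft-margin RBF-kernel SVM, one-versus-one.

    When ``cfg.cost``/``cfg.gamma`` are ``"grid"``, (C, gamma) are chosen
    by 5-fold cross-validated accuracy over log2 grids C in 2^-3..2^7 and
    gamma in 2^-10..2^2; ties break toward smaller C, then smaller gamma.
    """
    cfg = cfg or SVMConfig()
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=str)
    classes = _check_two_classes(y)
    pos = _resolve_positive(classes, positive_class)
    c_grid = SVM_C_GRID if cfg.cost == "grid" else (float(cfg.cost),)
    g_grid = SVM_GAMMA_GRID if cfg.gamma == "grid" else (float(cfg.gamma),)
    if len(c_grid) * len(g_grid) > 1:
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(seed))
        folds = list(skf.split(X, y))
        best = None  # strictly-greater update keeps the first (smallest C, gamma)
        for C in c_grid:
            for g in g_grid:
                acc = 0.0
                for tr, te in folds:
                    clf = SVC(kernel="rbf", C=C, gamma=g,
                              decision_function_shape="ovo")
                    clf.fit(X[tr], y[tr])
                    acc += float(np.mean(clf.predict(X[te]) == y[te]))
                acc /= len(folds)
                if best is None or acc > best[0] + 1e-12:
                    best = (acc, C, g)
        C, g = best[1], best[2]
    else:
        C, g = c_grid[0], g_grid[0]
    clf = SVC(kernel="rbf", C=C, gamma=g, decision_function_shape="ovo")
    clf.fit(X, y)
    return TrainedModel(
        kind="svm",
        tuned_params={"C": float(C), "gamma": float(g), "strategy": "OVO"},
        selected_variable_idx=np.arange(X.shape[1]),
        fitted_state=clf,
        classes_=classes,
        positive_class=pos,
        n_features_in=X.shape[1],
        training_metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def plsda_outlier_removal(Xcal, cfg: PLSDAConfig | None = None) -> np.ndarray:
    """PCA + Mahalanobis-distance outlier screen; returns retained indices.

    PCA scores are kept up to ``outlier_pca_variance`` cumulative explained
    variance; squared Mahalanobis distances of the scores are compared with
    the chi-square(k) ``outlier_chi2_quantile`` quantile.
    """
    cfg = cfg or PLSDAConfig()
    X = np.asarray(Xcal, dtype=float)
    n = X.shape[0]
    if cfg.outlier_chi2_quantile >= 1.0:
        return np.arange(n)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, cfg.outlier_pca_variance) + 1)
    k = min(k, scores.shape[1], n - 2)
    k = max(k, 1)
    while k >= 1:
        sub = scores[:, :k]
        cov = np.cov(sub, rowvar=False).reshape(k, k)
        sign, logdet = np.linalg.slogdet(cov)
        if sign > 0 and np.isfinite(logdet):
            break
        warnings.warn(f"singular score covariance at k={k}; reducing")
        k -= 1
    if k < 1:
        return np.arange(n)
    inv = np.linalg.inv(cov)
    centered = sub - sub.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    thresh = chi2.ppf(cfg.outlier_chi2_quantile, df=k)
    return np.where(d2 <= thresh)[0]


def fit_plsda(Xcal, ycal, cfg: PLSDAConfig | None = None,
              seed: int = DEFAULT_SEED, positive_class: str | None = None,
              metadata: dict | None = None) -> TrainedModel:
    """PLS1 regression on a {0, 1} class code (SIMPLS-family NIPALS as
    implemented by scikit-learn, mean-centered, unscaled columns).

    The component count is chosen by 5-fold CV misclassification at the 0.5
    threshold (ties -> fewer components).  Call
    :func:`plsda_outlier_removal` beforehand to screen the calibration set.
    """
    cfg = cfg or PLSDAConfig()
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=str)
    classes = _check_two_classes(y)
    pos = _resolve_positive(classes, positive_class)
    y01 = (y == pos).astype(float)
    cap = int(min(cfg.max_components, X.shape[0] - 2, X.shape[1],
                  np.linalg.matrix_rank(X - X.mean(axis=0))))
    cap = max(cap, 1)
    if cfg.n_components == "cv" and cap > 1:
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(seed))
        folds = list(skf.split(X, y))
        best = None
        for nc in range(1, cap + 1):
            err = 0.0
            for tr, te in folds:
                pls = PLSRegression(n_components=nc, scale=False)
                pls.fit(X[tr], y01[tr])
                pred = pls.predict(X[te]).ravel() >= cfg.decision_threshold
                err += float(np.mean(pred != (y01[te] == 1)))
            err /= len(folds)
            if best is None or err < best[0] - 1e-12:
                best = (err, nc)
        n_comp = best[1]
    elif cfg.n_components == "cv":
        n_comp = 1
    else:
        n_comp = int(cfg.n_components)
        if n_comp > cap:
            warnings.warn(f"n_components={n_comp} exceeds rank cap {cap}; truncated")
            n_comp = cap
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(X, y01)
    return TrainedModel(
        kind="plsda",
        tuned_params={"n_components": int(n_comp),
                      "threshold": cfg.decision_threshold},
        selected_variable_idx=np.arange(X.shape[1]),
        fitted_state=pls,
        classes_=classes,
        positive_class=pos,
        n_features_in=X.shape[1],
        training_metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: TrainedModel, Xnew) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and positive-class scores in [0, 1] for new rows.

    ``Xnew`` must have the training variable count; the model's variable
    selection is applied internally.
    """
    X = np.asarray(Xnew, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise SpectraError(
            f"expected {model.n_features_in} variables, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-matrix input'}")
    Xs = X[:, model.selected_variable_idx]
    pos = model.positive_class
    neg = [c for c in model.classes_ if c != pos][0]
    if model.kind == "rf":
        forest: _Forest = model.fitted_state
        frac = forest.vote_fractions(Xs)
        pred = np.asarray(forest.classes_)[frac.argmax(axis=1)]
        score = frac[:, forest.classes_.index(pos)]
    elif model.kind == "svm":
        clf: SVC = model.fitted_state
        pred = clf.predict(Xs)
        dec = clf.decision_function(Xs).ravel()
        # libsvm orients the decision toward classes_[1]
        if list(clf.classes_).index(pos) == 0:
            dec = -dec
        score = 1.0 / (1.0 + np.exp(-dec))
    elif model.kind == "plsda":
        pls: PLSRegression = model.fitted_state
        yhat = pls.predict(Xs).ravel()
        thr = model.tuned_params.get("threshold", 0.5)
        pred = np.where(yhat >= thr, pos, neg)
        score = np.clip(yhat, 0.0, 1.0)
    else:
        raise SpectraError(f"unknown model kind {model.kind!r}")
    return np.asarray(pred, dtype=object), np.asarray(score, dtype=float)
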