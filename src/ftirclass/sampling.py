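"""Sample partitioning: Kennard-Stone calibration/validation splitting and
stratified k-fold construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.model_selection import StratifiedKFold

from .core import SpectraError, SpectrumSet

__all__ = ["SplitResult", "kennard_stone", "stratified_kfold"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation index partition."""

    calibration_idx: np.ndarray
    validation_idx: np.ndarray
    fraction: float

    def __post_init__(self):
        cal = set(self.calibration_idx.tolist())
        val = set(self.validation_idx.tolist())
        if cal & val:
            raise SpectraError("calibration and validation sets overlap")

    def to_frame(self, sample_ids):
        import pandas as pd

        rows = [(sample_ids[i], "calibration") for i in self.calibration_idx]
        rows += [(sample_ids[i], "validation") for i in self.validation_idx]
        return pd.DataFrame(rows, columns=["sample_id", "set"])


def _ks_select(X: np.ndarray, m: int) -> list[int]:
    """Greedy Kennard-Stone selection of ``m`` rows of ``X``.

    Seeds with the maximal-distance pair (ties -> lowest row indices), then
    repeatedly adds the sample whose minimum distance to the selected set is
    largest (tie -> lowest index).  Fully deterministic.
    """
    n = X.shape[0]
    if m >= n:
        return list(range(n))
    D = squareform(pdist(X, metric="euclidean"))
    i, j = np.unravel_index(np.argmax(D), D.shape)  # row-major -> lowest indices
    selected = [min(i, j), max(i, j)]
    if m == 1:   # degenerate: keep only the first seed
        return [selected[0]]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    mind = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < m:
        cand = np.where(remaining)[0]
        k = cand[np.argmax(mind[cand])]  # argmax picks the lowest index on ties
        selected.append(int(k))
        remaining[k] = False
        mind = np.minimum(mind, D[k])
    return selected


def kennard_stone(s: SpectrumSet | np.ndarray, fraction: float = 0.8,
                  stratified: bool = True,
                  labels=None) -> SplitResult:
    """Kennard-Stone calibration/validation split.

    Euclidean distances are computed on the rows as given (apply the
    pretreatment under evaluation first).  With ``stratified=True``
    (default) the selection runs independently within each class so both
    sets stay class-balanced; the per-stratum calibration quota is
    ``round(fraction * n_stratum)``.
    """
    if isinstance(s, SpectrumSet):
        X = s.values
        if labels is None and s.labels is not None:
            labels = s.labels
    else:
        X = np.asarray(s, dtype=float)
    if not 0 < fraction <= 1:
        raise SpectraError("fraction must be in (0, 1]")
    n = X.shape[0]
    if labels is None or not stratified:
        strata = {None: np.arange(n)}
    else:
        lab = np.asarray(labels, dtype=object)
        strata = {c: np.where(lab == c)[0] for c in sorted(set(lab.tolist()))}
    cal: list[int] = []
    for _, idx in strata.items():
        if idx.size < 2 and fraction < 1:
            raise SpectraError("each stratum needs >= 2 samples to split")
        quota = int(np.floor(fraction * idx.size + 0.5))
        quota = max(1, min(quota, idx.size))
        picked = _ks_select(X[idx], quota)
        cal.extend(int(idx[p]) for p in picked)
    cal_arr = np.array(sorted(cal), dtype=int)
    val_arr = np.array(sorted(set(range(n)) - set(cal)), dtype=int)
    return SplitResult(cal_arr, val_arr, fraction)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Class-stratified k-fold partition of the index set.

    Per-class counts across folds differ by at most 1; deterministic under
    ``seed``.  Returns the k held-out index arrays.
    """
    lab = np.asarray(labels, dtype=object)
    if k < 2:
        raise SpectraError("k must be >= 2")
    classes, counts = np.unique(lab.astype(str), return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise SpectraError(f"classes smaller than k={k}: {small.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [test for _, test in skf.split(np.zeros((lab.size, 1)), lab.astype(str))]
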