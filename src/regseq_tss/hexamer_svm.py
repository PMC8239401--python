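"""Hexamer-frequency SVM baseline.

Each sequence is encoded as the frequency vector of all 4^6 = 4096 hexamers
(sliding window, stride 1; windows containing N are skipped and the
denominator reduced). An RBF-kernel support vector machine is tuned by grid
search over integer exponents of C (-3..1) and gamma (-13..-1), base 2,
scored by the same stratified fivefold cross-validated AU-ROC protocol as
the convolutional models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .cnn_model import compute_auroc, stratified_folds

K = 6
N_HEXAMERS = 4 ** K  # 4096

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_BASE_CODE[ord("N")] = -1

#: All 4096 hexamer strings in lexicographic A<C<G<T order (index order).
HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=K)]


def hexamer_features(seq: str, frequencies: bool = True) -> np.ndarray:
    """4096-dimensional hexamer count (or frequency) vector.

    Index is the lexicographic rank of the hexamer over A<C<G<T, i.e. the
    base-4 number with A=0, C=1, G=2, T=3, most significant base first.
    """
    seq = seq.upper()
    if len(seq) < K:
        raise ValueError(f"sequence length {len(seq)} < {K}")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < -1):
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    windows = np.lib.stride_tricks.sliding_window_view(codes, K)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(K - 1, -1, -1)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=N_HEXAMERS).astype(np.float64)
    if not frequencies:
        return counts
    total = counts.sum()
    return counts / total if total > 0 else counts


def hexamer_matrix(seqs: Sequence[str], frequencies: bool = True) -> np.ndarray:
    return np.stack([hexamer_features(s, frequencies) for s in seqs])


@dataclass
class GridSearchResult:
    """Outcome of the (C, gamma) exponent grid search."""

    grid_auc: dict[tuple[int, int], float]  # (C exponent, gamma exponent) -> CV AUC
    best_c_exp: int
    best_gamma_exp: int
    best_auc: float
    best_model: SVC
    base: float = 2.0

    @property
    def best_C(self) -> float:
        return self.base ** self.best_c_exp

    @property
    def best_gamma(self) -> float:
        return self.base ** self.best_gamma_exp


def grid_search_train(
    features: np.ndarray,
    labels: np.ndarray,
    exponents_C: Sequence[int] = range(-3, 2),
    exponents_gamma: Sequence[int] = range(-13, 0),
    base: float = 2.0,
    k: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive exponent grid search scored by k-fold CV AU-ROC.

    Ties on AUC resolve to the first grid point in (C, gamma) iteration
    order, so reruns on the same data and seed are identical. The returned
    model is refit on all the data at the best setting.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("grid_search_train: both classes must be present")
    rng = np.random.default_rng(seed)
    folds = stratified_folds(labels, k, rng)
    for fold in folds:
        if len(np.unique(labels[fold])) < 2:
            raise ValueError("degenerate single-class fold; dataset too small")
    grid_auc: dict[tuple[int, int], float] = {}
    best: tuple[float, int, int] | None = None
    for c_exp in exponents_C:
        for g_exp in exponents_gamma:
            aucs = []
            for fold in folds:
                mask = np.zeros(len(labels), dtype=bool)
                mask[fold] = True
                clf = SVC(C=base**c_exp, gamma=base**g_exp, kernel="rbf")
                clf.fit(features[~mask], labels[~mask])
                scores = clf.decision_function(features[mask])
                aucs.append(compute_auroc(labels[mask], scores))
            auc = float(np.mean(aucs))
            grid_auc[(c_exp, g_exp)] = auc
            if best is None or auc > best[0]:
                best = (auc, c_exp, g_exp)
    assert best is not None
    best_auc, c_exp, g_exp = best
    final = SVC(C=base**c_exp, gamma=base**g_exp, kernel="rbf")
    final.fit(features, labels)
    return GridSearchResult(grid_auc=grid_auc, best_c_exp=c_exp,
                            best_gamma_exp=g_exp, best_auc=best_auc,
                            best_model=final, base=base)


def svm_scores(result: GridSearchResult, features: np.ndarray) -> np.ndarray:
    """Decision-function scores of the refit best model (rank-equivalent to
    probabilities for AU-ROC)."""
    return result.best_model.decision_function(np.asarray(features, dtype=np.float64))
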