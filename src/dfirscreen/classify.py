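"""Cancer vs non-cancer RBF-SVM classification of spot spectra.

Protocol: for each cancer class, every cancer patient is tested leave-one-
out against a model trained on all 10 controls plus the remaining 9 cancer
patients.  The (C, gamma) pair is chosen once per run by stratified 3-fold
cross-validated grid search on the first held-out patient's training set,
then held fixed for the remaining patients of that run.  Each class model
is run in triplicate with different fold shuffles; the per-patient decision
is the modal vote over the three runs, and the fraction of unanimous
triples is reported.

The gamma grid is expressed relative to the variance-scaled reference
1 / (n_features * Var(X)) (sklearn's ``gamma='scale'``): min-max scaled
spot spectra concentrate at tiny pairwise distances, so absolute gamma
values in the usual libsvm range leave the RBF kernel effectively constant
and every grid cell degenerates to the same underfit predictor.  A
symmetric exponent ladder around the scale reference spans the underfit to
overfit regimes regardless of the feature scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import Spectrum
from .spots import SpotSpectrum

__all__ = [
    "SVMConfig",
    "ClassificationResult",
    "loo_classify_class",
    "triplicate_modal",
    "accuracy_report",
]

# log2 ladders: C is absolute (libsvm convention); gamma is RELATIVE to the
# variance-scale reference computed from the training matrix.
_DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 16, 2))
_DEFAULT_GAMMA_REL_GRID = tuple(float(2.0**k) for k in range(-9, 10, 2))


@dataclass(frozen=True)
class SVMConfig:
    """Grid-search and replication settings for the RBF-SVM protocol."""

    c_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_rel_grid: tuple[float, ...] = _DEFAULT_GAMMA_REL_GRID
    n_cv_folds: int = 3
    n_replicate_runs: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_rel_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.n_cv_folds < 2:
            raise ValueError("need >= 2 CV folds")
        if self.n_replicate_runs % 2 == 0:
            raise ValueError("replicate runs must be odd so modal votes cannot tie")


@dataclass
class ClassificationResult:
    """Triplicate LOO outcome for one cancer class vs the controls."""

    class_label: str
    decisions: np.ndarray        # (n_patients, n_runs) bool: classified cancer
    modal: np.ndarray            # (n_patients,) bool
    params_per_run: list[tuple[float, float]]   # (C, gamma) per run
    run_seeds: list[int]

    def __post_init__(self) -> None:
        expected = np.array([Counter(row).most_common(1)[0][0]
                             for row in self.decisions.astype(bool)])
        if not np.array_equal(expected, self.modal):
            raise ValueError("modal decisions must be the per-patient majority")

    @property
    def n_tested(self) -> int:
        return int(self.decisions.shape[0])

    @property
    def n_correct(self) -> int:
        # every tested patient is truly cancer; correct = classified cancer
        return int(self.modal.sum())

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.n_correct / self.n_tested

    @property
    def unanimous_fraction(self) -> float:
        rows = self.decisions.astype(bool)
        return float(np.mean(rows.all(axis=1) | (~rows).all(axis=1)))


def _as_matrix(spectra: Sequence[SpotSpectrum | Spectrum]) -> np.ndarray:
    rows = []
    for s in spectra:
        spec = s.spectrum if isinstance(s, SpotSpectrum) else s
        rows.append(np.asarray(spec.absorbance, dtype=float))
    X = np.vstack(rows)
    if np.ptp(X) <= 0:
        raise ValueError("degenerate features: all spectra identical/flat")
    return X


def _gamma_scale(X: np.ndarray) -> float:
    """Variance-scale gamma reference: 1 / (n_features * Var(X))."""
    v = X.var()
    if v <= 0:
        raise ValueError("degenerate features: zero variance")
    return 1.0 / (X.shape[1] * v)


def _grid_search(X: np.ndarray, y: np.ndarray, cfg: SVMConfig,
                 run_seed: int) -> tuple[float, float]:
    """Best (C, gamma) by stratified k-fold CV accuracy; ties resolved to
    the smallest C, then the smallest gamma (grid order)."""
    skf = StratifiedKFold(n_splits=cfg.n_cv_folds, shuffle=True,
                          random_state=run_seed)
    folds = list(skf.split(X, y))
    gs = _gamma_scale(X)
    best = None
    best_acc = -1.0
    for C in cfg.c_grid:
        for g_rel in cfg.gamma_rel_grid:
            gamma = g_rel * gs
            correct = 0
            total = 0
            for tr, te in folds:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                correct += int((clf.predict(X[te]) == y[te]).sum())
                total += te.size
            acc = correct / total
            if acc > best_acc:
                best_acc = acc
                best = (C, gamma)
    assert best is not None
    return best


def loo_classify_class(cancer_spectra: Sequence[SpotSpectrum | Spectrum],
                       control_spectra: Sequence[SpotSpectrum | Spectrum],
                       cfg: SVMConfig = SVMConfig(),
                       run_seed: int = 0,
                       ) -> tuple[np.ndarray, tuple[float, float]]:
    """One LOO run over the cancer patients of a class.

    (C, gamma) is tuned by CV on the first patient's training set (10
    controls + 9 cancer), then fixed while training/testing every patient.
    Returns the boolean decisions (True = classified cancer) and the
    parameter pair used.
    """
    if len(cancer_spectra) < 2 or len(control_spectra) < 2:
        raise ValueError("need >= 2 spectra per class")
    Xc = _as_matrix(cancer_spectra)
    X0 = _as_matrix(control_spectra)
    if Xc.shape[1] != X0.shape[1]:
        raise ValueError("cancer and control spectra must share one axis")
    n = Xc.shape[0]

    def train_set(held_out: int) -> tuple[np.ndarray, np.ndarray]:
        keep = [i for i in range(n) if i != held_out]
        X = np.vstack([X0, Xc[keep]])
        y = np.concatenate([np.zeros(X0.shape[0]), np.ones(len(keep))])
        return X, y

    X1, y1 = train_set(0)
    C, gamma = _grid_search(X1, y1, cfg, run_seed)
    decisions = np.zeros(n, dtype=bool)
    for i in range(n):
        X, y = train_set(i)
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X, y)
        decisions[i] = bool(clf.predict(Xc[i][None, :])[0] == 1)
    return decisions, (C, gamma)


def triplicate_modal(cancer_spectra: Sequence[SpotSpectrum | Spectrum],
                     control_spectra: Sequence[SpotSpectrum | Spectrum],
                     cfg: SVMConfig = SVMConfig(),
                     class_label: str = "cancer") -> ClassificationResult:
    """Replicate LOO runs (seeds base, base+1, ...) with a modal vote.

    The only run-to-run variation is the CV fold shuffle, which can select
    different (C, gamma); the modal vote makes the per-patient outcome
    robust to it.
    """
    seeds = [cfg.base_seed + k for k in range(cfg.n_replicate_runs)]
    all_dec = []
    params = []
    for s in seeds:
        dec, cg = loo_classify_class(cancer_spectra, control_spectra, cfg, run_seed=s)
        all_dec.append(dec)
        params.append(cg)
    decisions = np.column_stack(all_dec)
    modal = decisions.sum(axis=1) > decisions.shape[1] / 2.0
    return ClassificationResult(class_label=class_label, decisions=decisions,
                                modal=modal, params_per_run=params,
                                run_seeds=seeds)


def accuracy_report(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-class summary table: n_correct / n_tested, percent accuracy and
    unanimity of the triplicate votes."""
    rows = []
    for r in results:
        rows.append({
            "class_label": r.class_label,
            "n_correct": r.n_correct,
            "n_tested": r.n_tested,
            "accuracy_percent": r.accuracy_percent,
            "unanimous_fraction": r.unanimous_fraction,
            "params_per_run": "; ".join(f"C={c:g},g={g:.3g}"
                                        for c, g in r.params_per_run),
        })
    return pd.DataFrame.from_records(rows)
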