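"""Penalized logistic-regression protocol for mTP/cTP discrimination.

The discrimination protocol featurizes the 15 N-terminal residues of each
targeting peptide as 36 Z-scale auto-cross-covariance terms and evaluates a
binomial logistic regression with an elastic-net penalty (l1-ratio ``a``,
inverse regularization ``C = 1/lambda``) by repeated balanced cross-validation:
in each of ``n_runs`` runs, the same number of sequences is drawn from each
class without replacement, split into stratified folds, and the held-out
accuracy recorded. Features are standardized on the training folds only.
A related elastic-net model (l1-ratio 0.15) trained on whole-peptide ACC
vectors of antimicrobial peptides versus targeting peptides scores how
TP-like a candidate peptide is (fitted class probability of the TP class).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import acc_matrix, DEFAULT_MAX_LAG
from .peptides import Peptide, PeptideSet, Role, extract_n_element

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Protocol parameters (defaults follow the published protocol)."""

    l1_ratio: float = 0.0
    C: float = 0.1
    n_runs: int = 100
    n_folds: int = 5
    balanced_n: Optional[int] = None  # default: min class size
    tune_folds: int = 10
    seed: int = 0
    standardize: bool = True
    max_iter: int = 20000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_folds < 2 or self.tune_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class ClassifierReport:
    """Aggregated result of the resampled cross-validation protocol."""

    per_run_accuracy: list[float]
    mean_accuracy: float
    sd_accuracy: float
    coefficients: list[float]  # final fit on all data
    intercept: float
    config: dict
    n_redraws: int = 0

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def featurize_n_termini(
    peptides: PeptideSet | Iterable[Peptide],
    n: int = 15,
    max_lag: int = DEFAULT_MAX_LAG,
    **acc_kwargs,
) -> tuple[pd.DataFrame, pd.Series]:
    """ACC feature matrix of peptide N-termini plus role labels.

    Each row is the 36-term ACC vector of a peptide's first ``n`` residues;
    peptides shorter than ``n`` are dropped with a warning.
    """
    if n < max_lag + 1:
        raise ValueError(f"n-terminus of {n} residues too short for max_lag={max_lag}")
    kept, labels = [], []
    for p in peptides:
        if len(p) < n:
            logger.warning("%s: length %d < %d, dropped from featurization",
                           p.id, len(p), n)
            continue
        kept.append(extract_n_element(p, n))
        labels.append(p.role.value)
    X = acc_matrix(kept, max_lag=max_lag, **acc_kwargs)
    X.index = pd.Index([pid.rsplit("_N", 1)[0] for pid in X.index],
                       name="peptide_id")
    return X, pd.Series(labels, index=X.index, name="role")


def _model(cfg: ClassifierConfig, seed: int) -> Pipeline:
    clf = LogisticRegression(
        solver="saga", l1_ratio=cfg.l1_ratio, C=cfg.C,
        max_iter=cfg.max_iter, tol=cfg.tol, random_state=seed,
    )
    steps = ([("scale", StandardScaler())] if cfg.standardize else []) + [("clf", clf)]
    return Pipeline(steps)


def _fit(model: Pipeline, X: np.ndarray, y: np.ndarray) -> Pipeline:
    """Fit, promoting convergence warnings to hard errors (never silent)."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        model.fit(X, y)
    return model


def _as_array(X) -> np.ndarray:
    return X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)


def balanced_cv_accuracy(
    X_mtp,
    X_ctp,
    cfg: Optional[ClassifierConfig] = None,
) -> ClassifierReport:
    """Resampled, balanced, stratified k-fold CV of the penalized model.

    Per run: draw ``balanced_n`` rows per class without replacement, split
    into ``n_folds`` stratified folds, fit on the training folds
    (standardizing on training data only) and record held-out accuracy.
    Runs are seeded from ``cfg.seed``; the same seed yields a byte-identical
    report. The returned coefficients come from one final fit on all data.
    """
    cfg = cfg or ClassifierConfig()
    A, B = _as_array(X_mtp), _as_array(X_ctp)
    balanced_n = cfg.balanced_n or min(len(A), len(B))
    if balanced_n > min(len(A), len(B)):
        raise ValueError("balanced_n exceeds a class size")

    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_runs + 1)
    per_run: list[float] = []
    n_redraws = 0
    for run in range(cfg.n_runs):
        run_seed = int(seeds[run] % (2**31 - 1))
        rng = np.random.default_rng(run_seed)
        for attempt in range(10):
            ia = rng.choice(len(A), size=balanced_n, replace=False)
            ib = rng.choice(len(B), size=balanced_n, replace=False)
            X = np.vstack([A[ia], B[ib]])
            y = np.concatenate([np.zeros(balanced_n), np.ones(balanced_n)])
            skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                  random_state=run_seed + attempt)
            try:
                fold_acc = []
                for train, test in skf.split(X, y):
                    if len(np.unique(y[train])) < 2:
                        raise _DegenerateFold()
                    model = _fit(_model(cfg, run_seed), X[train], y[train])
                    fold_acc.append(float(model.score(X[test], y[test])))
                break
            except _DegenerateFold:
                n_redraws += 1
                logger.warning("run %d: degenerate fold, redrawing", run)
        per_run.append(float(np.mean(fold_acc)))
    if n_redraws:
        logger.warning("%d degenerate folds redrawn in total", n_redraws)

    X_all = np.vstack([A, B])
    y_all = np.concatenate([np.zeros(len(A)), np.ones(len(B))])
    final = _fit(_model(cfg, int(seeds[-1] % (2**31 - 1))), X_all, y_all)
    clf = final.named_steps["clf"]
    return ClassifierReport(
        per_run_accuracy=per_run,
        mean_accuracy=float(np.mean(per_run)),
        sd_accuracy=float(np.std(per_run)),
        coefficients=[float(c) for c in clf.coef_.ravel()],
        intercept=float(clf.intercept_[0]),
        config={**asdict(cfg), "balanced_n": balanced_n},
    )


class _DegenerateFold(Exception):
    pass


def tune_hyperparameters(
    X,
    y,
    l1_grid: Sequence[float] = (0.0, 0.03, 0.06, 0.09, 0.15, 0.5, 1.0),
    C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    tune_folds: int = 10,
    cfg: Optional[ClassifierConfig] = None,
) -> pd.DataFrame:
    """Exhaustive (l1_ratio, C) grid evaluation by k-fold cross-validation.

    Returns the full accuracy table with an ``is_best`` flag; exact ties are
    all marked best rather than silently broken.
    """
    cfg = cfg or ClassifierConfig(tune_folds=tune_folds)
    X = _as_array(X)
    y = np.asarray(y)
    if len(l1_grid) == 0 or len(C_grid) == 0:
        raise ValueError("grid must be non-empty")
    skf = StratifiedKFold(n_splits=tune_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    rows = []
    for a in l1_grid:
        for C in C_grid:
            point = ClassifierConfig(**{**asdict(cfg), "l1_ratio": a, "C": C})
            accs = []
            for train, test in splits:
                model = _fit(_model(point, point.seed), X[train], y[train])
                accs.append(float(model.score(X[test], y[test])))
            rows.append(dict(l1_ratio=a, C=C, accuracy=float(np.mean(accs))))
    table = pd.DataFrame(rows)
    table["is_best"] = table["accuracy"] == table["accuracy"].max()
    return table


def tp_similarity_score(
    candidates: PeptideSet | Iterable[Peptide],
    ha_ramps: PeptideSet | Iterable[Peptide],
    tps: PeptideSet | Iterable[Peptide],
    l1_ratio: float = 0.15,
    C: float = 1.0,
    seed: int = 0,
    **acc_kwargs,
) -> pd.Series:
    """How TP-like each candidate is: fitted probability of the TP class.

    The model is trained on whole-peptide ACC vectors (antimicrobial peptides
    have no cleavage sites, so no N-terminal truncation is applied).
    """
    cfg = ClassifierConfig(l1_ratio=l1_ratio, C=C, seed=seed)
    X_amp = acc_matrix(ha_ramps, **acc_kwargs)
    X_tp = acc_matrix(tps, **acc_kwargs)
    if X_amp.empty or X_tp.empty:
        raise ValueError("both training sets must be non-empty")
    X = np.vstack([X_amp.to_numpy(), X_tp.to_numpy()])
    y = np.concatenate([np.zeros(len(X_amp)), np.ones(len(X_tp))])
    model = _fit(_model(cfg, seed), X, y)
    X_cand = acc_matrix(candidates, **acc_kwargs)
    proba = model.predict_proba(X_cand.to_numpy())[:, 1]
    return pd.Series(proba, index=X_cand.index, name="tp_similarity")


def pca_projection(X, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA of a feature matrix.

    Returns ``(coordinates, explained_variance_fractions)``; fractions are
    non-increasing and sum to at most 1.
    """
    X = _as_array(X)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
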