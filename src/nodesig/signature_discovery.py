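"""Outcome-signature discovery by nearest shrunken centroids (PAM-style).

The discovery stage classifies samples into binary distant-metastasis outcome
classes, soft-thresholds the standardized class-vs-overall centroid
differences by a shrinkage threshold Delta (performing embedded feature
selection), picks Delta by stratified 10-fold cross-validation, and converts
the surviving genes into a directional signature for the mean-Z index.

Standard shrunken-centroid equations, for gene g and class k with n_k of n
samples:

    d_kg  = (xbar_kg - xbar_g) / (m_k * (s_g + s0)),   m_k = sqrt(1/n_k - 1/n)
    d'_kg = sign(d_kg) * max(|d_kg| - Delta, 0)
    xbar'_kg = xbar_g + m_k * (s_g + s0) * d'_kg

with s_g the pooled within-class SD and s0 the median of the s_g (a fudge
constant guarding against near-zero variances). Prediction uses the
discriminant

    delta_k(x) = sum_g (x_g - xbar'_kg)^2 / (s_g + s0)^2  -  2 log pi_k

restricted to surviving genes, choosing the minimizing class (ties to the
class listed first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort_data import CohortTable, DMFS_HORIZON_MONTHS, ExpressionMatrix
from .errors import (
    EmptySignatureError,
    InvalidInputError,
    MissingFeatureError,
)
from .signature_registry import GeneSignature, SignatureGene

EVENT_CLASS = "event"
EVENT_FREE_CLASS = "event_free"


def make_outcome_classes(
    cohort: CohortTable, horizon: float = DMFS_HORIZON_MONTHS
) -> tuple[pd.Series, list]:
    """Binary DMFS outcome classes for signature training.

    ``event``: distant metastasis within the horizon. ``event_free``:
    metastasis-free with follow-up of at least the horizon. Samples censored
    before the horizon carry ambiguous class information and are excluded;
    their ids are returned alongside the labels.
    """
    t = cohort.durations()
    e = cohort.events()
    event = (e == 1) & (t <= horizon)
    event_free = (e == 0) & (t >= horizon)
    labels = pd.Series(np.where(event, EVENT_CLASS, EVENT_FREE_CLASS), index=t.index)
    keep = event | event_free
    excluded = list(t.index[~keep])
    return labels[keep], excluded


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return pd.DataFrame(X)


@dataclass
class ShrunkenCentroidModel:
    classes: list[str]
    class_counts: pd.Series
    priors: pd.Series
    overall_centroid: pd.Series  # per gene
    class_centroids: pd.DataFrame  # genes x classes
    pooled_sd: pd.Series  # s_g
    s0: float
    m_k: pd.Series  # per class
    d: pd.DataFrame  # genes x classes, standardized distances
    delta: float
    d_shrunk: pd.DataFrame = field(init=False)
    shrunken_centroids: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.d_shrunk = np.sign(self.d) * np.maximum(self.d.abs() - self.delta, 0.0)
        scale = pd.DataFrame(
            np.outer(self.pooled_sd + self.s0, self.m_k),
            index=self.d.index,
            columns=self.d.columns,
        )
        self.shrunken_centroids = self.d_shrunk * scale
        self.shrunken_centroids = self.shrunken_centroids.add(self.overall_centroid, axis=0)

    @property
    def surviving_genes(self) -> list:
        mask = (self.d_shrunk.abs() > 0).any(axis=1)
        return list(self.d_shrunk.index[mask])

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "delta": self.delta,
            "s0": self.s0,
            "priors": self.priors.to_dict(),
            "n_surviving_genes": len(self.surviving_genes),
            "surviving_genes": [str(g) for g in self.surviving_genes],
        }


@dataclass
class CvResult:
    delta_grid: np.ndarray
    cv_error: np.ndarray  # mean held-out misclassification per delta
    chosen_delta: float
    seed: int
    n_folds: int
    fold_errors: np.ndarray  # folds x deltas
    rule: str = "1se"

    def to_dict(self) -> dict:
        return {
            "delta_grid": [float(d) for d in self.delta_grid],
            "cv_error": [float(e) for e in self.cv_error],
            "chosen_delta": float(self.chosen_delta),
            "seed": int(self.seed),
            "n_folds": int(self.n_folds),
            "rule": self.rule,
        }


def nsc_train(X, labels, delta: float = 0.0) -> ShrunkenCentroidModel:
    """Fit a nearest-shrunken-centroid model at shrinkage threshold ``delta``.

    ``X`` is genes x samples (DataFrame or :class:`ExpressionMatrix`);
    ``labels`` assigns each sample to one of two (or more) classes, each with
    at least 2 members. Class order follows first appearance in ``labels``.
    """
    vals = _as_frame(X)
    y = pd.Series(labels, index=vals.columns) if not isinstance(labels, pd.Series) else labels
    y = y.loc[vals.columns]
    if delta < 0:
        raise InvalidInputError("delta must be >= 0")
    classes = list(dict.fromkeys(y))
    if len(classes) < 2:
        raise InvalidInputError("training needs at least two classes")
    counts = y.value_counts()
    if (counts.reindex(classes) < 2).any():
        raise InvalidInputError(f"every class needs >= 2 samples, got {counts.to_dict()}")

    n = len(y)
    overall = vals.mean(axis=1)
    class_cent = pd.DataFrame({k: vals.loc[:, y == k].mean(axis=1) for k in classes})
    # pooled within-class SD: s_g^2 = (1/(n-K)) * sum_k sum_{i in k} (x - xbar_k)^2
    ss = pd.Series(0.0, index=vals.index)
    for k in classes:
        sub = vals.loc[:, y == k]
        ss = ss + sub.sub(class_cent[k], axis=0).pow(2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    m_k = pd.Series({k: np.sqrt(1.0 / counts[k] - 1.0 / n) for k in classes})
    denom = pd.DataFrame(
        np.outer(pooled_sd + s0, m_k[classes]), index=vals.index, columns=classes
    )
    d = class_cent.sub(overall, axis=0) / denom
    priors = (counts.reindex(classes) / n).astype(float)
    return ShrunkenCentroidModel(
        classes=classes,
        class_counts=counts.reindex(classes),
        priors=priors,
        overall_centroid=overall,
        class_centroids=class_cent,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        d=d,
        delta=float(delta),
    )


def nsc_predict(model: ShrunkenCentroidModel, x):
    """Classify one sample (Series) or many (genes x samples DataFrame).

    Returns ``(label, scores)`` for a single sample or ``(labels, scores)``
    (Series, samples x classes DataFrame) for a matrix. The discriminant is
    evaluated over surviving genes only; with no surviving genes it reduces to
    the prior term and every sample gets the majority class.
    """
    single = isinstance(x, pd.Series)
    X = x.to_frame() if single else _as_frame(x)
    genes = model.surviving_genes
    missing = [g for g in genes if g not in X.index]
    if missing:
        raise MissingFeatureError(f"sample lacks surviving genes: {missing[:5]}")
    scores = pd.DataFrame(0.0, index=X.columns, columns=model.classes)
    if genes:
        sub = X.loc[genes]
        s = (model.pooled_sd + model.s0).loc[genes]
        for k in model.classes:
            diff = sub.sub(model.shrunken_centroids.loc[genes, k], axis=0).div(s, axis=0)
            scores[k] = diff.pow(2).sum(axis=0)
    for k in model.classes:
        scores[k] = scores[k] - 2.0 * np.log(model.priors[k])
    # argmin with deterministic tie-break to the class listed first
    order = {k: i for i, k in enumerate(model.classes)}
    arr = scores.to_numpy()
    best = np.argmin(arr + 1e-12 * np.array([order[k] for k in scores.columns]), axis=1)
    labels = pd.Series([scores.columns[i] for i in best], index=X.columns)
    if single:
        return labels.iloc[0], scores.iloc[0]
    return labels, scores


def default_delta_grid(X, labels, n_points: int = 30) -> np.ndarray:
    """Evenly spaced shrinkage grid from 0 to the largest |d| at Delta=0."""
    model = nsc_train(X, labels, delta=0.0)
    dmax = float(model.d.abs().to_numpy().max())
    return np.linspace(0.0, dmax, n_points)


def nsc_cv(
    X,
    labels,
    delta_grid: Optional[Sequence[float]] = None,
    k: int = 10,
    seed: int = 0,
    rule: str = "1se",
) -> CvResult:
    """Choose the shrinkage threshold by stratified k-fold cross-validation.

    For each Delta the mean held-out misclassification error over folds is
    computed. ``rule="min"`` picks the Delta attaining the minimal error,
    ties broken toward larger Delta (fewer genes); ``rule="1se"`` (default,
    the usual shrunken-centroid practice) picks the largest Delta whose error
    stays within one standard error of the minimum — near-flat CV curves
    otherwise retain batches of noise genes that dilute downstream indices.
    Fold assignment is fixed by ``seed``.
    """
    vals = _as_frame(X)
    y = pd.Series(labels, index=vals.columns) if not isinstance(labels, pd.Series) else labels
    y = y.loc[vals.columns]
    if delta_grid is None:
        delta_grid = default_delta_grid(vals, y)
    grid = np.asarray(list(delta_grid), dtype=float)
    if grid.size == 0:
        raise InvalidInputError("delta grid is empty")
    n_folds = min(k, int(y.value_counts().min()))
    if n_folds < 2:
        raise InvalidInputError("stratification degenerate: a class has < 2 samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cols = np.array(vals.columns)
    fold_errors = np.zeros((n_folds, grid.size))
    for f, (train_idx, test_idx) in enumerate(skf.split(cols, y.to_numpy())):
        tr, te = cols[train_idx], cols[test_idx]
        base = nsc_train(vals.loc[:, tr], y.loc[tr], delta=0.0)
        for j, delta in enumerate(grid):
            model = ShrunkenCentroidModel(
                classes=base.classes,
                class_counts=base.class_counts,
                priors=base.priors,
                overall_centroid=base.overall_centroid,
                class_centroids=base.class_centroids,
                pooled_sd=base.pooled_sd,
                s0=base.s0,
                m_k=base.m_k,
                d=base.d,
                delta=float(delta),
            )
            pred, _ = nsc_predict(model, vals.loc[:, te])
            fold_errors[f, j] = float((pred != y.loc[te]).mean())
    cv_error = fold_errors.mean(axis=0)
    best = cv_error.min()
    if rule == "min":
        chosen = grid[cv_error == best].max()  # ties -> larger delta (fewer genes)
    elif rule == "1se":
        j = int(np.flatnonzero(cv_error == best).max())
        se = float(fold_errors[:, j].std(ddof=1) / np.sqrt(n_folds))
        chosen = grid[cv_error <= best + se].max()
    else:
        raise InvalidInputError(f"unknown selection rule {rule!r}")
    return CvResult(
        delta_grid=grid,
        cv_error=cv_error,
        chosen_delta=float(chosen),
        seed=seed,
        n_folds=n_folds,
        fold_errors=fold_errors,
        rule=rule,
    )


def derive_signature(
    model: ShrunkenCentroidModel,
    event_class: str = EVENT_CLASS,
    name: str = "discovered",
) -> GeneSignature:
    """Label surviving genes by outcome association.

    A gene whose event-class shrunken centroid exceeds its overall centroid is
    elevated in metastasizing tumours — direction ``poor``; otherwise
    ``good``. The result feeds the directional mean-Z index.
    """
    if event_class not in model.classes:
        raise InvalidInputError(f"event class {event_class!r} not in {model.classes}")
    genes = model.surviving_genes
    if not genes:
        raise EmptySignatureError("no genes survive shrinkage at this delta")
    sig_genes = []
    for g in genes:
        elevated = (
            model.shrunken_centroids.loc[g, event_class] > model.overall_centroid.loc[g]
        )
        sig_genes.append(SignatureGene(symbol=str(g), direction="poor" if elevated else "good"))
    return GeneSignature(name, sig_genes, meta={"delta": model.delta})
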