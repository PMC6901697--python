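"""Diagnostic profile extraction from reactivity matrices.

A two-stage feature-selection strategy tuned for small serology cohorts:
(1) filter to peptides significantly reactive in at least one patient;
(2) per leave-one-out fold, a backward-elimination / forward-selection
greedy search maximizing the silhouette separation of the target dichotomy
(one "RFE-derived set", RFEDS, per fold); features recurring in at least n
folds form consensus sets. A linear max-margin classifier on the consensus
features (optionally through a 2-D classical-MDS reduction) is scored by the
Matthews correlation coefficient against a label-scrambled null band.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples
from sklearn.svm import SVC

from .peptide_space import classical_mds
from .reactivity import ReactivityCalls

log = logging.getLogger(__name__)

__all__ = [
    "FeatureSelectionReport",
    "ClassifierReport",
    "filter_features",
    "separation_criterion",
    "rfe_forward_select",
    "bootstrap_rfeds",
    "matthews_corrcoef",
    "train_eval_classifier",
    "scrambled_null",
    "estimate_profile_capacity",
]

IMPROVEMENT_TOL = 1e-6


def filter_features(calls: ReactivityCalls) -> list:
    """Peptides significantly reactive in at least one sample."""
    return calls.features_significant_anywhere()


def _zscore_features(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def separation_criterion(
    values: pd.DataFrame, features, labels: pd.Series
) -> float:
    """Worst-class silhouette of a dichotomy on z-scored selected features.

    Samples are points, features z-scored across samples, Euclidean distance;
    per-sample silhouette widths are averaged within each class and the
    smaller class mean is returned. Requiring BOTH patient clusters to be
    coherent is what makes the criterion reward convoluted multi-feature
    signatures: a single reactivity that separates only part of a diagnostic
    group scores poorly even if it makes the other group look tight (the
    plain mean silhouette is maximized by exactly such single features).
    Near 1 means both classes tight and well separated; near 0, no structure.
    Invariant to feature order.
    """
    features = list(features)
    if not features:
        raise ValueError("no features")
    y = labels.loc[values.columns]
    if y.nunique() < 2 or y.value_counts().min() < 2:
        raise ValueError("need >= 2 samples in each of two classes")
    X = _zscore_features(values.loc[features].to_numpy(dtype=float).T)
    s = silhouette_samples(X, y.to_numpy(), metric="euclidean")
    return float(min(pd.Series(s).groupby(y.to_numpy()).mean()))


def rfe_forward_select(
    values: pd.DataFrame,
    labels: pd.Series,
    features0,
    tol: float = IMPROVEMENT_TOL,
    min_features: int = 1,
) -> list:
    """Greedy backward elimination then forward re-addition of features.

    The backward pass repeatedly removes the feature whose removal most
    increases the separation criterion while any removal improves it by more
    than ``tol``; the forward pass greedily re-adds excluded features under
    the same rule. Ties break by feature id, so the procedure is
    deterministic. The final criterion is never below the starting one.
    """
    current = sorted(features0)
    if not current:
        raise ValueError("features0 is empty")
    score = separation_criterion(values, current, labels)
    # backward: remove while the best removal does not decrease the criterion
    # (equal-criterion removals prune redundant features down to min_features)
    while len(current) > min_features:
        best_s, best_f = -np.inf, None
        for f in current:  # sorted, so ties keep the lowest feature id removed
            trial = [g for g in current if g != f]
            s = separation_criterion(values, trial, labels)
            if s > best_s:
                best_s, best_f = s, f
        if best_f is None or best_s < score - 1e-12:
            break
        current.remove(best_f)
        score = best_s
    # forward: re-add excluded features only on strict improvement
    excluded = sorted(set(features0) - set(current))
    improved = True
    while improved and excluded:
        improved = False
        best_s, best_f = score + tol, None
        for f in excluded:
            s = separation_criterion(values, sorted(current + [f]), labels)
            if s > best_s:
                best_s, best_f = s, f
        if best_f is not None:
            current.append(best_f)
            current.sort()
            excluded.remove(best_f)
            score = best_s
            improved = True
    return current


@dataclass
class FeatureSelectionReport:
    """Per-fold RFE-derived sets and their consensus hierarchy."""

    rfeds: list[list]
    folds: list  # identifier of the left-out sample per fold

    def __post_init__(self):
        union = {f for s in self.rfeds for f in s}
        self._counts = pd.Series(
            {f: sum(f in set(s) for s in self.rfeds) for f in union}
        )

    def consensus(self, n: int) -> list:
        """Features present in at least n of the per-fold sets."""
        return sorted(self._counts.index[self._counts >= n])

    def set_sizes(self) -> list[int]:
        return [len(s) for s in self.rfeds]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"folds": list(self.folds), "rfeds": self.rfeds}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FeatureSelectionReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(rfeds=d["rfeds"], folds=d["folds"])


def bootstrap_rfeds(
    values: pd.DataFrame,
    labels: pd.Series,
    calls: ReactivityCalls | None = None,
    features0=None,
    tol: float = IMPROVEMENT_TOL,
) -> FeatureSelectionReport:
    """Leave-one-out bootstrap of the greedy feature selection.

    For each left-out sample, the filter (when ``calls``/``features0`` are
    recomputed per fold or given globally) and the greedy search are rerun on
    the remaining samples; the per-fold sets express how stable the selection
    is to a 2-sample difference between cohorts. Folds whose training labels
    collapse to one class are skipped (logged).
    """
    if values.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    if features0 is None:
        if calls is None:
            raise ValueError("provide either calls or features0")
        features0 = filter_features(calls)
    rfeds, folds = [], []
    for left_out in values.columns:
        rest = [c for c in values.columns if c != left_out]
        y = labels.loc[rest]
        if y.nunique() < 2 or y.value_counts().min() < 2:
            log.warning("skipping fold %s: degenerate labels", left_out)
            continue
        rfeds.append(rfe_forward_select(values[rest], y, features0, tol=tol))
        folds.append(left_out)
    return FeatureSelectionReport(rfeds=rfeds, folds=folds)


def matthews_corrcoef(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC from confusion counts; zero when any marginal is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class ClassifierReport:
    predictions: pd.Series
    tp: int
    tn: int
    fp: int
    fn: int
    mcc: float
    scheme: str
    null_band: tuple[float, float] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "predictions": {str(k): bool(v) for k, v in self.predictions.items()},
                    "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
                    "mcc": self.mcc,
                    "scheme": self.scheme,
                    "null_band": self.null_band,
                },
                fh,
                indent=2,
            )


def _fit_predict(X_train, y_train, X_test, C=1.0):
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def train_eval_classifier(
    values: pd.DataFrame,
    features,
    labels: pd.Series,
    scheme: str = "loo",
    test_samples=None,
    mds_dims: int | None = None,
    C: float = 1.0,
) -> ClassifierReport:
    """Linear max-margin classifier on selected features, scored by MCC.

    ``scheme='loo'`` leave-one-out predicts every sample; ``scheme='holdout'``
    trains on all samples except ``test_samples`` and predicts those. With
    ``mds_dims`` the feature matrix is first reduced by classical MDS on
    Euclidean distances (the surrogate-feature construction used to keep
    models testable with few cases); in holdout mode the reduction is fit on
    all samples jointly, as coordinates only (no labels) are involved.
    """
    features = list(features)
    y = labels.loc[values.columns].astype(bool)
    X = _zscore_features(values.loc[features].to_numpy(dtype=float).T)
    if mds_dims is not None:
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
        X = classical_mds(D, dims=mds_dims)
    samples = list(values.columns)
    preds = {}
    if scheme == "loo":
        for i, s in enumerate(samples):
            mask = np.arange(len(samples)) != i
            if y[mask].nunique() < 2:
                raise ValueError("single-class training fold")
            preds[s] = bool(_fit_predict(X[mask], y.to_numpy()[mask], X[i : i + 1], C)[0])
        evaluated = samples
    elif scheme == "holdout":
        if not test_samples:
            raise ValueError("holdout scheme needs test_samples")
        test_idx = [samples.index(s) for s in test_samples]
        train_mask = np.ones(len(samples), dtype=bool)
        train_mask[test_idx] = False
        if y[train_mask].nunique() < 2:
            raise ValueError("single-class training set")
        yhat = _fit_predict(X[train_mask], y.to_numpy()[train_mask], X[test_idx], C)
        preds = {s: bool(v) for s, v in zip(test_samples, yhat)}
        evaluated = list(test_samples)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    pred = pd.Series(preds)[evaluated]
    truth = y.loc[evaluated]
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    return ClassifierReport(
        predictions=pred,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        mcc=matthews_corrcoef(tp, tn, fp, fn),
        scheme=scheme,
    )


def scrambled_null(
    values: pd.DataFrame,
    features,
    labels: pd.Series,
    scheme: str = "loo",
    test_samples=None,
    B: int = 1000,
    seed: int = 0,
    mds_dims: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """5%/95% MCC band over B label-scrambled refits of the same classifier.

    Permutations that collapse a training set to one class are redrawn.
    Returns (q05, q95, all B null MCCs); deterministic per seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5C)))
    y = labels.loc[values.columns]
    mccs = np.empty(B)
    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        if attempts > 50 * B:
            raise RuntimeError("could not draw valid label permutations")
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        try:
            rep = train_eval_classifier(
                values, features, perm, scheme=scheme, test_samples=test_samples,
                mds_dims=mds_dims,
            )
        except ValueError:
            continue
        mccs[b] = rep.mcc
        b += 1
    return float(np.quantile(mccs, 0.05)), float(np.quantile(mccs, 0.95)), mccs


def estimate_profile_capacity(n_features: int, k_min: int, k_max: int) -> int:
    """Number of distinct qualitative profiles: sum of C(n, k) for k in range.

    Exact integer arithmetic; with ~500 significant reactivities and profiles
    of some tens of features the count exceeds 10^70, which bounds the
    resolution of presence/absence profiling.
    """
    if not (0 <= k_min <= k_max <= n_features):
        raise ValueError("need 0 <= k_min <= k_max <= n_features")
    return sum(comb(n_features, k) for k in range(k_min, k_max + 1))
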