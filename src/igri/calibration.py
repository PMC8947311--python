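"""Recalibration of the model's constants from a labeled cohort.

Three bespoke pieces sit on top of an external boosting engine:

* ``derive_importance`` — gradient-boosted-tree feature importances,
  normalized to sum to 1, yielding recalibrated index weights;
* ``derive_threshold`` — exhaustive midpoint sweep minimizing
  misclassification under the strict-inequality classification rule;
* ``sweep_ratio`` — base:NNI mixing-ratio comparison with per-ratio
  optimal thresholds.

The boosting engine is scikit-learn's ``GradientBoostingClassifier`` with
the published hyperparameters mapped onto it (learning rate 0.4, max depth
4, subsample 0.7); importance defaults to the impurity-gain type.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from igri.core_model import (
    FEATURES,
    ConfigurationError,
    IndexModel,
    NormalizationSpec,
    ReferenceDataset,
    ValidationError,
)
from igri.index import classify, score_cohort

#: Published boosting hyperparameters (as mapped onto the sklearn engine).
DEFAULT_BOOSTING_PARAMS: dict = {
    "learning_rate": 0.4,
    "max_depth": 4,
    "subsample": 0.7,
    "n_estimators": 100,
}

MIN_ROWS_PER_CLASS = 50


def derive_importance(
    X: np.ndarray,
    y: np.ndarray,
    params: Mapping | None = None,
    seed: int = 0,
    importance_type: str = "gain",
) -> dict[str, float]:
    """Fit a gradient-boosted classifier and return normalized importances.

    Parameters
    ----------
    X : (n, 6) array
        Normalized six-feature cohort in canonical feature order.
    y : (n,) array
        Binary labels.
    params : mapping, optional
        Overrides for :data:`DEFAULT_BOOSTING_PARAMS`.
    importance_type : {"gain", "weight"}
        "gain" uses impurity-based importances; "weight" counts splits per
        feature across all trees.

    Returns
    -------
    dict mapping feature name to nonnegative weight, summing to 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != len(FEATURES):
        raise ValidationError(f"expected (n, {len(FEATURES)}) feature matrix")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("cohort must contain both classes")
    if counts.min() < MIN_ROWS_PER_CLASS:
        raise ValidationError(
            f"need >= {MIN_ROWS_PER_CLASS} rows per class, got {counts.min()}"
        )
    constant = X.std(axis=0) == 0.0
    if constant.any():
        names = [FEATURES[j] for j in np.flatnonzero(constant)]
        warnings.warn(
            f"degenerate constant feature(s) {names}: importance will be 0",
            UserWarning,
            stacklevel=2,
        )

    merged = dict(DEFAULT_BOOSTING_PARAMS)
    merged.update(params or {})
    # Canonical row ordering makes the subsampled fit (and hence the
    # importances) invariant to how the caller happened to order the cohort.
    order = np.lexsort((y,) + tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)))
    model = GradientBoostingClassifier(random_state=seed, **merged)
    model.fit(X[order], y[order])

    if importance_type == "gain":
        raw = model.feature_importances_
    elif importance_type == "weight":
        raw = _split_counts(model, X.shape[1])
    else:
        raise ConfigurationError(
            f"unsupported importance_type {importance_type!r}; use 'gain' or 'weight'"
        )
    total = raw.sum()
    if total <= 0:
        raise ValidationError("model produced no splits; cannot derive importances")
    weights = raw / total
    return {name: float(w) for name, w in zip(FEATURES, weights)}


def _split_counts(model: GradientBoostingClassifier, n_features: int) -> np.ndarray:
    counts = np.zeros(n_features)
    for stage in model.estimators_:
        for tree in stage:
            feats = tree.tree_.feature
            for f in feats[feats >= 0]:
                counts[f] += 1
    return counts


def misclassification_count(scores: np.ndarray, labels: np.ndarray, cut: float) -> int:
    """Errors under the strict rule: glaucoma iff score > cut."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    predicted = (scores > cut).astype(int)
    return int((predicted != labels).sum())


def derive_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Optimal classification cut-point from a labeled score sample.

    Candidate cuts are the midpoints between consecutive sorted unique
    scores; the cut minimizing misclassification count (strict-inequality
    rule) is returned.  When several adjacent candidates tie, the midpoint
    of the widest optimal band in score space is returned (first such band
    on further ties).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    unique = np.unique(scores)
    if len(unique) < 2:
        raise ValidationError("all scores identical; threshold undefined")

    # Cumulative class counts at each unique score (inclusive).
    n1_at = np.array([(labels[scores == u] == 1).sum() for u in unique])
    n0_at = np.array([(labels[scores == u] == 0).sum() for u in unique])
    c1 = np.cumsum(n1_at)
    c0 = np.cumsum(n0_at)
    total0 = c0[-1]
    # Cut in gap i (between unique[i] and unique[i+1]): scores <= unique[i]
    # are predicted normal.
    errors = c1[:-1] + (total0 - c0[:-1])
    best = errors.min()
    optimal = np.flatnonzero(errors == best)

    # Merge adjacent optimal gaps into bands; a band over gaps i..j spans
    # (unique[i], unique[j+1]) in score space.
    bands: list[tuple[float, float]] = []
    start = optimal[0]
    prev = optimal[0]
    for i in optimal[1:]:
        if i == prev + 1:
            prev = i
            continue
        bands.append((unique[start], unique[prev + 1]))
        start = prev = i
    bands.append((unique[start], unique[prev + 1]))
    lo, hi = max(bands, key=lambda b: b[1] - b[0])
    return float((lo + hi) / 2.0)


def sweep_ratio(
    cohort,
    reference: ReferenceDataset,
    candidate_ratios: Sequence[float],
    spec: NormalizationSpec,
    model: IndexModel,
    leave_one_out: bool = True,
) -> dict:
    """Misclassification report over candidate base:NNI mixing ratios.

    For each candidate base ratio, the cohort is scored, an optimal
    threshold is derived, and the resulting misclassification rate is
    recorded.  Returns ``{"table": [...], "best_ratio": float}`` with one
    table row per candidate.
    """
    ratios = list(candidate_ratios)
    if not ratios or any(not (0.0 < r <= 1.0) for r in ratios):
        raise ConfigurationError("candidate ratios must lie in (0, 1]")
    labels = np.array([r.label for r in cohort], dtype=float)
    if np.isnan(labels).any():
        raise ValidationError("all cohort records must be labeled")
    labels = labels.astype(int)

    _, base, nni = score_cohort(
        cohort, spec, reference, model, leave_one_out=leave_one_out
    )
    table = []
    for ratio in ratios:
        igri = ratio * base + (1.0 - ratio) * nni
        cut = derive_threshold(igri, labels)
        err = misclassification_count(igri, labels, cut) / len(labels)
        table.append(
            {"base_ratio": ratio, "threshold": cut, "misclassification": err}
        )
    best = min(table, key=lambda row: row["misclassification"])
    return {"table": table, "best_ratio": best["base_ratio"]}


def calibrate_model(
    cohort,
    spec: NormalizationSpec,
    base_model: IndexModel,
    seed: int = 0,
    params: Mapping | None = None,
) -> IndexModel:
    """End-to-end recalibration: importances, then threshold, on one cohort."""
    from dataclasses import replace

    from igri.synthetic_cohort import build_reference

    reference = build_reference(cohort, spec, provenance="user-supplied")
    weights = derive_importance(
        reference.matrix, reference.labels, params=params, seed=seed
    )
    model = replace(base_model, weights=weights)
    labels = reference.labels
    igri, _, _ = score_cohort(cohort, spec, reference, model, leave_one_out=True)
    threshold = derive_threshold(igri, labels)
    return replace(model, threshold=threshold)
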