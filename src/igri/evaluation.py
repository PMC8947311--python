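"""Evaluation surface: misclassification, group separation, NNI ablation,
MD correlation, and stage-wise summaries."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from igri.core_model import (
    ExamRecord,
    IndexModel,
    NormalizationSpec,
    ReferenceDataset,
    ValidationError,
)
from igri.calibration import derive_threshold, misclassification_count
from igri.index import score_cohort, stage_by_md

OVERLAP_BINS = 50


def misclassification_rate(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> float:
    """Fraction of rows whose strict-rule prediction differs from the label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if scores.size == 0:
        raise ValidationError("empty input")
    return misclassification_count(scores, labels, threshold) / scores.size


def group_summary(
    scores: np.ndarray,
    groups: Sequence,
    test_pairs: Sequence[tuple] = (),
) -> dict:
    """Per-group mean/SD/n plus Welch two-sample tests for requested pairs.

    Returns ``{"groups": {name: {mean, sd, n}}, "tests": [...]}``.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if scores.shape != groups.shape:
        raise ValidationError("scores and groups must have equal length")
    by_group: dict = {}
    for name in np.unique(groups):
        vals = scores[groups == name]
        key = name.item() if hasattr(name, "item") else name
        by_group[key] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
        }
    tests = []
    for a, b in test_pairs:
        if a not in by_group or b not in by_group:
            raise ValidationError(f"unknown group in test pair ({a!r}, {b!r})")
        xa = scores[groups == a]
        xb = scores[groups == b]
        if len(xa) < 2 or len(xb) < 2:
            raise ValidationError("need >= 2 rows per group for the test")
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        tests.append({"pair": (a, b), "statistic": float(stat), "p_value": float(p)})
    return {"groups": by_group, "tests": tests}


def overlap_coefficient(
    scores_a: np.ndarray, scores_b: np.ndarray, bins: int = OVERLAP_BINS
) -> float:
    """Histogram overlap of two score samples on fixed bins over [0, 1]."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    pa, _ = np.histogram(np.asarray(scores_a, float), bins=edges)
    pb, _ = np.histogram(np.asarray(scores_b, float), bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def ablation_nni(
    cohort: Sequence[ExamRecord],
    reference: ReferenceDataset,
    model: IndexModel,
    spec: NormalizationSpec,
    leave_one_out: bool = True,
) -> dict:
    """Paired comparison: full index (with NNI) vs base-only index.

    For each variant: per-row scores, optimal-threshold misclassification,
    and the between-class histogram overlap coefficient.
    """
    labels = np.array([r.label for r in cohort], dtype=int)
    igri, base, _ = score_cohort(
        cohort, spec, reference, model, leave_one_out=leave_one_out
    )

    def _variant(scores: np.ndarray) -> dict:
        cut = derive_threshold(scores, labels)
        return {
            "threshold": cut,
            "misclassification": misclassification_count(scores, labels, cut)
            / len(labels),
            "overlap": overlap_coefficient(scores[labels == 0], scores[labels == 1]),
        }

    with_nni = _variant(igri)
    base_only = _variant(base)
    return {
        "with_nni": with_nni,
        "base_only": base_only,
        "overlap_reduction": base_only["overlap"] - with_nni["overlap"],
    }


def md_correlation(
    records: Sequence[ExamRecord], scores: np.ndarray
) -> dict:
    """Pearson correlation between raw MD and the index over glaucoma rows.

    The correlation is negative by construction (lower MD means higher
    index); both the signed value and |r| are reported.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.array([r.label == 1 for r in records])
    md = np.array([r.md for r in records])[mask]
    sub = scores[mask]
    if len(sub) < 3:
        raise ValidationError("need >= 3 glaucoma rows")
    if np.std(md) == 0 or np.std(sub) == 0:
        raise ValidationError("correlation undefined for constant input")
    r, p = stats.pearsonr(md, sub)
    return {"r": float(r), "abs_r": float(abs(r)), "p_value": float(p), "n": int(len(sub))}


def stage_summary(
    records: Sequence[ExamRecord],
    scores: np.ndarray,
    model: IndexModel,
) -> dict:
    """Mean index per MD-derived stage (normal label kept as its own group)."""
    scores = np.asarray(scores, dtype=float)
    stages = [
        "normal" if r.label == 0 else stage_by_md(r.md, model.staging_bins)
        for r in records
    ]
    return group_summary(scores, stages)


def evaluate_cohort(
    cohort: Sequence[ExamRecord],
    reference: ReferenceDataset,
    model: IndexModel,
    spec: NormalizationSpec,
    leave_one_out: bool = True,
) -> dict:
    """Full numeric report over one labeled cohort (in-sample if the cohort
    is the reference population itself; flagged in the output)."""
    labels = np.array([r.label for r in cohort], dtype=int)
    igri, base, nni = score_cohort(
        cohort, spec, reference, model, leave_one_out=leave_one_out
    )
    group_names = np.where(labels == 1, "glaucoma", "normal")
    report = {
        "evaluation_mode": "in-sample" if leave_one_out else "held-out",
        "n": int(len(cohort)),
        "misclassification_rate": misclassification_rate(igri, labels, model.threshold),
        "threshold": model.threshold,
        "group_summary": group_summary(
            igri, group_names, test_pairs=[("glaucoma", "normal")]
        ),
        "ablation": ablation_nni(cohort, reference, model, spec, leave_one_out),
        "md_correlation": md_correlation(cohort, igri),
        "stage_summary": stage_summary(cohort, igri, model),
    }
    return report
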