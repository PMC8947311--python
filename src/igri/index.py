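"""Base and final index computation, classification, and staging.

The base index is the importance-weighted sum of the six normalized-reversed
features; the final index mixes base and NNI at the configured ratio
(0.8:0.2 by default).  Classification is strict: glaucoma iff the index
exceeds the threshold.  Staging within glaucoma uses raw MD bins.
"""

from __future__ import annotations

import numpy as np

from igri.core_model import (
    ConfigurationError,
    ExamRecord,
    IndexModel,
    NormalizationSpec,
    ReferenceDataset,
    ScoreResult,
    StagingBins,
)
from igri.nni import compute_nni
from igri.normalization import transform_record

_WEIGHT_TOL = 1e-6


def compute_base(vector: np.ndarray, weights: np.ndarray) -> float:
    """Dot product of the normalized-reversed vector with the importance weights."""
    vector = np.asarray(vector, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > _WEIGHT_TOL:
        raise ConfigurationError(f"weights must sum to 1, got {weights.sum()!r}")
    return float(vector @ weights)


def compute_igri(base: float, nni: float, model: IndexModel) -> float:
    """Convex combination ``base_ratio * base + nni_ratio * nni``."""
    if abs(model.base_ratio + model.nni_ratio - 1.0) > 1e-9:
        raise ConfigurationError("base_ratio + nni_ratio must equal 1")
    return model.base_ratio * base + model.nni_ratio * nni


def classify(igri: float, threshold: float) -> int:
    """1 (glaucoma) iff ``igri > threshold``, strict inequality."""
    return int(igri > threshold)


def stage_by_md(md: float, bins: StagingBins | None = None) -> str:
    """Stage a glaucoma-classified eye by its raw MD value.

    advanced if md < advanced_below; intermediate on
    [advanced_below, intermediate_upper]; early above.  The published bins
    leave a gap between early and intermediate, resolved here by assigning
    the gap to early (consistent with the monotone ordering of stage means).
    """
    bins = bins or StagingBins()
    if md < bins.advanced_below:
        return "advanced"
    if md <= bins.intermediate_upper:
        return "intermediate"
    return "early"


def score_cohort(
    records,
    spec: NormalizationSpec,
    reference: ReferenceDataset,
    model: IndexModel,
    leave_one_out: bool = False,
):
    """Vectorized pipeline over a cohort.

    With ``leave_one_out=True`` the records are assumed to be, in order, the
    rows of ``reference`` and each is scored against the others.

    Returns ``(igri, base, nni)`` arrays aligned with the records.
    """
    from igri.nni import nni_for_queries, nni_profile
    from igri.normalization import transform_matrix

    raw = np.array([r.as_vector() for r in records], dtype=float)
    vectors = transform_matrix(raw, spec)
    if leave_one_out:
        if len(records) != len(reference):
            raise ConfigurationError("leave-one-out requires cohort == reference rows")
        nni, _ = nni_profile(reference, k=model.k)
    else:
        nni = nni_for_queries(vectors, reference, k=model.k)
    base = vectors @ model.weight_vector()
    igri = model.base_ratio * base + model.nni_ratio * nni
    return igri, base, nni


def score_record(
    record: ExamRecord,
    spec: NormalizationSpec,
    reference: ReferenceDataset,
    model: IndexModel,
    exclude_row: int | None = None,
) -> ScoreResult:
    """Run the full pipeline for one record.

    transform -> NNI -> base -> final index, then classify and stage.
    ``exclude_row`` enables leave-one-out scoring of a row that is itself
    part of the reference.
    """
    vector = transform_record(record, spec)
    nni = compute_nni(vector, reference, k=model.k, exclude_row=exclude_row)
    base = compute_base(vector, model.weight_vector())
    igri = compute_igri(base, nni, model)
    predicted = classify(igri, model.threshold)
    stage = stage_by_md(record.md, model.staging_bins) if predicted == 1 else "normal"
    border = abs(igri - model.threshold) <= model.border_margin
    return ScoreResult(
        normalized_vector=vector,
        nni=nni,
        base=base,
        igri=igri,
        predicted_class=predicted,
        stage=stage,
        in_border_band=border,
    )
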