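"""Min-max normalization into the severity-aligned unit space.

Every raw feature is mapped onto [0, 1] with its published bounds, clipping
outside values, and the features whose clinical direction opposes severity
(MD and the three RNFL sectors by default) are flipped via ``1 - x`` so that
larger always means more severe.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from igri.core_model import (
    FEATURES,
    ConfigurationError,
    ExamRecord,
    NormalizationSpec,
)


def normalize_feature(value: float, bounds: tuple[float, float]) -> float:
    """Min-max normalize ``value`` onto [0, 1], saturating outside the bounds."""
    lo, hi = bounds
    if not (lo < hi):
        raise ConfigurationError(f"bounds must satisfy min < max, got ({lo}, {hi})")
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def reverse(value: float) -> float:
    """Flip a unit-interval value: ``1 - value``."""
    return 1.0 - value


def transform_record(record: ExamRecord, spec: NormalizationSpec) -> np.ndarray:
    """Normalize and reverse one record into the unit severity space.

    Returns the six-vector in canonical order (PSD, MD, RNFL_S, RNFL_I,
    RNFL_T, IOP), each coordinate in [0, 1], with exactly the features in
    ``spec.reversed_features`` flipped.
    """
    out = np.empty(len(FEATURES), dtype=float)
    for j, name in enumerate(FEATURES):
        v = normalize_feature(record.feature(name), spec.bounds[name])
        out[j] = reverse(v) if name in spec.reversed_features else v
    return out


def transform_matrix(raw: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Vectorized :func:`transform_record` over an (n, 6) raw matrix."""
    raw = np.asarray(raw, dtype=float)
    lo = np.array([spec.bounds[name][0] for name in FEATURES])
    hi = np.array([spec.bounds[name][1] for name in FEATURES])
    out = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    rev = np.array([name in spec.reversed_features for name in FEATURES])
    out[:, rev] = 1.0 - out[:, rev]
    return out


def fit_bounds(
    raw: np.ndarray, lower_pct: float = 0.5, upper_pct: float = 99.5
) -> dict[str, tuple[float, float]]:
    """Estimate normalization bounds from a cohort with a percentile outlier rule.

    Non-canonical helper: the shipped default uses the published bounds; this
    exists only for users recalibrating on their own data.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != len(FEATURES):
        raise ValueError(f"expected (n, {len(FEATURES)}) matrix")
    lo = np.percentile(raw, lower_pct, axis=0)
    hi = np.percentile(raw, upper_pct, axis=0)
    return {name: (float(lo[j]), float(hi[j])) for j, name in enumerate(FEATURES)}


def present_rounded(vector: Sequence[float], ndigits: int = 4) -> list[float]:
    """Presentation-style rounding (half away from zero) of a vector."""
    from igri.core_model import round_half_away

    return [round_half_away(float(v), ndigits) for v in vector]
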