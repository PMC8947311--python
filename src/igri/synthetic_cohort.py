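"""Synthetic two-class examination cohorts.

Stands in for the unavailable hospital dataset: per-class truncated
multivariate Gaussians over the six raw features whose class-conditional
means respect the clinical direction of effect (glaucoma: higher PSD, more
negative MD, thinner RNFL; IOP difference small by default, since many
cases are normal-tension glaucoma).

Default class-mean anchors follow the typical published examination rows;
the covariance structure is fabricated for testing (see
``_default_correlation``), not estimated from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from igri.core_model import (
    DEFAULT_BOUNDS,
    FEATURES,
    ExamRecord,
    NormalizationSpec,
    ReferenceDataset,
    ValidationError,
)
from igri.normalization import transform_matrix

#: Typical glaucoma / normal examination profiles used as default class means.
GLAUCOMA_MEAN: dict[str, float] = {
    "PSD": 9.54, "MD": -7.84, "RNFL_S": 56.0, "RNFL_I": 54.0,
    "RNFL_T": 48.0, "IOP": 11.0,
}
NORMAL_MEAN: dict[str, float] = {
    "PSD": 1.43, "MD": -1.49, "RNFL_S": 125.0, "RNFL_I": 140.0,
    "RNFL_T": 63.0, "IOP": 13.0,
}


def _default_sds() -> np.ndarray:
    # SD = 1/4 of each feature's normalization range.
    return np.array(
        [(DEFAULT_BOUNDS[f][1] - DEFAULT_BOUNDS[f][0]) / 4.0 for f in FEATURES]
    )


def _default_correlation() -> np.ndarray:
    # Severity couples the raw features: RNFL sectors thin together (0.5),
    # MD declines with RNFL thinning (0.6), PSD rises as MD declines (-0.5)
    # and as RNFL thins (-0.4); IOP uncorrelated.  Fabricated for testing,
    # not estimated from data; the matrix is positive definite.
    corr = np.eye(len(FEATURES))
    idx = {f: j for j, f in enumerate(FEATURES)}
    rnfl = ("RNFL_S", "RNFL_I", "RNFL_T")
    for a in rnfl:
        for b in rnfl:
            if a != b:
                corr[idx[a], idx[b]] = 0.5
    for r in rnfl:
        corr[idx["MD"], idx[r]] = corr[idx[r], idx["MD"]] = 0.6
        corr[idx["PSD"], idx[r]] = corr[idx[r], idx["PSD"]] = -0.4
    corr[idx["PSD"], idx["MD"]] = corr[idx["MD"], idx["PSD"]] = -0.5
    return corr


def _default_cov() -> np.ndarray:
    sds = _default_sds()
    return _default_correlation() * np.outer(sds, sds)


def _default_truncation(margin: float = 0.1) -> np.ndarray:
    # Normalization bounds extended by a margin, but never beyond physical
    # plausibility (so generated cohorts always pass validation on re-read).
    from igri.core_model import PLAUSIBLE_BOUNDS

    out = np.empty((len(FEATURES), 2))
    for j, f in enumerate(FEATURES):
        lo, hi = DEFAULT_BOUNDS[f]
        pad = margin * (hi - lo)
        plo, phi = PLAUSIBLE_BOUNDS[f]
        out[j] = (max(lo - pad, plo), min(hi + pad, phi))
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Generative configuration for a two-class synthetic cohort."""

    n_normal: int = 955
    n_glaucoma: int = 1349
    mean_normal: np.ndarray = field(
        default_factory=lambda: np.array([NORMAL_MEAN[f] for f in FEATURES])
    )
    mean_glaucoma: np.ndarray = field(
        default_factory=lambda: np.array([GLAUCOMA_MEAN[f] for f in FEATURES])
    )
    cov_normal: np.ndarray = field(default_factory=_default_cov)
    cov_glaucoma: np.ndarray = field(default_factory=_default_cov)
    truncation: np.ndarray = field(default_factory=_default_truncation)
    separation_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_glaucoma < 1:
            raise ValidationError("class counts must be >= 1")
        if self.separation_scale < 0:
            raise ValidationError("separation scale must be >= 0")
        for cov in (self.cov_normal, self.cov_glaucoma):
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValidationError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValidationError("covariance must be positive semidefinite")

    def class_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Class means after applying the separation scale about the pooled mean."""
        n = self.n_normal + self.n_glaucoma
        pooled = (
            self.n_normal * self.mean_normal + self.n_glaucoma * self.mean_glaucoma
        ) / n
        s = self.separation_scale
        return (
            pooled + s * (self.mean_normal - pooled),
            pooled + s * (self.mean_glaucoma - pooled),
        )


def _sample_truncated_mvn(
    rng: np.random.Generator,
    mean: np.ndarray,
    cov: np.ndarray,
    bounds: np.ndarray,
    n: int,
    max_rounds: int = 1000,
) -> np.ndarray:
    sds = np.sqrt(np.maximum(np.diag(cov), 1e-12))
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(mean < lo - 6 * sds) or np.any(mean > hi + 6 * sds):
        raise ValidationError("truncation bounds exclude the class mean by > 6 SD")
    out = np.empty((n, len(mean)))
    filled = 0
    for _ in range(max_rounds):
        draw = rng.multivariate_normal(mean, cov, size=max(n - filled, 16))
        ok = draw[((draw >= lo) & (draw <= hi)).all(axis=1)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == n:
            return out
    raise ValidationError("truncated sampling failed to converge; bounds too tight")


def generate_cohort(config: CohortConfig) -> list[ExamRecord]:
    """Draw a labeled synthetic cohort; same seed and config give identical output."""
    rng = np.random.default_rng(config.seed)
    mean_n, mean_g = config.class_means()
    normals = _sample_truncated_mvn(
        rng, mean_n, np.asarray(config.cov_normal, float), config.truncation,
        config.n_normal,
    )
    glaucomas = _sample_truncated_mvn(
        rng, mean_g, np.asarray(config.cov_glaucoma, float), config.truncation,
        config.n_glaucoma,
    )
    raw = np.vstack([normals, glaucomas])
    labels = np.concatenate(
        [np.zeros(config.n_normal, int), np.ones(config.n_glaucoma, int)]
    )
    perm = rng.permutation(len(raw))
    raw, labels = raw[perm], labels[perm]
    return [
        ExamRecord(*row, label=int(lab)) for row, lab in zip(raw.tolist(), labels)
    ]


def build_reference(
    cohort: list[ExamRecord],
    spec: NormalizationSpec,
    provenance: str = "synthetic",
) -> ReferenceDataset:
    """Transform a labeled cohort into an NNI reference dataset."""
    if not cohort:
        raise ValidationError("cohort is empty")
    if any(r.label is None for r in cohort):
        raise ValidationError("all cohort records must be labeled")
    raw = np.array([r.as_vector() for r in cohort])
    labels = np.array([r.label for r in cohort], dtype=int)
    return ReferenceDataset(
        matrix=transform_matrix(raw, spec), labels=labels, provenance=provenance
    )
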