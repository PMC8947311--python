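"""Domain types, validation, and shared configuration.

The six input features, in canonical order, are PSD and MD from the visual
field test, the three RNFL sector thicknesses from OCT, and IOP.  All
downstream code works on vectors in this fixed order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical feature order used by every vector-valued API.
FEATURES: tuple[str, ...] = ("PSD", "MD", "RNFL_S", "RNFL_I", "RNFL_T", "IOP")

#: Published min-max normalization bounds per feature.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "PSD": (0.95, 16.9),
    "MD": (-24.1, 6.39),
    "RNFL_S": (6.0, 172.0),
    "RNFL_I": (0.0, 195.0),
    "RNFL_T": (20.0, 110.0),
    "IOP": (5.0, 29.0),
}

#: Features whose normalized value is flipped (1 - x) so that higher always
#: means more severe.  MD is more negative with worse field loss and the
#: RNFL sectors thin with damage; PSD and IOP already point toward severity.
DEFAULT_REVERSED: frozenset[str] = frozenset({"MD", "RNFL_S", "RNFL_I", "RNFL_T"})

#: Published per-feature importance weights (sum to 1).
DEFAULT_WEIGHTS: dict[str, float] = {
    "PSD": 0.27,
    "MD": 0.14,
    "RNFL_S": 0.11,
    "RNFL_I": 0.31,
    "RNFL_T": 0.10,
    "IOP": 0.07,
}

# Plausibility bounds for validation only -- deliberately looser than the
# normalization bounds.  Validation warns outside the normalization range
# (values will be clipped during scoring) and errors outside these.
PLAUSIBLE_BOUNDS: dict[str, tuple[float, float]] = {
    "PSD": (0.0, 30.0),
    "MD": (-40.0, 10.0),
    "RNFL_S": (0.0, 300.0),
    "RNFL_I": (0.0, 300.0),
    "RNFL_T": (0.0, 300.0),
    "IOP": (1.0, 80.0),
}

STAGES = ("normal", "early", "intermediate", "advanced")


class ValidationError(ValueError):
    """Raised when an examination record or configuration is invalid."""


class ConfigurationError(ValueError):
    """Raised when model/normalization configuration violates an invariant."""


@dataclass(frozen=True)
class ExamRecord:
    """One eye's raw six-feature measurement vector.

    Parameters
    ----------
    psd, md : float
        Visual field pattern standard deviation and mean deviation, in dB.
    rnfl_s, rnfl_i, rnfl_t : float
        RNFL thickness in the superior, inferior, and temporal sectors (µm).
    iop : float
        Intraocular pressure (mmHg).
    label : int or None
        Optional binary class: 0 normal, 1 glaucoma.
    """

    psd: float
    md: float
    rnfl_s: float
    rnfl_i: float
    rnfl_t: float
    iop: float
    label: int | None = None

    _FIELD_BY_FEATURE = {
        "PSD": "psd",
        "MD": "md",
        "RNFL_S": "rnfl_s",
        "RNFL_I": "rnfl_i",
        "RNFL_T": "rnfl_t",
        "IOP": "iop",
    }

    def as_vector(self) -> np.ndarray:
        """Raw values in canonical feature order."""
        return np.array(
            [self.psd, self.md, self.rnfl_s, self.rnfl_i, self.rnfl_t, self.iop],
            dtype=float,
        )

    def feature(self, name: str) -> float:
        return getattr(self, self._FIELD_BY_FEATURE[name.upper()])

    def to_dict(self) -> dict:
        d = {name: self.feature(name) for name in FEATURES}
        if self.label is not None:
            d["label"] = self.label
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExamRecord":
        kwargs = {}
        lowered = {str(k).upper(): v for k, v in d.items()}
        for name in FEATURES:
            if name not in lowered:
                raise ValidationError(f"missing feature {name}")
            kwargs[cls._FIELD_BY_FEATURE[name]] = float(lowered[name])
        label = lowered.get("LABEL")
        if label is not None and not (isinstance(label, float) and math.isnan(label)):
            kwargs["label"] = int(label)
        return cls(**kwargs)


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-feature min/max bounds plus the set of reversed features."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    reversed_features: frozenset[str] = DEFAULT_REVERSED

    def __post_init__(self) -> None:
        for name in FEATURES:
            if name not in self.bounds:
                raise ConfigurationError(f"missing bounds for feature {name}")
            lo, hi = self.bounds[name]
            if not (lo < hi):
                raise ConfigurationError(
                    f"bounds for {name} must satisfy min < max, got ({lo}, {hi})"
                )
        unknown = set(self.reversed_features) - set(FEATURES)
        if unknown:
            raise ConfigurationError(f"unknown reversed features: {sorted(unknown)}")
        object.__setattr__(self, "reversed_features", frozenset(self.reversed_features))

    def to_dict(self) -> dict:
        return {
            "bounds": {k: list(self.bounds[k]) for k in FEATURES},
            "reversed_features": sorted(self.reversed_features),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationSpec":
        bounds = {k: (float(v[0]), float(v[1])) for k, v in d["bounds"].items()}
        return cls(
            bounds=bounds, reversed_features=frozenset(d.get("reversed_features", []))
        )


@dataclass(frozen=True)
class StagingBins:
    """MD boundaries separating the three glaucoma progression stages.

    ``advanced`` strictly below ``advanced_below``; ``intermediate`` on the
    closed interval up to ``intermediate_upper``; ``early`` above that.  The
    published intermediate range is -5.0 to -12.0 dB with advanced below -12.
    """

    advanced_below: float = -12.0
    intermediate_upper: float = -5.0

    def __post_init__(self) -> None:
        if not self.advanced_below < self.intermediate_upper:
            raise ConfigurationError("staging bins must be ordered")

    def to_dict(self) -> dict:
        return {
            "advanced_below": self.advanced_below,
            "intermediate_upper": self.intermediate_upper,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StagingBins":
        return cls(float(d["advanced_below"]), float(d["intermediate_upper"]))


@dataclass(frozen=True)
class IndexModel:
    """Weights, mixing ratio, threshold, staging bins, and neighbor count."""

    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    base_ratio: float = 0.8
    nni_ratio: float = 0.2
    threshold: float = 0.36
    staging_bins: StagingBins = field(default_factory=StagingBins)
    k: int = 5
    border_margin: float = 0.05

    def __post_init__(self) -> None:
        for name in FEATURES:
            if name not in self.weights:
                raise ConfigurationError(f"missing weight for feature {name}")
            if self.weights[name] < 0:
                raise ConfigurationError(f"negative weight for feature {name}")
        total = sum(self.weights[name] for name in FEATURES)
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"weights must sum to 1, got {total!r}")
        if abs(self.base_ratio + self.nni_ratio - 1.0) > 1e-9:
            raise ConfigurationError("base_ratio + nni_ratio must equal 1")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must lie strictly in (0, 1)")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[name] for name in FEATURES], dtype=float)

    def to_dict(self) -> dict:
        return {
            "weights": {k: self.weights[k] for k in FEATURES},
            "base_ratio": self.base_ratio,
            "nni_ratio": self.nni_ratio,
            "threshold": self.threshold,
            "staging_bins": self.staging_bins.to_dict(),
            "k": self.k,
            "border_margin": self.border_margin,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IndexModel":
        kwargs: dict = {"weights": {k: float(v) for k, v in d["weights"].items()}}
        for key in ("base_ratio", "nni_ratio", "threshold", "border_margin"):
            if key in d:
                kwargs[key] = float(d[key])
        if "k" in d:
            kwargs["k"] = int(d["k"])
        if "staging_bins" in d:
            kwargs["staging_bins"] = StagingBins.from_dict(d["staging_bins"])
        return cls(**kwargs)

    def with_ratio(self, base_ratio: float) -> "IndexModel":
        return replace(self, base_ratio=base_ratio, nni_ratio=1.0 - base_ratio)


@dataclass(frozen=True)
class ReferenceDataset:
    """Normalized-and-reversed feature matrix with binary labels.

    This is the lookup population for the nearest-neighbor index.  Rows are
    treated as independent observations.
    """

    matrix: np.ndarray
    labels: np.ndarray
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if matrix.ndim != 2 or matrix.shape[1] != len(FEATURES):
            raise ValidationError(
                f"reference matrix must be (n, {len(FEATURES)}), got {matrix.shape}"
            )
        if labels.shape != (matrix.shape[0],):
            raise ValidationError("labels must align with reference rows")
        if matrix.size and (matrix.min() < 0.0 or matrix.max() > 1.0):
            raise ValidationError("reference entries must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be binary (0/1)")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def require_valid_for_k(self, k: int) -> None:
        if len(self) < k + 1:
            raise ValidationError(
                f"reference needs at least k+1 = {k + 1} rows, has {len(self)}"
            )
        if len(set(self.labels.tolist())) < 2:
            raise ValidationError("reference must contain both classes")


@dataclass(frozen=True)
class ScoreResult:
    """Full scoring output for one examination record."""

    normalized_vector: np.ndarray
    nni: float
    base: float
    igri: float
    predicted_class: int
    stage: str | None = None
    in_border_band: bool = False

    def to_dict(self) -> dict:
        d = {f"{name}_norm": float(v) for name, v in zip(FEATURES, self.normalized_vector)}
        d.update(
            nni=self.nni,
            base=self.base,
            igri=self.igri,
            predicted_class=self.predicted_class,
            stage=self.stage,
            in_border_band=self.in_border_band,
        )
        return d


def default_normalization_spec() -> NormalizationSpec:
    """The published normalization bounds with the default reversal set."""
    return NormalizationSpec()


def default_index_model() -> IndexModel:
    """The published weights, 0.8:0.2 mixing ratio, and 0.36 threshold."""
    return IndexModel()


def validate_record(record: ExamRecord, spec: NormalizationSpec | None = None) -> ExamRecord:
    """Validate an examination record.

    All six features must be finite and within broad plausibility bounds.
    Values outside the normalization bounds are flagged with a warning only
    (they will saturate at 0 or 1 during normalization); validation never
    alters the data.

    Raises
    ------
    ValidationError
        If a feature is missing (NaN), non-finite, or physically implausible.
    """
    spec = spec or default_normalization_spec()
    for name in FEATURES:
        value = record.feature(name)
        if not isinstance(value, (int, float, np.floating, np.integer)):
            raise ValidationError(f"feature {name} is not numeric: {value!r}")
        if math.isnan(value):
            raise ValidationError(f"feature {name} is missing (NaN)")
        if not math.isfinite(value):
            raise ValidationError(f"feature {name} is not finite: {value!r}")
        lo, hi = PLAUSIBLE_BOUNDS[name]
        if not (lo <= value <= hi):
            raise ValidationError(
                f"feature {name}={value} outside plausible range [{lo}, {hi}]"
            )
        nlo, nhi = spec.bounds[name]
        if not (nlo <= value <= nhi):
            warnings.warn(
                f"feature {name}={value} outside normalization range "
                f"[{nlo}, {nhi}]; it will be clipped",
                UserWarning,
                stacklevel=2,
            )
    if record.label is not None and record.label not in (0, 1):
        raise ValidationError(f"label must be 0 or 1, got {record.label!r}")
    return record


def records_to_frame(records: Iterable[ExamRecord]):
    """Stack records into raw matrix + labels (None where unlabeled)."""
    records = list(records)
    matrix = np.array([r.as_vector() for r in records], dtype=float)
    labels = [r.label for r in records]
    return matrix, labels


def round_half_away(value: float, ndigits: int) -> float:
    """Decimal rounding with ties away from zero, matching printed tables."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def stack_records(records: Sequence[ExamRecord]) -> np.ndarray:
    return np.array([r.as_vector() for r in records], dtype=float)
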