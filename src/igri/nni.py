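"""Nearest-neighbor index (NNI): the synthesized seventh feature.

For a query vector in the normalized-reversed unit space, the NNI is the
fraction of glaucoma-labeled rows among its k nearest reference rows
(k = 5 by default).  Distances are computed in that space, where all six
coordinates are commensurate.

Tie handling is deterministic and independent of reference row order:
candidates are ranked by (distance, canonical row key), where the canonical
key is the lexicographic feature vector followed by the label.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from igri.core_model import ReferenceDataset, ValidationError

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def _canonical_rank(reference: ReferenceDataset) -> np.ndarray:
    """Rank of each row under the canonical (features, label) ordering."""
    keys = [reference.labels] + [
        reference.matrix[:, j] for j in range(reference.matrix.shape[1] - 1, -1, -1)
    ]
    order = np.lexsort(keys)
    rank = np.empty(len(reference), dtype=np.intp)
    rank[order] = np.arange(len(reference))
    return rank


def _check_metric(metric: str) -> str:
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unsupported metric {metric!r}; use 'euclidean' or 'manhattan'")


def compute_nni(
    query: np.ndarray,
    reference: ReferenceDataset,
    k: int = 5,
    exclude_row: int | None = None,
    metric: str = "euclidean",
) -> float:
    """Class fraction of glaucoma labels among the k nearest reference rows.

    Parameters
    ----------
    query : array-like of shape (6,)
        Point in the normalized-reversed unit space.
    reference : ReferenceDataset
        Labeled lookup population.
    k : int
        Neighbor count; must not exceed the usable reference size.
    exclude_row : int, optional
        Index of the query's own row within the reference, excluded before
        the neighbor search (leave-one-out).  New patients omit this.
    metric : {"euclidean", "manhattan"}

    Returns
    -------
    float
        A value in {0, 1/k, ..., 1}.
    """
    scipy_metric = _check_metric(metric)
    if len(reference) == 0:
        raise ValidationError("reference dataset is empty")
    query = np.asarray(query, dtype=float).reshape(1, -1)
    if query.shape[1] != reference.matrix.shape[1]:
        raise ValidationError("query dimensionality does not match reference")

    mask = np.ones(len(reference), dtype=bool)
    if exclude_row is not None:
        mask[exclude_row] = False
    if mask.sum() < k:
        raise ValidationError(
            f"reference has {int(mask.sum())} usable rows, fewer than k={k}"
        )

    dist = cdist(query, reference.matrix[mask], metric=scipy_metric)[0]
    rank = _canonical_rank(reference)[mask]
    order = np.lexsort((rank, dist))
    neighbors = order[:k]
    return float(reference.labels[mask][neighbors].sum()) / k


def nni_profile(
    reference: ReferenceDataset, k: int = 5, metric: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-self-out NNI for every reference row.

    Returns ``(nni_values, labels)`` aligned with the reference rows,
    suitable for boxplot-style group comparison.
    """
    scipy_metric = _check_metric(metric)
    reference.require_valid_for_k(k)
    n = len(reference)
    dist = cdist(reference.matrix, reference.matrix, metric=scipy_metric)
    # Exclude self-matches by pushing them past any real distance.
    np.fill_diagonal(dist, np.inf)
    rank = _canonical_rank(reference)
    rank2d = np.broadcast_to(rank, (n, n))
    order = np.lexsort((rank2d, dist), axis=-1)
    neighbor_labels = reference.labels[order[:, :k]]
    return neighbor_labels.sum(axis=1).astype(float) / k, reference.labels.copy()


def nni_for_queries(
    queries: np.ndarray,
    reference: ReferenceDataset,
    k: int = 5,
    metric: str = "euclidean",
) -> np.ndarray:
    """Vectorized :func:`compute_nni` for a batch of out-of-reference queries."""
    scipy_metric = _check_metric(metric)
    if len(reference) < k:
        raise ValidationError(f"reference has {len(reference)} rows, fewer than k={k}")
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    dist = cdist(queries, reference.matrix, metric=scipy_metric)
    rank = _canonical_rank(reference)
    rank2d = np.broadcast_to(rank, dist.shape)
    order = np.lexsort((rank2d, dist), axis=-1)
    neighbor_labels = reference.labels[order[:, :k]]
    return neighbor_labels.sum(axis=1).astype(float) / k
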