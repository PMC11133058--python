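"""Cosine geometry primitives.

Everything downstream — clustering, close-space construction, lure
selection, output distances — measures proximity as cosine distance
(1 minus the cosine of the angle between two vectors).  This module owns
the scalar primitives plus full neighbor rankings of a space against a
reference vector.

Rankings are fully deterministic: distances are computed in double
precision, compared exactly, and ties broken by lexicographic label order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .space import VectorSpace

__all__ = [
    "cosine_similarity",
    "cosine_distance",
    "centroid",
    "rank_neighbors",
    "NeighborRanking",
]


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValidationError(f"cosine undefined for zero-norm {name}")
    return v / n


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between ``u`` and ``v``; in [-1, 1].

    Symmetric and invariant to positive rescaling of either argument.
    Raises :class:`~fmg.errors.ValidationError` on a zero-norm input.
    """
    uu, vv = _unit(u), _unit(v)
    if uu.shape != vv.shape:
        raise ValidationError(
            f"dimension mismatch: {uu.shape[0]} vs {vv.shape[0]}"
        )
    return float(np.clip(uu @ vv, -1.0, 1.0))


def cosine_distance(u, v) -> float:
    """1 - cosine_similarity(u, v); in [0, 2]."""
    return 1.0 - cosine_similarity(u, v)


def centroid(vectors) -> np.ndarray:
    """Arithmetic per-dimension mean of a nonempty collection of vectors."""
    arr = np.asarray(vectors, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.size == 0:
        raise ValidationError("centroid of an empty collection is undefined")
    return arr.mean(axis=0)


@dataclass(frozen=True)
class NeighborRanking:
    """All eligible items of a space ranked by cosine distance to a reference.

    ``labels[i]`` is the item at rank ``i + 1``; ``distances`` is
    non-decreasing; equal distances are ordered lexicographically by label.
    """

    reference: np.ndarray
    labels: np.ndarray  # object array of str, ascending distance
    distances: np.ndarray

    @property
    def entries(self) -> list[tuple[str, float]]:
        return list(zip(self.labels.tolist(), self.distances.tolist()))

    def __len__(self) -> int:
        return len(self.labels)

    def rank_of(self, label: str) -> int:
        """1-based rank of ``label``; raises ``KeyError`` if not ranked."""
        hits = np.nonzero(self.labels == label)[0]
        if len(hits) == 0:
            raise KeyError(label)
        return int(hits[0]) + 1


def _distances_to(space: VectorSpace, reference: np.ndarray) -> np.ndarray:
    """Cosine distance of every space item to ``reference`` (vectorized)."""
    ref = _unit(reference, "reference")
    sims = space.unit_vectors @ ref
    return 1.0 - np.clip(sims, -1.0, 1.0)


def _ranked_indices(
    space: VectorSpace, reference: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of masked-in items sorted by (distance, label).

    Internal fast path shared by rank_neighbors and the generation loop.
    Returns (indices, distances) aligned arrays.
    """
    dists = _distances_to(space, reference)
    idx = np.flatnonzero(mask)
    # lexsort: last key is primary
    order = idx[np.lexsort((space.labels_array[idx], dists[idx]))]
    return order, dists[order]


def rank_neighbors(
    space: VectorSpace, reference, excluded=()
) -> NeighborRanking:
    """Rank every non-excluded item by ascending cosine distance to reference.

    Parameters
    ----------
    space
        The item universe.
    reference
        Nonzero vector of the space's dimensionality.
    excluded
        Labels to omit from the ranking (must all belong to the space).
    """
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != (space.dim,):
        raise ValidationError(
            f"reference has dimension {reference.shape}, space has {space.dim}"
        )
    excluded = set(excluded)
    unknown = excluded - set(space.labels)
    if unknown:
        raise ValidationError(f"excluded labels not in space: {sorted(unknown)!r}")
    mask = np.ones(len(space), dtype=bool)
    for l in excluded:
        mask[space.index(l)] = False
    if not mask.any():
        raise ValidationError("all items excluded: empty ranking")
    order, dists = _ranked_indices(space, reference, mask)
    return NeighborRanking(
        reference=reference,
        labels=space.labels_array[order],
        distances=dists,
    )
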