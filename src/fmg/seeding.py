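"""List seeding by k-means partition of the vector space.

One stimulus list is grown per seed item, so seeds must come from mutually
dissimilar regions of the space.  The space is partitioned with k-means
(k drawn uniformly from {n_lists, ..., n_lists + 3} to vary item selection
across runs), the first ``n_lists`` cluster centroids in the clustering's
output order are retained, and each retained centroid is mapped to its
nearest item by cosine distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import InfeasibleError
from .geometry import _ranked_indices
from .space import VectorSpace

__all__ = ["ListSeedSet", "find_list_seeds"]


@dataclass(frozen=True)
class ListSeedSet:
    """Seed items for the lists: (label, cluster-center vector) pairs.

    ``centers`` are the retained k-means centroids (in the original vector
    dimensionality); each label is the space item nearest its center.
    """

    labels: list[str]
    centers: np.ndarray  # (n_lists, dim)
    k_used: int

    def __len__(self) -> int:
        return len(self.labels)


def find_list_seeds(
    space: VectorSpace, n_lists: int, rng: np.random.Generator
) -> ListSeedSet:
    """Pick one seed item per requested list from distinct space regions.

    k-means runs on unit-normalized vectors (Euclidean on the unit sphere
    orders pairs identically to cosine distance) with k-means++ init, 10
    restarts and a 300-iteration cap.  If two retained centroids map to
    the same nearest item, the later one takes its next-nearest item so
    seeds stay distinct.
    """
    if n_lists < 1:
        raise InfeasibleError("n_lists must be >= 1")
    if len(space) < n_lists:
        raise InfeasibleError(
            f"space has {len(space)} items but {n_lists} lists were requested"
        )
    k_hi = min(n_lists + 3, len(space))
    k = int(rng.integers(n_lists, k_hi + 1))
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=300,
        random_state=int(rng.integers(2**31)),
    )
    km.fit(space.unit_vectors)
    centers = km.cluster_centers_[:n_lists]

    labels: list[str] = []
    taken: set[int] = set()
    all_mask = np.ones(len(space), dtype=bool)
    for center in centers:
        order, _ = _ranked_indices(space, center, all_mask)
        for idx in order:
            if int(idx) not in taken:
                taken.add(int(idx))
                labels.append(space.labels[int(idx)])
                break
    return ListSeedSet(labels=labels, centers=np.array(centers), k_used=k)
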