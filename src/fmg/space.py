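"""Vector-space containers and I/O.

A vector space is the universe of candidate stimulus items: one label per
item (a word, lemma, or any non-whitespace identifier) paired with a
fixed-dimension real vector.  Files follow the word2vec / GloVe text
dialects: one item per line, label first, values space-separated, with an
optional leading ``count dim`` header (word2vec).  The loader autodetects
the header so both dialects work without a flag, and the writer mirrors
whichever dialect was read.

:func:`make_synthetic_space` builds clustered unit-vector spaces emulating
the neighborhood structure of a distributional semantic model, with ground
truth attached, for testing and demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "VectorSpace",
    "SyntheticSpace",
    "load_vector_space",
    "save_vector_space",
    "make_synthetic_space",
]


@dataclass
class VectorSpace:
    """Labeled collection of fixed-dimension vectors.

    Parameters
    ----------
    labels
        Ordered unique item identifiers.  Order is significant and stable
        (file order for loaded spaces).
    vectors
        Matrix with one row per label, ``float64``, dimensionality >= 2.
    header
        Whether the source file carried a word2vec ``count dim`` header;
        the writer mirrors it.
    """

    labels: list[str]
    vectors: np.ndarray
    header: bool = False

    _index: dict[str, int] = field(init=False, repr=False)
    _labels_arr: np.ndarray = field(init=False, repr=False)
    _units: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if len(self.labels) == 0:
            raise ValidationError("vector space is empty")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.labels):
            raise ValidationError(
                f"vector matrix shape {self.vectors.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if self.vectors.shape[1] < 2:
            raise ValidationError("vector dimensionality must be >= 2")
        for l in self.labels:
            if not l or any(c.isspace() for c in l):
                raise ValidationError(f"label {l!r} is empty or contains whitespace")
        if not np.all(np.isfinite(self.vectors)):
            bad = self.labels[int(np.argwhere(~np.isfinite(self.vectors))[0, 0])]
            raise ValidationError(f"non-finite value in vector for item {bad!r}")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0.0):
            bad = self.labels[int(np.argmin(norms))]
            raise ValidationError(f"zero-norm vector for item {bad!r}")
        self._index = {}
        for i, l in enumerate(self.labels):
            if l in self._index:
                raise ValidationError(f"duplicate label {l!r}")
            self._index[l] = i
        self._labels_arr = np.array(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def labels_array(self) -> np.ndarray:
        return self._labels_arr

    @property
    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy of the matrix (cached)."""
        if self._units is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            self._units = self.vectors / norms
        return self._units

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown item {label!r}") from None

    def vector(self, label: str) -> np.ndarray:
        return self.vectors[self.index(label)]

    def __contains__(self, label: str) -> bool:
        return label in self._index


def _is_header(tokens: list[str]) -> bool:
    # word2vec text header: exactly two integer tokens (count, dim)
    if len(tokens) != 2:
        return False
    try:
        int(tokens[0]), int(tokens[1])
    except ValueError:
        return False
    return True


def load_vector_space(path) -> VectorSpace:
    """Read a word2vec/GloVe text embedding file.

    A first line with exactly two integer tokens is treated as the
    word2vec ``count dim`` header and skipped.  Any run of spaces or tabs
    separates tokens.  Raises :class:`FormatError` for ragged rows or
    undecodable bytes and :class:`ValidationError` for duplicate labels or
    zero-norm vectors, naming the offending line or item.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(
            f"{path}: not valid UTF-8 at byte offset {exc.start}"
        ) from exc

    labels: list[str] = []
    rows: list[np.ndarray] = []
    dim: int | None = None
    header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if lineno == 1 and _is_header(tokens):
            header = True
            continue
        label, values = tokens[0], tokens[1:]
        if not values:
            raise FormatError(f"{path}, line {lineno}: no vector values")
        if dim is None:
            dim = len(values)
        elif len(values) != dim:
            raise FormatError(
                f"{path}, line {lineno}: expected {dim} values, got {len(values)}"
            )
        try:
            rows.append(np.array(values, dtype=np.float64))
        except ValueError:
            raise FormatError(
                f"{path}, line {lineno}: non-numeric vector value"
            ) from None
        labels.append(label)
    if not labels:
        raise FormatError(f"{path}: no data lines")
    return VectorSpace(labels=labels, vectors=np.vstack(rows), header=header)


def save_vector_space(space: VectorSpace, path) -> None:
    """Write a space back to text, mirroring the input dialect.

    Values are printed with six decimal places, so a load/save round trip
    reproduces labels exactly and values to within 5e-7.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if space.header:
            fh.write(f"{len(space)} {space.dim}\n")
        for label, row in zip(space.labels, space.vectors):
            fh.write(label + " " + " ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class SyntheticSpace:
    """A generated clustered space with its ground truth.

    ``assignments`` maps each label to its generating cluster index and
    ``directions`` holds the unit-length cluster center directions.
    """

    space: VectorSpace
    assignments: dict[str, int]
    directions: np.ndarray

    def __iter__(self):  # allow  space, truth, dirs = make_synthetic_space(...)
        return iter((self.space, self.assignments, self.directions))


def make_synthetic_space(
    n_clusters: int = 12,
    items_per_cluster: int = 500,
    dim: int = 50,
    within_spread: float = 0.15,
    seed: int = 0,
) -> SyntheticSpace:
    """Generate a clustered space of unit vectors with known ground truth.

    Each cluster gets a random unit direction; each item is that direction
    plus isotropic Gaussian noise of scale ``within_spread``, renormalized
    to unit length.  ``within_spread = 0`` collapses every cluster to a
    single repeated vector.  Labels encode the generating cluster
    (``c<cluster>_i<item>``).  Deterministic per seed.
    """
    if n_clusters < 1 or items_per_cluster < 1:
        raise ValidationError("n_clusters and items_per_cluster must be >= 1")
    if dim < 2:
        raise ValidationError("dim must be >= 2")
    if within_spread < 0:
        raise ValidationError("within_spread must be non-negative")
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((n_clusters, dim))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    labels: list[str] = []
    vectors = np.empty((n_clusters * items_per_cluster, dim))
    assignments: dict[str, int] = {}
    row = 0
    for c in range(n_clusters):
        noise = rng.standard_normal((items_per_cluster, dim)) * within_spread
        pts = directions[c] + noise
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        for i in range(items_per_cluster):
            label = f"c{c:02d}_i{i:04d}"
            labels.append(label)
            assignments[label] = c
            vectors[row] = pts[i]
            row += 1
    return SyntheticSpace(
        space=VectorSpace(labels=labels, vectors=vectors),
        assignments=assignments,
        directions=directions,
    )
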