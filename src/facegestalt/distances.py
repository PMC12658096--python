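"""Ensemble-averaged cosine distance between images and cohort statistics.

Image-to-image similarity is the mean of the m member-wise cosine distances
(member k of image A against member k of image B — matched-member pairing,
giving exactly m = 12 distances per image pair for the conventional
ensemble).  Lower values indicate greater resemblance; for unit vectors the
distance is ``1 - dot`` and lies in [0, 2].

The cohort-level statistic is the arithmetic mean of all n(n-1)/2 pairwise
image distances among cohort members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .gallery import Cohort, Gallery, GalleryError, ImageEncoding

__all__ = [
    "cosine_distance",
    "image_distance",
    "pairwise_distance_matrix",
    "cohort_mean_pairwise_distance",
    "DistanceMatrix",
]

_RANGE_TOL = 1e-9


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - dot(u, v)`` for unit vectors; 0 identical, 1 orthogonal, 2 antipodal."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise GalleryError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(1.0 - u @ v)


def image_distance(a: ImageEncoding, b: ImageEncoding) -> float:
    """Mean of the m matched-member cosine distances between two images.

    For unit vectors ``1 - dot(u, v) == ||u - v||^2 / 2``; the squared-norm
    form is used because it is exactly 0 when matched members coincide,
    which keeps the zero-noise limit exact.
    """
    if a.vectors.shape != b.vectors.shape:
        raise GalleryError(
            f"ensemble mismatch: {a.vectors.shape} vs {b.vectors.shape}"
        )
    diff = a.vectors - b.vectors
    return float(np.mean(np.einsum("kd,kd->k", diff, diff)) / 2.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of ensemble-averaged cosine distances.

    ``values[i, j]`` is the distance between ``ids[i]`` and ``ids[j]``;
    exactly symmetric, zero diagonal, entries in [0, 2].
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if v.shape != (n, n):
            raise GalleryError(f"matrix shape {v.shape} does not match {n} ids")
        if n and not np.array_equal(v, v.T):
            raise GalleryError("distance matrix is not symmetric")
        if n and np.any(np.diag(v) != 0.0):
            raise GalleryError("distance matrix diagonal is not zero")
        if n and (v.min() < -_RANGE_TOL or v.max() > 2.0 + _RANGE_TOL):
            raise GalleryError("distance entries outside [0, 2]")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "_index", {image_id: i for i, image_id in enumerate(self.ids)}
        )

    def indices_of(self, members: Sequence[str]) -> np.ndarray:
        idx = self.__dict__["_index"]
        missing = [x for x in members if x not in idx]
        if missing:
            raise GalleryError(f"id(s) not in distance matrix: {missing}")
        return np.fromiter((idx[x] for x in members), dtype=np.intp, count=len(members))

    def to_csv(self, path: str | Path) -> None:
        """Square labelled CSV; floats in shortest round-trip form."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("," + ",".join(self.ids) + "\n")
            for image_id, row in zip(self.ids, self.values):
                fh.write(image_id + "," + ",".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        values = frame.to_numpy(dtype=np.float64)
        # Symmetrize away the read round-trip's last-bit asymmetry, if any.
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(tuple(str(x) for x in frame.index), values)


def pairwise_distance_matrix(images: Sequence[ImageEncoding] | Gallery) -> DistanceMatrix:
    """Distance matrix over all unordered image pairs, input order preserved.

    Computed member-wise as halved squared Euclidean distances (equal to
    ``1 - dot`` for unit vectors but exactly 0 at coincidence), averaged over
    the m members, then symmetrized exactly and clipped to [0, 2] against
    last-bit floating-point excursions.
    """
    encodings = images.encodings if isinstance(images, Gallery) else list(images)
    if not encodings:
        raise GalleryError("need at least one image")
    ids = tuple(enc.image_id for enc in encodings)
    if len(set(ids)) != len(ids):
        raise GalleryError("duplicate image ids in distance-matrix input")
    shapes = {enc.vectors.shape for enc in encodings}
    if len(shapes) > 1:
        raise GalleryError(f"non-uniform ensemble shapes: {sorted(shapes)}")
    stack = np.stack([enc.vectors for enc in encodings])  # (n, m, d)
    n, m, _ = stack.shape
    dist = np.zeros((n, n))
    for k in range(m):
        vk = np.ascontiguousarray(stack[:, k, :])
        dist += cdist(vk, vk, "sqeuclidean")
    dist /= 2.0 * m
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, 2.0, out=dist)
    return DistanceMatrix(ids, dist)


def cohort_mean_pairwise_distance(cohort: Cohort, dmatrix: DistanceMatrix) -> float:
    """Mean of the n(n-1)/2 pairwise distances among cohort members.

    Invariant to member order and to images outside the cohort.
    """
    if cohort.n < 2:
        raise GalleryError("cohort mean pairwise distance needs n >= 2")
    idx = dmatrix.indices_of(cohort.members)
    return mean_pairwise_from_indices(dmatrix.values, idx)


def mean_pairwise_from_indices(values: np.ndarray, idx: np.ndarray) -> float:
    """Mean pairwise distance for pre-resolved row/column indices (hot path).

    Indices are sorted first so the floating-point summation order — and
    hence the value — is exactly invariant to member order.
    """
    idx = np.sort(idx)
    sub = values[np.ix_(idx, idx)]
    n = len(idx)
    return float((sub.sum() / 2.0) / (n * (n - 1) / 2.0))
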