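"""Core data types and text I/O for face-embedding galleries.

A *gallery* is a collection of images, each represented by an ensemble of
``m`` embedding vectors of dimension ``d`` (model ensemble x test-time
augmentation; by convention m=12, d=512).  Every image carries a subject
label and exactly one syndrome label.  Vectors are renormalized to unit
Euclidean norm at load time so that cosine distance reduces to
``1 - dot(u, v)``.

The on-disk format is a flat delimited text table with one row per
(image, ensemble member)::

    image_id, subject_id, syndrome_id, member_index, v0001 .. v<d>

Comma or tab delimited, auto-detected from the file extension
(``.tsv``/``.tab`` -> tab, anything else -> comma).  Floats are written in
shortest round-trip decimal form, which makes write -> load -> write
byte-stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GalleryError",
    "ImageEncoding",
    "Gallery",
    "Cohort",
    "RunConfig",
    "load_gallery",
    "write_gallery",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

_NORM_TOL = 1e-9


class GalleryError(ValueError):
    """Structured load/validation error.

    Carries the offending row number (1-based, counting the header as row 1)
    and field name when they are known, so callers can report the exact
    location of a malformed record.
    """

    def __init__(self, message: str, *, row: int | None = None, fieldname: str | None = None):
        self.row = row
        self.fieldname = fieldname
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if fieldname is not None:
            prefix += f"field {fieldname!r}: "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class ImageEncoding:
    """One image's ensemble of unit-norm embedding vectors.

    Parameters
    ----------
    image_id, subject_id, syndrome_id
        Opaque string labels.  ``image_id`` must be unique within a gallery;
        each image carries exactly one syndrome label.
    vectors
        Array of shape ``(m, d)``.  Rows are renormalized to unit norm on
        construction; a zero-norm row is an error.
    """

    image_id: str
    subject_id: str
    syndrome_id: str
    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2:
            raise GalleryError(
                f"image {self.image_id!r}: vectors must be 2-D (m, d), got ndim={v.ndim}"
            )
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0.0) or not np.all(np.isfinite(norms)):
            bad = int(np.flatnonzero((norms == 0.0) | ~np.isfinite(norms))[0])
            raise GalleryError(
                f"image {self.image_id!r}, member {bad + 1}: zero-norm or non-finite vector"
            )
        # renormalize, but leave already-unit rows untouched so that a
        # write -> load cycle does not perturb last bits (byte-stable I/O)
        needs = np.abs(norms - 1.0) > 1e-12
        if np.any(needs):
            v = v.copy()
            v[needs] /= norms[needs, None]
        object.__setattr__(self, "vectors", v)

    @property
    def m(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


class Gallery:
    """Indexed collection of :class:`ImageEncoding` with a syndrome index.

    Invariants: image ids unique; uniform ensemble size ``m`` and dimension
    ``d``; the syndrome index partitions the image ids exactly.
    """

    def __init__(self, encodings: Iterable[ImageEncoding]):
        self.encodings: list[ImageEncoding] = list(encodings)
        self._by_id: dict[str, ImageEncoding] = {}
        for enc in self.encodings:
            if enc.image_id in self._by_id:
                raise GalleryError(f"duplicate image_id {enc.image_id!r}")
            self._by_id[enc.image_id] = enc
        if self.encodings:
            m0, d0 = self.encodings[0].m, self.encodings[0].d
            for enc in self.encodings:
                if (enc.m, enc.d) != (m0, d0):
                    raise GalleryError(
                        f"image {enc.image_id!r}: ensemble shape ({enc.m}, {enc.d}) "
                        f"differs from gallery shape ({m0}, {d0})"
                    )
            self.m, self.d = m0, d0
        else:
            self.m, self.d = 0, 0
        self.syndrome_index: dict[str, list[str]] = {}
        for enc in self.encodings:
            self.syndrome_index.setdefault(enc.syndrome_id, []).append(enc.image_id)

    def __len__(self) -> int:
        return len(self.encodings)

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._by_id

    def __getitem__(self, image_id: str) -> ImageEncoding:
        return self._by_id[image_id]

    @property
    def image_ids(self) -> list[str]:
        return [enc.image_id for enc in self.encodings]

    def syndromes(self, min_size: int = 1) -> dict[str, list[str]]:
        """Syndrome index restricted to syndromes with at least ``min_size`` images."""
        return {s: ids for s, ids in self.syndrome_index.items() if len(ids) >= min_size}

    def merged_with(self, other: "Gallery") -> "Gallery":
        """New gallery holding this gallery's encodings followed by ``other``'s."""
        return Gallery(self.encodings + other.encodings)

    def vector_stack(self) -> np.ndarray:
        """All vectors as one array of shape (n_images, m, d), in gallery order."""
        if not self.encodings:
            return np.zeros((0, self.m, self.d))
        return np.stack([enc.vectors for enc in self.encodings])


@dataclass(frozen=True)
class Cohort:
    """Ordered list of distinct image ids; the target group under test."""

    members: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        if len(set(self.members)) != len(self.members):
            dupes = sorted({x for x in self.members if self.members.count(x) > 1})
            raise GalleryError(f"duplicate cohort member(s): {dupes}")

    @property
    def n(self) -> int:
        return len(self.members)


def validate_cohort(cohort: Cohort, gallery: Gallery, *, min_n: int = 2) -> Cohort:
    """Check that a cohort is usable against ``gallery`` for distance statistics.

    Members must be distinct (enforced by :class:`Cohort` itself), present in
    the gallery, and number at least ``min_n`` (2 for any pairwise statistic).
    """
    if cohort.n < min_n:
        raise GalleryError(f"cohort has {cohort.n} member(s); need at least {min_n}")
    missing = [x for x in cohort.members if x not in gallery]
    if missing:
        raise GalleryError(f"cohort member(s) not in gallery: {missing}")
    return cohort


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants for a full pipeline run.

    Defaults follow the study conditions: 100 cohorts per (syndrome, size)
    control cell, 10,000 sub-cohort draws for the cohort test, 5-fold
    cross-validation, match cutoff rank 50 and strong-match cutoff 10.
    """

    seed: int = 0
    cohorts_per_cell: int = 100
    cohort_test_reps: int = 10_000
    cv_folds: int = 5
    rank_cutoff: int = 50
    strong_rank_cutoff: int = 10
    threshold_override: float | None = None

    def __post_init__(self):
        for name in ("cohorts_per_cell", "cohort_test_reps", "cv_folds",
                     "rank_cutoff", "strong_rank_cutoff"):
            if int(getattr(self, name)) <= 0:
                raise GalleryError(f"RunConfig.{name} must be positive")
        if self.cv_folds < 2:
            raise GalleryError("RunConfig.cv_folds must be >= 2")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise GalleryError(f"unknown RunConfig key(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Gallery file I/O

_META_COLS = ("image_id", "subject_id", "syndrome_id", "member_index")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _vector_columns(d: int) -> list[str]:
    width = max(4, len(str(d)))
    return [f"v{i + 1:0{width}d}" for i in range(d)]


def write_gallery(gallery: Gallery, path: str | Path) -> None:
    """Write a gallery as delimited text, one row per (image, ensemble member).

    Floats use Python's shortest round-trip ``repr``, so a write/load/write
    cycle is byte-identical.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    cols = list(_META_COLS) + _vector_columns(gallery.d)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join(cols) + "\n")
        for enc in gallery.encodings:
            for k in range(gallery.m):
                head = [enc.image_id, enc.subject_id, enc.syndrome_id, str(k + 1)]
                vals = [repr(float(x)) for x in enc.vectors[k]]
                fh.write(sep.join(head + vals) + "\n")


def load_gallery(path: str | Path,
                 expected_m: int | None = None,
                 expected_d: int | None = None) -> Gallery:
    """Load and validate a gallery file.

    Rows for one image must appear contiguously with member_index 1..m.
    Errors name the offending row (1-based, header = row 1).
    """
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise GalleryError("empty file", row=1)
        header = header_line.rstrip("\n").split(sep)
        if tuple(header[:4]) != _META_COLS:
            raise GalleryError(
                f"expected header starting with {_META_COLS}, got {header[:4]}", row=1
            )
        d = len(header) - 4  # 0 is legal for a header-only (empty) gallery
        if expected_d is not None and d != expected_d:
            raise GalleryError(f"dimension is {d}, expected {expected_d}", row=1)

        # (image_id -> {member_index -> vector}), insertion ordered
        rows: dict[str, dict[int, np.ndarray]] = {}
        labels: dict[str, tuple[str, str]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if d == 0:
                raise GalleryError("data row in a gallery with no vector columns",
                                   row=lineno)
            if len(parts) != 4 + d:
                raise GalleryError(
                    f"has {len(parts) - 4} vector entries, expected {d}",
                    row=lineno, fieldname="vector",
                )
            image_id, subject_id, syndrome_id, midx_s = parts[:4]
            try:
                midx = int(midx_s)
            except ValueError:
                raise GalleryError(f"member_index {midx_s!r} is not an integer",
                                   row=lineno, fieldname="member_index") from None
            try:
                vec = np.array(parts[4:], dtype=np.float64)
            except ValueError:
                raise GalleryError("non-numeric vector entry",
                                   row=lineno, fieldname="vector") from None
            if image_id in rows and midx in rows[image_id]:
                raise GalleryError(
                    f"duplicate image_id/member_index ({image_id!r}, {midx})",
                    row=lineno, fieldname="image_id",
                )
            if image_id in labels and labels[image_id] != (subject_id, syndrome_id):
                raise GalleryError(
                    f"inconsistent labels for image {image_id!r}",
                    row=lineno, fieldname="syndrome_id",
                )
            norm = float(np.linalg.norm(vec))
            if norm == 0.0 or not math.isfinite(norm):
                raise GalleryError("zero-norm or non-finite vector",
                                   row=lineno, fieldname="vector")
            rows.setdefault(image_id, {})[midx] = vec
            labels[image_id] = (subject_id, syndrome_id)

    encodings = []
    for image_id, members in rows.items():
        m = len(members)
        if sorted(members) != list(range(1, m + 1)):
            raise GalleryError(
                f"image {image_id!r}: member_index values {sorted(members)} "
                f"are not 1..{m}"
            )
        if expected_m is not None and m != expected_m:
            raise GalleryError(
                f"image {image_id!r}: ensemble size {m}, expected {expected_m}"
            )
        subject_id, syndrome_id = labels[image_id]
        vectors = np.stack([members[k] for k in range(1, m + 1)])
        encodings.append(ImageEncoding(image_id, subject_id, syndrome_id, vectors))
    return Gallery(encodings)


# ---------------------------------------------------------------------------
# Cohort file I/O: one image_id per line, '#' comments allowed.


def read_cohort(path: str | Path) -> Cohort:
    members = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.append(line)
    return Cohort(tuple(members))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for member in cohort.members:
            fh.write(member + "\n")
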