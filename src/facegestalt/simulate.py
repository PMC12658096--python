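"""Synthetic embedding galleries with syndrome-cluster structure.

Real clinical-photo galleries (syndrome-labelled face embeddings) are not
redistributable, so downstream statistics are exercised on synthetic
galleries that reproduce the structure the analysis relies on:

* each syndrome is a cluster of unit vectors around a random center on the
  ``d``-sphere (Gaussian perturbation followed by renormalization — a
  practical stand-in for a von Mises-Fisher draw whose zero-noise limit is
  exact);
* each ensemble member ``k`` carries a systematic offset ``o_k``, drawn once
  per gallery and shared by all images, mimicking bias of one model in the
  ensemble;
* each (image, member) vector additionally receives independent test-time
  augmentation (TTA) noise.

Stored vector: ``v_ik = normalize(x_i + o_k + sigma_tta * e_ik)`` where
``x_i = normalize(c_s + sigma_within * g_i)`` is the image's latent
direction in its syndrome cluster.

Because Gaussian perturbations act per coordinate, the angular scale of a
dispersion parameter ``sigma`` grows with ``sqrt(d)``: at d=512 the expected
within-cluster cosine distance is roughly ``1 - 1/(1 + sigma^2 d)``, so
sigma near 0.12 gives the weak clustering (within-syndrome distances ~0.85,
random pairs ~1.0) typical of facial-gestalt embeddings, while sigma below
~0.05 gives tight, easily recovered clusters.

Randomness is split into named substreams (centers, latents, member offsets,
TTA noise) so that, e.g., changing the TTA noise level leaves cluster
centers untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gallery import Cohort, Gallery, GalleryError, ImageEncoding

__all__ = ["SimConfig", "generate_gallery", "generate_cohort", "default_gallery_config"]

# Substream labels appended to the user seed; fixed so that results are
# reproducible across sessions and independent across streams.
_STREAM_CENTERS = 1
_STREAM_LATENTS = 2
_STREAM_OFFSETS = 3
_STREAM_TTA = 4


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic gallery.

    ``images_per_syndrome`` may be a single int or a per-syndrome sequence of
    length ``n_syndromes``.  All sigmas are per-coordinate standard
    deviations (see module docstring for the angular scale at dimension d).
    """

    n_syndromes: int
    images_per_syndrome: int | Sequence[int]
    d: int = 512
    m: int = 12
    sigma_within: float = 0.12
    sigma_member: float = 0.02
    sigma_tta: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_syndromes < 1:
            raise GalleryError("n_syndromes must be >= 1")
        if min(self.syndrome_sizes()) < 1:
            raise GalleryError("every syndrome needs >= 1 image")
        if min(self.sigma_within, self.sigma_member, self.sigma_tta) < 0:
            raise GalleryError("sigmas must be non-negative")
        if self.d < 1 or self.m < 1:
            raise GalleryError("d and m must be >= 1")

    def syndrome_sizes(self) -> list[int]:
        if isinstance(self.images_per_syndrome, int):
            return [self.images_per_syndrome] * self.n_syndromes
        sizes = [int(x) for x in self.images_per_syndrome]
        if len(sizes) != self.n_syndromes:
            raise GalleryError(
                f"images_per_syndrome has {len(sizes)} entries for "
                f"{self.n_syndromes} syndromes"
            )
        return sizes


def default_gallery_config(seed: int = 0) -> SimConfig:
    """Control-gallery configuration emulating the reference gallery's shape.

    328 syndromes totalling 1,555 images (243 syndromes of 5 images and 85 of
    4), twelve 512-d vectors per image, with the weak within-syndrome
    clustering described in the module docstring.
    """
    sizes = [5] * 243 + [4] * 85
    return SimConfig(n_syndromes=328, images_per_syndrome=sizes, seed=seed)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _normalize(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def _member_offsets(config: SimConfig) -> np.ndarray:
    """Per-ensemble-member systematic offsets, shape (m, d); drawn once per gallery."""
    rng = _rng(config.seed, _STREAM_OFFSETS)
    return config.sigma_member * rng.standard_normal((config.m, config.d))


def _encode(latents: np.ndarray, offsets: np.ndarray, sigma_tta: float,
            rng_tta: np.random.Generator) -> np.ndarray:
    """Stored vectors (n, m, d) from latent directions (n, d) and offsets (m, d)."""
    n, d = latents.shape
    m = offsets.shape[0]
    noise = sigma_tta * rng_tta.standard_normal((n, m, d)) if sigma_tta > 0 else 0.0
    return _normalize(latents[:, None, :] + offsets[None, :, :] + noise)


def generate_gallery(config: SimConfig) -> Gallery:
    """Generate a synthetic gallery; deterministic under ``config.seed``.

    Syndromes are labelled ``syn_001``... and images ``img_0001``... in draw
    order.  Subject ids equal image ids (one image per subject).
    """
    sizes = config.syndrome_sizes()
    n_images = sum(sizes)
    rng_centers = _rng(config.seed, _STREAM_CENTERS)
    rng_latents = _rng(config.seed, _STREAM_LATENTS)
    rng_tta = _rng(config.seed, _STREAM_TTA)
    offsets = _member_offsets(config)

    syn_w = max(3, len(str(config.n_syndromes)))
    img_w = max(4, len(str(n_images)))

    centers = _normalize(rng_centers.standard_normal((config.n_syndromes, config.d)))
    encodings: list[ImageEncoding] = []
    img_no = 0
    for s, size in enumerate(sizes):
        g = rng_latents.standard_normal((size, config.d))
        latents = _normalize(centers[s] + config.sigma_within * g)
        vectors = _encode(latents, offsets, config.sigma_tta, rng_tta)
        syndrome_id = f"syn_{s + 1:0{syn_w}d}"
        for i in range(size):
            img_no += 1
            image_id = f"img_{img_no:0{img_w}d}"
            encodings.append(ImageEncoding(image_id, image_id, syndrome_id, vectors[i]))
    return Gallery(encodings)


def generate_cohort(gallery_config: SimConfig, cohort_size: int, dispersion: float,
                    seed: int, syndrome_id: str = "target_cohort") -> tuple[Gallery, Cohort]:
    """Draw a fresh target cohort compatible with an existing synthetic gallery.

    The cohort's images cluster around a new random center with the given
    ``dispersion`` (same role as ``sigma_within``) and reuse the *gallery's*
    per-member offsets, so cohort and gallery encodings live in the same
    ensemble geometry.  ``dispersion`` much greater than 1 makes members
    mutually independent random directions.

    Returns the cohort encodings as a small :class:`Gallery` (merge with the
    background via :meth:`Gallery.merged_with`) plus the :class:`Cohort` of
    their ids.
    """
    if cohort_size < 2:
        raise GalleryError("cohort_size must be >= 2")
    if dispersion < 0:
        raise GalleryError("dispersion must be non-negative")
    offsets = _member_offsets(gallery_config)
    rng_center = _rng(seed, _STREAM_CENTERS)
    rng_latents = _rng(seed, _STREAM_LATENTS)
    rng_tta = _rng(seed, _STREAM_TTA)

    center = _normalize(rng_center.standard_normal(gallery_config.d))
    g = rng_latents.standard_normal((cohort_size, gallery_config.d))
    latents = _normalize(center + dispersion * g)
    vectors = _encode(latents, offsets, gallery_config.sigma_tta, rng_tta)

    w = max(2, len(str(cohort_size)))
    encodings = []
    ids = []
    for i in range(cohort_size):
        image_id = f"cohort_{i + 1:0{w}d}"
        ids.append(image_id)
        encodings.append(ImageEncoding(image_id, image_id, syndrome_id, vectors[i]))
    return Gallery(encodings), Cohort(tuple(ids))
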