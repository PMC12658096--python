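import numpy as np
import pytest

from facegestalt import Gallery, ImageEncoding, SimConfig, generate_gallery


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@pytest.fixture
def tiny_gallery():
    """Four images, two syndromes, m=2, d=3, hand-built vectors."""
    e1 = np.eye(3)

    def enc(image_id, syndrome, v0, v1):
        return ImageEncoding(image_id, image_id, syndrome, np.stack([unit(v0), unit(v1)]))

    return Gallery([
        enc("a", "synA", e1[0], e1[1]),
        enc("b", "synA", e1[0], e1[1]),
        enc("c", "synB", e1[1], e1[2]),
        enc("d", "synB", [1.0, 1.0, 0.0], e1[2]),
    ])


@pytest.fixture
def sim_gallery():
    """Small clustered synthetic gallery: 6 syndromes x 5 images, d=32, m=4."""
    cfg = SimConfig(n_syndromes=6, images_per_syndrome=5, d=32, m=4,
                    sigma_within=0.08, sigma_member=0.03, sigma_tta=0.02, seed=3)
    return generate_gallery(cfg)
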