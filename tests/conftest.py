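import numpy as np
import pytest

from mandiseg.geometry import build_mandibular_planes, build_reference_frame
from mandiseg.phantom import PhantomSpec, generate_phantom
from mandiseg.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def default_phantom():
    """Default symmetric phantom at the acquisition spacing (0.4 mm)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default-shape phantom at 0.8 mm, cheap enough for repeated reuse."""
    return generate_phantom(PhantomSpec(spacing=0.8))


@pytest.fixture(scope="session")
def fine_phantom():
    """Default phantom at half the acquisition spacing (0.2 mm)."""
    return generate_phantom(PhantomSpec(spacing=0.2))


@pytest.fixture(scope="session")
def asymmetric_phantom():
    return generate_phantom(
        PhantomSpec(s_condyle_L=0.7, s_ramus_L=0.85, spacing=0.8)
    )


@pytest.fixture(scope="session")
def canonical_landmarks(coarse_phantom):
    return coarse_phantom.landmarks


@pytest.fixture(scope="session")
def canonical_frame(canonical_landmarks):
    return build_reference_frame(canonical_landmarks)


@pytest.fixture(scope="session")
def canonical_planes(canonical_landmarks, canonical_frame):
    return {
        side: build_mandibular_planes(canonical_landmarks, canonical_frame,
                                      side)
        for side in ("L", "R")
    }


@pytest.fixture
def no_closing_config():
    """Pipeline config without morphological closing (the phantoms carry
    no canal to seal, so accuracy comparisons are discretization-only)."""
    return PipelineConfig(closing_radius_mm=0.0)


def random_rigid_transform(rng):
    """Uniformly random rotation (QR-based) plus a bounded translation."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return Q, t
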