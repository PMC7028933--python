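import numpy as np
import pytest

from icbrad import LabeledVolume, render_phantom


def digitized_sphere(radius_mm: float, spacing: float,
                     intensity: float = 100.0) -> LabeledVolume:
    """Sphere mask built directly from voxel-center distances (no phantom
    machinery) — the geometric ground truth for closed-form checks."""
    n = int(np.ceil(2 * radius_mm / spacing)) + 7
    ax = (np.arange(n) - (n - 1) / 2.0) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = X ** 2 + Y ** 2 + Z ** 2 <= radius_mm ** 2
    rng = np.random.default_rng(0)
    img = np.full(mask.shape, 20.0)
    img[mask] = intensity + rng.normal(0, 5, size=int(mask.sum()))
    return LabeledVolume(img, mask, (spacing,) * 3)


@pytest.fixture(scope="session")
def sphere_r10_coarse() -> LabeledVolume:
    return digitized_sphere(10.0, 1.0)


@pytest.fixture(scope="session")
def sphere_r10_fine() -> LabeledVolume:
    return digitized_sphere(10.0, 0.5)


@pytest.fixture(scope="session")
def small_blob() -> LabeledVolume:
    """An irregular ~12 mm³ blob on a 48³ grid — the cheap all-purpose input."""
    return render_phantom(12.0, 0.25, seed=42, shape=(48, 48, 48),
                          spacing=(0.12, 0.12, 0.12))
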