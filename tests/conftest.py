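import numpy as np
import pytest

import scarshape as ss
from scarshape.classify import ThresholdConfig, TissueLabelField


@pytest.fixture(scope="session")
def noise_free_spec() -> ss.PhantomSpec:
    """Default-geometry phantom with one channelled scar patch, no noise."""
    patch = ss.ScarPatchSpec(channels=(ss.ChannelSpec(width_mm=5.0),))
    return ss.PhantomSpec(scar_patches=(patch,), noise_sigma=0.0)


@pytest.fixture(scope="session")
def noise_free_stack(noise_free_spec) -> ss.LGEStack:
    return ss.generate_phantom(noise_free_spec)


@pytest.fixture(scope="session")
def spherical_spec() -> ss.PhantomSpec:
    """Spherical shell at isotropic spacing: analytic-oracle geometry."""
    return ss.PhantomSpec(
        grid_shape=(64, 64, 56),
        spacing=(1.3, 1.3, 1.3),
        endo_radii=(20.0, 20.0, 20.0),
        epi_radii=(30.0, 30.0, 30.0),
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def spherical_stack(spherical_spec) -> ss.LGEStack:
    return ss.generate_phantom(spherical_spec)


def make_label_field(labels: np.ndarray, spacing=(1.3, 1.3, 5.0)) -> TissueLabelField:
    """Wrap an integer label array (-1 outside mask) as a TissueLabelField."""
    labels = np.asarray(labels, dtype=np.int8)
    return TissueLabelField(
        labels=labels,
        mask=labels >= 0,
        config=ThresholdConfig(40.0, 60.0),
        spacing=spacing,
    )


def sphere_core_field(radius_mm=10.0, spacing=(1.3, 1.3, 1.3)) -> TissueLabelField:
    """An all-BZ block with an embedded spherical core of given radius."""
    sp = np.asarray(spacing, float)
    shape = tuple(int(np.ceil(2 * (radius_mm + 6.0) / s)) for s in sp)
    center = (np.asarray(shape) - 1) / 2 * sp
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)), indexing="ij")
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    labels = np.full(shape, ss.BZ, dtype=np.int8)
    labels[r <= radius_mm] = ss.CORE
    return make_label_field(labels, spacing=tuple(sp))
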