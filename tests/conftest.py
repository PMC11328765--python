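import numpy as np
import pytest

from confluencemorph.morphometry import quantify
from confluencemorph.phantom import PhantomConfig, make_phantom

SLAB = dict(kind="slab", confluence_length=30.0, gap=3.0, r_confluence=2.5, spacing=0.5)
SPHERE_ARC = dict(
    kind="sphere_arc", la_radius=20.0, gap=2.0, theta=1.0, r_confluence=1.6, spacing=0.5
)


@pytest.fixture(scope="session")
def slab_phantom():
    """Reference slab phantom: L=30 mm confluence at d=3 mm from a flat LA."""
    return make_phantom(PhantomConfig(**SLAB))


@pytest.fixture(scope="session")
def sphere_phantom():
    """Reference concentric-arc phantom: R=20 mm LA, g=2 mm, theta=1 rad."""
    return make_phantom(PhantomConfig(**SPHERE_ARC))


@pytest.fixture(scope="session")
def slab_quantified(slab_phantom):
    vol, truth = slab_phantom
    metrics, cs = quantify(vol, bsa_m2=0.26)
    return metrics, cs, truth


@pytest.fixture(scope="session")
def sphere_quantified(sphere_phantom):
    vol, truth = sphere_phantom
    metrics, cs = quantify(vol, bsa_m2=0.26)
    return metrics, cs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240625)
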