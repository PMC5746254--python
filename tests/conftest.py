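import numpy as np
import pytest

from plaidnet.builder import TorusGeometry, place_population


@pytest.fixture
def small_layout():
    """A 120-neuron population on a small torus (fast builder tests)."""
    return place_population(120, TorusGeometry(600.0, 600.0), seed=42)


@pytest.fixture
def medium_layout():
    """An 800-neuron population at cortical density for statistics."""
    from plaidnet.pipeline import scaled_geometry
    return place_population(800, scaled_geometry(800), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
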