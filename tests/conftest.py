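import numpy as np
import pytest

from megnet.connectivity import SpectralParams
from megnet.core import SourceSeriesSet
from megnet.synthetic import CouplingSpec, generate_coupled_sources, generate_toy_graph

FS = 200.0
DURATION = 60.0


@pytest.fixture(scope="session")
def params() -> SpectralParams:
    return SpectralParams()


@pytest.fixture(scope="session")
def coupled_pair() -> SourceSeriesSet:
    """Two ROIs sharing a noiseless 10 Hz oscillation at lag pi/4."""
    spec = CouplingSpec(pairs=((0, 1, 10.0, np.pi / 4, 1.0),), noise_sd=0.0)
    return generate_coupled_sources(spec, 2, DURATION, FS, seed=1)


@pytest.fixture(scope="session")
def zero_lag_pair() -> SourceSeriesSet:
    spec = CouplingSpec(pairs=((0, 1, 10.0, 0.0, 1.0),), noise_sd=0.0)
    return generate_coupled_sources(spec, 2, DURATION, FS, seed=1)


@pytest.fixture(scope="session")
def noise_pair() -> SourceSeriesSet:
    spec = CouplingSpec(pairs=(), noise_sd=1.0)
    return generate_coupled_sources(spec, 2, DURATION, FS, seed=7)


@pytest.fixture(scope="session")
def toy_graphs() -> dict:
    return {
        "complete4": generate_toy_graph("complete", n_nodes=4),
        "star5": generate_toy_graph("star", n_nodes=5),
        "path3": generate_toy_graph("path", n_nodes=3),
        "ring8": generate_toy_graph("ring", n_nodes=8),
        "club20": generate_toy_graph("planted_club", n_nodes=20, club_size=5),
        "two_cliques5": generate_toy_graph("two_cliques", clique_size=5),
    }
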