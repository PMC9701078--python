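import numpy as np
import pytest

from vagchip.chip_transport import ChipGeometry, TransportParams, build_grid


@pytest.fixture(scope="session")
def geometry():
    return ChipGeometry()


@pytest.fixture(scope="session")
def params():
    return TransportParams()


@pytest.fixture(scope="session")
def coarse_grid(geometry, params):
    """Small grid for fast solver tests."""
    return build_grid(geometry, nx=40, ny=70, params=params)


def random_reads(rng: np.random.Generator, n: int, length: int = 100):
    """Random reads with qualities spanning the trimming threshold."""
    from vagchip.strain_composition import QualityRead

    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        m = int(rng.integers(1, length))
        seq = "".join(bases[rng.integers(0, 4, m)])
        quals = tuple(int(q) for q in rng.integers(2, 41, m))
        out.append(QualityRead(f"r{i}", seq, quals))
    return out
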