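import numpy as np
import pytest

from tsqscreen import (
    PortfolioSpec,
    generate_hueckel_aom,
    generate_portfolio,
    generate_ring_geometry,
)


@pytest.fixture(scope="session")
def benzene_aom():
    """Closed-shell Hueckel benzene pi system: 6 sites, 3 doubly occupied MOs."""
    return generate_hueckel_aom(6, (3, 3), compound_id="benzene")


@pytest.fixture(scope="session")
def cot_aom():
    """Triplet-like open-shell Hueckel 8-cycle with (5, 3) filling."""
    return generate_hueckel_aom(8, (5, 3), compound_id="cot")


@pytest.fixture(scope="session")
def portfolio():
    """Default-composition synthetic portfolio with planted truth labels."""
    records, truth = generate_portfolio(PortfolioSpec(seed=7))
    return records, truth


@pytest.fixture()
def puckered_octagon():
    return generate_ring_geometry(
        8, pucker_amplitude=0.3, mode="tub", jitter=0.05, seed=11, compound_id="oct"
    )


def dihedral_oracle(p0, p1, p2, p3):
    """Independent signed-dihedral routine: angle between half-planes
    measured in the plane orthogonal to the central bond (Gram-Schmidt
    projection + atan2), distinct from the cross-product implementation."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b = p2 - p1
    b /= np.linalg.norm(b)
    u = (p0 - p1) - np.dot(p0 - p1, b) * b
    w = (p3 - p2) - np.dot(p3 - p2, b) * b
    x = np.dot(u, w)
    y = np.dot(np.cross(b, u), w)
    return float(np.degrees(np.arctan2(y, x)))
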