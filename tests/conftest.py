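import pytest

from papdiff import CylinderGeometry, PhysicalConstants


@pytest.fixture(scope="session")
def geom() -> CylinderGeometry:
    """Reference cylinder: L = 1000 nm, D = 100 nm."""
    return CylinderGeometry()


@pytest.fixture(scope="session")
def constants() -> PhysicalConstants:
    """Reference constants: Dab = 300 um^2/s, 0.8 s degradation horizon."""
    return PhysicalConstants()


@pytest.fixture(scope="session")
def volume_l(geom: CylinderGeometry) -> float:
    return geom.volume_l
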